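"""Naive pure-Python reference implementation of the per-locus estimators.

Deliberately written with plain loops and no shared code with the package,
so it can serve as an independent oracle for the vectorised estimators.
"""

from __future__ import annotations

import math


def naive_locus_stats(pops: list[list[tuple[int, int] | None]]) -> dict:
    """Nei–Chesser components for one locus.

    ``pops`` is a list of populations, each a list of calls; a call is an
    (a, b) allele pair or None for missing.  Populations with fewer than
    two typed calls are excluded.  Returns ho/hs/ht/fst/fis (NaN when
    undefined) plus the retained population count.
    """
    kept = []
    for calls in pops:
        typed = [c for c in calls if c is not None]
        if len(typed) >= 2:
            kept.append(typed)
    if not kept:
        return dict(
            ho=math.nan, hs=math.nan, ht=math.nan, fst=math.nan,
            fis=math.nan, n_pops=0,
        )

    ho_k, hs_k, freqs_k, n_k = [], [], [], []
    for typed in kept:
        n = len(typed)
        ho = sum(1 for a, b in typed if a != b) / n
        counts: dict[int, int] = {}
        for a, b in typed:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        p = {al: c / (2 * n) for al, c in counts.items()}
        sum_p2 = sum(v * v for v in p.values())
        hs = (n / (n - 1)) * (1 - sum_p2 - ho / (2 * n))
        ho_k.append(ho)
        hs_k.append(hs)
        freqs_k.append(p)
        n_k.append(n)

    np_ = len(kept)
    ho = sum(ho_k) / np_
    hs = sum(hs_k) / np_
    if np_ >= 2:
        n_tilde = np_ / sum(1 / n for n in n_k)
        alleles = set()
        for p in freqs_k:
            alleles |= set(p)
        p_bar = {al: sum(p.get(al, 0.0) for p in freqs_k) / np_ for al in alleles}
        ht = (
            1
            - sum(v * v for v in p_bar.values())
            + hs / (n_tilde * np_)
            - ho / (2 * n_tilde * np_)
        )
        fst = (ht - hs) / ht if ht > 0 else math.nan
    else:
        ht = math.nan
        fst = math.nan
    fis = 1 - ho / hs if hs > 0 else math.nan
    return dict(ho=ho, hs=hs, ht=ht, fst=fst, fis=fis, n_pops=np_)


def matrix_to_pops(gm) -> list[list[list[tuple[int, int] | None]]]:
    """Per-locus nested call lists from a GenotypeMatrix, for the oracle."""
    out = []
    idx = gm.pop_indices()
    for j in range(gm.n_loci):
        locus = []
        for members in idx.values():
            calls = []
            for i in members:
                a, b = (int(x) for x in gm.calls[i, j])
                calls.append(None if a < 0 else (a, b))
            locus.append(calls)
        out.append(locus)
    return out
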