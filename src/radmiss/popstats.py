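"""F-statistics and heterozygosities per locus and multilocus under missing data.

Default estimator: Nei / Nei–Chesser sample-size-corrected gene diversities.
Per locus, for each population k with n_k >= 2 typed individuals,

    Ho_k = heterozygote fraction among typed individuals
    Hs_k = n_k/(n_k - 1) * (1 - sum_i p_{k,i}^2 - Ho_k / (2 n_k))

and across the np populations retained at the locus (harmonic mean sample
size n~, mean frequencies p_bar):

    ho = mean_k Ho_k
    hs = mean_k Hs_k
    ht = 1 - sum_i p_bar_i^2 + hs/(n~ * np) - ho/(2 * n~ * np)
    fst = (ht - hs) / ht        (defined when np >= 2 and ht > 0)
    fis = 1 - ho / hs           (defined when hs > 0)

Populations with fewer than two typed individuals at a locus are excluded
from that locus (the unbiased Hs needs n >= 2); loci typed in fewer than
two populations have no fst, flagged as undefined rather than zeroed.

Multilocus values are ratios of averages, never averages of ratios: the
components ho, hs, ht are averaged over the usable loci and the F-statistics
recomputed from those averages.

The Weir–Cockerham (1984) theta estimator is provided as an explicit
alternative (variance components a, b, c per allele, summed within and
across loci).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matrix import GenotypeMatrix

__all__ = [
    "LocusComponents",
    "LocusStats",
    "MultilocusStats",
    "locus_components",
    "per_locus_stats",
    "multilocus_stats",
    "multilocus_from_matrix",
    "wc_theta",
    "pairwise_one_vs_rest",
    "fis_from_het",
    "per_location_stats",
    "LocationStats",
    "stat_histogram",
    "Histogram",
]


# ---------------------------------------------------------------------------
# per-locus components (vectorised core)


@dataclass
class LocusComponents:
    """Vectorised per-locus diversity components for a genotype matrix.

    All arrays are length L (or K x L for per-population pieces); undefined
    entries are NaN.  This is the working representation shared by the
    multilocus aggregator and the resampling machinery, which only ever
    needs to re-average these components over locus subsets.
    """

    locus_ids: list[str]
    pop_labels: list[str]
    n_typed: np.ndarray        # (K, L) typed individuals per pop per locus
    ho_pop: np.ndarray         # (K, L) observed het, NaN where n_k < 2
    hs_pop: np.ndarray         # (K, L) unbiased gene diversity, NaN where n_k < 2
    n_pops_used: np.ndarray    # (L,) populations with n_k >= 2
    ho: np.ndarray             # (L,) mean Ho over used pops
    hs: np.ndarray             # (L,)
    ht: np.ndarray             # (L,) NaN where n_pops_used < 2
    fst: np.ndarray            # (L,) NaN where undefined (ht <= 0 or < 2 pops)
    fis: np.ndarray            # (L,) NaN where undefined (hs <= 0)

    @property
    def usable(self) -> np.ndarray:
        """Loci that enter multilocus aggregation (typed in >= 2 pops)."""
        return self.n_pops_used >= 2


def _pop_allele_stats(gm: GenotypeMatrix):
    """Per-population typed counts, het counts and allele frequencies.

    Returns (pop_labels, n_typed (K,L), ho_raw (K,L), p (K,L,A)).
    ho_raw and p are NaN where a population has no typed individual.
    """
    pops = gm.pop_indices()
    k, l = len(pops), gm.n_loci
    n_alleles = max(gm.n_alleles(), 1)
    typed = gm.typed
    het = gm.heterozygous
    n_typed = np.empty((k, l))
    het_count = np.empty((k, l))
    counts = np.zeros((k, l, n_alleles))
    for ki, idx in enumerate(pops.values()):
        n_typed[ki] = typed[idx].sum(axis=0)
        het_count[ki] = het[idx].sum(axis=0)
        c0 = gm.calls[idx, :, 0]
        c1 = gm.calls[idx, :, 1]
        for a in range(n_alleles):
            counts[ki, :, a] = (c0 == a).sum(axis=0) + (c1 == a).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho_raw = het_count / n_typed
        p = counts / (2.0 * n_typed)[:, :, None]
    return list(pops.keys()), n_typed, ho_raw, p


def locus_components(gm: GenotypeMatrix) -> LocusComponents:
    """Compute Nei–Chesser per-locus components for every locus at once."""
    pop_labels, n_typed, ho_raw, p = _pop_allele_stats(gm)
    include = n_typed >= 2  # (K, L)

    with np.errstate(invalid="ignore", divide="ignore"):
        sum_p2 = (p**2).sum(axis=2)
        hs_pop = (n_typed / (n_typed - 1.0)) * (
            1.0 - sum_p2 - ho_raw / (2.0 * n_typed)
        )
    ho_pop = np.where(include, ho_raw, np.nan)
    hs_pop = np.where(include, hs_pop, np.nan)

    n_pops = include.sum(axis=0).astype(float)  # (L,)
    with np.errstate(invalid="ignore", divide="ignore"):
        # harmonic mean of the retained sample sizes
        inv_n = np.where(include, 1.0 / n_typed, 0.0).sum(axis=0)
        n_tilde = n_pops / inv_n
        ho = np.where(include, ho_raw, 0.0).sum(axis=0) / n_pops
        hs = np.where(include, np.nan_to_num(hs_pop), 0.0).sum(axis=0) / n_pops
        p_bar = (
            np.where(include[:, :, None], np.nan_to_num(p), 0.0).sum(axis=0)
            / n_pops[:, None]
        )
        ht = (
            1.0
            - (p_bar**2).sum(axis=1)
            + hs / (n_tilde * n_pops)
            - ho / (2.0 * n_tilde * n_pops)
        )
    ho = np.where(n_pops >= 1, ho, np.nan)
    hs = np.where(n_pops >= 1, hs, np.nan)
    ht = np.where(n_pops >= 2, ht, np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / ht, np.nan)
        fis = np.where(hs > 0, 1.0 - ho / hs, np.nan)

    return LocusComponents(
        locus_ids=list(gm.locus_ids),
        pop_labels=pop_labels,
        n_typed=n_typed,
        ho_pop=ho_pop,
        hs_pop=hs_pop,
        n_pops_used=n_pops,
        ho=ho,
        hs=hs,
        ht=ht,
        fst=fst,
        fis=fis,
    )


# ---------------------------------------------------------------------------
# public per-locus / multilocus surfaces


@dataclass
class LocusStats:
    """Diversity statistics for one locus; NaN marks an undefined value."""

    locus_id: str
    n_typed_per_pop: dict[str, int]
    ho: float
    hs: float
    ht: float
    fst: float
    fis: float

    @property
    def fst_defined(self) -> bool:
        return not math.isnan(self.fst)

    @property
    def fis_defined(self) -> bool:
        return not math.isnan(self.fis)


def per_locus_stats(gm: GenotypeMatrix) -> list[LocusStats]:
    """Nei–Chesser heterozygosities and F-statistics for every locus."""
    c = locus_components(gm)
    out = []
    for j, lid in enumerate(c.locus_ids):
        out.append(
            LocusStats(
                locus_id=lid,
                n_typed_per_pop={
                    p: int(c.n_typed[k, j]) for k, p in enumerate(c.pop_labels)
                },
                ho=float(c.ho[j]),
                hs=float(c.hs[j]),
                ht=float(c.ht[j]),
                fst=float(c.fst[j]),
                fis=float(c.fis[j]),
            )
        )
    return out


@dataclass
class MultilocusStats:
    """Ratio-of-averages multilocus statistics.

    ho_bar, hs_bar, ht_bar are means over the usable loci (typed in >= 2
    populations); fst = (ht_bar - hs_bar)/ht_bar and fis = 1 - ho_bar/hs_bar
    are recomputed from those means.
    """

    ho_bar: float
    hs_bar: float
    ht_bar: float
    fst: float
    fis: float
    n_loci_used: int


def _aggregate(ho, hs, ht, usable) -> MultilocusStats:
    n_used = int(usable.sum())
    if n_used == 0:
        raise ValueError("no usable loci (none typed in >= 2 populations)")
    ho_bar = float(np.mean(ho[usable]))
    hs_bar = float(np.mean(hs[usable]))
    ht_bar = float(np.mean(ht[usable]))
    fst = (ht_bar - hs_bar) / ht_bar if ht_bar > 0 else math.nan
    fis = 1.0 - ho_bar / hs_bar if hs_bar > 0 else math.nan
    return MultilocusStats(ho_bar, hs_bar, ht_bar, fst, fis, n_used)


def multilocus_stats(
    loci: Sequence[LocusStats] | LocusComponents,
) -> MultilocusStats:
    """Aggregate per-locus components into multilocus statistics.

    Accepts either the list from :func:`per_locus_stats` or the vectorised
    :class:`LocusComponents`.
    """
    if isinstance(loci, LocusComponents):
        return _aggregate(loci.ho, loci.hs, loci.ht, loci.usable)
    ho = np.array([s.ho for s in loci])
    hs = np.array([s.hs for s in loci])
    ht = np.array([s.ht for s in loci])
    usable = ~np.isnan(ht)
    return _aggregate(ho, hs, ht, usable)


def multilocus_from_matrix(gm: GenotypeMatrix) -> MultilocusStats:
    """Convenience: multilocus statistics straight from a matrix."""
    return multilocus_stats(locus_components(gm))


# ---------------------------------------------------------------------------
# Weir–Cockerham (1984) theta


@dataclass
class WcTheta:
    per_locus: np.ndarray  # (L,) theta per locus, NaN where undefined
    overall: float         # components pooled over loci and alleles
    locus_ids: list[str] = field(default_factory=list)
    # per-locus pooled variance components (NaN where undefined), so a
    # locus subset's theta is a_sum[idx].nansum()/abc_sum[idx].nansum()
    a_sum: np.ndarray = field(default_factory=lambda: np.empty(0))
    abc_sum: np.ndarray = field(default_factory=lambda: np.empty(0))


def wc_theta(gm: GenotypeMatrix) -> WcTheta:
    """Weir–Cockerham (1984) theta from variance components a, b, c.

    Components are computed per allele per locus from the populations with
    at least one typed individual; per-locus theta is sum(a)/sum(a+b+c) over
    alleles, overall theta pools components over loci as well.  Loci with
    fewer than two populations typed, or with mean sample size <= 1, are
    undefined.
    """
    pop_labels, n_typed, ho_raw, p = _pop_allele_stats(gm)
    include = n_typed >= 1  # (K, L)

    # h[k, l, a]: frequency of heterozygotes carrying exactly one copy of a
    pops = gm.pop_indices()
    k, l = len(pops), gm.n_loci
    n_alleles = max(gm.n_alleles(), 1)
    h_count = np.zeros((k, l, n_alleles))
    for ki, idx in enumerate(pops.values()):
        c0 = gm.calls[idx, :, 0]
        c1 = gm.calls[idx, :, 1]
        for a in range(n_alleles):
            one_copy = (c0 == a) ^ (c1 == a)
            h_count[ki, :, a] = one_copy.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = h_count / n_typed[:, :, None]

    r = include.sum(axis=0).astype(float)           # (L,)
    n_sum = np.where(include, n_typed, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_sum / r
        n_c = (n_sum - np.where(include, n_typed**2, 0.0).sum(axis=0) / n_sum) / (
            r - 1.0
        )
        w = np.where(include, n_typed, 0.0)[:, :, None]  # weights
        p_filled = np.where(include[:, :, None], p, 0.0)
        p_bar = (w * p_filled).sum(axis=0) / n_sum[:, None]          # (L, A)
        s2 = (w * (p_filled - p_bar[None]) ** 2).sum(axis=0) / (
            (r - 1.0)[:, None] * n_bar[:, None]
        )
        h_filled = np.where(include[:, :, None], h, 0.0)
        h_bar = (w * h_filled).sum(axis=0) / n_sum[:, None]          # (L, A)

        pq = p_bar * (1.0 - p_bar)
        rr = ((r - 1.0) / r)[:, None]
        a_comp = (n_bar / n_c)[:, None] * (
            s2
            - (1.0 / (n_bar - 1.0))[:, None] * (pq - rr * s2 - h_bar / 4.0)
        )
        b_comp = (n_bar / (n_bar - 1.0))[:, None] * (
            pq - rr * s2 - ((2.0 * n_bar - 1.0) / (4.0 * n_bar))[:, None] * h_bar
        )
        c_comp = h_bar / 2.0

    defined = (r >= 2) & (n_bar > 1.0)
    a_comp = np.where(defined[:, None], a_comp, np.nan)
    b_comp = np.where(defined[:, None], b_comp, np.nan)
    c_comp = np.where(defined[:, None], c_comp, np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        num = np.nansum(a_comp, axis=1)
        den = np.nansum(a_comp + b_comp + c_comp, axis=1)
        per_locus = np.where(defined & (den != 0), num / den, np.nan)
        a_sum = np.where(defined, num, np.nan)
        abc_sum = np.where(defined, den, np.nan)
        tot_num = np.nansum(a_sum)
        tot_den = np.nansum(abc_sum)
        overall = float(tot_num / tot_den) if tot_den != 0 else math.nan

    return WcTheta(
        per_locus=per_locus,
        overall=overall,
        locus_ids=list(gm.locus_ids),
        a_sum=a_sum,
        abc_sum=abc_sum,
    )


# ---------------------------------------------------------------------------
# derived analyses


def pairwise_one_vs_rest(gm: GenotypeMatrix, focal: str) -> float:
    """Multilocus fst between ``focal`` and all other individuals pooled."""
    labels = gm.pop_labels
    if focal not in labels:
        raise ValueError(f"unknown population {focal!r}; have {labels}")
    if len(labels) < 2:
        raise ValueError("need at least one non-focal population")
    mapping = {p: ("__rest__" if p != focal else focal) for p in labels}
    return multilocus_from_matrix(gm.with_populations(mapping)).fst


def fis_from_het(ho: float, he: float) -> float:
    """Inbreeding coefficient (He - Ho) / He; NaN when He is zero."""
    if ho < 0 or he < 0:
        raise ValueError("heterozygosities must be non-negative")
    if he == 0:
        return math.nan
    return (he - ho) / he


@dataclass
class LocationStats:
    """Per-population summary: mean Ho over loci and the local F_IS.

    ``ho`` averages Ho over loci with >= 1 typed member; ``he`` and ``fis``
    are restricted to loci where the unbiased Hs is defined (>= 2 typed
    members), with fis = (he - ho_paired)/he computed on that shared set so
    the ratio is internally consistent.
    """

    population: str
    ho: float
    ho_paired: float
    he: float
    fis: float
    n_loci_ho: int
    n_loci_he: int


def per_location_stats(gm: GenotypeMatrix) -> dict[str, LocationStats]:
    """Mean observed heterozygosity and F_IS per sampling location."""
    pop_labels, n_typed, ho_raw, p = _pop_allele_stats(gm)
    with np.errstate(invalid="ignore", divide="ignore"):
        sum_p2 = (p**2).sum(axis=2)
        hs_all = (n_typed / (n_typed - 1.0)) * (
            1.0 - sum_p2 - ho_raw / (2.0 * n_typed)
        )
    out: dict[str, LocationStats] = {}
    for k, pop in enumerate(pop_labels):
        typed_loci = n_typed[k] >= 1
        hs_loci = n_typed[k] >= 2
        ho = float(np.mean(ho_raw[k][typed_loci])) if typed_loci.any() else math.nan
        if hs_loci.any():
            ho_paired = float(np.mean(ho_raw[k][hs_loci]))
            he = float(np.mean(hs_all[k][hs_loci]))
            fis = fis_from_het(ho_paired, he) if he > 0 else math.nan
        else:
            ho_paired = he = fis = math.nan
        out[pop] = LocationStats(
            population=pop,
            ho=ho,
            ho_paired=ho_paired,
            he=he,
            fis=fis,
            n_loci_ho=int(typed_loci.sum()),
            n_loci_he=int(hs_loci.sum()),
        )
    return out


# ---------------------------------------------------------------------------
# per-locus distribution summaries


@dataclass
class Histogram:
    """Half-open-bin histogram of a per-locus statistic.

    ``bin_lo`` holds the lower edge of each bin [lo, lo + width); values
    strictly above ``extreme_threshold`` are tallied in ``extreme_count``
    (they also appear in their bins); NaN values are excluded and counted
    in ``n_undefined``.
    """

    bin_lo: np.ndarray
    counts: np.ndarray
    bin_width: float
    extreme_threshold: float
    extreme_count: int
    n_undefined: int
    n_values: int


def stat_histogram(
    values: Sequence[float] | np.ndarray,
    bin_width: float = 0.05,
    extreme_threshold: float = 0.975,
) -> Histogram:
    """Bin per-locus statistic values into half-open bins of ``bin_width``."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = np.asarray(values, dtype=float)
    finite = vals[~np.isnan(vals)]
    n_undef = int(vals.size - finite.size)
    if finite.size == 0:
        return Histogram(
            bin_lo=np.empty(0),
            counts=np.empty(0, dtype=int),
            bin_width=bin_width,
            extreme_threshold=extreme_threshold,
            extreme_count=0,
            n_undefined=n_undef,
            n_values=int(vals.size),
        )
    idx = np.floor(finite / bin_width).astype(int)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    bin_lo = (np.arange(lo, hi + 1)) * bin_width
    return Histogram(
        bin_lo=bin_lo,
        counts=counts,
        bin_width=bin_width,
        extreme_threshold=extreme_threshold,
        extreme_count=int((finite > extreme_threshold).sum()),
        n_undefined=n_undef,
        n_values=int(vals.size),
    )
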