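"""Bootstrap CIs over loci and the locus-subsampling experiment.

Both procedures treat loci as exchangeable units.  Because the multilocus
statistics are ratios of per-locus component averages, each replicate is
computed by re-averaging the (ho, hs, ht) components of the drawn loci —
exactly the statistic that would come from rebuilding the matrix, without
re-touching genotypes.

Seeding: replicate ``i`` of an experiment with seed ``s`` uses
``numpy.random.default_rng(numpy.random.SeedSequence((s, i)))``; experiments
are therefore reproducible piecemeal, replicate by replicate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .matrix import GenotypeMatrix
from .popstats import LocusComponents, WcTheta, locus_components, wc_theta

__all__ = [
    "ResamplingResult",
    "SubsampleResult",
    "CiOverlap",
    "bootstrap_ci",
    "subsample_experiment",
    "ci_overlap",
]

_STATS = ("fst", "fis", "ho", "hs", "ht", "theta")


def _components(
    gm: GenotypeMatrix | LocusComponents | WcTheta, statistic: str
) -> LocusComponents | WcTheta:
    """Per-locus components appropriate for the statistic.

    The Nei components serve fst/fis/ho/hs/ht; Weir-Cockerham variance
    components serve theta (unbiased for a generating F, so the right
    statistic when a CI is meant to cover a simulation target).
    """
    if statistic == "theta":
        if isinstance(gm, WcTheta):
            return gm
        if isinstance(gm, GenotypeMatrix):
            return wc_theta(gm)
        raise TypeError("theta resampling needs a GenotypeMatrix or WcTheta")
    if isinstance(gm, WcTheta):
        raise TypeError(f"WcTheta components cannot serve statistic {statistic!r}")
    return gm if isinstance(gm, LocusComponents) else locus_components(gm)


def _stat_from_indices(
    comps: LocusComponents | WcTheta, idx: np.ndarray, statistic: str
) -> float:
    """Ratio-of-averages statistic over the loci at positions ``idx``.

    NaN when no drawn locus is usable or the denominator vanishes.
    """
    if statistic == "theta":
        assert isinstance(comps, WcTheta)
        den = np.nansum(comps.abc_sum[idx])
        if not np.isfinite(comps.abc_sum[idx]).any() or den == 0:
            return math.nan
        return float(np.nansum(comps.a_sum[idx]) / den)
    usable = comps.usable[idx]
    if not usable.any():
        return math.nan
    sel = idx[usable]
    ho = comps.ho[sel].mean()
    hs = comps.hs[sel].mean()
    ht = comps.ht[sel].mean()
    if statistic == "fst":
        return (ht - hs) / ht if ht > 0 else math.nan
    if statistic == "fis":
        return 1.0 - ho / hs if hs > 0 else math.nan
    if statistic == "ho":
        return float(ho)
    if statistic == "hs":
        return float(hs)
    if statistic == "ht":
        return float(ht)
    raise ValueError(f"unknown statistic {statistic!r}; choose from {_STATS}")


@dataclass
class ResamplingResult:
    """Replicate values of a multilocus statistic plus a percentile CI.

    CI endpoints are closed: a value equal to a bound counts as inside.
    """

    statistic: str
    replicate_values: np.ndarray
    point_estimate: float
    ci_low: float
    ci_high: float
    n_replicates: int
    seed: int
    alpha: float

    def contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def _percentile_ci(values: np.ndarray, alpha: float) -> tuple[float, float]:
    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def bootstrap_ci(
    gm: GenotypeMatrix | LocusComponents | WcTheta,
    statistic: str = "fst",
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ResamplingResult:
    """Percentile bootstrap CI of a multilocus statistic over loci.

    Loci are resampled with replacement (same count) B times.  A replicate
    on which the statistic is undefined is redrawn, up to 10*B total draws.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    comps = _components(gm, statistic)
    l = len(comps.locus_ids)
    if l == 0:
        raise ValueError("no loci to resample")
    point = _stat_from_indices(comps, np.arange(l), statistic)

    values = np.empty(B)
    draws = 0
    i = 0
    redrawn = 0
    while i < B:
        if draws >= 10 * B:
            raise RuntimeError(
                f"statistic {statistic!r} undefined on too many bootstrap "
                f"replicates ({draws} draws for {i} kept)"
            )
        rng = np.random.default_rng(np.random.SeedSequence((seed, draws)))
        draws += 1
        idx = rng.integers(0, l, size=l)
        v = _stat_from_indices(comps, idx, statistic)
        if math.isnan(v):
            redrawn += 1
            continue
        values[i] = v
        i += 1
    if redrawn:
        warnings.warn(
            f"{redrawn} bootstrap replicate(s) redrawn (undefined {statistic})"
        )
    lo, hi = _percentile_ci(values, alpha)
    return ResamplingResult(
        statistic=statistic,
        replicate_values=values,
        point_estimate=point,
        ci_low=lo,
        ci_high=hi,
        n_replicates=B,
        seed=seed,
        alpha=alpha,
    )


@dataclass
class CiOverlap:
    """Verdict comparing two resampling results."""

    overlap: bool
    fraction_a_inside_b: float


def ci_overlap(a: ResamplingResult, b: ResamplingResult) -> CiOverlap:
    """Do the two closed CIs intersect, and how many of a's replicates fall
    inside b's CI (boundary counts as inside)?"""
    overlap = a.ci_low <= b.ci_high and b.ci_low <= a.ci_high
    inside = (a.replicate_values >= b.ci_low) & (a.replicate_values <= b.ci_high)
    return CiOverlap(overlap=bool(overlap), fraction_a_inside_b=float(inside.mean()))


@dataclass
class SubsampleResult:
    """Distribution of a statistic over random locus subsets of one size."""

    size: int
    result: ResamplingResult
    mean: float
    frac_inside_full_ci: float
    overlap_with_full: bool
    frac_inside_reference_ci: float | None
    overlap_with_reference: bool | None


def subsample_experiment(
    gm_full: GenotypeMatrix | LocusComponents | WcTheta,
    sizes: Sequence[int],
    reps: int = 100,
    seed: int = 0,
    statistic: str = "fst",
    alpha: float = 0.05,
    full_result: ResamplingResult | None = None,
    reference: ResamplingResult | None = None,
    bootstrap_B: int = 1000,
) -> dict[int, SubsampleResult]:
    """Draw ``reps`` locus subsets (without replacement) per size.

    For each size the statistic's distribution over draws is compared
    against (a) the full matrix's bootstrap CI (computed here unless
    ``full_result`` is supplied) and (b) an optional external reference
    result, e.g. the completeness-filtered dataset of the same size.
    """
    comps = _components(gm_full, statistic)
    l = len(comps.locus_ids)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    for s in sizes:
        if not 1 <= s <= l:
            raise ValueError(f"subsample size {s} out of range [1, {l}]")
    if full_result is None:
        full_result = bootstrap_ci(
            comps, statistic=statistic, B=bootstrap_B, alpha=alpha, seed=seed
        )

    out: dict[int, SubsampleResult] = {}
    for s_i, size in enumerate(sizes):
        values = np.empty(reps)
        for r in range(reps):
            rng = np.random.default_rng(
                np.random.SeedSequence((seed, s_i, r))
            )
            idx = rng.choice(l, size=size, replace=False)
            values[r] = _stat_from_indices(comps, idx, statistic)
        finite = values[~np.isnan(values)]
        if finite.size == 0:
            raise RuntimeError(f"statistic undefined on every draw at size {size}")
        lo, hi = _percentile_ci(finite, alpha)
        res = ResamplingResult(
            statistic=statistic,
            replicate_values=values,
            point_estimate=full_result.point_estimate,
            ci_low=lo,
            ci_high=hi,
            n_replicates=reps,
            seed=seed,
            alpha=alpha,
        )
        ov_full = ci_overlap(res, full_result)
        if reference is not None:
            ov_ref = ci_overlap(res, reference)
            frac_ref: float | None = ov_ref.fraction_a_inside_b
            ovl_ref: bool | None = ov_ref.overlap
        else:
            frac_ref = ovl_ref = None
        out[size] = SubsampleResult(
            size=size,
            result=res,
            mean=float(finite.mean()),
            frac_inside_full_ci=ov_full.fraction_a_inside_b,
            overlap_with_full=ov_full.overlap,
            frac_inside_reference_ci=frac_ref,
            overlap_with_reference=ovl_ref,
        )
    return out
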