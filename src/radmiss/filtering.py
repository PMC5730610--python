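"""RAD locus filtering: single SNP per tag, MAF, and completeness cutoffs.

The completeness-cutoff gradient turns one large matrix into an ordered
family of nested datasets (stricter cutoff -> fewer, more complete loci),
each summarised by its locus count, the percentage of individuals required,
and the percentage of missing cells remaining.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix, pct_missing_cells

__all__ = [
    "select_single_snp",
    "filter_maf",
    "filter_min_individuals",
    "build_dataset_family",
    "DatasetFamily",
    "pct_individuals_required",
]


def select_single_snp(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep one locus per RAD tag: the first locus in input order.

    Raises if the matrix carries no tag labels (then this stage does not
    apply and should be skipped).
    """
    if gm.tags is None:
        raise ValueError(
            "matrix has no RAD-tag labels; skip single-SNP selection"
        )
    seen: set[str] = set()
    keep: list[int] = []
    for j, tag in enumerate(gm.tags):
        if tag not in seen:
            seen.add(tag)
            keep.append(j)
    return gm.subset_loci(keep)


def pooled_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Per-locus minor-allele frequency over all typed individuals pooled.

    Defined as 1 - (frequency of the most common allele), which equals
    min(p, 1-p) for biallelic loci and generalises to multiallelic ones.
    Loci with zero typed calls get MAF 0.
    """
    n_alleles = gm.n_alleles()
    counts = np.zeros((max(n_alleles, 1), gm.n_loci))
    for a in range(n_alleles):
        counts[a] = (gm.calls[:, :, 0] == a).sum(axis=0) + (
            gm.calls[:, :, 1] == a
        ).sum(axis=0)
    total = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        # (total - max) / total keeps exact boundary fractions exact
        maf = (total - counts.max(axis=0)) / total
    return np.where(total > 0, maf, 0.0)


def filter_maf(gm: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Keep loci with pooled minor-allele frequency strictly above ``maf_min``.

    Monomorphic (and fully missing) loci have MAF 0 and are always removed
    for any ``maf_min`` >= 0.
    """
    if not 0.0 <= maf_min < 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5), got {maf_min}")
    return gm.subset_loci(pooled_maf(gm) > maf_min)


def filter_min_individuals(gm: GenotypeMatrix, k: int) -> GenotypeMatrix:
    """Keep exactly the loci typed in at least ``k`` individuals."""
    if not 1 <= k <= gm.n_individuals:
        raise ValueError(
            f"cutoff {k} out of range [1, {gm.n_individuals}]"
        )
    return gm.subset_loci(gm.typed.sum(axis=0) >= k)


def pct_individuals_required(cutoff: int, n_individuals: int) -> float:
    """100 * cutoff / N, rounded half-up to one decimal (e.g. 75/96 -> 78.1)."""
    pct = Decimal(100 * cutoff) / Decimal(n_individuals)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class DatasetFamily:
    """Ordered set of completeness-filtered matrices plus their summary.

    ``members`` pairs each cutoff (minimum individuals typed to retain a
    locus) with the filtered matrix.  ``summary()`` tabulates cutoff, locus
    count, percentage of individuals required, and percentage of missing
    cells in each retained matrix.
    """

    members: list[tuple[int, GenotypeMatrix]]
    source_n_individuals: int

    def __iter__(self):
        return iter(self.members)

    def matrix(self, cutoff: int) -> GenotypeMatrix:
        for c, gm in self.members:
            if c == cutoff:
                return gm
        raise KeyError(f"no family member with cutoff {cutoff}")

    def summary(self) -> pd.DataFrame:
        rows = []
        for cutoff, gm in self.members:
            rows.append(
                {
                    "cutoff_individuals": cutoff,
                    "n_loci": gm.n_loci,
                    "pct_individuals_required": pct_individuals_required(
                        cutoff, self.source_n_individuals
                    ),
                    "pct_missing_cells": round(pct_missing_cells(gm), 1),
                }
            )
        return pd.DataFrame(rows)


def build_dataset_family(
    gm: GenotypeMatrix, cutoffs: Sequence[int]
) -> DatasetFamily:
    """Apply each completeness cutoff to ``gm`` and collect the results.

    Cutoffs must be unique and within [1, N]; they are kept in the order
    given.  Individuals are never removed — only loci are filtered.
    """
    cutoffs = list(cutoffs)
    if not cutoffs:
        raise ValueError("cutoffs must be non-empty")
    if len(set(cutoffs)) != len(cutoffs):
        raise ValueError(f"duplicate cutoffs in {cutoffs}")
    members = [(k, filter_min_individuals(gm, k)) for k in cutoffs]
    return DatasetFamily(members=members, source_n_individuals=gm.n_individuals)
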