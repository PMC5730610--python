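"""Diploid multi-population genotype matrices.

The central container is :class:`GenotypeMatrix`: individuals x loci diploid
calls with an explicit missing sentinel, a population label per individual,
and an optional RAD-tag label per locus (used for single-SNP-per-tag
selection).  Calls are unordered allele pairs of small non-negative integer
codes; codes are per-locus (RAD tags are anonymous, so there is no global
allele registry).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

#: Sentinel allele code for a missing call.  A call is either fully typed
#: (both allele codes >= 0) or fully missing (both codes == MISSING);
#: half-calls are rejected at construction.
MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid genotype calls with population labels.

    Parameters
    ----------
    individual_ids
        Ordered unique individual names (length N).
    populations
        Population label per individual (length N); every individual belongs
        to exactly one population.
    locus_ids
        Ordered unique locus names (length L).
    calls
        Integer array of shape (N, L, 2).  Allele pairs are unordered:
        they are canonicalised to ascending order at construction, so
        (a, b) and (b, a) are the same call.  A missing call is
        (MISSING, MISSING).
    tags
        Optional RAD-tag label per locus (length L); several loci may share
        a tag (multiple SNPs on one tag).
    """

    individual_ids: list[str]
    populations: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    tags: list[str] | None = None

    def __post_init__(self) -> None:
        self.individual_ids = [str(x) for x in self.individual_ids]
        self.populations = [str(x) for x in self.populations]
        self.locus_ids = [str(x) for x in self.locus_ids]
        n, l = len(self.individual_ids), len(self.locus_ids)
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.locus_ids)) != l:
            raise ValueError("duplicate locus ids")
        if len(self.populations) != n:
            raise ValueError(
                f"{len(self.populations)} population labels for {n} individuals"
            )
        calls = np.asarray(self.calls, dtype=np.int16)
        if calls.shape != (n, l, 2):
            raise ValueError(f"calls shape {calls.shape} != {(n, l, 2)}")
        miss = calls == MISSING
        if calls.min(initial=0) < MISSING:
            raise ValueError("allele codes must be >= 0 (or MISSING)")
        if np.any(miss[..., 0] != miss[..., 1]):
            raise ValueError(
                "half-calls are not allowed: both alleles typed or both MISSING"
            )
        self.calls = np.sort(calls, axis=2)  # canonical unordered pairs
        if self.tags is not None:
            self.tags = [str(t) for t in self.tags]
            if len(self.tags) != l:
                raise ValueError(f"{len(self.tags)} tags for {l} loci")

    # -- basic shape ------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def pop_labels(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.populations))

    def pop_indices(self) -> dict[str, np.ndarray]:
        """Map population label -> integer indices of its members."""
        pops = np.asarray(self.populations)
        return {p: np.flatnonzero(pops == p) for p in self.pop_labels}

    @property
    def population_of(self) -> dict[str, str]:
        return dict(zip(self.individual_ids, self.populations))

    @property
    def tag_of(self) -> dict[str, str] | None:
        if self.tags is None:
            return None
        return dict(zip(self.locus_ids, self.tags))

    # -- masks ------------------------------------------------------------

    @property
    def typed(self) -> np.ndarray:
        """Boolean (N, L): True where the call is not missing."""
        return self.calls[:, :, 0] != MISSING

    @property
    def heterozygous(self) -> np.ndarray:
        """Boolean (N, L): True where the call is a typed heterozygote."""
        return self.typed & (self.calls[:, :, 0] != self.calls[:, :, 1])

    def n_alleles(self) -> int:
        """Largest allele code + 1 over the whole matrix (0 if all missing)."""
        return int(self.calls.max(initial=MISSING)) + 1

    # -- subsetting -------------------------------------------------------

    def subset_loci(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the given locus positions (order kept)."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            individual_ids=self.individual_ids,
            populations=self.populations,
            locus_ids=[self.locus_ids[i] for i in idx],
            calls=self.calls[:, idx, :],
            tags=None if self.tags is None else [self.tags[i] for i in idx],
        )

    def subset_individuals(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            locus_ids=self.locus_ids,
            calls=self.calls[idx, :, :],
            tags=self.tags,
        )

    def with_populations(self, mapping: Mapping[str, str]) -> "GenotypeMatrix":
        """Relabel populations (e.g. pooling several into one group)."""
        return GenotypeMatrix(
            individual_ids=self.individual_ids,
            populations=[mapping.get(p, p) for p in self.populations],
            locus_ids=self.locus_ids,
            calls=self.calls,
            tags=self.tags,
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.individual_ids == other.individual_ids
            and self.populations == other.populations
            and self.locus_ids == other.locus_ids
            and self.tags == other.tags
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class MissingnessSummary:
    """Missing-data bookkeeping for a genotype matrix.

    ``per_population_rate`` is the fraction of missing (individual, locus)
    cells among a population's members — the default reading of a
    per-location "% loci missing" figure.  ``per_population_locus_rate`` is
    the alternative reading: the fraction of loci at which at least one of
    the population's members is missing.
    """

    per_locus_typed: dict[str, int]
    per_individual_rate: dict[str, float]
    per_population_rate: dict[str, float]
    per_population_locus_rate: dict[str, float]

    @property
    def overall_rate(self) -> float:
        """Fraction of missing cells over the whole matrix."""
        rates = self.per_individual_rate.values()
        return float(np.mean(list(rates))) if rates else 0.0


def missingness_summary(gm: GenotypeMatrix) -> MissingnessSummary:
    """Per-locus typed counts and per-individual / per-population missing rates."""
    typed = gm.typed
    l = gm.n_loci
    per_locus = {lid: int(c) for lid, c in zip(gm.locus_ids, typed.sum(axis=0))}
    if l == 0:
        ind_rate = {i: 0.0 for i in gm.individual_ids}
        pop_rate = {p: 0.0 for p in gm.pop_labels}
        pop_locus_rate = dict(pop_rate)
    else:
        ind_rate = {
            i: float(r)
            for i, r in zip(gm.individual_ids, 1.0 - typed.mean(axis=1))
        }
        pop_rate = {}
        pop_locus_rate = {}
        for pop, idx in gm.pop_indices().items():
            block = typed[idx]
            pop_rate[pop] = float(1.0 - block.mean())
            pop_locus_rate[pop] = float((~block).any(axis=0).mean())
    return MissingnessSummary(per_locus, ind_rate, pop_rate, pop_locus_rate)


def pct_missing_cells(gm: GenotypeMatrix) -> float:
    """Percentage of missing calls in the matrix (0-100)."""
    if gm.n_loci == 0 or gm.n_individuals == 0:
        return 0.0
    return float(100.0 * (~gm.typed).mean())
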