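"""Synthetic SNP / microsatellite panels with RAD-style missingness.

The generator mirrors the sampling design the pipeline is aimed at: an
island model of K demes (default 12 populations of 8 diploids, N = 96),
with per-deme allele frequencies drawn around an ancestral frequency by the
Balding–Nichols model, whose dispersion parameter F is the expected F_ST —
giving a closed-form differentiation target to recover.

Three missingness mechanisms are layered on top:

* MCAR — every call independently missing with one rate (the neutral
  baseline against which biased mechanisms are contrasted);
* per-individual missingness — each individual its own rate (sample-quality
  variation across sampling locations);
* restriction-site allelic dropout — a third, unobservable "null" allele
  segregating at each locus.  An individual carrying two null copies yields
  a missing call; one null copy hides one haplotype, so a heterozygote is
  miscalled as a homozygote for its surviving allele.  This is the minimal
  mechanism producing both the missing data and the heterozygote-deficit /
  F_ST-inflation biases of RAD loci, and its severity is locus-specific
  (null frequency drawn per locus), so missingness concentrates in a
  subset of loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .matrix import MISSING, GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_snp_panel",
    "simulate_ssr_panel",
    "apply_mcar",
    "apply_individual_missingness",
    "apply_allelic_dropout",
]


@dataclass
class SimConfig:
    """Parameters of a synthetic panel.

    Defaults reproduce the study shape: 12 populations x 8 diploids,
    biallelic SNPs with ancestral minor-allele frequency uniform on
    [0.05, 0.5] (so panels pass a MAF > 0.05 filter by construction),
    and a differentiation target F (expected F_ST) of 0.1.
    """

    n_pops: int = 12
    n_per_pop: int = 8
    n_loci: int = 1000
    target_fst: float = 0.1
    maf_min: float = 0.05
    maf_max: float = 0.5
    marker_type: str = "snp"
    n_alleles: int = 10            # ssr only
    dirichlet_concentration: float = 1.0  # ssr ancestral-frequency law
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pops, self.n_per_pop, self.n_loci) < 1:
            raise ValueError("n_pops, n_per_pop and n_loci must be >= 1")
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target_fst must be in [0, 1)")
        if not 0.0 <= self.maf_min < self.maf_max <= 0.5:
            raise ValueError("need 0 <= maf_min < maf_max <= 0.5")
        if self.marker_type not in ("snp", "ssr"):
            raise ValueError("marker_type must be 'snp' or 'ssr'")
        if self.marker_type == "ssr" and self.n_alleles < 2:
            raise ValueError("ssr panels need n_alleles >= 2")


@dataclass
class SimTruth:
    """Generating parameters of a panel, for parameter-recovery tests."""

    ancestral_freqs: np.ndarray   # (L, A)
    deme_freqs: np.ndarray        # (K, L, A)
    target_fst: float
    seed: int
    dropout_q_ancestral: np.ndarray | None = None  # (L,) null fraction in lineage
    dropout_q_deme: np.ndarray | None = None       # (K, L)
    dropout_linked_allele: np.ndarray | None = None  # (L,) allele code of null background
    miscalled: np.ndarray | None = None            # (N, L) bool, het->hom calls


def _pop_structure(cfg: SimConfig) -> tuple[list[str], list[str]]:
    pops = [f"pop{k + 1:02d}" for k in range(cfg.n_pops)]
    individual_ids = [
        f"{p}_ind{i + 1}" for p in pops for i in range(cfg.n_per_pop)
    ]
    populations = [p for p in pops for _ in range(cfg.n_per_pop)]
    return individual_ids, populations


def _bn_deme_freqs(
    p: np.ndarray, f: float, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Balding–Nichols deme frequencies: Beta(p(1-F)/F, (1-p)(1-F)/F).

    At F = 0 every deme equals the ancestral frequency exactly.
    ``p`` is (L,); the result is (K, L).
    """
    p = np.asarray(p, dtype=float)
    if f == 0.0:
        return np.broadcast_to(p, (k, p.size)).copy()
    scale = (1.0 - f) / f
    out = np.empty((k, p.size))
    interior = (p > 0.0) & (p < 1.0)
    out[:, ~interior] = p[~interior]  # fixed alleles stay fixed
    out[:, interior] = rng.beta(
        p[interior] * scale, (1.0 - p[interior]) * scale, size=(k, int(interior.sum()))
    )
    return out


def _draw_genotypes(
    deme_freqs: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """HWE genotypes within demes from (K, L, A) frequencies -> (N, L, 2)."""
    k, l, a = deme_freqs.shape
    n = cfg.n_per_pop
    calls = np.empty((k * n, l, 2), dtype=np.int16)
    cum = deme_freqs.cumsum(axis=2)
    cum[:, :, -1] = 1.0  # guard rounding
    for ki in range(k):
        u = rng.random(size=(n, l, 2))
        # inverse-CDF draw of two independent gene copies per individual
        calls[ki * n : (ki + 1) * n] = (
            u[:, :, :, None] > cum[ki][None, :, None, :]
        ).sum(axis=3)
    return calls


def simulate_snp_panel(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Island-model biallelic SNP panel at the configured expected F_ST.

    Ancestral allele-1 frequencies are uniform on [maf_min, maf_max]; deme
    frequencies follow Balding–Nichols with dispersion ``target_fst``;
    genotypes are Hardy–Weinberg within demes.  Every locus gets its own
    singleton RAD tag.
    """
    if cfg.marker_type != "snp":
        raise ValueError("simulate_snp_panel needs marker_type='snp'")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    l = cfg.n_loci
    p = rng.uniform(cfg.maf_min, cfg.maf_max, size=l)
    deme_p = _bn_deme_freqs(p, cfg.target_fst, cfg.n_pops, rng)
    deme_freqs = np.stack([1.0 - deme_p, deme_p], axis=2)  # (K, L, 2)
    calls = _draw_genotypes(deme_freqs, cfg, rng)
    individual_ids, populations = _pop_structure(cfg)
    gm = GenotypeMatrix(
        individual_ids=individual_ids,
        populations=populations,
        locus_ids=[f"L{j + 1:06d}" for j in range(l)],
        calls=calls,
        tags=[f"tag{j + 1:06d}" for j in range(l)],
    )
    truth = SimTruth(
        ancestral_freqs=np.stack([1.0 - p, p], axis=1),
        deme_freqs=deme_freqs,
        target_fst=cfg.target_fst,
        seed=cfg.seed,
    )
    return gm, truth


def simulate_ssr_panel(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Island-model multiallelic (microsatellite-like) panel.

    Ancestral frequencies are symmetric-Dirichlet; deme frequencies follow
    Dirichlet(ancestral * (1-F)/F), the multi-allele analogue of
    Balding–Nichols, preserving expected F_ST ~ F.
    """
    if cfg.marker_type != "ssr":
        raise ValueError("simulate_ssr_panel needs marker_type='ssr'")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    l, a = cfg.n_loci, cfg.n_alleles
    anc = rng.dirichlet([cfg.dirichlet_concentration] * a, size=l)  # (L, A)
    if cfg.target_fst == 0.0:
        deme_freqs = np.broadcast_to(anc, (cfg.n_pops, l, a)).copy()
    else:
        scale = (1.0 - cfg.target_fst) / cfg.target_fst
        deme_freqs = np.empty((cfg.n_pops, l, a))
        for j in range(l):
            # Dirichlet cannot take zero concentration; floor tiny masses
            conc = np.maximum(anc[j] * scale, 1e-9)
            deme_freqs[:, j, :] = rng.dirichlet(conc, size=cfg.n_pops)
    calls = _draw_genotypes(deme_freqs, cfg, rng)
    individual_ids, populations = _pop_structure(cfg)
    gm = GenotypeMatrix(
        individual_ids=individual_ids,
        populations=populations,
        locus_ids=[f"SSR{j + 1:03d}" for j in range(l)],
        calls=calls,
    )
    truth = SimTruth(
        ancestral_freqs=anc,
        deme_freqs=deme_freqs,
        target_fst=cfg.target_fst,
        seed=cfg.seed,
    )
    return gm, truth


# ---------------------------------------------------------------------------
# missingness mechanisms


def apply_mcar(gm: GenotypeMatrix, rate: float, seed: int = 0) -> GenotypeMatrix:
    """Set each call MISSING independently with probability ``rate``."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x4D43)))
    drop = rng.random((gm.n_individuals, gm.n_loci)) < rate
    calls = gm.calls.copy()
    calls[drop] = MISSING
    return GenotypeMatrix(
        individual_ids=gm.individual_ids,
        populations=gm.populations,
        locus_ids=gm.locus_ids,
        calls=calls,
        tags=gm.tags,
    )


def apply_individual_missingness(
    gm: GenotypeMatrix,
    rate_per_individual: dict[str, float] | Sequence[float] | np.ndarray,
    seed: int = 0,
) -> GenotypeMatrix:
    """Per-individual independent missingness at the given rates.

    ``rate_per_individual`` is either a mapping individual_id -> rate or a
    sequence aligned with the matrix's individual order.
    """
    if isinstance(rate_per_individual, dict):
        missing = [i for i in gm.individual_ids if i not in rate_per_individual]
        if missing:
            raise ValueError(f"no rate for individuals: {missing[:5]}")
        rates = np.array([rate_per_individual[i] for i in gm.individual_ids])
    else:
        rates = np.asarray(rate_per_individual, dtype=float)
        if rates.shape != (gm.n_individuals,):
            raise ValueError(
                f"need {gm.n_individuals} rates, got shape {rates.shape}"
            )
    if rates.min(initial=0.0) < 0 or rates.max(initial=0.0) > 1:
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x494D)))
    drop = rng.random((gm.n_individuals, gm.n_loci)) < rates[:, None]
    calls = gm.calls.copy()
    calls[drop] = MISSING
    return GenotypeMatrix(
        individual_ids=gm.individual_ids,
        populations=gm.populations,
        locus_ids=gm.locus_ids,
        calls=calls,
        tags=gm.tags,
    )


def apply_allelic_dropout(
    gm: GenotypeMatrix,
    truth: SimTruth,
    q_law: Callable[[np.random.Generator, int], np.ndarray] | tuple[float, float] = (
        0.0,
        1.0,
    ),
    seed: int = 0,
) -> tuple[GenotypeMatrix, SimTruth]:
    """Overlay restriction-site null alleles on a SNP panel.

    The null allele is modelled as a restriction-site mutation that arose
    on one of the two SNP haplotype backgrounds, so it is linked to one
    observed allele (drawn per locus with probability equal to that
    allele's ancestral frequency — a mutation lands on a random ancestral
    copy, hence usually on the major allele).  ``q_law`` — a (lo, hi)
    uniform range or a callable ``(rng, size) -> array`` with support in
    [0, 1] — gives each locus's ancestral null fraction within the linked
    lineage; it is propagated to demes by Balding–Nichols with the panel's
    F, and every gene copy carrying the linked allele is a null with its
    deme's fraction.

    Two null copies give a MISSING call; one null copy hides that
    haplotype, so the call becomes a homozygote for the surviving copy's
    allele (a heterozygote carrying the linked allele is miscalled); calls
    without null copies are unchanged.  Because the linked allele is
    preferentially the more frequent one, heterozygosity is deflated and
    the deme-to-deme variation of the dropout severity distorts observed
    allele frequencies differently in each deme, inflating apparent
    differentiation — most strongly at the high-dropout loci that only
    survive liberal completeness cutoffs.

    Returns the corrupted matrix and an updated truth recording the null
    fractions, the linked alleles, and the miscalled cells.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD0)))
    l = gm.n_loci
    if callable(q_law):
        q = np.asarray(q_law(rng, l), dtype=float)
    else:
        lo, hi = q_law
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("q_law range must lie within [0, 1]")
        q = rng.uniform(lo, hi, size=l)
    if q.shape != (l,) or q.min(initial=0.0) < 0 or q.max(initial=0.0) > 1:
        raise ValueError("q_law must yield one value per locus in [0, 1]")

    if truth.ancestral_freqs.shape[1] != 2:
        raise ValueError("allelic dropout needs a biallelic SNP panel")
    # haplotype background of the restriction-site mutation
    linked = (rng.random(l) < truth.ancestral_freqs[:, 1]).astype(np.int16)

    k = len(gm.pop_labels)
    q_deme = np.clip(_bn_deme_freqs(q, truth.target_fst, k, rng), 0.0, 1.0)

    # per-individual deme q, aligned with matrix rows
    pop_index = {p: i for i, p in enumerate(gm.pop_labels)}
    row_pop = np.array([pop_index[p] for p in gm.populations])
    q_ind = q_deme[row_pop]  # (N, L)

    carries = gm.calls == linked[None, :, None]  # (N, L, 2)
    null = carries & (rng.random((gm.n_individuals, l, 2)) < q_ind[:, :, None])
    calls = gm.calls.copy()
    typed = gm.typed
    both_null = null.all(axis=2) & typed
    one_null = (null.sum(axis=2) == 1) & typed

    # one null copy: the surviving copy's allele is called homozygous
    surviving = np.where(null[:, :, 0], calls[:, :, 1], calls[:, :, 0])
    miscalled = one_null & (calls[:, :, 0] != calls[:, :, 1])
    calls[one_null, 0] = surviving[one_null]
    calls[one_null, 1] = surviving[one_null]
    calls[both_null] = MISSING

    out = GenotypeMatrix(
        individual_ids=gm.individual_ids,
        populations=gm.populations,
        locus_ids=gm.locus_ids,
        calls=calls,
        tags=gm.tags,
    )
    new_truth = replace(
        truth,
        dropout_q_ancestral=q,
        dropout_q_deme=q_deme,
        dropout_linked_allele=linked,
        miscalled=miscalled,
    )
    return out, new_truth
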