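"""Genotype principal-component analysis for cluster visualisation.

Genotypes are encoded as allele dosages, centred by twice the pooled allele
frequency, optionally scaled by sqrt(p(1-p)), with missing dosages imputed
to the locus mean (so an individual missing everywhere lands at the
origin).  Components come from the SVD of the standardised matrix, which is
the eigendecomposition of the individual x individual covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrix import MISSING, GenotypeMatrix

__all__ = ["PcaResult", "pca_genotypes", "dosage_matrix"]


@dataclass
class PcaResult:
    """PCA scores and variances for a genotype matrix.

    ``coordinates`` is (N, n_components) with components ordered by
    non-increasing explained variance; ``explained_variance`` are the
    eigenvalues of the centred individual-covariance matrix (columns
    divided by the number of dosage columns used).
    """

    individual_ids: list[str]
    populations: list[str]
    coordinates: np.ndarray
    explained_variance: np.ndarray
    n_components: int
    loci_used: int
    scaling: str


def dosage_matrix(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Dosage encoding of a matrix: (dosages (N, C), typed mask (N, C)).

    Biallelic loci contribute one column (count of allele 1, in {0, 1, 2});
    loci with more than two alleles (microsatellites) are one-hot expanded
    to one dosage column per allele.
    """
    n, l = gm.n_individuals, gm.n_loci
    typed = gm.typed
    cols: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    c0, c1 = gm.calls[:, :, 0], gm.calls[:, :, 1]
    max_code = c1.max(axis=0, initial=MISSING)  # per-locus max allele
    if l and max_code.max(initial=MISSING) <= 1:  # all-biallelic fast path
        return ((c0 == 1).astype(float) + (c1 == 1)), typed.copy()
    for j in range(l):
        if max_code[j] <= 1:  # biallelic (or monomorphic/empty)
            cols.append(((c0[:, j] == 1).astype(float) + (c1[:, j] == 1)))
            masks.append(typed[:, j])
        else:
            for a in range(int(max_code[j]) + 1):
                cols.append(
                    (c0[:, j] == a).astype(float) + (c1[:, j] == a)
                )
                masks.append(typed[:, j])
    if not cols:
        return np.empty((n, 0)), np.empty((n, 0), dtype=bool)
    return np.column_stack(cols), np.column_stack(masks)


def pca_genotypes(
    gm: GenotypeMatrix, n_components: int = 4, scaling: str = "unit"
) -> PcaResult:
    """PCA of the dosage matrix.

    Parameters
    ----------
    n_components
        Number of leading components to return (capped at the rank bound
        min(N, usable columns)).
    scaling
        ``"unit"`` divides each centred column by sqrt(p(1-p)) (standard
        SNP-PCA normalisation); ``"none"`` leaves columns centred only.
    """
    if scaling not in ("unit", "none"):
        raise ValueError("scaling must be 'unit' or 'none'")
    if gm.n_individuals < 2:
        raise ValueError("PCA needs at least 2 individuals")
    dos, mask = dosage_matrix(gm)
    n_typed = mask.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.where(mask, dos, 0.0).sum(axis=0) / (2.0 * n_typed)
    informative = (n_typed > 0) & (p_hat > 0) & (p_hat < 1)
    if not informative.any():
        raise ValueError("no polymorphic loci with data: PCA undefined")
    if (~informative).any():
        warnings.warn(
            f"dropping {int((~informative).sum())} monomorphic/empty dosage column(s)"
        )
    dos = dos[:, informative]
    mask = mask[:, informative]
    p_hat = p_hat[informative]

    x = np.where(mask, dos, 2.0 * p_hat[None, :]) - 2.0 * p_hat[None, :]
    if scaling == "unit":
        x = x / np.sqrt(p_hat * (1.0 - p_hat))[None, :]

    m = x.shape[1]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, u.shape[1])
    coords = u[:, :k] * s[:k]
    explained = s**2 / m  # eigenvalues of x x^T / m; sums to trace(x x^T)/m
    return PcaResult(
        individual_ids=list(gm.individual_ids),
        populations=list(gm.populations),
        coordinates=coords,
        explained_variance=explained[:k],
        n_components=k,
        loci_used=m,
        scaling=scaling,
    )
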