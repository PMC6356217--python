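"""Population structure (PCA + Tracy-Widom), kinship and diversity.

Structure is summarized by principal components of the mean-centred
genotype matrix; the number of significant components can be chosen by the
sequential Tracy-Widom test on leading eigenvalues (Patterson-style
effective-size normalization). The retained scores form the covariate
matrix ``S`` used by the structure-corrected LD estimators.

Kinship is the rescaled simple-matching (identity-by-state) matrix
``V = (s - s_min) / (1 - s_min)`` where ``s`` are pairwise simple matching
coefficients and ``s_min`` their off-diagonal minimum, so the least related
pair is anchored at 0 and identical lines at 1.

Nucleotide diversity treats each inbred line as one haploid sequence over
the SNP sites: pi is the mean pairwise difference fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateKinshipError,
    ValidationError,
)
from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Upper-tail critical values of the Tracy-Widom(1) distribution.
TW1_CRITICAL = {0.10: 0.4501, 0.05: 0.9793, 0.01: 2.0234}


@dataclass
class PcaResult:
    """Principal components of the accessions.

    ``scores`` are the projections (accessions x components), ``eigenvalues``
    the descending eigenvalues of the accession covariance,
    ``variance_fraction`` each eigenvalue over the trace, and ``loadings``
    the locus-space axes (components x loci) so that
    ``scores @ loadings`` reconstructs the centred matrix.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    loadings: np.ndarray


@dataclass
class StructureMatrix:
    """Column-centred retained PC scores used as LD covariates."""

    S: np.ndarray
    k: int


@dataclass
class KinshipMatrix:
    """Rescaled simple-matching relatedness with its anchoring minimum."""

    V: np.ndarray
    smin: float


def _as_float_complete(G: GenotypeMatrix) -> np.ndarray:
    if (G.values == MISSING).any():
        raise ValidationError(
            "matrix contains missing entries; impute before PCA"
        )
    return G.values.astype(float)


def pca_scores(G: GenotypeMatrix) -> PcaResult:
    """PCA of the accession x locus matrix, loci mean-centred, unscaled.

    Centring without variance scaling matches the common default for
    genotype PCA on dosage data. Eigenvalues are those of the accession
    covariance ``X X^T / (n - 1)`` for the centred ``X``.
    """
    X = _as_float_complete(G)
    n, m = X.shape
    if n < 2 or m < 2:
        raise ValidationError("PCA needs at least 2 accessions and 2 loci")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    if total <= 0:
        raise ValidationError("zero total variance: all accessions identical")
    # fix signs deterministically: largest-magnitude loading positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U * s
    return PcaResult(
        scores=scores,
        eigenvalues=eig,
        variance_fraction=eig / total,
        loadings=Vt,
    )


def tracy_widom_count(
    eigenvalues: np.ndarray,
    n_accessions: int,
    n_loci: int,
    alpha: float = 0.05,
) -> int:
    """Number of consecutive significant leading eigenvalues.

    Sequential procedure: standardize the current leading eigenvalue with
    the effective-size normalization estimated from the remaining spectrum,
    compare against the Tracy-Widom(1) upper-``alpha`` critical value, and
    stop at the first non-significant one. The effective marker count is
    re-estimated after each accepted component.
    """
    if alpha not in TW1_CRITICAL:
        raise ValidationError(
            f"alpha={alpha} not tabulated; supported: {sorted(TW1_CRITICAL)}"
        )
    crit = TW1_CRITICAL[alpha]
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 0
    if np.any(np.diff(lam) > 1e-9):
        raise ValidationError("eigenvalues must be in descending order")
    count = 0
    for i in range(lam.size - 1):
        rest = lam[i:]
        mprime = rest.size
        s1 = rest.sum()
        s2 = (rest**2).sum()
        denom = (mprime - 1) * s2 - s1**2
        if denom <= 0:
            n_eff = float(n_loci)
        else:
            n_eff = (mprime + 1) * s1**2 / denom
        n_eff = min(max(n_eff, 2.0), float(max(n_loci, 2)))
        ell = mprime * rest[0] / s1
        sq_n = np.sqrt(n_eff - 1)
        sq_m = np.sqrt(mprime)
        mu = (sq_n + sq_m) ** 2 / n_eff
        sigma = (sq_n + sq_m) / n_eff * (1.0 / sq_n + 1.0 / sq_m) ** (1.0 / 3.0)
        x = (ell - mu) / sigma
        if x > crit:
            count += 1
        else:
            break
    return count


def build_S(pca: PcaResult, k: int = 4) -> StructureMatrix:
    """First ``k`` score columns, column-centred.

    ``k = 0`` yields an empty covariate matrix, under which the
    structure-corrected LD estimators reduce exactly to their uncorrected
    counterparts.
    """
    if k < 0:
        raise ValidationError("k must be >= 0")
    n = pca.scores.shape[0]
    if k > pca.scores.shape[1]:
        raise ValidationError(
            f"k={k} exceeds the {pca.scores.shape[1]} available components"
        )
    S = pca.scores[:, :k].copy()
    if k:
        S -= S.mean(axis=0, keepdims=True)
    else:
        S = np.zeros((n, 0))
    return StructureMatrix(S=S, k=k)


def kinship_sm(G: GenotypeMatrix) -> KinshipMatrix:
    """Rescaled simple-matching kinship ``(s - s_min) / (1 - s_min)``.

    Simple matching is the fraction of loci at which two lines carry
    identical codes. Complete (imputed) data is expected; with missing
    entries the comparison is pairwise-complete and a warning is logged.
    The minimum is taken over off-diagonal pairs; the diagonal is forced
    to 1.
    """
    v = G.values
    n = G.n_accessions
    if n < 2:
        raise ValidationError("kinship needs at least 2 accessions")
    if (v == MISSING).any():
        logger.warning(
            "kinship on incomplete data: using pairwise-complete loci"
        )
    obs = (v != MISSING).astype(np.float64)
    both = obs @ obs.T
    matches = np.zeros((n, n))
    for code in (0, 1, 2):
        ind = (v == code).astype(np.float64)
        matches += ind @ ind.T
    if (both <= 0).any():
        raise ValidationError("some line pairs share no observed loci")
    s = matches / both
    off = ~np.eye(n, dtype=bool)
    smin = float(s[off].min())
    if smin >= 1.0:
        raise DegenerateKinshipError("all lines identical: s_min = 1")
    V = (s - smin) / (1.0 - smin)
    np.fill_diagonal(V, 1.0)
    V = np.clip(V, 0.0, 1.0)
    V = (V + V.T) / 2.0
    return KinshipMatrix(V=V, smin=smin)


def nucleotide_diversity(
    G: GenotypeMatrix, subset: list[int] | np.ndarray | None = None
) -> float:
    """Mean pairwise difference fraction (pi) over the SNP sites.

    Each inbred line (codes {0, 2}) counts as one haploid sequence;
    pi = average over unordered line pairs of the fraction of sites at
    which they differ, equivalently the mean over loci of
    ``2 p (1 - p) n / (n - 1)``.
    """
    idx = np.arange(G.n_accessions) if subset is None else np.asarray(subset)
    if idx.size < 2:
        raise ValidationError("pi needs at least 2 lines")
    v = G.values[idx]
    if (v == MISSING).any():
        raise ValidationError("pi requires complete data over the subset")
    if (v == 1).any():
        raise ValidationError("pi expects inbred codes {0, 2}")
    n = v.shape[0]
    p = (v == 2).mean(axis=0)
    per_locus = 2.0 * p * (1.0 - p) * n / (n - 1)
    return float(per_locus.mean())
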