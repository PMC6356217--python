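"""The four LD estimators, Fisher-exact significance and FDR control.

For dosage vectors ``x_A, x_B`` over ``n`` inbred accessions:

* ``r2`` — squared Pearson correlation (ordinary LD).
* ``r2_s`` — squared partial correlation given the structure covariates
  ``S``: each vector is residualized on ``[1, S]`` by ordinary least
  squares and the residuals are correlated.
* ``r2_v`` — squared generalized correlation under the kinship covariance
  ``V``: with inner product ``<a, b> = a' V^{-1} b``, each vector is
  centred by its generalized mean and the V-weighted correlation is
  squared. ``V`` is ridge-regularized (``V + eps I``,
  ``eps = 1e-6 tr(V)/n``) since the rescaled simple-matching matrix is not
  guaranteed positive definite.
* ``r2_vs`` — both corrections: generalized-least-squares residuals on
  ``[1, S]`` under the V-metric, then the squared V-weighted correlation
  of the residuals.

All four are invariant under the allele-label flip ``x -> 2 - x``; with
``V = I`` the kinship-corrected measures reduce to their unweighted
counterparts, and with an empty ``S`` the structure-corrected ones reduce
to theirs.

Significance per pair is a two-sided Fisher exact test on the 2x2 allele
count table (valid because homozygous lines carry one haplotype each);
multiplicity is handled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import cholesky, solve_triangular
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConditioningError,
    DegenerateTableError,
    InsufficientDataError,
    MonomorphicLocusError,
    ValidationError,
)
from .genotype_io import MISSING, GenotypeMatrix
from .structure_kinship import KinshipMatrix, StructureMatrix

_ZERO_NORM = 1e-9

LD_MEASURES = ("r2", "rs2", "rv2", "rvs2")


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _corr_sq(a: np.ndarray, b: np.ndarray) -> float:
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na < _ZERO_NORM or nb < _ZERO_NORM:
        raise MonomorphicLocusError("zero-variance (residual) vector")
    c = float(a @ b / (na * nb))
    return min(c * c, 1.0)


def r2(xa, xb) -> float:
    """Ordinary squared dosage correlation over jointly non-missing entries."""
    xa = _as_array(xa)
    xb = _as_array(xb)
    mask = (xa != MISSING) & (xb != MISSING)
    if mask.sum() < 3:
        raise InsufficientDataError("fewer than 3 complete pairs")
    a = xa[mask] - xa[mask].mean()
    b = xb[mask] - xb[mask].mean()
    return _corr_sq(a, b)


def _design(S: StructureMatrix | np.ndarray | None, n: int) -> np.ndarray:
    """Covariate matrix [1, S] for n accessions."""
    if S is None:
        Smat = np.zeros((n, 0))
    elif isinstance(S, StructureMatrix):
        Smat = S.S
    else:
        Smat = np.asarray(S, dtype=float)
        if Smat.ndim == 1:
            Smat = Smat[:, None]
    if Smat.shape[0] != n:
        raise ValidationError("S row count does not match accessions")
    return np.column_stack([np.ones(n), Smat])


def _ols_residual(x: np.ndarray, X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return x - Q @ (Q.T @ x)


def r2_s(xa, xb, S: StructureMatrix | np.ndarray | None) -> float:
    """Squared partial correlation given the structure covariates."""
    xa = _as_array(xa)
    xb = _as_array(xb)
    if (xa == MISSING).any() or (xb == MISSING).any():
        raise ValidationError("structure-corrected LD requires complete data")
    n = len(xa)
    X = _design(S, n)
    if n <= X.shape[1] + 1:
        raise InsufficientDataError("too few accessions for the covariates")
    ra = _ols_residual(xa, X)
    rb = _ols_residual(xb, X)
    return _corr_sq(ra, rb)


def regularize_kinship(
    V: KinshipMatrix | np.ndarray, ridge: float | str = "auto"
) -> np.ndarray:
    """Return ``V + eps I`` with the default ridge ``1e-6 tr(V)/n``."""
    Vm = V.V if isinstance(V, KinshipMatrix) else np.asarray(V, dtype=float)
    n = Vm.shape[0]
    if Vm.shape != (n, n):
        raise ValidationError("V must be square")
    eps = 1e-6 * np.trace(Vm) / n if ridge == "auto" else float(ridge)
    return Vm + eps * np.eye(n)


def _whitener(Vr: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of the regularized kinship."""
    try:
        return cholesky(Vr, lower=True)
    except Exception as exc:  # scipy LinAlgError on non-PD input
        raise ConditioningError(
            f"kinship not positive definite after ridge; smallest eigenvalue "
            f"{np.linalg.eigvalsh(Vr)[0]:.3e}"
        ) from exc


def r2_v(xa, xb, V: KinshipMatrix | np.ndarray, *, ridge: float | str = "auto") -> float:
    """Kinship-corrected squared correlation (generalized, V-whitened)."""
    xa = _as_array(xa)
    xb = _as_array(xb)
    if (xa == MISSING).any() or (xb == MISSING).any():
        raise ValidationError("kinship-corrected LD requires complete data")
    n = len(xa)
    Vr = regularize_kinship(V, ridge)
    Lw = _whitener(Vr)
    wa = solve_triangular(Lw, xa, lower=True)
    wb = solve_triangular(Lw, xb, lower=True)
    w1 = solve_triangular(Lw, np.ones(n), lower=True)
    ra = _ols_residual(wa, w1[:, None])
    rb = _ols_residual(wb, w1[:, None])
    return _corr_sq(ra, rb)


def r2_vs(
    xa,
    xb,
    S: StructureMatrix | np.ndarray | None,
    V: KinshipMatrix | np.ndarray,
    *,
    ridge: float | str = "auto",
) -> float:
    """Jointly structure- and kinship-corrected squared correlation.

    GLS residuals on ``[1, S]`` under the V-metric, then the squared
    V-inner-product correlation of the residuals.
    """
    xa = _as_array(xa)
    xb = _as_array(xb)
    if (xa == MISSING).any() or (xb == MISSING).any():
        raise ValidationError("corrected LD requires complete data")
    n = len(xa)
    X = _design(S, n)
    if n <= X.shape[1] + 1:
        raise InsufficientDataError("too few accessions for the covariates")
    Vr = regularize_kinship(V, ridge)
    Lw = _whitener(Vr)
    wa = solve_triangular(Lw, xa, lower=True)
    wb = solve_triangular(Lw, xb, lower=True)
    Xw = solve_triangular(Lw, X, lower=True)
    ra = _ols_residual(wa, Xw)
    rb = _ols_residual(wb, Xw)
    return _corr_sq(ra, rb)


def fisher_exact_ld(xa, xb) -> float:
    """Two-sided Fisher exact p for the 2x2 allele table of an inbred pair.

    Each homozygous line contributes one haplotype; jointly non-missing
    lines are cross-tabulated by their alleles. The two-sided p-value sums
    hypergeometric probabilities of all tables (margins fixed) no more
    probable than the observed one.
    """
    xa = np.asarray(xa)
    xb = np.asarray(xb)
    mask = (xa != MISSING) & (xb != MISSING)
    a = xa[mask]
    b = xb[mask]
    if np.isin(a, (0, 2)).all() and np.isin(b, (0, 2)).all():
        pass
    else:
        raise ValidationError("Fisher LD test expects inbred codes {0, 2}")
    t00 = int(((a == 0) & (b == 0)).sum())
    t01 = int(((a == 0) & (b == 2)).sum())
    t10 = int(((a == 2) & (b == 0)).sum())
    t11 = int(((a == 2) & (b == 2)).sum())
    table = np.array([[t00, t01], [t10, t11]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError(f"empty margin in {table.tolist()}")
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def fdr_bh(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


# ---------------------------------------------------------------------------
# pairwise streams
# ---------------------------------------------------------------------------

@dataclass
class LDRecord:
    """One locus pair with its LD measures and significance."""

    locus_a: int
    locus_b: int
    same_chrom: bool
    distance_bp: int | None
    r2: float
    rs2: float
    rv2: float
    rvs2: float
    p_fisher: float
    fdr_significant: bool
    status: str = "ok"


def _normalized_residual_matrix(X: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Unit-norm residual columns; zero-variance columns become NaN."""
    Q, _ = np.linalg.qr(design)
    R = X - Q @ (Q.T @ X)
    norms = np.linalg.norm(R, axis=0)
    out = np.full_like(R, np.nan)
    ok = norms > _ZERO_NORM
    out[:, ok] = R[:, ok] / norms[ok]
    return out


def pairwise_ld(
    G: GenotypeMatrix,
    L: pd.DataFrame,
    S: StructureMatrix | np.ndarray | None = None,
    V: KinshipMatrix | np.ndarray | None = None,
    *,
    scope: str = "within_chrom",
    measures: tuple[str, ...] = LD_MEASURES,
    fdr_q: float = 0.05,
    with_fisher: bool = True,
    batch_size: int = 20_000,
    ridge: float | str = "auto",
) -> pd.DataFrame:
    """All requested locus-pair LD records as a tidy DataFrame.

    Pairs are emitted in deterministic order (chromosome blocks in table
    order, positions ascending, ``a`` before ``b``). Corrected measures
    require a complete (imputed) matrix. Per-pair degeneracies (e.g. a
    monomorphic residual) yield NaN measures and ``status != "ok"``
    instead of aborting. FDR flags are computed over the full emitted set.
    ``batch_size`` only chunks the internal pair iteration; results are
    independent of it.
    """
    if scope not in ("within_chrom", "all_pairs"):
        raise ValidationError("scope must be 'within_chrom' or 'all_pairs'")
    unknown = set(measures) - set(LD_MEASURES)
    if unknown:
        raise ValidationError(f"unknown measures {sorted(unknown)}")
    need_complete = bool({"rs2", "rv2", "rvs2"} & set(measures))
    X = G.values.astype(float)
    n, m = X.shape
    if need_complete and (G.values == MISSING).any():
        raise ValidationError("corrected measures require a complete matrix")
    if ("rv2" in measures or "rvs2" in measures) and V is None:
        raise ValidationError("kinship matrix required for rv2/rvs2")

    chroms = L["chrom"].to_numpy()
    pos = L["pos"].to_numpy()

    # residualized unit columns per measure
    cols: dict[str, np.ndarray] = {}
    ones = np.ones((n, 1))
    if "r2" in measures:
        cols["r2"] = _normalized_residual_matrix(X, ones)
    if "rs2" in measures:
        cols["rs2"] = _normalized_residual_matrix(X, _design(S, n))
    if "rv2" in measures or "rvs2" in measures:
        Vr = regularize_kinship(V, ridge)
        Lw = _whitener(Vr)
        Xw = solve_triangular(Lw, X, lower=True)
        if "rv2" in measures:
            w1 = solve_triangular(Lw, np.ones(n), lower=True)[:, None]
            cols["rv2"] = _normalized_residual_matrix(Xw, w1)
        if "rvs2" in measures:
            Xdes = solve_triangular(Lw, _design(S, n), lower=True)
            cols["rvs2"] = _normalized_residual_matrix(Xw, Xdes)

    # deterministic pair list
    if scope == "within_chrom":
        pair_a: list[np.ndarray] = []
        pair_b: list[np.ndarray] = []
        for chrom in L["chrom"].unique():
            idx = np.flatnonzero(chroms == chrom)
            ia, ib = np.triu_indices(len(idx), k=1)
            pair_a.append(idx[ia])
            pair_b.append(idx[ib])
        ia = np.concatenate(pair_a) if pair_a else np.zeros(0, dtype=int)
        ib = np.concatenate(pair_b) if pair_b else np.zeros(0, dtype=int)
    else:
        ia, ib = np.triu_indices(m, k=1)

    frames = []
    for start in range(0, len(ia), max(batch_size, 1)):
        sa = ia[start : start + batch_size]
        sb = ib[start : start + batch_size]
        same = chroms[sa] == chroms[sb]
        dist = np.where(same, np.abs(pos[sa] - pos[sb]), -1)
        data: dict[str, np.ndarray] = {
            "idx_a": sa,
            "idx_b": sb,
            "chrom_a": chroms[sa],
            "pos_a": pos[sa],
            "chrom_b": chroms[sb],
            "pos_b": pos[sb],
            "same_chrom": same,
            "distance_bp": dist,
        }
        status = np.full(len(sa), "ok", dtype=object)
        for meas in LD_MEASURES:
            if meas not in measures:
                data[meas] = np.full(len(sa), np.nan)
                continue
            U = cols[meas]
            vals = np.einsum("ij,ij->j", U[:, sa], U[:, sb]) ** 2
            vals = np.minimum(vals, 1.0)
            bad = np.isnan(vals)
            status[bad] = "degenerate"
            data[meas] = vals
        if with_fisher:
            pvals = np.full(len(sa), np.nan)
            for t in range(len(sa)):
                try:
                    pvals[t] = fisher_exact_ld(G.values[:, sa[t]], G.values[:, sb[t]])
                except (DegenerateTableError, ValidationError):
                    status[t] = "degenerate"
            data["p_fisher"] = pvals
        else:
            data["p_fisher"] = np.full(len(sa), np.nan)
        data["status"] = status
        frames.append(pd.DataFrame(data))
    if frames:
        records = pd.concat(frames, ignore_index=True)
    else:
        records = pd.DataFrame(
            columns=[
                "idx_a", "idx_b", "chrom_a", "pos_a", "chrom_b", "pos_b",
                "same_chrom", "distance_bp", "r2", "rs2", "rv2", "rvs2",
                "p_fisher", "status",
            ]
        )
    flags = np.zeros(len(records), dtype=bool)
    p = records["p_fisher"].to_numpy() if len(records) else np.zeros(0)
    ok = ~np.isnan(p)
    if ok.any():
        flags[ok] = fdr_bh(p[ok], q=fdr_q)
    records["fdr_significant"] = flags
    return records
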