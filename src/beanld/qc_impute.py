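"""Filtering and window-based nearest-neighbour imputation.

The filter chain for inbred GBS panels:

1. :func:`het_to_missing` — heterozygous calls in a predominantly
   autogamous panel are treated as sequencing errors and set to missing.
2. :func:`filter_missing` — drop loci whose missing fraction exceeds a
   threshold (default 10%, inclusive: a locus at exactly the threshold is
   kept).
3. :func:`impute_window` — fill remaining no-calls from the nearest
   neighbouring line within a sliding window of flanking loci,
   chromosome by chromosome.
4. :func:`filter_maf` — drop loci with minor-allele frequency below a
   threshold (default 5%, kept at equality).

The imputation window size is chosen per chromosome by leave-one-out
self-prediction of observed calls over a candidate range (default 5-150
loci per flank), taking the smallest window on accuracy ties
(:func:`select_window_size`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedCorrelationError, ValidationError
from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    recompute_locus_stats,
)

DEFAULT_MAX_MISSING = 0.10
DEFAULT_MIN_MAF = 0.05
DEFAULT_WINDOW_CANDIDATES = range(5, 151)


@dataclass
class QcReport:
    """Counts and choices recorded along the filter chain."""

    n_loci_in: int = 0
    n_het_converted: int = 0
    n_loci_after_missing_filter: int = 0
    chosen_window_size: dict[str, int] = field(default_factory=dict)
    imputation_self_accuracy: dict[str, dict[int, float]] = field(
        default_factory=dict
    )
    n_loci_after_maf_filter: int = 0

    def to_dict(self) -> dict:
        return {
            "n_loci_in": self.n_loci_in,
            "n_het_converted": self.n_het_converted,
            "n_loci_after_missing_filter": self.n_loci_after_missing_filter,
            "chosen_window_size": dict(self.chosen_window_size),
            "imputation_self_accuracy": {
                c: {int(w): float(a) for w, a in accs.items()}
                for c, accs in self.imputation_self_accuracy.items()
            },
            "n_loci_after_maf_filter": self.n_loci_after_maf_filter,
        }


def het_to_missing(G: GenotypeMatrix) -> tuple[GenotypeMatrix, int]:
    """Convert all heterozygous calls (code 1) to missing.

    Returns the new matrix and the number of converted entries.
    """
    values = G.values.copy()
    het = values == 1
    values[het] = MISSING
    return GenotypeMatrix(values, list(G.accession_ids)), int(het.sum())


def filter_missing(
    G: GenotypeMatrix, L: pd.DataFrame, max_md: float = DEFAULT_MAX_MISSING
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop loci whose missing fraction exceeds ``max_md`` (kept at equality)."""
    if not 0.0 <= max_md <= 1.0:
        raise ValidationError("max_md must lie in [0, 1]")
    frac = (G.values == MISSING).mean(axis=0)
    keep = np.flatnonzero(frac <= max_md)
    G2 = G.take_loci(keep)
    L2 = L.iloc[keep].reset_index(drop=True)
    return G2, recompute_locus_stats(G2, L2)


def filter_maf(
    G: GenotypeMatrix, L: pd.DataFrame, min_maf: float = DEFAULT_MIN_MAF
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop loci with MAF below ``min_maf`` (kept at equality).

    MAF is recomputed from non-missing calls; all-missing loci (MAF
    undefined) are dropped.
    """
    from .genotype_io import compute_maf

    maf = compute_maf(G.values)
    keep = np.flatnonzero(maf >= min_maf)  # NaN compares False -> dropped
    G2 = G.take_loci(keep)
    L2 = L.iloc[keep].reset_index(drop=True)
    return G2, recompute_locus_stats(G2, L2)


# ---------------------------------------------------------------------------
# nearest-neighbour window imputation
# ---------------------------------------------------------------------------

def _check_inbred(values: np.ndarray) -> None:
    if (values == 1).any():
        raise ValidationError(
            "imputation expects inbred codes {0, 2, missing}; run "
            "het_to_missing first"
        )


class _WindowStats:
    """Sliding pairwise mismatch/comparable counts over flanking loci.

    For the current centre locus ``j`` the window is the up-to-``w``
    nearest loci on each side of ``j`` (``j`` itself excluded). The class
    maintains, for every line pair ``(i, h)``, the number of window loci
    where both are non-missing (``comparable``) and where they differ
    (``mismatch``), updated incrementally as ``j`` advances.
    """

    def __init__(self, values: np.ndarray, w: int):
        self.values = values
        self.w = w
        n, m = values.shape
        self.m = m
        self.mismatch = np.zeros((n, n), dtype=np.int32)
        self.comparable = np.zeros((n, n), dtype=np.int32)
        self.lo = 0  # current range [lo, hi) of included columns
        self.hi = 0

    def _col_stats(self, c: int) -> tuple[np.ndarray, np.ndarray]:
        x = self.values[:, c]
        obs = x != MISSING
        both = obs[:, None] & obs[None, :]
        diff = both & (x[:, None] != x[None, :])
        return diff, both

    def _add(self, c: int) -> None:
        d, b = self._col_stats(c)
        self.mismatch += d
        self.comparable += b

    def _remove(self, c: int) -> None:
        d, b = self._col_stats(c)
        self.mismatch -= d
        self.comparable -= b

    def at(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Counts over the window of ``j`` (exclusive of ``j``)."""
        lo = max(0, j - self.w)
        hi = min(self.m, j + self.w + 1)
        while self.hi < hi:
            self._add(self.hi)
            self.hi += 1
        while self.lo < lo:
            self._remove(self.lo)
            self.lo += 1
        # ranges only ever advance; j strictly increasing per sweep
        dj, bj = self._col_stats(j)
        return self.mismatch - dj, self.comparable - bj


def _predict_column(
    values: np.ndarray,
    j: int,
    mism: np.ndarray,
    comp: np.ndarray,
    targets: np.ndarray,
) -> np.ndarray:
    """Nearest-neighbour prediction of ``values[targets, j]``.

    ``mism``/``comp`` are pairwise counts over the window of ``j``.
    Candidate lines must be non-missing at ``j`` and share at least one
    comparable window locus with the target; the call is the majority at
    ``j`` among all lines attaining the minimum mismatch distance, ties
    broken toward the locus-wise major call.
    """
    col = values[:, j]
    donor_ok = col != MISSING
    tot2 = int((col == 2).sum())
    tot0 = int((col == 0).sum())
    out = np.empty(len(targets), dtype=np.int8)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = mism / comp
    for t, i in enumerate(targets):
        # major call excluding the target's own (masked or missing) entry
        m2 = tot2 - (1 if col[i] == 2 else 0)
        m0 = tot0 - (1 if col[i] == 0 else 0)
        major = 2 if m2 > m0 else 0
        valid = donor_ok & (comp[i] > 0)
        valid[i] = False
        if not valid.any():
            out[t] = major
            continue
        d = np.where(valid, dist[i], np.inf)
        dmin = d.min()
        cand = d == dmin
        calls = col[cand]
        n2 = int((calls == 2).sum())
        n0 = int((calls == 0).sum())
        if n2 > n0:
            out[t] = 2
        elif n0 > n2:
            out[t] = 0
        else:
            out[t] = major
    return out


def _chrom_blocks(L: pd.DataFrame) -> list[tuple[str, np.ndarray]]:
    blocks = []
    for chrom in L["chrom"].unique():
        blocks.append((chrom, np.flatnonzero((L["chrom"] == chrom).to_numpy())))
    return blocks


def impute_window(
    G: GenotypeMatrix, L: pd.DataFrame, window: int | dict[str, int]
) -> GenotypeMatrix:
    """Fill every missing call by nearest-neighbour vote within a window.

    ``window`` counts loci per flank (so up to ``2 * window`` flanking loci
    enter each distance computation, truncated at chromosome ends). It may
    be a single integer or a per-chromosome mapping. Observed calls are
    never altered; predictions use observed data only, so the operation is
    idempotent.
    """
    _check_inbred(G.values)
    values = G.values.copy()
    for chrom, idx in _chrom_blocks(L):
        w = window[chrom] if isinstance(window, dict) else int(window)
        if w < 1:
            raise ValidationError("window must be >= 1")
        block = G.values[:, idx]  # predictions from original observed data
        filled = values[:, idx]
        stats = _WindowStats(block, w)
        for jj in range(block.shape[1]):
            targets = np.flatnonzero(block[:, jj] == MISSING)
            if len(targets) == 0:
                continue
            mism, comp = stats.at(jj)
            filled[targets, jj] = _predict_column(block, jj, mism, comp, targets)
        values[:, idx] = filled
    return GenotypeMatrix(values, list(G.accession_ids))


def _self_accuracy_block(block: np.ndarray, w: int) -> float:
    """Leave-one-out self-prediction accuracy of one chromosome block."""
    stats = _WindowStats(block, w)
    correct = 0
    total = 0
    for jj in range(block.shape[1]):
        targets = np.flatnonzero(block[:, jj] != MISSING)
        if len(targets) == 0:
            continue
        mism, comp = stats.at(jj)
        # masking one call at a time: the window excludes jj, and each
        # target's own call is hidden from the donor set by construction
        # (a line is never its own donor), so pairwise window counts and
        # the donor calls at jj are unaffected by the mask.
        pred = _predict_column(block, jj, mism, comp, targets)
        correct += int((pred == block[targets, jj]).sum())
        total += len(targets)
    return correct / total if total else float("nan")


def select_window_size(
    G: GenotypeMatrix,
    L: pd.DataFrame,
    candidates=DEFAULT_WINDOW_CANDIDATES,
) -> tuple[dict[str, int], dict[str, dict[int, float]]]:
    """Choose the imputation window per chromosome by self-prediction.

    For each candidate window every observed call is masked one at a time
    and predicted by the imputation rule; accuracy is the fraction of
    correct self-predictions. Returns the per-chromosome argmax (smallest
    candidate on ties) and the full accuracy table.

    Candidates that span the whole chromosome are equivalent; only the
    smallest such candidate is evaluated and the others inherit its
    accuracy.
    """
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValidationError("empty window candidate set")
    if candidates[0] < 1:
        raise ValidationError("window candidates must be >= 1")
    _check_inbred(G.values)
    if (G.values != MISSING).sum() == 0:
        raise ValidationError("no observed calls to self-predict")
    chosen: dict[str, int] = {}
    table: dict[str, dict[int, float]] = {}
    for chrom, idx in _chrom_blocks(L):
        block = G.values[:, idx]
        m = block.shape[1]
        accs: dict[int, float] = {}
        cache: dict[int, float] = {}
        for w in candidates:
            w_eff = min(w, m - 1) if m > 1 else 1
            if w_eff not in cache:
                cache[w_eff] = _self_accuracy_block(block, w_eff)
            accs[w] = cache[w_eff]
        best = max(accs, key=lambda w: (accs[w], -w))
        chosen[chrom] = best
        table[chrom] = accs
    return chosen, table


def imputation_concordance(
    G_original: GenotypeMatrix, G_imputed: GenotypeMatrix
) -> float:
    """Pearson correlation of dosages over entries observed in the original.

    The pre/post-imputation concordance reported for GBS panels; with
    observed calls preserved it is 1.0 by construction, and it degrades
    only if imputation (or any other step) altered observed entries.
    """
    a = G_original.values
    b = G_imputed.values
    if a.shape != b.shape:
        raise ValidationError("matrices differ in shape")
    mask = a != MISSING
    x = a[mask].astype(float)
    y = b[mask].astype(float)
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: fewer than 2 observed entries or zero variance"
        )
    return float(np.corrcoef(x, y)[0, 1])


def run_qc(
    G: GenotypeMatrix,
    L: pd.DataFrame,
    *,
    max_md: float = DEFAULT_MAX_MISSING,
    min_maf: float = DEFAULT_MIN_MAF,
    window: int | str = "auto",
    window_candidates=DEFAULT_WINDOW_CANDIDATES,
) -> tuple[GenotypeMatrix, pd.DataFrame, QcReport]:
    """Full chain: het-to-missing, missing filter, imputation, MAF filter."""
    report = QcReport(n_loci_in=G.n_loci)
    G1, n_het = het_to_missing(G)
    report.n_het_converted = n_het
    G2, L2 = filter_missing(G1, L, max_md)
    report.n_loci_after_missing_filter = G2.n_loci
    if G2.n_loci > 0 and not G2.is_complete():
        if window == "auto":
            chosen, table = select_window_size(G2, L2, window_candidates)
            report.chosen_window_size = chosen
            report.imputation_self_accuracy = table
            G3 = impute_window(G2, L2, chosen)
        else:
            w = int(window)
            report.chosen_window_size = {
                c: w for c in L2["chrom"].unique()
            }
            G3 = impute_window(G2, L2, w)
    else:
        G3 = G2
    G4, L4 = filter_maf(G3, L2, min_maf)
    report.n_loci_after_maf_filter = G4.n_loci
    return G4, L4, report
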