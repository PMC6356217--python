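import numpy as np
import pytest

from beanld.errors import UndefinedCorrelationError, ValidationError
from beanld.genotype_io import MISSING, GenotypeMatrix, build_locus_table
from beanld.qc_impute import (
    filter_maf,
    filter_missing,
    het_to_missing,
    imputation_concordance,
    impute_window,
    run_qc,
    select_window_size,
)
from beanld.synthetic_panel import PanelSpec, simulate_panel


def _panel(values, chrom=None, pos=None):
    values = np.asarray(values, dtype=np.int8)
    n, m = values.shape
    ids = [f"l{i}" for i in range(n)]
    chrom = chrom or ["Pv01"] * m
    pos = pos or list(range(100, 100 + 100 * m, 100))
    G = GenotypeMatrix(values, ids)
    L = build_locus_table(chrom, pos, ["A"] * m, ["G"] * m, values)
    return G, L


def test_het_to_missing_converts_all_heterozygotes():
    G, _ = _panel([[0, 1, 0], [1, 1, 2], [2, 1, 2]])
    G2, n = het_to_missing(G)
    assert n == 4
    assert not (G2.values == 1).any()
    # column of all hets becomes all-missing; others untouched
    np.testing.assert_array_equal(G2.values[:, 1], [MISSING] * 3)
    np.testing.assert_array_equal(G2.values[:, 2], [0, 2, 2])
    G3, n3 = het_to_missing(G2)
    assert n3 == 0 and np.array_equal(G2.values, G3.values)


def test_missing_filter_boundary_is_inclusive():
    # 180 lines: 18 missing (exactly 10%) kept, 19 dropped
    col_keep = np.array([MISSING] * 18 + [0] * 81 + [2] * 81)
    col_drop = np.array([MISSING] * 19 + [0] * 81 + [2] * 80)
    G, L = _panel(np.column_stack([col_keep, col_drop]))
    G2, L2 = filter_missing(G, L, 0.10)
    assert G2.n_loci == 1 and L2["pos"].iloc[0] == 100
    G3, _ = filter_missing(G, L, 1.0)
    assert G3.n_loci == 2


def test_missing_filter_small_panel_counts():
    rows = 10
    cols = []
    for n_miss in (0, 1, 2):
        col = np.array([MISSING] * n_miss + [0] * (rows - n_miss - 2) + [2, 2])
        cols.append(col)
    G, L = _panel(np.column_stack(cols))
    G2, _ = filter_missing(G, L, 0.10)
    assert G2.n_loci == 2  # survivors have <= 1 missing of 10


def test_maf_filter_boundary_keeps_exact_threshold():
    # 180 complete calls, 9 minor-homozygote lines -> maf 0.05 retained
    col_at = np.array([2] * 9 + [0] * 171)
    col_below = np.array([2] * 8 + [0] * 172)
    col_mono = np.zeros(180, dtype=int)
    G, L = _panel(np.column_stack([col_at, col_below, col_mono]))
    G2, L2 = filter_maf(G, L, 0.05)
    assert G2.n_loci == 1 and L2["maf"].iloc[0] == pytest.approx(0.05)
    # min_maf = 0 keeps everything, including monomorphic loci (0 >= 0)
    G3, _ = filter_maf(G, L, 0.0)
    assert G3.n_loci == 3


def test_impute_copies_unique_nearest_neighbour(toy_matrix):
    # A=(0,0,?,0) matches B exactly over the flanking window -> copies B's 2
    G, L = toy_matrix
    G2 = impute_window(G, L, window=2)
    assert G2.values[0, 2] == 2
    # observed entries untouched
    obs = G.values != MISSING
    np.testing.assert_array_equal(G.values[obs], G2.values[obs])


def test_impute_without_missing_is_identity_and_idempotent(toy_matrix):
    G, L = toy_matrix
    G2 = impute_window(G, L, window=2)
    G3 = impute_window(G2, L, window=2)
    np.testing.assert_array_equal(G2.values, G3.values)


def test_impute_recovers_duplicated_lines_exactly():
    rng = np.random.default_rng(4)
    base = rng.choice([0, 2], size=(6, 40))
    full = np.repeat(base, 3, axis=0)  # 18 lines in 6 identical triplets
    masked = full.copy()
    holes = rng.random(full.shape) < 0.15
    masked[holes] = MISSING
    G, L = _panel(masked)
    G2 = impute_window(G, L, window=5)
    np.testing.assert_array_equal(G2.values, full)


def test_window_selection_prefers_smallest_on_ties():
    # base lines pairwise distinct inside every >= 2-locus window
    base = np.zeros((3, 30), dtype=int)
    base[1] = 2
    base[2] = np.tile([0, 2], 15)
    full = np.repeat(base, 2, axis=0)
    G, L = _panel(full)
    chosen, table = select_window_size(G, L, candidates=range(3, 9))
    assert chosen["Pv01"] == 3
    assert all(acc == 1.0 for acc in table["Pv01"].values())


def test_window_selection_matches_exhaustive_loo_oracle():
    """Hand-coded leave-one-out loop on a 6x12 panel reproduces accuracies."""
    rng = np.random.default_rng(15)
    values = rng.choice([0, 2, MISSING], size=(6, 12), p=[0.45, 0.45, 0.1])
    values[:, 0] = [0, 0, 0, 2, 2, 2]  # guarantee an observed column
    G, L = _panel(values)
    _, table = select_window_size(G, L, candidates=[2, 4])

    def predict(i, j, w):
        lo, hi = max(0, j - w), min(values.shape[1], j + w + 1)
        win = [c for c in range(lo, hi) if c != j]
        best, bestd = [], None
        for h in range(values.shape[0]):
            if h == i or values[h, j] == MISSING:
                continue
            comp = [c for c in win if values[i, c] != MISSING and values[h, c] != MISSING]
            if not comp:
                continue
            d = sum(values[i, c] != values[h, c] for c in comp) / len(comp)
            if bestd is None or d < bestd - 1e-12:
                best, bestd = [h], d
            elif abs(d - bestd) <= 1e-12:
                best.append(h)
        col = [values[h, j] for h in range(values.shape[0]) if h != i and values[h, j] != MISSING]
        major = 2 if col.count(2) > col.count(0) else 0
        if not best:
            return major
        calls = [values[h, j] for h in best]
        if calls.count(2) > calls.count(0):
            return 2
        if calls.count(0) > calls.count(2):
            return 0
        return major

    for w in (2, 4):
        correct = total = 0
        for i in range(values.shape[0]):
            for j in range(values.shape[1]):
                if values[i, j] == MISSING:
                    continue
                total += 1
                correct += predict(i, j, w) == values[i, j]
        assert table["Pv01"][w] == pytest.approx(correct / total)


def test_self_accuracy_invariant_under_line_permutation():
    rng = np.random.default_rng(23)
    values = rng.choice([0, 2, MISSING], size=(10, 25), p=[0.45, 0.45, 0.1])
    G, L = _panel(values)
    _, t1 = select_window_size(G, L, candidates=[3, 6])
    perm = rng.permutation(10)
    G2 = GenotypeMatrix(values[perm], [f"l{i}" for i in perm])
    _, t2 = select_window_size(G2, L, candidates=[3, 6])
    assert t1 == t2


def test_concordance_definition_and_degenerate_input():
    a = GenotypeMatrix(np.array([[0, 2, 0, 2]], dtype=np.int8).T.reshape(1, 4), ["x"])
    same = imputation_concordance(a, a)
    assert same == pytest.approx(1.0)
    b = GenotypeMatrix(np.array([[2, 0, 2, 0]], dtype=np.int8).reshape(1, 4), ["x"])
    assert imputation_concordance(a, b) == pytest.approx(-1.0)
    mono = GenotypeMatrix(np.zeros((1, 4), dtype=np.int8), ["x"])
    with pytest.raises(UndefinedCorrelationError):
        imputation_concordance(mono, mono)


def test_qc_chain_counts_are_consistent(small_panel):
    G, L, _ = small_panel
    G2, L2, report = run_qc(G, L, window_candidates=range(5, 21))
    assert report.n_loci_in == G.n_loci
    assert (
        report.n_loci_in
        >= report.n_loci_after_missing_filter
        >= report.n_loci_after_maf_filter
        == G2.n_loci
        == len(L2)
    )
    assert G2.is_complete()
    for chrom, accs in report.imputation_self_accuracy.items():
        best = report.chosen_window_size[chrom]
        top = max(accs.values())
        assert accs[best] == top
        assert best == min(w for w, a in accs.items() if a == top)


def test_window_validation_errors(toy_matrix):
    G, L = toy_matrix
    with pytest.raises(ValidationError):
        impute_window(G, L, window=0)
    with pytest.raises(ValidationError):
        select_window_size(G, L, candidates=[])
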