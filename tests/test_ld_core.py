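import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_inbred_pair, random_kinship
from oracles import (
    brute_fisher_two_sided,
    brute_r2,
    brute_r2_s,
    brute_r2_v,
    brute_r2_vs,
)

from beanld.errors import (
    DegenerateTableError,
    InsufficientDataError,
    MonomorphicLocusError,
    ValidationError,
)
from beanld.genotype_io import MISSING, GenotypeMatrix, build_locus_table
from beanld.ld_core import (
    fdr_bh,
    fisher_exact_ld,
    pairwise_ld,
    r2,
    r2_s,
    r2_v,
    r2_vs,
    regularize_kinship,
)


def test_r2_hand_examples():
    xa = np.array([0, 0, 2, 2])
    assert r2(xa, xa) == pytest.approx(1.0)
    assert r2(xa, 2 - xa) == pytest.approx(1.0)
    assert r2(xa, [0, 2, 0, 2]) == pytest.approx(0.0, abs=1e-12)
    assert r2(xa, [0, 0, 2, 0]) == pytest.approx(1.0 / 3.0)


def test_r2_skips_missing_and_guards_degenerate():
    xa = np.array([0, 0, 2, 2, MISSING])
    xb = np.array([0, 0, 2, 0, 2])
    assert r2(xa, xb) == pytest.approx(1.0 / 3.0)
    with pytest.raises(InsufficientDataError):
        r2([0, 2, MISSING, MISSING], [0, 2, 0, 2])
    with pytest.raises(MonomorphicLocusError):
        r2([0, 0, 0, 0], [0, 2, 0, 2])


def test_structure_confounded_pair_raises_monomorphic_residual():
    pool = np.array([0, 0, 0, 0, 2, 2, 2, 2], dtype=float)
    S = (pool - pool.mean())[:, None]
    with pytest.raises(MonomorphicLocusError):
        r2_s(pool, pool, S)


def test_corrected_measures_match_brute_force_on_random_instances():
    rng = np.random.default_rng(101)
    for _ in range(100):
        n = int(rng.integers(6, 15))
        xa, xb = random_inbred_pair(rng, n)
        S = rng.normal(size=(n, 2))
        S -= S.mean(axis=0)
        V = regularize_kinship(random_kinship(rng, n), ridge=0.0)
        assert r2_s(xa, xb, S) == pytest.approx(brute_r2_s(xa, xb, S), abs=1e-9)
        assert r2_v(xa, xb, V, ridge=0.0) == pytest.approx(
            brute_r2_v(xa, xb, V), abs=1e-9
        )
        assert r2_vs(xa, xb, S, V, ridge=0.0) == pytest.approx(
            brute_r2_vs(xa, xb, S, V), abs=1e-9
        )


def test_diagonal_kinship_matches_weighted_gls_oracle():
    xa = np.array([0.0, 2.0, 0.0, 2.0])
    xb = np.array([0.0, 2.0, 2.0, 2.0])
    V = np.diag([1.0, 1.0, 1.0, 4.0])
    assert r2_v(xa, xb, V, ridge=0.0) == pytest.approx(
        brute_r2_v(xa, xb, V), abs=1e-10
    )


def test_reduction_identities_and_allele_flip_invariance():
    rng = np.random.default_rng(202)
    for _ in range(200):
        n = int(rng.integers(8, 25))
        xa, xb = random_inbred_pair(rng, n)
        S = rng.normal(size=(n, 2))
        S -= S.mean(axis=0)
        V = random_kinship(rng, n)
        base = r2(xa, xb)
        # V = I: whitening is a no-op
        assert r2_v(xa, xb, np.eye(n)) == pytest.approx(base, abs=1e-10)
        assert r2_vs(xa, xb, S, np.eye(n)) == pytest.approx(
            r2_s(xa, xb, S), abs=1e-10
        )
        # S empty: no projection
        assert r2_s(xa, xb, None) == pytest.approx(base, abs=1e-10)
        assert r2_vs(xa, xb, None, V) == pytest.approx(
            r2_v(xa, xb, V), abs=1e-10
        )
        # allele flip xa -> 2 - xa leaves every measure unchanged
        fa = 2 - xa
        assert r2(fa, xb) == pytest.approx(base, abs=1e-10)
        assert r2_s(fa, xb, S) == pytest.approx(r2_s(xa, xb, S), abs=1e-10)
        assert r2_v(fa, xb, V) == pytest.approx(r2_v(xa, xb, V), abs=1e-10)
        assert r2_vs(fa, xb, S, V) == pytest.approx(
            r2_vs(xa, xb, S, V), abs=1e-10
        )
        assert fisher_exact_ld(fa, xb) == pytest.approx(
            fisher_exact_ld(xa, xb), abs=1e-12
        )


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(st.sampled_from([0, 2]), min_size=6, max_size=40),
    st.data(),
)
def test_measures_invariant_under_allele_flip_property(xa_list, data):
    xa = np.array(xa_list, dtype=float)
    xb = np.array(
        data.draw(
            st.lists(
                st.sampled_from([0, 2]),
                min_size=len(xa_list),
                max_size=len(xa_list),
            )
        ),
        dtype=float,
    )
    if xa.std() == 0 or xb.std() == 0:
        return
    assert r2(2 - xa, xb) == pytest.approx(r2(xa, xb), abs=1e-10)
    assert r2(xa, 2 - xb) == pytest.approx(r2(xa, xb), abs=1e-10)
    assert fisher_exact_ld(2 - xa, 2 - xb) == pytest.approx(
        fisher_exact_ld(xa, xb), abs=1e-12
    )


def test_fisher_exact_hand_examples():
    # [[3,0],[0,3]]: only 4 tables share the margins; extremes have p 1/20
    xa = np.array([0, 0, 0, 2, 2, 2])
    assert fisher_exact_ld(xa, xa) == pytest.approx(0.1)
    # balanced independent table is modal -> p = 1
    xa20 = np.array([0] * 10 + [2] * 10)
    xb20 = np.array(([0] * 5 + [2] * 5) * 2)
    assert fisher_exact_ld(xa20, xb20) == pytest.approx(1.0)
    # [[10,0],[0,10]]: two extreme tables out of C(20,10)
    assert fisher_exact_ld(xa20, xa20) == pytest.approx(2.0 / 184756.0)
    with pytest.raises(DegenerateTableError):
        fisher_exact_ld(np.zeros(6, dtype=int), xa)
    with pytest.raises(ValidationError):
        fisher_exact_ld(np.array([0, 1, 2, 0, 2, 2]), xa)


def test_fisher_matches_enumeration_oracle():
    rng = np.random.default_rng(303)
    for _ in range(50):
        n = int(rng.integers(6, 20))
        xa, xb = random_inbred_pair(rng, n)
        t00 = int(((xa == 0) & (xb == 0)).sum())
        t01 = int(((xa == 0) & (xb == 2)).sum())
        t10 = int(((xa == 2) & (xb == 0)).sum())
        t11 = int(((xa == 2) & (xb == 2)).sum())
        expected = brute_fisher_two_sided([[t00, t01], [t10, t11]])
        assert fisher_exact_ld(xa, xb) == pytest.approx(expected, abs=1e-10)


def test_fdr_bh_step_up_examples():
    np.testing.assert_array_equal(
        fdr_bh([0.01, 0.02, 0.20], 0.05), [True, True, False]
    )
    np.testing.assert_array_equal(fdr_bh([1.0, 1.0, 1.0]), [False] * 3)
    np.testing.assert_array_equal(fdr_bh([0.04], 0.05), [True])
    assert fdr_bh([]).size == 0


def _panel_for_pairs():
    rng = np.random.default_rng(55)
    values = rng.choice([0, 2], size=(12, 4)).astype(np.int8)
    values[:, 3] = values[:, 2]  # duplicated locus pair across chromosomes
    G = GenotypeMatrix(values, [f"l{i}" for i in range(12)])
    L = build_locus_table(
        ["Pv01", "Pv01", "Pv02", "Pv03"],
        [100, 900, 500, 700],
        ["A"] * 4,
        ["G"] * 4,
        values,
    )
    return G, L


def test_pairwise_ld_scope_and_counts():
    G, L = _panel_for_pairs()
    kin = np.eye(12)
    within = pairwise_ld(G, L, None, kin, scope="within_chrom")
    assert len(within) == 1  # only Pv01 has two loci
    assert within["distance_bp"].iloc[0] == 800
    allp = pairwise_ld(G, L, None, kin, scope="all_pairs")
    assert len(allp) == 6
    assert int(allp["same_chrom"].sum()) == 1
    dup = allp[(allp["chrom_a"] == "Pv02") & (allp["chrom_b"] == "Pv03")]
    for meas in ("r2", "rs2", "rv2", "rvs2"):
        assert dup[meas].iloc[0] == pytest.approx(1.0)


def test_pairwise_ld_independent_of_batch_size():
    G, L = _panel_for_pairs()
    kin = np.eye(12)
    a = pairwise_ld(G, L, None, kin, scope="all_pairs", batch_size=1)
    b = pairwise_ld(G, L, None, kin, scope="all_pairs", batch_size=10_000)
    assert a.equals(b)


def test_pairwise_ld_flags_degenerate_pairs_without_aborting():
    values = np.zeros((10, 3), dtype=np.int8)
    values[:5, 0] = 2
    values[::2, 1] = 2
    # locus 2 monomorphic -> degenerate in every pair that involves it
    G = GenotypeMatrix(values, [f"l{i}" for i in range(10)])
    L = build_locus_table(
        ["Pv01"] * 3, [10, 20, 30], ["A"] * 3, ["G"] * 3, values
    )
    rec = pairwise_ld(G, L, None, np.eye(10), scope="within_chrom")
    assert len(rec) == 3
    assert (rec["status"] == "degenerate").sum() == 2
    ok = rec[rec["status"] == "ok"]
    assert np.isfinite(ok[["r2", "rs2", "rv2", "rvs2", "p_fisher"]]).all().all()
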