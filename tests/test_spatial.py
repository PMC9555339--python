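"""Moran's I: statistic, kNN weights, significance tests, screen and selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cardiocomm.spatial import (
    SpatialWeights,
    build_knn_weights,
    morans_i,
    morans_test,
    screen_genes,
    select_spatial_degs,
)

from conftest import make_matrix, moran_double_loop


def four_cycle() -> SpatialWeights:
    a = np.array(
        [[0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0]], dtype=float
    ) / 2.0
    return SpatialWeights(sp.csr_matrix(a))


def random_weights(rng, n) -> SpatialWeights:
    emb = rng.normal(size=(n, 2))
    return build_knn_weights(emb, k=min(5, n - 1))


class TestKnnWeights:
    def test_line_k1_matches_pairwise_distance_scan(self):
        pts = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0]])
        w = build_knn_weights(pts, k=1, row_standardize=False).w.toarray()
        # nearest neighbours: 0->1, 1->0 (tie with 2 broken by index), 2->1, 3->2;
        # union symmetrization yields the chain
        expected = np.array(
            [[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]], dtype=float
        )
        assert np.array_equal(w, expected)

    def test_k_equals_n_minus_one_complete_graph(self, rng):
        emb = rng.normal(size=(7, 2))
        w = build_knn_weights(emb, k=6, row_standardize=False).w.toarray()
        assert np.array_equal(w > 0, ~np.eye(7, dtype=bool))

    def test_zero_diagonal_and_unit_row_sums(self, rng):
        w = build_knn_weights(rng.normal(size=(40, 2)), k=5).w
        assert not w.diagonal().any()
        rowsums = np.asarray(w.sum(axis=1)).ravel()
        assert np.allclose(rowsums[rowsums > 0], 1.0)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            build_knn_weights(rng.normal(size=(5, 2)), k=5)


class TestMoransI:
    def test_alternating_pattern_on_cycle_is_perfect_dispersion(self):
        assert morans_i(np.array([1.0, -1, 1, -1]), four_cycle()) == pytest.approx(-1.0)

    def test_split_pattern_on_cycle_is_zero(self):
        assert morans_i(np.array([1.0, 1, -1, -1]), four_cycle()) == pytest.approx(0.0)

    def test_constant_vector_undefined(self):
        assert np.isnan(morans_i(np.ones(4), four_cycle()))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            morans_i(np.ones(3), four_cycle())

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 50))
            w = random_weights(rng, n)
            x = rng.normal(size=n)
            assert morans_i(x, w) == pytest.approx(
                moran_double_loop(x, w.w.toarray()), abs=1e-12
            )

    def test_bounded_on_row_standardized_graphs(self, rng):
        for _ in range(20):
            w = random_weights(rng, 30)
            x = rng.normal(size=30)
            assert abs(morans_i(x, w)) <= 1.0 + 1e-9


class TestMoransTest:
    def test_permutation_null_mean_matches_expectation(self, rng):
        n = 25
        w = random_weights(rng, n)
        vals = [morans_i(rng.permutation(np.arange(n, dtype=float)), w) for _ in range(200)]
        expect = -1.0 / (n - 1)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expect) < 3 * se + 1e-12

    def test_sampled_permutation_matches_exhaustive_enumeration(self):
        # 4 nodes: all 4! = 24 relabelings enumerable exactly
        w = four_cycle()
        x = np.array([1.0, -1, 0.5, -0.5])
        obs = morans_i(x, w)
        exact = [
            morans_i(x[list(perm)], w) for perm in itertools.permutations(range(4))
        ]
        p_exact = sum(v >= obs - 1e-12 for v in exact) / len(exact)
        res = morans_test(x, w, method="permutation", n_perm=4999, seed=3)
        assert res.p == pytest.approx(p_exact, abs=0.03)

    def test_clustered_pattern_passes_filter(self, rng):
        # two blobs with distinct means: strong positive autocorrelation
        emb = np.vstack([rng.normal(0, 1, (50, 2)), rng.normal(8, 1, (50, 2))])
        x = np.concatenate([rng.normal(0, 0.3, 50), rng.normal(3, 0.3, 50)])
        w = build_knn_weights(emb, k=8)
        res = morans_test(x, w, method="permutation", n_perm=199, seed=0)
        assert res.i > 0.1
        assert res.p <= 0.05

    def test_analytic_and_permutation_agree_on_strong_signal(self, rng):
        emb = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(6, 1, (40, 2))])
        x = np.concatenate([np.zeros(40), np.ones(40)]) + rng.normal(0, 0.1, 80)
        w = build_knn_weights(emb, k=6)
        pa = morans_test(x, w, method="analytic_z").p
        pp = morans_test(x, w, method="permutation", n_perm=999, seed=1).p
        assert pa < 0.01 and pp < 0.01

    def test_constant_vector_undefined_p(self):
        res = morans_test(np.ones(4), four_cycle())
        assert np.isnan(res.i) and np.isnan(res.p)


def stratum_matrix(rng, n=300, n_genes=30, planted=()):  # planted: gene indices
    emb = rng.normal(0, 1, (n, 2))
    counts = rng.poisson(1.0, (n, n_genes))
    for j in planted:
        d2 = (emb**2).sum(axis=1)
        counts[:, j] = rng.poisson(0.05 + 8.0 * np.exp(-d2), n)
    return make_matrix(counts, embedding=emb)


class TestScreenGenes:
    def test_low_detection_fails_regardless_of_autocorrelation(self, rng):
        m = stratum_matrix(rng, n=400, n_genes=5, planted=(0,))
        # silence gene 0 in all but 1 cell (0.25% detection)
        dense = m.counts.toarray()
        dense[1:, 0] = 0
        dense[0, 0] = 5
        m2 = make_matrix(
            dense, embedding=m.cell_meta[["embedding_x", "embedding_y"]].to_numpy()
        )
        tab = screen_genes(m2, "Normal", "typeA", k=10)
        assert not tab.loc[tab["gene"] == "g000", "passes"].item()

    def test_planted_gene_recovered_among_nulls(self, rng):
        m = stratum_matrix(rng, n=400, n_genes=100, planted=(7,))
        tab = screen_genes(m, "Normal", "typeA", k=10)
        passing = set(tab.loc[tab["passes"], "gene"])
        assert passing == {"g007"}

    def test_null_raw_rate_and_bh_control(self, rng):
        m = stratum_matrix(rng, n=250, n_genes=1000)
        tab = screen_genes(m, "Normal", "typeA", k=10, method="permutation",
                           n_perm=99, seed=5)
        raw = (tab["p"] <= 0.05).sum()
        assert 20 <= raw <= 85  # ~50 expected of 1000 nulls
        assert int(tab["passes"].sum()) == 0

    def test_small_stratum_skipped(self, rng):
        m = stratum_matrix(rng, n=10, n_genes=3)
        tab = screen_genes(m, "Normal", "typeA", k=15)
        assert len(tab) == 0


def moran_row(gene, i, passes, defined=True):
    return {
        "condition": "x", "cell_type": "cardiomyocyte", "gene": gene, "I": i,
        "p": 0.001 if passes else 0.5, "p_adj": 0.01 if passes else 0.9,
        "frac_expressed": 0.5, "defined": defined, "passes": passes,
    }


class TestSelectSpatialDEGs:
    def test_single_condition_rule_above_threshold(self):
        normal = pd.DataFrame([moran_row("g1", 0.05, False)])
        hcm = pd.DataFrame([moran_row("g1", 0.15, True)])
        sel = select_spatial_degs(normal, hcm)
        assert list(sel["gene"]) == ["g1"]
        assert sel["rule"].item() == "single"
        assert sel["condition"].item() == "HCM"

    def test_single_condition_rule_below_threshold(self):
        normal = pd.DataFrame([moran_row("g1", 0.0, False)])
        hcm = pd.DataFrame([moran_row("g1", 0.09, True)])
        assert len(select_spatial_degs(normal, hcm)) == 0

    def test_both_condition_delta_rule(self):
        normal = pd.DataFrame(
            [moran_row("close", 0.25, True), moran_row("far", 0.25, True)]
        )
        hcm = pd.DataFrame(
            [moran_row("close", 0.30, True), moran_row("far", 0.40, True)]
        )
        sel = select_spatial_degs(normal, hcm)
        assert list(sel["gene"]) == ["far"]  # |0.25-0.40| = 0.15 > 0.1
        assert sel["delta_I"].item() == pytest.approx(0.15)

    def test_gene_passing_nowhere_never_selected(self):
        normal = pd.DataFrame([moran_row("g1", 0.5, False)])
        hcm = pd.DataFrame([moran_row("g1", 0.5, False)])
        assert len(select_spatial_degs(normal, hcm)) == 0

    def test_computed_availability_alternative(self):
        # defined in both conditions but significant in one: under the
        # "computed" reading the both-condition delta rule applies
        normal = pd.DataFrame([moran_row("g1", 0.0, False)])
        hcm = pd.DataFrame([moran_row("g1", 0.5, True)])
        sel = select_spatial_degs(normal, hcm, availability="computed")
        assert sel["rule"].item() == "both"
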