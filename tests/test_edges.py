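"""Empirical edge-centric measures and their exact identities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import edgenull as en


def _random_bold(n, t, seed):
    return en.zscore(en.BoldMatrix(np.random.default_rng(seed).normal(size=(n, t))))


class TestZscore:
    def test_centres_and_scales(self, rng):
        bold = en.BoldMatrix(rng.normal(2.0, 5.0, size=(5, 100)))
        z = en.zscore(bold)
        assert np.all(np.abs(z.values.mean(axis=1)) < 1e-10)
        assert np.allclose(z.values.std(axis=1), 1.0, atol=1e-12)  # population scale
        assert z.mean is not None and z.std is not None

    def test_idempotent(self, rng):
        z = en.zscore(en.BoldMatrix(rng.normal(size=(4, 50))))
        again = en.zscore(z)
        assert np.allclose(again.values, z.values, atol=1e-12)

    def test_affine_invariance(self, rng):
        raw = rng.normal(size=(5, 100))
        z = en.zscore(en.BoldMatrix(raw))
        for i in range(5):
            assert np.corrcoef(raw[i], z.values[i])[0, 1] == pytest.approx(1.0)

    def test_simple_row(self):
        z = en.zscore(en.BoldMatrix(np.array([[1.0, 2.0, 3.0], [0.0, 1.0, 0.0]])))
        assert abs(z.values[0].mean()) < 1e-12

    def test_constant_row_names_node(self):
        bold = en.BoldMatrix(np.array([[1.0, 2.0], [3.0, 3.0]]), node_ids=["a", "b"])
        with pytest.raises(en.DegenerateSignalError, match="'b'"):
            en.zscore(bold)


class TestEdgeSet:
    @pytest.mark.parametrize("n,expected", [(2, 1), (5, 10), (200, 19900)])
    def test_edge_count(self, n, expected):
        assert en.EdgeSet(n).n_edges == expected

    def test_lexicographic_order_and_bijection(self):
        es = en.EdgeSet(6)
        pairs = [tuple(p) for p in es.pairs()]
        assert pairs == sorted(pairs)
        for e, (i, j) in enumerate(pairs):
            assert es.index(i, j) == e
            assert es.index(j, i) == e  # unordered
            assert es.pair(e) == (i, j)

    @given(st.integers(2, 40))
    def test_every_pair_exactly_once(self, n):
        es = en.EdgeSet(n)
        assert len({tuple(p) for p in es.pairs()}) == n * (n - 1) // 2

    def test_self_pair_rejected(self):
        with pytest.raises(en.InvalidInputError):
            en.EdgeSet(4).index(2, 2)


class TestEdgeTimeSeries:
    def test_hand_product(self):
        z = en.BoldMatrix(np.array([[1.0, -1.0], [1.0, -1.0]]), zscored=True)
        ets = en.edge_time_series(z)
        assert np.array_equal(ets.values, np.array([[1.0, 1.0]]))

    def test_duplicated_node_gives_square(self, rng):
        row = en.zscore(en.BoldMatrix(rng.normal(size=(1, 50)).repeat(2, axis=0) + 0))
        ets = en.edge_time_series(row)
        assert np.all(ets.values >= 0.0)
        assert np.allclose(ets.values[0], row.values[0] ** 2)

    def test_time_mean_equals_correlation(self):
        z = _random_bold(4, 50, seed=0)
        ets = en.edge_time_series(z)
        R = en.CorrelationModel.from_bold(z).matrix
        iu = np.triu_indices(4, 1)
        assert np.allclose(ets.values.mean(axis=1), R[iu], atol=1e-12)


class TestEdgeFC:
    def test_unit_diagonal(self, rng):
        efc = en.edge_fc(en.edge_time_series(_random_bold(5, 40, 1)))
        assert np.allclose(np.diag(efc.values), 1.0)
        assert np.allclose(efc.values, efc.values.T)
        assert np.all(np.abs(efc.values) <= 1.0 + 1e-12)

    def test_sign_flip_antisymmetry(self):
        # node 2 = -node 1, so edge (0,1) = -(0,2) and their eFC entry is -1
        base = _random_bold(2, 30, seed=2)
        z = en.BoldMatrix(
            np.vstack([base.values[0], base.values[1], -base.values[1]]), zscored=True
        )
        efc = en.edge_fc(en.edge_time_series(z)).values
        es = en.EdgeSet(3)
        assert efc[es.index(0, 1), es.index(0, 2)] == pytest.approx(-1.0)

    def test_matches_double_loop_oracle(self):
        z = _random_bold(4, 20, seed=3)
        ets = en.edge_time_series(z)
        efc = en.edge_fc(ets).values
        E = ets.values.shape[0]
        oracle = np.empty((E, E))
        for e in range(E):
            for f in range(E):
                num = sum(ets.values[e, t] * ets.values[f, t] for t in range(20))
                den = np.sqrt(sum(ets.values[e, t] ** 2 for t in range(20))) * np.sqrt(
                    sum(ets.values[f, t] ** 2 for t in range(20))
                )
                oracle[e, f] = num / den
        assert np.allclose(efc, oracle, atol=1e-10)

    def test_zero_edge_rejected(self):
        es = en.EdgeSet(3)
        vals = np.ones((3, 5))
        vals[1] = 0.0
        with pytest.raises(en.DegenerateEdgeError, match=r"\(0, 2\)"):
            en.edge_fc(en.EdgeTimeSeriesMatrix(values=vals, edge_set=es))


class TestRss:
    def test_zero_frame(self):
        vals = np.array([[1.0, 0.0, -1.0], [2.0, 0.0, -2.0]])
        z = en.BoldMatrix(vals, zscored=True)
        for conv in ("upper_triangular", "all_pairs"):
            assert en.rss(z, conv).values[1] == 0.0

    def test_all_ones_frame_all_pairs(self):
        z = en.BoldMatrix(np.ones((6, 2)) * np.array([1.0, -1.0]), zscored=True)
        assert np.allclose(en.rss(z, "all_pairs").values, 6.0)

    def test_all_pairs_equals_squared_norm_via_edge_sum(self):
        z = _random_bold(5, 30, seed=4)
        # brute-force oracle: sum the squares of all N^2 ordered edge products
        full = np.einsum("it,jt->ijt", z.values, z.values)
        oracle = np.sqrt((full**2).sum(axis=(0, 1)))
        direct = np.einsum("it,it->t", z.values, z.values)  # ||z(t)||^2
        assert np.allclose(en.rss(z, "all_pairs").values, direct, atol=1e-10)
        assert np.allclose(oracle, direct, atol=1e-8)

    def test_upper_triangular_matches_edge_definition(self):
        z = _random_bold(5, 30, seed=5)
        ets = en.edge_time_series(z)
        oracle = np.sqrt((ets.values**2).sum(axis=0))
        assert np.allclose(en.rss(z).values, oracle, atol=1e-10)

    def test_nonnegative(self):
        z = _random_bold(4, 100, seed=6)
        assert np.all(en.rss(z).values >= 0.0)


class TestKurtosisRatio:
    def test_single_node_is_one(self, rng):
        z = en.zscore(en.BoldMatrix(rng.normal(size=(1, 200))))
        assert en.kurtosis_ratio_check(z) == pytest.approx(1.0)

    def test_gaussian_bound_large_n(self):
        spec = en.SurrogateSpec(
            correlation=en.CorrelationSpec(200, "identity"), n_frames=2000, seed=7
        )
        z = en.zscore(en.sample_bold(spec))
        # Gaussian kurtosis 3 gives the bound 3N/N^2 = 0.015
        assert en.kurtosis_ratio_check(z) < 0.02

    def test_decreases_with_n(self):
        ratios = []
        for n in (10, 100):
            spec = en.SurrogateSpec(
                correlation=en.CorrelationSpec(n, "identity"), n_frames=3000, seed=8
            )
            ratios.append(en.kurtosis_ratio_check(en.zscore(en.sample_bold(spec))))
        assert ratios[1] < ratios[0]


class TestBinarizeEdges:
    def test_sign_rule(self):
        es = en.EdgeSet(2)
        ets = en.EdgeTimeSeriesMatrix(
            values=np.array([[0.5, -0.2, 3.0, 0.0]]), edge_set=es
        )
        b = en.binarize_edges(ets)
        assert b.values.tolist() == [[1, 0, 1, 0]]
        assert b.tie_count == 1

    def test_perfectly_correlated_nodes_all_ones(self, rng):
        x = rng.normal(size=(1, 60))
        z = en.zscore(en.BoldMatrix(np.vstack([x, x])))
        b = en.binarize_edges(en.edge_time_series(z))
        assert b.tie_count == 0
        assert np.all(b.values == 1)

    def test_independent_edges_fair_coin(self):
        spec = en.SurrogateSpec(
            correlation=en.CorrelationSpec(4, "identity"), n_frames=1_000_000, seed=9
        )
        b = en.binarize_edges(en.edge_time_series(en.zscore(en.sample_bold(spec))))
        assert np.all(np.abs(b.values.mean(axis=1) - 0.5) < 0.0015)

    def test_arcsine_law_on_correlated_surrogate(self, modular_model):
        spec = en.SurrogateSpec(correlation=modular_model, n_frames=200_000, seed=10)
        z = en.zscore(en.sample_bold(spec))
        b = en.binarize_edges(en.edge_time_series(z))
        means = b.values.mean(axis=1)
        es = b.edge_set
        p = en.predict_binary_nfc(modular_model)[es.i_idx, es.j_idx]
        se = np.sqrt(p * (1 - p) / 200_000)
        assert np.all(np.abs(means - p) < 3 * se + 1e-3)


class TestFrameSortedReconstruction:
    def test_full_fraction_is_exact(self, null_surrogate):
        model = en.CorrelationModel.from_bold(null_surrogate)
        out = en.frame_sorted_reconstruction(null_surrogate, model, [1.0])
        assert out.descending[0] == pytest.approx(1.0, abs=1e-10)
        assert out.ascending[0] == pytest.approx(1.0, abs=1e-10)

    def test_top_frames_beat_bottom_frames(self):
        model = en.build_correlation(
            en.CorrelationSpec(50, "modular", module_sizes=(20, 15, 15), rho_within=0.4)
        )
        bold = en.sample_bold(en.SurrogateSpec(correlation=model, n_frames=1200, seed=11))
        out = en.frame_sorted_reconstruction(en.zscore(bold), model, [0.05])
        assert out.descending[0] > out.ascending[0]

    def test_single_aligned_frame_matches_rank1(self, modular_model):
        # frame exactly aligned with u1: z = sqrt(lambda1) u1 (Eq. of aligned frames)
        z_vec = np.sqrt(modular_model.eigenvalues[0]) * modular_model.leading_eigenvector
        values = np.column_stack([z_vec, -0.01 * z_vec])
        bold = en.BoldMatrix(values, zscored=True)
        out = en.frame_sorted_reconstruction(bold, modular_model, [0.5])
        rank1 = en.rank1_fc(modular_model)
        assert out.descending[0] == pytest.approx(
            en.matrix_similarity(rank1, modular_model.matrix), abs=1e-10
        )

    def test_zero_selection_rejected(self, null_surrogate):
        model = en.CorrelationModel.from_bold(null_surrogate)
        with pytest.raises(en.InvalidInputError, match="zero frames"):
            en.frame_sorted_reconstruction(null_surrogate, model, [1e-9])


class TestStaticInvariance:
    def test_efc_and_rss_invariant_under_frame_permutation(self, rng):
        z = _random_bold(5, 200, seed=12)
        perm = rng.permutation(200)
        z_perm = en.BoldMatrix(z.values[:, perm], zscored=True)
        a = en.edge_fc(en.edge_time_series(z)).values
        b = en.edge_fc(en.edge_time_series(z_perm)).values
        assert np.allclose(a, b, atol=1e-12)
        assert np.allclose(
            np.sort(en.rss(z).values), np.sort(en.rss(z_perm).values), atol=1e-12
        )

    def test_empirical_efc_converges_to_prediction(self):
        model = en.build_correlation(
            en.CorrelationSpec(10, "random_factor", n_factors=3, seed=13)
        )
        bold = en.sample_bold(
            en.SurrogateSpec(correlation=model, n_frames=100_000, seed=14)
        )
        emp = en.edge_fc(en.edge_time_series(en.zscore(bold))).values
        pred = en.predict_efc(model).values
        iu = np.triu_indices(emp.shape[0], 1)
        assert np.corrcoef(emp[iu], pred[iu])[0, 1] > 0.99
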