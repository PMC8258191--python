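"""Hellinger transform, PCA, clustering diagnostics, SCA, variation partitioning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.distance import pdist, squareform

import oracles
from mesozoo import community as comm


class TestHellinger:
    def test_hand_arithmetic_example(self):
        out = comm.hellinger_transform(np.array([[4.0, 1.0, 4.0]]))
        np.testing.assert_allclose(out, [[2 / 3, 1 / 3, 2 / 3]])
        assert np.sum(out**2) == pytest.approx(1.0)

    def test_single_taxon_row_is_one(self):
        np.testing.assert_allclose(comm.hellinger_transform(np.array([[7.3]])), [[1.0]])

    def test_identical_rows_stay_identical(self):
        out = comm.hellinger_transform(np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out[0], out[1])

    @given(
        arrays(
            float,
            (5, 4),
            elements=st.floats(0.0, 1e4, allow_nan=False, allow_infinity=False),
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_nonzero_rows_have_unit_sum_of_squares(self, X):
        out = comm.hellinger_transform(X)
        totals = X.sum(axis=1)
        norms = (out**2).sum(axis=1)
        np.testing.assert_allclose(norms[totals > 0], 1.0, atol=1e-9)
        assert np.all(norms[totals == 0] == 0)

    def test_not_idempotent_on_generic_row(self):
        once = comm.hellinger_transform(np.array([[4.0, 1.0, 4.0]]))
        twice = comm.hellinger_transform(once)
        assert not np.allclose(once, twice)

    def test_distances_bounded_by_sqrt2(self, rng):
        X = rng.random((30, 8)) * 100
        H = comm.hellinger_transform(X)
        assert pdist(H).max() <= np.sqrt(2) + 1e-12

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            comm.hellinger_transform(np.array([[1.0, -0.1]]))

    def test_transformer_in_sklearn_pipeline(self, rng):
        from sklearn.pipeline import make_pipeline

        pipe = make_pipeline(comm.HellingerTransformer(), comm.CommunityPCA(n_components=2))
        scores = pipe.fit_transform(rng.random((10, 5)))
        assert scores.shape == (10, 2)


class TestPCA:
    def test_rank_one_matrix_single_eigenvalue(self):
        X = np.outer([1.0, 2.0, 3.0, 4.0], [0.5, 0.5, 0.7])
        model = comm.CommunityPCA().fit(X)
        nonzero = np.sum(model.eigenvalues_ > 1e-12)
        assert nonzero == 1

    def test_matches_dense_eigensolver(self, rng):
        X = comm.hellinger_transform(rng.random((12, 7)))
        model = comm.CommunityPCA().fit(X)
        w, _ = oracles.naive_covariance_eigen(np.asarray(X))
        np.testing.assert_allclose(np.sort(model.eigenvalues_)[::-1], w[: len(model.eigenvalues_)], atol=1e-8)
        assert np.sum(model.eigenvalues_) == pytest.approx(np.sum(w), abs=1e-8)

    def test_duplicate_rows_get_identical_scores(self, rng):
        X = rng.random((6, 4))
        X = np.vstack([X, X[2]])
        model = comm.CommunityPCA().fit(X)
        scores = model.transform(X)
        np.testing.assert_allclose(scores[2], scores[-1], atol=1e-10)


class TestClusterMethodSelection:
    def test_ultrametric_configuration_upgma_perfect(self):
        # two tight pairs with all cross distances equal: within 1, across 2
        X = np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
             [0.5, np.sqrt(3.5), 0.5], [0.5, np.sqrt(3.5), -0.5]]
        )
        sel = comm.cluster_suite(X)
        upgma = sel.models_["upgma"]
        assert upgma.cophenetic_correlation == pytest.approx(1.0)
        assert upgma.gower_criterion == pytest.approx(0.0, abs=1e-20)

    def test_equilateral_degenerate_flagged(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        sel = comm.cluster_suite(X)
        assert np.isnan(sel.models_["upgma"].cophenetic_correlation)

    def test_single_linkage_equals_minimax_paths(self, rng):
        X = rng.random((6, 3))
        sel = comm.cluster_suite(X)
        d = squareform(pdist(X))
        expected = oracles.minimax_path_distances(d)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(
            sel.models_["single"].cophenetic_matrix, expected, atol=1e-12
        )

    @pytest.mark.parametrize("method", ["single", "complete", "upgma", "ward"])
    def test_cophenetic_matches_naive_agglomeration(self, method):
        # brute-force agglomeration oracle on small random point sets
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = rng.integers(4, 8)
            X = rng.random((n, 3))
            sel = comm.ClusterMethodSelector(methods=[method]).fit(X)
            expected = oracles.naive_linkage_cophenetic(X, method)
            np.testing.assert_allclose(
                sel.models_[method].cophenetic_matrix, expected, atol=1e-9,
                err_msg=f"{method}, seed {seed}",
            )

    def test_fewer_than_three_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            comm.cluster_suite(rng.random((2, 4)))

    def test_selection_prefers_best_fitting_dendrogram(self, rng):
        X = comm.hellinger_transform(rng.random((15, 6)))
        sel = comm.cluster_suite(X)
        best = sel.selection_.set_index("method").loc[sel.best_method_]
        assert best["cophenetic_correlation"] == sel.selection_["cophenetic_correlation"].max()


class TestClusterNumberDiagnostics:
    def test_two_separated_blobs_peak_at_k2(self):
        X = np.array([[0.0], [0.1], [0.2], [10.0], [10.1]])
        sel = comm.cluster_suite(X)
        table, suggested = comm.cluster_number_diagnostics(
            sel.models_["upgma"], sel.distances_
        )
        silmax = table.loc[table["mean_silhouette"].idxmax(), "k"]
        assert silmax == 2
        assert suggested == 2

    def test_singleton_silhouette_convention(self):
        X = np.array([[0.0], [1.0], [2.5], [10.0]])
        sel = comm.cluster_suite(X)
        table, _ = comm.cluster_number_diagnostics(sel.models_["upgma"], sel.distances_, k_range=[3])
        # k = n−1 forces singletons; their silhouette contribution is 0
        d = squareform(sel.distances_)
        from scipy.cluster import hierarchy

        labels = hierarchy.fcluster(sel.models_["upgma"].linkage_matrix, 3, "maxclust")
        naive = oracles.naive_silhouette(d, labels).mean()
        assert table.loc[0, "mean_silhouette"] == pytest.approx(naive)

    def test_binary_correlation_peaks_at_true_partition(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (8, 2)), rng.normal(6, 0.3, (7, 2))])
        sel = comm.cluster_suite(X)
        table, _ = comm.cluster_number_diagnostics(
            sel.models_["upgma"], sel.distances_, k_range=[2, 3, 4]
        )
        best_k = table.loc[table["binary_correlation"].idxmax(), "k"]
        assert best_k == 2

    def test_silhouette_and_binary_match_naive_reimplementations(self, rng):
        X = rng.random((20, 5))
        sel = comm.cluster_suite(X)
        model = sel.best_model_
        d = squareform(sel.distances_)
        from scipy.cluster import hierarchy

        table, _ = comm.cluster_number_diagnostics(model, sel.distances_, k_range=[2, 4, 6])
        for _, row in table.iterrows():
            labels = hierarchy.fcluster(model.linkage_matrix, int(row["k"]), "maxclust")
            assert row["mean_silhouette"] == pytest.approx(
                oracles.naive_silhouette(d, labels).mean(), abs=1e-10
            )
            assert row["binary_correlation"] == pytest.approx(
                oracles.naive_binary_correlation(d, labels), abs=1e-10
            )

    def test_out_of_range_k_rejected(self, rng):
        X = rng.random((6, 3))
        sel = comm.cluster_suite(X)
        with pytest.raises(ValueError):
            comm.cluster_number_diagnostics(sel.best_model_, sel.distances_, k_range=[6])


class TestSpeciesContribution:
    def test_single_differing_taxon_contributes_everything(self):
        X = pd.DataFrame(
            [[1.0, 0.5], [1.0, 0.5], [1.0, 0.9], [1.0, 0.9]], columns=["a", "b"]
        )
        out = comm.species_contribution(X, [1, 1, 2, 2])
        contrib = out.set_index("taxon")["contribution"]
        assert contrib["b"] == pytest.approx(1.0)
        assert contrib["a"] == pytest.approx(0.0)

    def test_equal_differences_split_evenly(self):
        X = pd.DataFrame(np.array([[0.0] * 4, [1.0] * 4]), columns=list("abcd"))
        out = comm.species_contribution(X, [1, 2])
        np.testing.assert_allclose(out["contribution"], 0.25)

    def test_contributions_sum_to_one_per_pair(self, community_matrix):
        H = comm.hellinger_transform(community_matrix)
        sel = comm.cluster_suite(H)
        labels = comm.cut_tree(sel.best_model_, 3)
        out = comm.species_contribution(H, labels)
        sums = out.groupby(["cluster_a", "cluster_b"])["contribution"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_flag_threshold_prints_7_and_13_percent(self):
        assert round(comm.sca_flag_threshold(28)) == 7
        assert round(comm.sca_flag_threshold(15)) == 13

    def test_identical_centroids_flagged_undefined(self):
        X = pd.DataFrame([[1.0, 2.0]] * 4, columns=["a", "b"])
        out = comm.species_contribution(X, [1, 1, 2, 2])
        assert out["contribution"].isna().all()


class TestCircularPredictor:
    def test_arithmetic_examples(self):
        out = comm.circular_date_predictor([91])
        assert out[0, 0] == pytest.approx(1.0, abs=1e-4)
        assert out[0, 1] == pytest.approx(0.0043, abs=1e-3)
        full = comm.circular_date_predictor([365])
        assert full[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert full[0, 1] == pytest.approx(1.0)

    def test_rows_on_unit_circle(self):
        out = comm.circular_date_predictor(list(range(1, 367)))
        np.testing.assert_allclose((out**2).sum(axis=1), 1.0)

    def test_year_boundary_dates_are_close(self):
        sep, aug, apr = 266, 232, 91  # late Sep 2013, late Aug 2014, early Apr
        points = comm.circular_date_predictor([sep, aug, apr])
        d_sep_aug = np.linalg.norm(points[0] - points[1])
        d_sep_apr = np.linalg.norm(points[0] - points[2])
        assert d_sep_aug < d_sep_apr

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            comm.circular_date_predictor([0])


class TestRDA:
    def test_exact_linear_response(self, rng):
        X = rng.random((20, 2))
        Y = X @ rng.random((2, 5))
        r2, adj = comm.rda_adjusted_r2(Y, X)
        assert r2 == pytest.approx(1.0)

    def test_orthogonal_predictor_penalized_below_zero(self):
        n = 12
        Y = np.column_stack([np.sin(np.arange(n)), np.cos(np.arange(n))])
        X = (np.arange(n) % 2).astype(float)  # unrelated alternation
        r2, adj = comm.rda_adjusted_r2(Y, X)
        assert r2 < 0.2
        assert adj < r2

    def test_ezekiel_formula_oracle(self):
        # adj = 1 − (1 − 0.5)(23)/(21)
        n, m, r2 = 24, 2, 0.5
        adj = 1 - (1 - r2) * (n - 1) / (n - m - 1)
        assert adj == pytest.approx(0.4524, abs=5e-5)
        # recover through the implementation on a constructed data set
        rng = np.random.default_rng(1)
        X = rng.random((n, m))
        Y = rng.random((n, 4))
        r2_hat, adj_hat = comm.rda_adjusted_r2(Y, X)
        assert adj_hat == pytest.approx(1 - (1 - r2_hat) * (n - 1) / (n - m - 1))


class TestVariationPartition:
    def _stations_doy(self, n=24):
        stations = ["C", "B", "T"] * (n // 3)
        doy = list(np.tile([15, 60, 105, 150, 195, 240, 285, 330], n // 24 * 3))[:n]
        return stations, doy

    def test_identity_sums_to_one_exactly(self, rng):
        stations, doy = self._stations_doy()
        Y = rng.random((24, 6))
        part = comm.variation_partition(Y, stations, doy)
        assert part.a + part.b + part.c + part.d == pytest.approx(1.0, abs=1e-12)

    def test_station_coding_invariance(self, rng):
        stations, doy = self._stations_doy()
        Y = rng.random((24, 6))
        base = comm.variation_partition(Y, stations, doy)
        recoded = comm.variation_partition(
            Y, [{"C": "z9", "B": "a0", "T": "mm"}[s] for s in stations], doy
        )
        for attr in ("a", "b", "c", "d"):
            assert getattr(base, attr) == pytest.approx(getattr(recoded, attr), abs=1e-10)

    def test_pure_seasonal_signal_attributed_to_date(self, rng):
        stations, doy = self._stations_doy()
        date_pred = comm.circular_date_predictor(doy)
        cs = []
        for _ in range(100):
            Y = date_pred @ rng.normal(size=(2, 5)) + rng.normal(0, 0.05, (24, 5))
            part = comm.variation_partition(Y, stations, doy)
            assert part.a > 0
            cs.append(part.c)
        assert abs(np.mean(cs)) < 0.05

    def test_estimator_wrapper(self, rng):
        stations, doy = self._stations_doy()
        Y = rng.random((24, 5))
        est = comm.VariationPartitioner().fit(Y, station=stations, day_of_year=doy)
        assert set(est.fractions_) >= {"a_date_unique", "b_shared", "c_station_unique", "d_residual"}
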