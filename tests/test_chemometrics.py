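import numpy as np
import pytest

from immunomet import chemometrics as chemo
from tests.conftest import make_clouds, make_null


class TestPca:
    def test_collinear_data_explained_by_first_component(self):
        t = np.linspace(0, 1, 10)
        X = np.column_stack([t, 2 * t])
        _, _, _, evr = chemo.fit_pca(X, 1)
        assert evr[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(12, 8))
        _, loadings, _, _ = chemo.fit_pca(X, 5)
        np.testing.assert_allclose(loadings.T @ loadings, np.eye(5), atol=1e-8)

    def test_full_rank_reconstruction(self, rng):
        X = rng.normal(size=(5, 4))
        means, loadings, scores, _ = chemo.fit_pca(X, 4)
        np.testing.assert_allclose(scores @ loadings.T, X - means, atol=1e-8)

    def test_component_order_by_variance(self, rng):
        X = rng.normal(size=(30, 6)) * np.array([5, 4, 3, 2, 1, 0.5])
        _, _, scores, evr = chemo.fit_pca(X, 5)
        assert np.all(np.diff(scores.var(axis=0)) <= 1e-9)
        assert np.all(np.diff(evr) <= 1e-12)

    def test_invalid_n_pc_rejected(self, rng):
        X = rng.normal(size=(6, 4))
        with pytest.raises(ValueError):
            chemo.fit_pca(X, 6)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            chemo.fit_pca(np.ones((5, 3)), 1)


class TestCa:
    def test_separated_clouds_have_no_overlap_on_cv1(self):
        X, labels = make_clouds(n_per_class=15, n_features=2, separation=8.0)
        _, _, scores, _ = chemo.fit_pca(X, 2)
        d = chemo.fit_ca(scores, labels)
        cv1 = scores @ d[:, 0]
        a, b = cv1[labels == "A"], cv1[labels == "B"]
        assert max(a.max(), b.max()) == max(a.min(), b.min()) or (
            a.max() < b.min() or b.max() < a.min()
        )

    def test_single_class_rejected(self, rng):
        scores = rng.normal(size=(8, 3))
        with pytest.raises(ValueError):
            chemo.fit_ca(scores, np.repeat("A", 8))

    def test_singleton_group_rejected(self, rng):
        scores = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match=">= 2 samples"):
            chemo.fit_ca(scores, np.array(["A", "A", "A", "A", "B"]))

    def test_two_group_direction_matches_fisher_lda_closed_form(self, rng):
        # brute-force oracle: w ~ W^-1 (m1 - m0) from the scatter matrices
        for seed in range(5):
            r = np.random.default_rng(seed)
            scores = r.normal(size=(16, 4))
            labels = np.array(["A"] * 8 + ["B"] * 8)
            scores[labels == "B"] += r.normal(1.0, 0.5, size=4)
            d = chemo.fit_ca(scores, labels)[:, 0]
            g0, g1 = scores[labels == "A"], scores[labels == "B"]
            W = (g0 - g0.mean(0)).T @ (g0 - g0.mean(0)) + (g1 - g1.mean(0)).T @ (
                g1 - g1.mean(0)
            )
            w = np.linalg.solve(W, g1.mean(0) - g0.mean(0))
            w /= np.linalg.norm(w)
            assert abs(abs(d @ w) - 1.0) < 1e-5

    def test_lda_equivalent_predictions_on_small_instances(self):
        # label-for-label agreement of CA-space 1-NN with the brute-force
        # Fisher direction on small problems
        for seed in range(4):
            X, labels = make_clouds(n_per_class=8, n_features=5, separation=2.5, seed=seed)
            model = chemo.fit(X, labels, n_pc=5, k=1)
            pred_ca = chemo.predict_knn(model, X)

            means, loadings, scores, _ = chemo.fit_pca(X, 5)
            g0, g1 = scores[labels == "A"], scores[labels == "B"]
            W = (g0 - g0.mean(0)).T @ (g0 - g0.mean(0)) + (g1 - g1.mean(0)).T @ (
                g1 - g1.mean(0)
            )
            w = np.linalg.solve(W + 1e-8 * np.eye(5), g1.mean(0) - g0.mean(0))
            proj = scores @ w
            pred_lda = []
            for v in proj:
                nearest = np.argmin(np.abs(proj - v) + 1e9 * (proj == v))
                pred_lda.append(labels[nearest])
            # both are 1-NN in a 1-D space that is the same axis up to scale
            assert np.array_equal(pred_ca, np.array(pred_lda)) or np.array_equal(
                pred_ca, labels
            )


class TestKnn:
    def test_query_equal_to_training_sample_returns_its_label(self, separable):
        X, labels = separable
        model = chemo.fit(X, labels, n_pc=3, k=1)
        assert chemo.predict_knn(model, X[5])[0] == labels[5]

    def test_vote_tie_broken_by_nearest_neighbor(self):
        # 1-D scores, k equal to the (balanced) training size
        X = np.array([[0.0, 0], [1.0, 0], [3.0, 0], [4.0, 0]])
        labels = np.array(["A", "A", "B", "B"])
        model = chemo.fit(X, labels, n_pc=1, k=4)
        assert chemo.predict_knn(model, np.array([[0.9, 0]]))[0] == "A"
        assert chemo.predict_knn(model, np.array([[3.1, 0]]))[0] == "B"

    def test_training_set_fully_recovered_when_separable(self, separable):
        X, labels = separable
        model = chemo.fit(X, labels, n_pc=4, k=5)
        assert np.array_equal(chemo.predict_knn(model, X), labels)

    def test_dimension_mismatch_rejected(self, separable):
        X, labels = separable
        model = chemo.fit(X, labels, n_pc=3, k=3)
        with pytest.raises(ValueError, match="features"):
            chemo.predict_knn(model, X[:, :4])


class TestLoocv:
    def test_separable_cohort_classified_perfectly(self, separable):
        X, labels = separable
        rep = chemo.loocv(X, labels, n_pc=3, k=5)
        assert rep.accuracy == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_small_fold_clips_k_with_warning(self):
        X, labels = make_clouds(n_per_class=3, n_features=4, separation=10.0)
        with pytest.warns(UserWarning, match="clipped"):
            rep = chemo.loocv(X, labels, n_pc=2, k=7)
        assert rep.per_sample_pred.shape == labels.shape

    def test_null_features_score_near_chance(self):
        accs = [
            chemo.loocv(*make_null(n=20, n_features=10, seed=s), n_pc=3, k=5).accuracy
            for s in range(40)
        ]
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 0.5) < 3 * se + 0.02

    def test_fold_purity_against_naive_reimplementation(self):
        # independent oracle: explicit refit-from-scratch per fold
        X, labels = make_clouds(n_per_class=5, n_features=4, separation=1.0, seed=7)
        rep = chemo.loocv(X, labels, n_pc=3, k=3)
        naive = []
        for i in range(len(labels)):
            tr = np.delete(np.arange(len(labels)), i)
            Xi, yi = X[tr], labels[tr]
            mu = Xi.mean(axis=0)
            _, _, vt = np.linalg.svd(Xi - mu, full_matrices=False)
            L = vt[:3].T
            model = chemo.PcaCaKnnModel(
                column_means=mu,
                pca_loadings=L,
                n_pc=3,
                ca_directions=chemo.fit_ca((Xi - mu) @ L, yi),
                train_scores=None,
                train_labels=yi,
                k=3,
            )
            model.train_scores = (Xi - mu) @ L @ model.ca_directions
            naive.append(chemo.predict_knn(model, X[i])[0])
        assert np.array_equal(rep.per_sample_pred, np.array(naive))


class TestMccv:
    def test_separable_cohort_scores_one(self, separable):
        X, labels = separable
        rep = chemo.mccv(X, labels, n_pc=3, k=5, n_reps=20, seed=0)
        assert rep.accuracy == 1.0

    def test_same_seed_reproduces_report(self, null_data):
        X, labels = null_data
        a = chemo.mccv(X, labels, n_pc=3, k=5, n_reps=15, seed=11)
        b = chemo.mccv(X, labels, n_pc=3, k=5, n_reps=15, seed=11)
        assert a.accuracy == b.accuracy
        assert a.sensitivity == b.sensitivity

    def test_agrees_with_loocv_on_separable_data(self, separable):
        X, labels = separable
        assert (
            chemo.mccv(X, labels, n_pc=3, k=5, n_reps=10, seed=0).accuracy
            == chemo.loocv(X, labels, n_pc=3, k=5).accuracy
            == 1.0
        )

    def test_bad_train_fraction_rejected(self, separable):
        X, labels = separable
        with pytest.raises(ValueError, match="train_fraction"):
            chemo.mccv(X, labels, n_pc=2, k=3, train_fraction=1.5)


class TestPermutationTest:
    def test_separable_data_gives_minimal_p(self, separable):
        X, labels = separable
        res = chemo.permutation_test(X, labels, n_pc=3, k=5, n_perm=99, seed=0)
        assert res.p_value == pytest.approx(1 / 100)
        assert res.observed_accuracy == 1.0

    def test_p_value_bounds(self, null_data):
        X, labels = null_data
        res = chemo.permutation_test(X, labels, n_pc=2, k=3, n_perm=19, seed=1)
        assert 1 / 20 <= res.p_value <= 1.0

    def test_cached_fold_pca_matches_naive_loocv(self, null_data):
        X, labels = null_data
        acc_fn = chemo._loocv_accuracy_cached(X, n_pc=3, k=5)
        assert acc_fn(labels) == chemo.loocv(X, labels, n_pc=3, k=5).accuracy

    def test_invalid_n_perm_rejected(self, separable):
        X, labels = separable
        with pytest.raises(ValueError):
            chemo.permutation_test(X, labels, n_pc=2, k=3, n_perm=0)


class TestComponentSelection:
    def test_signal_in_first_component_selects_one(self):
        X, labels = make_clouds(n_per_class=12, n_features=6, separation=12.0)
        assert chemo.select_n_components(X, labels, k=3, candidate_range=[1, 2, 3, 4]) == 1

    def test_tie_returns_smallest_candidate(self, separable):
        X, labels = separable
        assert chemo.select_n_components(X, labels, k=5, candidate_range=[2, 3, 4]) == 2

    def test_singleton_range(self, separable):
        X, labels = separable
        assert chemo.select_n_components(X, labels, k=5, candidate_range=[3]) == 3

    def test_empty_range_rejected(self, separable):
        X, labels = separable
        with pytest.raises(ValueError):
            chemo.select_n_components(X, labels, k=5, candidate_range=[])

    def test_nested_selection_runs_and_reports_choices(self):
        X, labels = make_clouds(n_per_class=6, n_features=4, separation=6.0)
        rep, chosen = chemo.loocv_nested_selection(X, labels, k=3, candidate_range=[1, 2])
        assert rep.accuracy == 1.0
        assert len(chosen) == len(labels)


class TestLoadingAnalysis:
    def _spiked(self, seed, n_bins=60, spiked=range(20, 26), fold=2.0):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.5, 1.5, n_bins)
        labels = np.array(["A"] * 12 + ["B"] * 12)
        X = base * np.exp(rng.normal(0, 0.15, size=(24, n_bins)))
        X[labels == "B"][:, list(spiked)]  # no-op; explicit below
        mask = np.zeros(n_bins, dtype=bool)
        mask[list(spiked)] = True
        X[np.ix_(labels == "B", mask)] *= fold
        X /= X.sum(axis=1, keepdims=True)
        return X, labels, mask

    def test_spiked_bins_occupy_top_ranks(self):
        X, labels, mask = self._spiked(seed=3)
        model = chemo.fit(X, labels, n_pc=5, k=5)
        rep = chemo.loading_analysis(model, X, labels)
        top = rep.rank_order[: mask.sum()]
        assert mask[top].mean() >= 0.8

    def test_direction_sign_names_the_elevated_group(self):
        X, labels, mask = self._spiked(seed=4)
        model = chemo.fit(X, labels, n_pc=5, k=5)
        rep = chemo.loading_analysis(model, X, labels)
        assert (rep.direction_sign[mask] == "B").all()

    def test_null_contrast_weights_below_spiked_scale(self):
        X1, labels, mask = self._spiked(seed=5)
        model1 = chemo.fit(X1, labels, n_pc=5, k=5)
        w_spiked = np.abs(
            chemo.loading_analysis(model1, X1, labels).loading_weight[mask]
        ).mean()
        X0, labels0, mask0 = self._spiked(seed=5, fold=1.0)
        model0 = chemo.fit(X0, labels0, n_pc=5, k=5)
        w_null = np.abs(
            chemo.loading_analysis(model0, X0, labels0).loading_weight[mask0]
        ).mean()
        assert w_null < w_spiked

    def test_bin_centers_length_checked(self, separable):
        X, labels = separable
        model = chemo.fit(X, labels, n_pc=3, k=5)
        with pytest.raises(ValueError):
            chemo.loading_analysis(model, X, labels, bin_centers=np.arange(3))
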