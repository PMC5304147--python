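"""OPLS-DA: preprocessing, NIPALS fit, orthogonality, CV diagnostics."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import silhouette_score

import shadescreen as ss
from shadescreen.opls import preprocess, venetian_blind_folds


def dummy(labels):
    return pd.get_dummies(list(labels)).to_numpy(dtype=float)


class TestPreprocess:
    def test_standardized_matrix_passes_through(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 5))
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        Xs, prep = preprocess(X, scaling="uv")
        assert np.allclose(Xs, X, atol=1e-12)

    def test_constant_column_dropped_with_warning(self, caplog):
        X = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        with caplog.at_level("WARNING", logger="shadescreen.opls"):
            Xs, prep = preprocess(X)
        assert prep.dropped == ["b"]
        assert Xs.shape == (3, 1)

    def test_round_trip_inverse_transform(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(1, 5, size=(20, 6))
        for scaling in ("uv", "pareto", "center"):
            Xs, prep = preprocess(X, scaling=scaling)
            assert np.allclose(prep.inverse_transform(Xs), X, atol=1e-12)

    def test_all_constant_columns_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            preprocess(np.ones((5, 3)))


class TestPls2Equivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_zero_orthogonal_matches_reference_pls2(self, seed):
        """With no orthogonal components the model degenerates to PLS2; its
        predictions must match an independent NIPALS implementation."""
        rng = np.random.default_rng(seed)
        n = 24
        X = rng.normal(size=(n, 7))
        labels = ["a"] * (n // 2) + ["b"] * (n // 2)
        model = ss.fit_opls_da(
            pd.DataFrame(X), labels, n_predictive=2, n_orthogonal=0, scaling="center"
        )
        ref = PLSRegression(n_components=2, scale=False).fit(X, dummy(labels))
        assert np.allclose(model.predict(pd.DataFrame(X)), ref.predict(X), atol=1e-8)


class TestOrthogonalComponent:
    def planted_data(self, seed=0, n=40):
        """Two-class signal along v1 plus a stronger Y-uncorrelated direction v2."""
        rng = np.random.default_rng(seed)
        p = 10
        v1 = np.zeros(p); v1[0] = 1.0
        v2 = np.zeros(p); v2[1] = 1.0
        y = np.repeat([1.0, -1.0], n // 2)
        ortho = rng.normal(scale=3.0, size=n)
        ortho -= ortho @ y / (y @ y) * y  # exactly uncorrelated with class
        X = np.outer(y, v1) + np.outer(ortho, v2) + rng.normal(scale=0.02, size=(n, p))
        labels = ["a" if v > 0 else "b" for v in y]
        return X, labels, v2

    def test_recovers_planted_orthogonal_direction(self):
        X, labels, v2 = self.planted_data()
        model = ss.fit_opls_da(
            pd.DataFrame(X), labels, n_predictive=1, n_orthogonal=1, scaling="center"
        )
        w_o = model.ortho_weights[:, 0]
        cosine = abs(w_o @ v2) / np.linalg.norm(w_o)
        assert cosine > 0.99

    def test_orthogonal_scores_uncorrelated_with_dummy(self, seed_opls):
        Y = dummy(seed_opls.labels)
        for a in range(seed_opls.n_orthogonal):
            t_o = seed_opls.ortho_scores[:, a]
            for j in range(Y.shape[1]):
                r = np.corrcoef(t_o, Y[:, j])[0, 1]
                assert abs(r) < 1e-6


class TestVarianceBookkeeping:
    def test_r2x_components_and_residual_sum_to_one(self, seed_opls, seed_X_labels):
        X, _ = seed_X_labels
        Xs = seed_opls.preprocessor.transform(X)
        recon = (
            seed_opls.scores @ seed_opls.loadings.T
            + seed_opls.ortho_scores @ seed_opls.ortho_loadings.T
        )
        residual = ((Xs - recon) ** 2).sum() / (Xs**2).sum()
        total = seed_opls.r2x_predictive + seed_opls.r2x_orthogonal + residual
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_r2_values_are_fractions(self, seed_opls):
        for v in (seed_opls.r2x, seed_opls.r2x_predictive, seed_opls.r2y):
            assert 0.0 <= v <= 1.0


class TestCrossValidation:
    def test_q2_never_exceeds_r2y(self, seed_X_labels):
        X, labels = seed_X_labels
        for n_orth in (0, 1):
            model = ss.fit_opls_da(X, labels, 2, n_orth)
            q2 = ss.cross_validate(X, labels, 2, n_orth, k_folds=7)
            assert q2 <= model.r2y

    def test_separable_classes_give_high_q2(self, seed_X_labels):
        X, labels = seed_X_labels
        q2 = ss.cross_validate(X, labels, 2, 1, k_folds=7)
        assert q2 > 0.8

    def test_permuted_labels_destroy_q2(self, seed_X_labels):
        """Label permutation must drive Q2 to chance level on structured data."""
        X, labels = seed_X_labels
        labels = np.asarray(labels)
        rng = np.random.default_rng(0)
        low = 0
        n_perm = 100
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            q2 = ss.cross_validate(X, list(perm), 2, 1, k_folds=7)
            if q2 <= 0.2:
                low += 1
        assert low >= 0.95 * n_perm

    def test_folds_are_stratified_and_deterministic(self):
        labels = ["a"] * 7 + ["b"] * 7
        folds = venetian_blind_folds(labels, 7)
        assert np.array_equal(folds, venetian_blind_folds(labels, 7))
        for k in range(7):
            fold_labels = [l for l, f in zip(labels, folds) if f == k]
            assert set(fold_labels) == {"a", "b"}

    def test_bad_fold_count_rejected(self, seed_X_labels):
        X, labels = seed_X_labels
        with pytest.raises(ValueError, match="k_folds"):
            ss.cross_validate(X, labels, 2, 1, k_folds=1)


class TestThreeClassStructure:
    def test_score_plot_separates_classes_along_each_axis(self, seed_opls):
        scores, _ = ss.export_scores_loadings(seed_opls)
        s1 = silhouette_score(scores[["t1"]], scores["class"] == "susceptible")
        assert s1 > 0
        rest = scores[scores["class"] != "susceptible"]
        s2 = silhouette_score(rest[["t2"]], rest["class"])
        assert s2 > 0

    def test_aglycones_load_on_the_tolerant_side(self, seed_opls):
        scores, loadings = ss.export_scores_loadings(seed_opls)
        tol_side = np.sign(scores.loc[scores["class"] == "tolerant", "t1"].mean())
        p1 = loadings.set_index("variable")["p1"]
        for var in ("GE", "DE", "GLE", "T-e"):
            assert np.sign(p1[var]) == tol_side

    def test_export_shapes(self, seed_opls, seed_X_labels):
        X, _ = seed_X_labels
        scores, loadings = ss.export_scores_loadings(seed_opls)
        assert len(scores) == len(X)
        assert len(loadings) == X.shape[1]


class TestValidation:
    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 4))
        with pytest.raises(ValueError, match="2 classes"):
            ss.fit_opls_da(X, ["a"] * 6)

    def test_rank_deficiency_reduces_components(self, caplog):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(8, 2))
        X = base @ rng.normal(size=(2, 6))  # rank 2
        labels = ["a", "b"] * 4
        with caplog.at_level("WARNING", logger="shadescreen.opls"):
            model = ss.fit_opls_da(pd.DataFrame(X), labels, n_predictive=3, n_orthogonal=2)
        assert model.n_predictive + model.n_orthogonal < 3 + 2
        assert any("reducing" in r.message for r in caplog.records)

    def test_determinism_of_fit(self, seed_X_labels):
        X, labels = seed_X_labels
        a = ss.fit_opls_da(X, labels, 2, 1)
        b = ss.fit_opls_da(X, labels, 2, 1)
        assert np.array_equal(a.scores, b.scores)
        assert np.array_equal(a.loadings, b.loadings)
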