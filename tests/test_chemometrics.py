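"""Supervised modelling: PCA/T2, PLS-DA, OPLS-DA, MMC, CV, ROC, ANOVA loadings."""

import numpy as np
import pytest
from scipy import stats

from mucometa import chemometrics as chem


def _two_class(n_per=20, p=10, gap=4.0, noise=0.5, seed=0, spread=True):
    rng = np.random.default_rng(seed)
    y = np.repeat(["a", "b"], n_per)
    shift = (np.ones(p) / np.sqrt(p) if spread else np.eye(p)[0]) * gap
    X = rng.normal(scale=noise, size=(2 * n_per, p))
    X[y == "b"] += shift
    return X, y


class TestPca:
    def test_line_data_loads_on_first_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=80)
        direction = np.array([3.0, 1.0, -2.0])
        X = np.outer(t, direction) + rng.normal(scale=0.01, size=(80, 3))
        m = chem.fit_pca(X, 2)
        assert m.explained_variance_ratio[0] > 0.99

    def test_loadings_orthonormal(self):
        X = np.random.default_rng(1).normal(size=(30, 8))
        m = chem.fit_pca(X, 4)
        np.testing.assert_allclose(m.loadings @ m.loadings.T, np.eye(4), atol=1e-10)

    def test_displaced_sample_exceeds_t2_limit(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(51, 12))
        d = rng.normal(size=12)
        X[7] += 10 * d / np.linalg.norm(d)
        m = chem.fit_pca(X, 3)
        assert m.hotelling_t2[7] > m.t2_limit

    def test_excess_components_rejected(self):
        with pytest.raises(ValueError):
            chem.fit_pca(np.random.default_rng(0).normal(size=(5, 10)), 5)


class TestRemoveOutliers:
    def test_no_exceedance_is_identity(self):
        X = np.random.default_rng(3).normal(size=(40, 6))
        m = chem.fit_pca(X, 2, confidence=0.999999)
        kept, removed = chem.remove_outliers(X, m)
        assert removed == [] and kept.shape == X.shape

    def test_planted_outliers_removed_54_to_51(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(54, 10))
        planted = [5, 20, 40]
        for i in planted:
            d = rng.normal(size=10)
            X[i] += 10 * d / np.linalg.norm(d)
        m = chem.fit_pca(X, 3)
        kept, removed = chem.remove_outliers(X, m, sample_ids=list(range(54)))
        assert sorted(removed) == planted
        assert kept.shape[0] == 51

    def test_refuses_to_remove_everything(self):
        X = np.random.default_rng(5).normal(size=(10, 3))
        m = chem.fit_pca(X, 2)
        m.t2_limit = -1.0
        with pytest.raises(ValueError):
            chem.remove_outliers(X, m)


class TestPlsda:
    def test_separated_classes_have_disjoint_scores(self):
        X, y = _two_class(gap=8.0, seed=6)
        m = chem.fit_plsda(X, y, 1)
        a, b = m.scores[y == "a", 0], m.scores[y == "b", 0]
        assert max(a) < min(b) or max(b) < min(a)

    def test_first_direction_matches_eigen_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 12))
        y = np.array(["a", "b"] * 15)
        m = chem.fit_plsda(X, y, 1)
        Y = np.column_stack([(y == c).astype(float) for c in ("a", "b")])
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        M = Xc.T @ Yc @ Yc.T @ Xc
        evals, evecs = np.linalg.eigh(M)
        w_oracle = evecs[:, -1]
        cos = abs(m.extras["W"][:, 0] @ w_oracle)
        assert cos > 1 - 1e-8

    def test_null_data_gives_nonpositive_mean_q2(self):
        q2 = []
        for s in range(8):
            rng = np.random.default_rng(60 + s)
            X = rng.normal(size=(24, 15))
            y = np.array(["a", "b"] * 12)
            q2.append(chem.cross_validate(
                {"kind": "plsda", "n_components": 1}, X, y, scheme="loo").q2)
        assert np.mean(q2) <= 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            chem.fit_plsda(np.ones((6, 3)), ["a"] * 6, 1)

    def test_planted_weight_direction_recovered(self):
        """Mean angle to a strongly planted discriminant axis stays below 5 deg."""
        angles = []
        for s in range(10):
            rng = np.random.default_rng(s)
            p = 5
            w = rng.normal(size=p)
            w /= np.linalg.norm(w)
            y = np.repeat(["a", "b"], 50)
            X = rng.normal(scale=0.5, size=(100, p))
            X[y == "b"] += 4 * w
            m = chem.fit_plsda(X, y, 1)
            cos = abs(m.extras["W"][:, 0] @ w)
            angles.append(np.degrees(np.arccos(min(1.0, cos))))
        assert np.mean(angles) < 5.0


class TestOplsda:
    @staticmethod
    def _constructed(seed=0, n=60, p=200):
        rng = np.random.default_rng(seed)
        y = np.repeat([0.0, 1.0], n // 2)
        w = rng.normal(size=p)
        w /= np.linalg.norm(w)
        p_o = rng.normal(size=p)
        p_o -= (p_o @ w) * w
        p_o /= np.linalg.norm(p_o)
        t_o = rng.normal(size=n)
        yc = y - y.mean()
        t_o = t_o - t_o.mean() - (t_o @ yc) / (yc @ yc) * yc  # class-orthogonal
        X = (np.outer(yc, w) * 3 + np.outer(t_o, p_o) * 2
             + rng.normal(scale=0.05, size=(n, p)))
        labels = np.where(y > 0, "tumour", "normal")
        return X, labels, y, t_o

    def test_zero_orthogonal_equals_plsda_first_component(self):
        X, labels, *_ = self._constructed()
        om = chem.fit_oplsda(X, labels, n_orthogonal=0)
        pm = chem.fit_plsda(X, labels, 1)
        cos = abs(np.corrcoef(om.scores[:, 0], pm.scores[:, 0])[0, 1])
        assert cos > 1 - 1e-8

    def test_predictive_and_orthogonal_separation(self):
        X, labels, y, t_o = self._constructed()
        m = chem.fit_oplsda(X, labels, n_orthogonal=1)
        assert abs(np.corrcoef(m.scores[:, 0], y)[0, 1]) > 0.99
        assert abs(np.corrcoef(m.orthogonal_scores[:, 0], t_o)[0, 1]) > 0.99
        assert abs(np.corrcoef(m.orthogonal_scores[:, 0], y)[0, 1]) < 0.05

    def test_transform_reproduces_training_scores(self):
        X, labels, *_ = self._constructed(seed=1)
        m = chem.fit_oplsda(X, labels, n_orthogonal=2)
        np.testing.assert_allclose(m.transform(X)[:, 0], m.scores[:, 0], atol=1e-10)

    def test_reconstruction_not_worse_than_pca_budget(self):
        """Predictive + orthogonal components account for at least as much
        X-variance as the same total number of PCA components captures of the
        residual bound (variance accounting sanity)."""
        X, labels, *_ = self._constructed(seed=2)
        m = chem.fit_oplsda(X, labels, n_orthogonal=1)
        Xc = X - X.mean(0)
        T = np.column_stack([m.scores, m.orthogonal_scores])
        P = np.column_stack([m.loadings, m.orthogonal_loadings])
        resid = Xc - T @ P.T
        pca = chem.fit_pca(X, 2)
        pca_resid = Xc - pca.scores @ pca.loadings
        assert (resid**2).sum() >= (pca_resid**2).sum() - 1e-8

    def test_multiclass_rejected(self):
        with pytest.raises(ValueError):
            chem.fit_oplsda(np.random.default_rng(0).normal(size=(9, 4)),
                            ["a", "b", "c"] * 3)


class TestMmc:
    def test_gap_direction_recovered(self):
        rng = np.random.default_rng(8)
        y = np.repeat(["a", "b"], 50)
        X = rng.normal(scale=0.5, size=(100, 10))
        X[y == "b", 0] += 3.0
        m = chem.fit_mmc(X, y, 1)
        assert abs(m.weights[0, 0]) > 0.99

    def test_identical_class_means_give_nonpositive_eigenvalues(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 6))
        y = np.array(["a", "b"] * 30)
        X[y == "b"] -= X[y == "b"].mean(0) - X[y == "a"].mean(0)  # equalize means
        m = chem.fit_mmc(X, y, 2)
        assert (m.extras["eigenvalues"] <= 1e-10).all()

    def test_high_dimensional_input_uses_pca_subspace(self):
        X, y = _two_class(n_per=15, p=300, gap=5.0, seed=10)
        m = chem.fit_mmc(X, y, 2)
        assert m.weights.shape == (300, 2)
        np.testing.assert_allclose(m.weights.T @ m.weights, np.eye(2), atol=1e-8)

    def test_singleton_class_needs_regularization(self):
        X = np.random.default_rng(11).normal(size=(5, 3))
        y = ["a", "a", "a", "a", "b"]
        with pytest.raises(ValueError):
            chem.fit_mmc(X, y, 1)
        m = chem.fit_mmc(X, y, 1, regularize=1e-3)
        assert m.scores.shape == (5, 1)


class TestCrossValidate:
    def test_every_sample_predicted_exactly_once(self):
        X, y = _two_class(seed=12)
        groups = np.repeat(np.arange(8), 5)
        cv = chem.cross_validate({"kind": "plsda", "n_components": 1}, X, y,
                                 groups=groups, scheme="lopo")
        assert len(cv.predictions) == len(y)
        assert not np.isnan(cv.y_pred).any()

    def test_separable_data_classified_perfectly(self):
        X, y = _two_class(gap=8.0, seed=13)
        cv = chem.cross_validate({"kind": "plsda", "n_components": 1}, X, y,
                                 scheme="loo")
        assert cv.accuracy == 1.0
        assert cv.q2 > 0.9

    def test_training_q2_bounds_cv_q2(self):
        for s in range(5):
            X, y = _two_class(gap=2.0, noise=1.0, seed=20 + s)
            m = chem.fit_plsda(X, y, 1)
            Y = np.column_stack([(np.asarray(y) == c).astype(float)
                                 for c in ("a", "b")])
            q2_train = chem.q2_score(Y, m.predict_y(X))
            cv = chem.cross_validate({"kind": "plsda", "n_components": 1},
                                     X, y, scheme="loo", scale=False)
            assert q2_train >= cv.q2

    def test_patient_scheme_requires_groups(self):
        X, y = _two_class(seed=14)
        with pytest.raises(ValueError):
            chem.cross_validate({"kind": "plsda", "n_components": 1}, X, y,
                                scheme="lopo")


class TestRoc:
    def test_perfectly_ranked_scores_give_unit_auc(self):
        r = chem.roc_auc([0.9, 0.8, 0.2, 0.1], ["pos", "pos", "neg", "neg"],
                         positive="pos")
        assert r.auc == 1.0

    def test_all_tied_scores_give_half(self):
        r = chem.roc_auc([0.5] * 8, ["a", "b"] * 4)
        assert np.isclose(r.auc, 0.5)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(15)
        scores = rng.normal(size=2000)
        labels = np.where(rng.random(2000) < 0.5, "a", "b")
        r = chem.roc_auc(scores, labels)
        assert 0.47 <= r.auc <= 0.53

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(16)
        scores = rng.normal(size=100)
        labels = np.where(rng.random(100) < 0.4, "a", "b")
        r1 = chem.roc_auc(scores, labels)
        r2 = chem.roc_auc(np.exp(3 * scores) + 7, labels)
        assert np.isclose(r1.auc, r2.auc)

    def test_curve_monotone(self):
        rng = np.random.default_rng(17)
        r = chem.roc_auc(rng.normal(size=50), np.where(rng.random(50) < 0.5, "a", "b"))
        assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            chem.roc_auc([0.1, 0.2], ["a", "a"])


class TestPseudoLoadingsAnova:
    def test_planted_shift_detected_with_correct_sign(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(40, 50))
        y = np.repeat(["normal", "tumour"], 20)
        X[y == "tumour", 3] += 3.0
        out = chem.pseudo_loadings_anova(X, y, class_of_interest="tumour")
        assert out["q_fdr"].iloc[3] < 0.001
        assert out["sign"].iloc[3] == 1
        assert (out["q_fdr"] >= out["p_anova"] - 1e-12).all()

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(40, 2000))
        y = np.repeat(["a", "b"], 20)
        out = chem.pseudo_loadings_anova(X, y, scores=rng.normal(size=40))
        ks = stats.kstest(out["p_anova"], "uniform")
        assert ks.pvalue > 0.01

    def test_bh_matches_step_up_oracle(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(30, 10))
        y = np.repeat(["a", "b"], 15)
        out = chem.pseudo_loadings_anova(X, y, scores=rng.normal(size=30))
        # direct step-up oracle on the ANOVA p-values the routine produced
        pv = out["p_anova"].to_numpy()
        m = len(pv)
        order = np.argsort(pv)
        q_oracle = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, pv[i] * m / rank)
            q_oracle[i] = prev
        np.testing.assert_allclose(out["q_fdr"].to_numpy(), q_oracle, atol=1e-12)

    def test_constant_variable_gets_p_one(self):
        X = np.column_stack([np.ones(20), np.random.default_rng(21).normal(size=20)])
        y = np.repeat(["a", "b"], 10)
        out = chem.pseudo_loadings_anova(X, y, scores=np.arange(20.0))
        assert out["p_anova"].iloc[0] == 1.0
        assert out["sign"].iloc[0] == 0
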