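import numpy as np
import pytest

from empoweranc import nuisance as nu


def sim_binary(n=600, p=6, seed=0, beta=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, p))
    beta = np.zeros(p) if beta is None else np.asarray(beta)
    prob = 1 / (1 + np.exp(-(X @ beta)))
    return X, (rng.random(n) < prob).astype(float)


class TestSuperLearner:
    def test_single_learner_gets_weight_one(self):
        X, y = sim_binary(seed=1, beta=[1, 0, 0, 0, 0, 0])
        fit = nu.fit_super_learner(X, y, library=("logistic",), n_folds=3)
        assert fit.weights.tolist() == [1.0]

    @pytest.mark.parametrize(
        "loss,library",
        [
            ("nll", ("logistic", "lasso", "random_forest")),
            ("mse", ("linear", "ridge", "random_forest")),
        ],
    )
    def test_ensemble_dominates_every_single_learner(self, loss, library):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (500, 5))
        if loss == "nll":
            y = (rng.random(500) < 1 / (1 + np.exp(-X[:, 0]))).astype(float)
        else:
            y = X[:, 0] + 0.5 * X[:, 1] ** 2 + rng.normal(0, 1, 500)
        fit = nu.fit_super_learner(X, y, library=library, n_folds=5, loss=loss)
        assert fit.cv_risk_ensemble <= min(fit.cv_risks.values()) + 1e-8

    def test_sparse_linear_truth_favors_penalized_linear(self):
        # sparse logistic truth: the penalized-linear learners should carry
        # the bulk of the ensemble weight against a tree learner
        beta = np.zeros(20)
        beta[0], beta[1] = 1.5, -1.5
        X, y = sim_binary(n=2000, p=20, seed=7, beta=beta)
        fit = nu.fit_super_learner(
            X, y, library=("lasso", "elasticnet", "random_forest"), n_folds=5
        )
        w = dict(zip([s.name for s in fit.learners], fit.weights))
        assert w.get("lasso", 0) + w.get("elasticnet", 0) > 0.5

    def test_permuted_rows_give_same_predictions(self):
        X, y = sim_binary(seed=9, beta=[1, -1, 0, 0, 0, 0])
        fit_a = nu.fit_super_learner(X, y, library=("logistic",), n_folds=3)
        perm = np.random.default_rng(0).permutation(len(y))
        fit_b = nu.fit_super_learner(X[perm], y[perm], library=("logistic",), n_folds=3)
        np.testing.assert_allclose(fit_a.predict(X), fit_b.predict(X), atol=1e-6)

    def test_empty_library_rejected(self):
        X, y = sim_binary()
        with pytest.raises(ValueError):
            nu.fit_super_learner(X, y, library=())
        with pytest.raises(ValueError):
            nu.fit_super_learner(X, y, library=("logistic",), n_folds=1)


class TestPropensity:
    @staticmethod
    def random_exposure(n=3000, seed=4):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n, 4))
        a = rng.choice(["low", "medium", "high"], size=n, p=[0.25, 0.5, 0.25])
        return X, a

    def test_rows_sum_to_one(self):
        X, a = self.random_exposure()
        g, _ = nu.fit_propensity(X, a, library=("logistic",), n_folds=3)
        np.testing.assert_allclose(g.sum(axis=1), 1.0, atol=1e-12)

    def test_unconfounded_exposure_recovers_marginals(self):
        X, a = self.random_exposure(seed=12)
        g, _ = nu.fit_propensity(X, a, library=("logistic",), n_folds=3)
        marg = np.array([(a == lvl).mean() for lvl in ("low", "medium", "high")])
        np.testing.assert_allclose(g.mean(axis=0), marg, atol=0.05)

    def test_confounded_exposure_beats_intercept_model(self):
        rng = np.random.default_rng(21)
        n = 2000
        X = rng.normal(0, 1, (n, 3))
        latent = 1.5 * X[:, 0] + rng.normal(0, 1, n)
        q = np.quantile(latent, [0.25, 0.75])
        a = np.where(latent < q[0], "low", np.where(latent >= q[1], "high", "medium"))
        g, _ = nu.fit_propensity(X, a, library=("logistic",), n_folds=3)
        codes = np.select([a == l for l in ("low", "medium", "high")], [0, 1, 2])
        picked = g[np.arange(n), codes]
        ll_model = -np.mean(np.log(picked))
        marg = np.array([(a == l).mean() for l in ("low", "medium", "high")])
        ll_null = -np.mean(np.log(marg[codes]))
        assert ll_model < ll_null

    def test_thin_level_rejected(self):
        X, a = self.random_exposure(n=100, seed=5)
        a[:] = "medium"
        a[:5] = "low"
        a[5:60] = "high"
        with pytest.raises(ValueError, match="fewer than 10"):
            nu.fit_propensity(X, a, library=("logistic",))


class TestBoundPropensity:
    def test_inside_bounds_unchanged(self):
        g = np.array([[0.2, 0.5, 0.3]])
        out, frac = nu.bound_propensity(g, 0.025, 0.975)
        np.testing.assert_allclose(out, g)
        assert frac == 0.0

    def test_truncation_then_renormalization(self):
        g = np.array([[0.001, 0.499, 0.5]])
        out, frac = nu.bound_propensity(g, 0.025, 0.975)
        clipped = np.array([0.025, 0.499, 0.5])
        np.testing.assert_allclose(out[0], clipped / clipped.sum())
        assert frac == pytest.approx(1 / 3)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            nu.bound_propensity(np.full((2, 3), 1 / 3), 0.5, 0.4)


class TestOutcomeRegression:
    def test_degenerate_constant_outcome_flagged(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (60, 3))
        a = np.tile(["low", "medium", "high"], 20)
        qbar, qobs, fit, degenerate = nu.fit_outcome_regression(
            X, a, np.zeros(60), library=("logistic",), n_folds=3
        )
        assert degenerate and fit is None
        assert all(np.all(qbar[l] == 0.0) for l in ("low", "medium", "high"))

    def test_predictions_invariant_to_record_order(self):
        rng = np.random.default_rng(31)
        n = 300
        X = rng.normal(0, 1, (n, 3))
        a = rng.choice(["low", "medium", "high"], n, p=[0.25, 0.5, 0.25])
        y = (rng.random(n) < 0.4).astype(float)
        qb1, _, _, _ = nu.fit_outcome_regression(
            X, a, y, library=("logistic",), n_folds=3
        )
        perm = rng.permutation(n)
        qb2, _, _, _ = nu.fit_outcome_regression(
            X[perm], a[perm], y[perm], library=("logistic",), n_folds=3
        )
        for lvl in ("low", "medium", "high"):
            np.testing.assert_allclose(qb1[lvl][perm], qb2[lvl], atol=1e-6)
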