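"""Nuisance estimation: outcome regression and propensity score.

Both nuisance functions of the doubly robust analysis are fit with a
convex Super Learner -- a V-fold cross-validated stack whose meta-weights
minimize the cross-validated loss of the convex combination over the
probability simplex, so the ensemble can never do worse (on the CV
objective) than its best single member.

The learner library mirrors the one used in the study: plain and
Bayesian-regularized logistic regression, LASSO / ridge / elastic net,
random forest, extreme gradient boosting, and a spline-basis LASSO
(an indicator-basis, capped-size surrogate for the highly adaptive
LASSO). Each has a continuous-outcome counterpart.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import (
    ElasticNet,
    Lasso,
    LinearRegression,
    LogisticRegression,
    Ridge,
)
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

PRED_BOUND = 1e-6


class IndicatorBasis(BaseEstimator, TransformerMixin):
    """Zero-order spline (indicator) basis expansion.

    For each input column, emits indicators 1(x >= knot) at within-sample
    quantile knots; total basis size is capped. This is the design behind
    the spline-basis LASSO learner.
    """

    def __init__(self, n_knots: int = 10, max_columns: int = 300):
        self.n_knots = n_knots
        self.max_columns = max_columns

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n_knots = max(2, min(self.n_knots, self.max_columns // max(1, X.shape[1])))
        self.knots_ = []
        qs = np.linspace(0.1, 0.9, n_knots)
        for j in range(X.shape[1]):
            k = np.unique(np.quantile(X[:, j], qs))
            self.knots_.append(k)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        cols = [
            (X[:, j, None] >= k[None, :]).astype(float)
            for j, k in enumerate(self.knots_)
        ]
        return np.hstack(cols)


def _binary_factories(seed: int):
    return {
        "logistic": lambda: LogisticRegression(penalty=None, max_iter=2000),
        "bayes_logistic": lambda: LogisticRegression(C=1.0, max_iter=2000),
        "lasso": lambda: Pipeline(
            [
                ("scale", StandardScaler()),
                ("m", LogisticRegression(penalty="l1", solver="liblinear", C=1.0)),
            ]
        ),
        "ridge": lambda: Pipeline(
            [("scale", StandardScaler()), ("m", LogisticRegression(C=0.5, max_iter=2000))]
        ),
        "elasticnet": lambda: Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "m",
                    LogisticRegression(
                        penalty="elasticnet",
                        solver="saga",
                        l1_ratio=0.5,
                        C=1.0,
                        max_iter=3000,
                    ),
                ),
            ]
        ),
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=200, min_samples_leaf=20, random_state=seed
        ),
        "xgboost": lambda: _xgb_classifier(seed),
        "spline_lasso": lambda: Pipeline(
            [
                ("basis", IndicatorBasis()),
                ("m", LogisticRegression(penalty="l1", solver="liblinear", C=1.0)),
            ]
        ),
    }


def _continuous_factories(seed: int):
    return {
        "linear": lambda: LinearRegression(),
        "bayes_linear": lambda: Pipeline(
            [("scale", StandardScaler()), ("m", Ridge(alpha=1.0))]
        ),
        "lasso": lambda: Pipeline(
            [("scale", StandardScaler()), ("m", Lasso(alpha=0.01, max_iter=5000))]
        ),
        "ridge": lambda: Pipeline(
            [("scale", StandardScaler()), ("m", Ridge(alpha=10.0))]
        ),
        "elasticnet": lambda: Pipeline(
            [("scale", StandardScaler()), ("m", ElasticNet(alpha=0.01, max_iter=5000))]
        ),
        "random_forest": lambda: RandomForestRegressor(
            n_estimators=200, min_samples_leaf=20, random_state=seed
        ),
        "xgboost": lambda: _xgb_regressor(seed),
        "spline_lasso": lambda: Pipeline(
            [("basis", IndicatorBasis()), ("m", Lasso(alpha=0.005, max_iter=5000))]
        ),
    }


def _xgb_classifier(seed: int):
    from xgboost import XGBClassifier

    return XGBClassifier(
        n_estimators=100,
        max_depth=3,
        learning_rate=0.1,
        subsample=0.8,
        random_state=seed,
        n_jobs=1,
        verbosity=0,
    )


def _xgb_regressor(seed: int):
    from xgboost import XGBRegressor

    return XGBRegressor(
        n_estimators=100,
        max_depth=3,
        learning_rate=0.1,
        subsample=0.8,
        random_state=seed,
        n_jobs=1,
        verbosity=0,
    )


PENALIZED_LINEAR = ("lasso", "ridge", "elasticnet", "bayes_logistic", "bayes_linear",
                    "spline_lasso")

DEFAULT_OUTCOME_LIBRARY = (
    "logistic",
    "bayes_logistic",
    "lasso",
    "ridge",
    "elasticnet",
    "random_forest",
    "xgboost",
    "spline_lasso",
)
DEFAULT_PROPENSITY_LIBRARY = ("lasso", "ridge", "elasticnet", "random_forest", "xgboost")
FAST_LIBRARY = ("logistic",)


@dataclass
class LearnerSpec:
    name: str
    estimator: object


def build_library(names, loss: str, seed: int) -> list[LearnerSpec]:
    factories = (
        _binary_factories(seed) if loss == "nll" else _continuous_factories(seed)
    )
    # allow binary names for continuous targets and vice versa
    alias = {"logistic": "linear", "bayes_logistic": "bayes_linear"}
    specs = []
    for name in names:
        key = name
        if key not in factories:
            key = alias.get(key, {v: k for k, v in alias.items()}.get(key, key))
        if key not in factories:
            raise ValueError(f"unknown learner {name!r}")
        specs.append(LearnerSpec(name=name, estimator=factories[key]()))
    return specs


def _predict(est, X, loss: str) -> np.ndarray:
    if loss == "nll":
        p = est.predict_proba(X)[:, 1]
        return np.clip(p, PRED_BOUND, 1 - PRED_BOUND)
    return np.asarray(est.predict(X), dtype=float)


def _loss_value(y, pred, loss: str) -> float:
    if loss == "nll":
        p = np.clip(pred, PRED_BOUND, 1 - PRED_BOUND)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return float(np.mean((y - pred) ** 2))


def _solve_simplex_weights(y, Z, loss: str) -> np.ndarray:
    """Meta-weights minimizing CV loss of the convex combination."""
    k = Z.shape[1]
    if k == 1:
        return np.ones(1)

    def objective(w):
        return _loss_value(y, Z @ w, loss)

    w0 = np.full(k, 1.0 / k)
    res = minimize(
        objective,
        w0,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    w = np.clip(res.x, 0.0, None)
    w = w / w.sum()
    # the simplex contains every vertex: never return a combination worse
    # than the best single learner
    candidates = [w] + [np.eye(k)[j] for j in range(k)]
    values = [objective(c) for c in candidates]
    return candidates[int(np.argmin(values))]


@dataclass
class SuperLearnerFit:
    """A fitted convex stack: refit base learners, simplex meta-weights,
    per-learner cross-validated risks, and the CV fold assignment."""

    learners: list[LearnerSpec]
    weights: np.ndarray
    cv_risks: dict[str, float]
    cv_risk_ensemble: float
    folds: np.ndarray
    loss: str

    def predict(self, X) -> np.ndarray:
        preds = np.column_stack(
            [_predict(spec.estimator, X, self.loss) for spec in self.learners]
        )
        out = preds @ self.weights
        if self.loss == "nll":
            out = np.clip(out, PRED_BOUND, 1 - PRED_BOUND)
        return out


def fit_super_learner(
    features,
    target,
    library=DEFAULT_OUTCOME_LIBRARY,
    n_folds: int = 10,
    loss: str = "nll",
    seed: int = 0,
) -> SuperLearnerFit:
    """Fit the convex Super Learner.

    ``loss`` is ``"nll"`` (binary negative log-likelihood; learners must
    produce probabilities) or ``"mse"`` (continuous squared error). Folds
    are stratified by the target for binary targets. Base learners that
    fail to fit on any fold are dropped with a warning; an empty surviving
    library is an error.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float)
    if loss not in ("nll", "mse"):
        raise ValueError("loss must be 'nll' or 'mse'")
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if len(library) == 0:
        raise ValueError("learner library is empty")
    specs = build_library(library, loss, seed)

    if loss == "nll" and np.unique(y).size < 2:
        # degenerate target: every learner would be a constant anyway
        logger.warning("constant binary target; returning degenerate fit")

    if loss == "nll" and np.unique(y).size >= 2:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X)

    folds = np.empty(len(y), dtype=int)
    oof = np.full((len(y), len(specs)), np.nan)
    failed: set[int] = set()
    for f, (tr, te) in enumerate(split_iter):
        folds[te] = f
        for j, spec in enumerate(specs):
            if j in failed:
                continue
            try:
                est = clone_or_rebuild(spec.estimator)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[tr], y[tr])
                oof[te, j] = _predict(est, X[te], loss)
            except Exception as exc:  # noqa: BLE001 - learner failure is data-dependent
                failed.add(j)
                logger.warning("dropping learner %s: %s", spec.name, exc)

    keep = [j for j in range(len(specs)) if j not in failed]
    if not keep:
        raise RuntimeError("every base learner failed to fit")
    specs = [specs[j] for j in keep]
    oof = oof[:, keep]

    cv_risks = {
        spec.name: _loss_value(y, oof[:, j], loss) for j, spec in enumerate(specs)
    }
    weights = _solve_simplex_weights(y, oof, loss)
    cv_risk_ens = _loss_value(y, oof @ weights, loss)

    for spec in specs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec.estimator.fit(X, y)
    return SuperLearnerFit(
        learners=specs,
        weights=weights,
        cv_risks=cv_risks,
        cv_risk_ensemble=cv_risk_ens,
        folds=folds,
        loss=loss,
    )


def clone_or_rebuild(est):
    try:
        return clone(est)
    except TypeError:
        import copy

        return copy.deepcopy(est)


# --- analysis-facing wrappers -------------------------------------------

LEVELS = ("low", "medium", "high")


@dataclass
class NuisanceEstimates:
    """Predictions needed by the targeting step.

    ``qbar`` maps each exposure level to the predicted outcome for every
    record with exposure forced to that level; ``qbar_obs`` is the
    prediction at the observed exposure. ``g`` is the (n, 3) matrix of
    exposure-level probabilities, already truncated to ``g_bounds`` and
    renormalized.
    """

    qbar: dict[str, np.ndarray]
    qbar_obs: np.ndarray
    g: np.ndarray
    g_bounds: tuple[float, float]
    g_truncated_fraction: float
    outcome_fit: SuperLearnerFit | None = None
    degenerate_outcome: bool = False


def _exposure_design(features: np.ndarray, level_codes: np.ndarray) -> np.ndarray:
    dummies = np.column_stack(
        [(level_codes == i).astype(float) for i in (1, 2)]
    )  # medium, high vs low baseline
    return np.hstack([dummies, features])


def _encode_levels(exposure) -> np.ndarray:
    exposure = np.asarray(exposure)
    codes = np.select(
        [exposure == "low", exposure == "medium", exposure == "high"], [0, 1, 2], -1
    )
    if (codes < 0).any():
        raise ValueError("exposure contains values outside {low, medium, high}")
    return codes


def fit_outcome_regression(
    features,
    exposure,
    outcome,
    library=DEFAULT_OUTCOME_LIBRARY,
    n_folds: int = 10,
    loss: str = "nll",
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], np.ndarray, SuperLearnerFit | None, bool]:
    """Fit Q(A, W) once and predict with A forced to each level.

    Returns ``(qbar_by_level, qbar_observed, fit, degenerate)``. A constant
    outcome yields a degenerate (constant) fit, flagged rather than fatal
    so downstream targeting can short-circuit.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(outcome, dtype=float)
    codes = _encode_levels(exposure)

    if np.unique(y).size < 2:
        const = float(y[0])
        qb = {lvl: np.full(len(y), const) for lvl in LEVELS}
        return qb, np.full(len(y), const), None, True

    fit = fit_super_learner(
        _exposure_design(X, codes), y, library=library, n_folds=n_folds,
        loss=loss, seed=seed,
    )
    qbar = {}
    for i, lvl in enumerate(LEVELS):
        forced = np.full(len(y), i)
        qbar[lvl] = fit.predict(_exposure_design(X, forced))
    qbar_obs = fit.predict(_exposure_design(X, codes))
    if loss == "nll":
        qbar = {k: np.clip(v, PRED_BOUND, 1 - PRED_BOUND) for k, v in qbar.items()}
        qbar_obs = np.clip(qbar_obs, PRED_BOUND, 1 - PRED_BOUND)
    return qbar, qbar_obs, fit, False


def fit_propensity(
    features,
    exposure,
    library=DEFAULT_PROPENSITY_LIBRARY,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, SuperLearnerFit]]:
    """Three-level exposure probabilities via two nested binary stacks.

    First stack: P(A = low | W). Second, among the remaining records:
    P(A = high | W, A != low). The three probabilities multiply out and
    rows sum to one by construction, which lets every binary learner in
    the library be reused unchanged.
    """
    X = np.asarray(features, dtype=float)
    codes = _encode_levels(exposure)
    counts = {lvl: int((codes == i).sum()) for i, lvl in enumerate(LEVELS)}
    thin = [lvl for lvl, c in counts.items() if c < 10]
    if thin:
        raise ValueError(
            f"exposure level(s) {thin} have fewer than 10 observations; "
            "collapse categories before estimating propensities"
        )

    is_low = (codes == 0).astype(float)
    fit_low = fit_super_learner(
        X, is_low, library=library, n_folds=n_folds, loss="nll", seed=seed
    )
    p_low = fit_low.predict(X)

    rest = codes > 0
    is_high_rest = (codes[rest] == 2).astype(float)
    fit_high = fit_super_learner(
        X[rest], is_high_rest, library=library, n_folds=n_folds, loss="nll",
        seed=seed + 1,
    )
    p_high_given_rest = fit_high.predict(X)

    g = np.column_stack(
        [
            p_low,
            (1 - p_low) * (1 - p_high_given_rest),
            (1 - p_low) * p_high_given_rest,
        ]
    )
    g = g / g.sum(axis=1, keepdims=True)
    return g, {"low_vs_rest": fit_low, "high_vs_medium": fit_high}


def bound_propensity(
    g, lo: float = 0.025, hi: float = 0.975
) -> tuple[np.ndarray, float]:
    """Truncate propensities to [lo, hi] and renormalize rows.

    Returns the bounded matrix and the fraction of truncated cells --
    a positivity diagnostic worth reporting."""
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("bounds must satisfy 0 < lo < hi < 1")
    g = np.asarray(g, dtype=float)
    clipped = np.clip(g, lo, hi)
    frac = float(np.mean(clipped != g))
    return clipped / clipped.sum(axis=1, keepdims=True), frac


def estimate_nuisances(
    features,
    exposure,
    outcome,
    outcome_library=DEFAULT_OUTCOME_LIBRARY,
    propensity_library=DEFAULT_PROPENSITY_LIBRARY,
    n_folds: int = 10,
    outcome_loss: str = "nll",
    g_bounds: tuple[float, float] = (0.025, 0.975),
    seed: int = 0,
) -> NuisanceEstimates:
    """Convenience wrapper fitting both nuisances for one analysis."""
    qbar, qbar_obs, fit, degenerate = fit_outcome_regression(
        features, exposure, outcome, library=outcome_library, n_folds=n_folds,
        loss=outcome_loss, seed=seed,
    )
    g_raw, _ = fit_propensity(
        features, exposure, library=propensity_library, n_folds=n_folds, seed=seed
    )
    g, trunc = bound_propensity(g_raw, *g_bounds)
    return NuisanceEstimates(
        qbar=qbar,
        qbar_obs=qbar_obs,
        g=g,
        g_bounds=g_bounds,
        g_truncated_fraction=trunc,
        outcome_fit=fit,
        degenerate_outcome=degenerate,
    )
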