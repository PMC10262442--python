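"""Average treatment effect estimators.

The primary estimator is TMLE: take an initial outcome regression
Q(A, W), update it with one intercept-only logistic fluctuation per
exposure level -- weighted by the clever covariate
H_a(A, W) = 1(A = a) / g(a | W) -- and plug the targeted predictions into
the counterfactual-mean formula. The fluctuation MLE solves the efficient
influence curve (EIC) score equation exactly, so the empirical mean of
each level's EIC is zero after targeting and the EIC delivers valid
(here: village-clustered) standard errors.

Bounded count outcomes are handled the standard way: min-max scale to
[0, 1], run the logistic machinery, transform back.

Parametric G-computation (standardization with a cluster bootstrap) is
the robustness estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nuisance import LEVELS, NuisanceEstimates, PRED_BOUND

CANONICAL_COMPARISONS = (("high", "low"), ("high", "medium"), ("medium", "low"))


@dataclass(frozen=True)
class OutcomeSpec:
    """Which antenatal-care outcome is analyzed and on which subsample.

    ``kind`` is "binary" (a pairwise contrast of visit categories, run on
    the subsample the pair implies) or "count" (total visits on the full
    sample, min-max scaled for targeting).
    """

    name: str
    kind: str  # "binary" | "count"

    def subsample_mask(self, visits: np.ndarray) -> np.ndarray:
        visits = np.asarray(visits)
        if self.name == "ge4_vs_1to3":
            return visits >= 1
        if self.name == "none_vs_1to3":
            return visits <= 3
        if self.name == "ge4_vs_none":
            return (visits == 0) | (visits >= 4)
        if self.name == "count":
            return np.ones(len(visits), dtype=bool)
        raise ValueError(f"unknown outcome spec {self.name!r}")

    def outcome(self, visits: np.ndarray) -> np.ndarray:
        visits = np.asarray(visits)
        if self.name == "ge4_vs_1to3":
            return (visits >= 4).astype(float)
        if self.name == "none_vs_1to3":
            return (visits == 0).astype(float)
        if self.name == "ge4_vs_none":
            return (visits >= 4).astype(float)
        if self.name == "count":
            return visits.astype(float)
        raise ValueError(f"unknown outcome spec {self.name!r}")


OUTCOME_SPECS = {
    "ge4_vs_1to3": OutcomeSpec("ge4_vs_1to3", "binary"),
    "none_vs_1to3": OutcomeSpec("none_vs_1to3", "binary"),
    "ge4_vs_none": OutcomeSpec("ge4_vs_none", "binary"),
    "count": OutcomeSpec("count", "count"),
}


@dataclass
class TargetedMeans:
    """Per-level targeted counterfactual means with their EIC values."""

    psi: dict[str, float]
    eic: dict[str, np.ndarray]
    epsilon: dict[str, float]
    scale: tuple[float, float]  # (offset, range) used for count outcomes
    n: int


@dataclass
class ATEEstimate:
    psi: float
    se: float
    ci_lower: float
    ci_upper: float
    n_used: int
    n_clusters: int
    eic: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "psi": self.psi,
            "se": self.se,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "n_used": self.n_used,
            "n_clusters": self.n_clusters,
            "diagnostics": self.diagnostics,
        }


def _logit(p: np.ndarray) -> np.ndarray:
    # tighter than the nuisance-level prediction bound: only guards
    # against exact 0/1 from degenerate (e.g. saturated) nuisances
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _solve_fluctuation(y, q, weights, tol: float = 1e-13, max_iter: int = 200) -> float:
    """Newton solve for the intercept epsilon of the weighted logistic
    fluctuation: sum_i w_i (y_i - expit(logit(q_i) + eps)) = 0."""
    if weights.sum() == 0:
        return 0.0
    offset = _logit(q)
    eps = 0.0
    for _ in range(max_iter):
        p = _expit(offset + eps)
        score = np.sum(weights * (y - p))
        info = np.sum(weights * p * (1 - p))
        if info <= 0:
            break
        step = score / info
        eps += step
        if abs(step) < tol:
            return eps
    # Newton failed to converge: either a separation-type degeneracy or
    # weights concentrated on a constant outcome
    p = _expit(offset + eps)
    if abs(np.sum(weights * (y - p))) > 1e-6 * max(1.0, weights.sum()):
        raise RuntimeError(
            "TMLE fluctuation did not converge "
            f"(residual score {np.sum(weights * (y - p)):.3g})"
        )
    return eps


def tmle_counterfactual_means(
    exposure,
    outcome,
    nuisance: NuisanceEstimates,
    outcome_kind: str = "binary",
) -> TargetedMeans:
    """Target the three level-specific counterfactual means jointly.

    One intercept-only weighted logistic fluctuation per level, clever
    covariate used as weight. For ``outcome_kind == "count"`` the outcome
    and its nuisance predictions must already be on the observed-range
    [0, 1] scale set by :func:`scale_count`; psi and EIC are returned on
    that scale and back-transformed by the caller.
    """
    from .nuisance import _encode_levels

    y = np.asarray(outcome, dtype=float)
    codes = _encode_levels(exposure)
    n = len(y)
    if n == 0:
        raise ValueError("empty analysis subsample")
    if any(len(nuisance.qbar[lvl]) != n for lvl in LEVELS) or len(nuisance.g) != n:
        raise ValueError("nuisance prediction length does not match data")

    psi: dict[str, float] = {}
    eic: dict[str, np.ndarray] = {}
    epsilon: dict[str, float] = {}
    if nuisance.degenerate_outcome or np.unique(y).size < 2:
        # constant outcome: the targeted mean is the constant, EIC vanishes
        const = float(y[0]) if n else 0.0
        for lvl in LEVELS:
            psi[lvl] = const
            eic[lvl] = np.zeros(n)
            epsilon[lvl] = 0.0
        return TargetedMeans(psi=psi, eic=eic, epsilon=epsilon, scale=(0.0, 1.0), n=n)

    for i, lvl in enumerate(LEVELS):
        g_a = nuisance.g[:, i]
        h = (codes == i).astype(float) / g_a
        q_a = nuisance.qbar[lvl]
        eps = _solve_fluctuation(y, q_a, h)
        q_star = _expit(_logit(q_a) + eps)
        psi_a = float(np.mean(q_star))
        psi[lvl] = psi_a
        eic[lvl] = h * (y - q_star) + q_star - psi_a
        epsilon[lvl] = eps
    return TargetedMeans(psi=psi, eic=eic, epsilon=epsilon, scale=(0.0, 1.0), n=n)


def scale_count(y: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Min-max scale a count outcome to [0, 1] using the observed range."""
    y = np.asarray(y, dtype=float)
    lo, hi = float(y.min()), float(y.max())
    if hi <= lo:
        return np.zeros_like(y), (lo, 1.0)
    return (y - lo) / (hi - lo), (lo, hi - lo)


def cluster_variance(eic, cluster_ids, n: int | None = None) -> float:
    """Village-clustered influence-curve standard error.

    se^2 = (1/n^2) * sum over clusters of (within-cluster EIC sum)^2.
    With singleton clusters this reduces exactly to the unclustered
    influence-curve standard error sqrt(sum eic_i^2) / n.
    """
    eic = np.asarray(eic, dtype=float)
    cluster_ids = np.asarray(cluster_ids)
    if len(eic) != len(cluster_ids):
        raise ValueError("eic and cluster_ids length mismatch")
    uniq = pd.unique(cluster_ids)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters for a clustered variance")
    n = n or len(eic)
    sums = pd.Series(eic).groupby(pd.Series(cluster_ids), sort=False).sum().to_numpy()
    return float(np.sqrt(np.sum(sums**2)) / n)


def tmle_ate(
    means: TargetedMeans,
    comparison: tuple[str, str],
    cluster_ids,
) -> ATEEstimate:
    """Pairwise ATE from jointly targeted means.

    Because the three means share one targeting pass, the pairwise
    differences telescope exactly: psi(high, low) =
    psi(high, medium) + psi(medium, low).
    """
    a1, a0 = comparison
    if a1 not in LEVELS or a0 not in LEVELS:
        raise ValueError(f"unknown levels in comparison {comparison}")
    cluster_ids = np.asarray(cluster_ids)
    if len(cluster_ids) != means.n:
        raise ValueError("cluster_ids length does not match targeted means")

    offset, rng = means.scale
    psi = (means.psi[a1] - means.psi[a0]) * rng
    eic_diff = (means.eic[a1] - means.eic[a0]) * rng
    if np.allclose(eic_diff, 0.0):
        se = 0.0
    else:
        se = cluster_variance(eic_diff, cluster_ids)
    return ATEEstimate(
        psi=psi,
        se=se,
        ci_lower=psi - 1.96 * se,
        ci_upper=psi + 1.96 * se,
        n_used=means.n,
        n_clusters=len(pd.unique(cluster_ids)),
        eic=eic_diff,
        diagnostics={
            "mean_eic": {lvl: float(np.mean(means.eic[lvl])) for lvl in LEVELS},
            "epsilon": means.epsilon,
        },
    )


def tmle_pairwise_ates(
    exposure, outcome, nuisance, cluster_ids, outcome_kind: str = "binary",
    comparisons=CANONICAL_COMPARISONS,
) -> dict[tuple[str, str], ATEEstimate]:
    """Joint targeting, then all requested pairwise contrasts."""
    y = np.asarray(outcome, dtype=float)
    scale = (0.0, 1.0)
    if outcome_kind == "count":
        y, scale = scale_count(y)
    means = tmle_counterfactual_means(exposure, y, nuisance, outcome_kind)
    means.scale = scale
    return {cmp: tmle_ate(means, cmp, cluster_ids) for cmp in comparisons}


# --- saturated (nonparametric) nuisances, for oracle checks --------------

def saturated_nuisances(features, exposure, outcome) -> NuisanceEstimates:
    """Empirical stratum means and propensities for discrete covariates.

    With these nuisances TMLE collapses to nonparametric standardization,
    which is the hand-checkable oracle for the estimator stack.
    """
    from .nuisance import _encode_levels

    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] != len(np.asarray(outcome)):
        X = X.T
    y = np.asarray(outcome, dtype=float)
    codes = _encode_levels(exposure)
    strata = pd.DataFrame(X).apply(tuple, axis=1)

    qbar = {lvl: np.empty(len(y)) for lvl in LEVELS}
    g = np.empty((len(y), 3))
    for s in strata.unique():
        in_s = (strata == s).to_numpy()
        for i, lvl in enumerate(LEVELS):
            cell = in_s & (codes == i)
            if not cell.any():
                raise ValueError(
                    f"stratum {s} has no observations at level {lvl}; "
                    "saturated nuisances undefined"
                )
            qbar[lvl][in_s] = y[cell].mean()
            g[in_s, i] = cell.sum() / in_s.sum()
    qbar = {k: np.clip(v, 1e-12, 1 - 1e-12) for k, v in qbar.items()}
    qbar_obs = np.choose(codes, [qbar["low"], qbar["medium"], qbar["high"]])
    return NuisanceEstimates(
        qbar=qbar,
        qbar_obs=qbar_obs,
        g=g,
        g_bounds=(0.0, 1.0),
        g_truncated_fraction=0.0,
    )


def standardized_means(features, exposure, outcome) -> dict[str, float]:
    """Direct nonparametric standardization: average the stratum means
    over the empirical covariate distribution. Independent oracle for the
    saturated-model equivalence checks."""
    nuis = saturated_nuisances(features, exposure, outcome)
    return {lvl: float(np.mean(nuis.qbar[lvl])) for lvl in LEVELS}


# --- parametric G-computation -------------------------------------------

def _gcomp_design(X: np.ndarray, codes: np.ndarray, saturated: bool) -> np.ndarray:
    dummies = np.column_stack([(codes == i).astype(float) for i in (1, 2)])
    if not saturated:
        return np.hstack([np.ones((len(codes), 1)), dummies, X])
    # full interaction of discrete covariate pattern with exposure dummies
    strata = pd.DataFrame(X).apply(tuple, axis=1)
    stratum_dummies = pd.get_dummies(strata).to_numpy(dtype=float)
    cols = [stratum_dummies]
    for d in dummies.T:
        cols.append(stratum_dummies * d[:, None])
    return np.hstack(cols)


def _fit_glm(design: np.ndarray, y: np.ndarray, binary: bool):
    import statsmodels.api as sm

    family = sm.families.Binomial() if binary else sm.families.Gaussian()
    model = sm.GLM(y, design, family=family)
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(maxiter=200)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"G-computation outcome model failed: {exc}") from exc


def gcomp_ate(
    features,
    exposure,
    outcome,
    comparison: tuple[str, str],
    cluster_ids,
    outcome_kind: str = "binary",
    model: str = "main",
    n_boot: int = 1000,
    seed: int = 0,
) -> ATEEstimate:
    """Parametric G-computation with a village-cluster bootstrap CI.

    Fits one outcome model (main-terms GLM by default, ``model="saturated"``
    for discrete-covariate interactions with exposure), predicts with the
    exposure forced to each compared level, and differences the prediction
    means. The 95% CI is the percentile interval over ``n_boot`` resamples
    of whole villages with replacement.
    """
    from .nuisance import _encode_levels

    if n_boot < 50:
        import warnings

        warnings.warn(f"n_boot={n_boot} is too small for a stable percentile CI")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] != len(np.asarray(outcome)):
        X = X.T
    y = np.asarray(outcome, dtype=float)
    codes = _encode_levels(exposure)
    cluster_ids = np.asarray(cluster_ids)
    a1, a0 = comparison
    binary = outcome_kind == "binary"
    lvl_code = {lvl: i for i, lvl in enumerate(LEVELS)}

    def estimate(idx: np.ndarray) -> float:
        if a1 == a0:
            return 0.0
        if np.unique(y[idx]).size < 2:
            # constant outcome: any fitted model predicts the constant
            return 0.0
        design = _gcomp_design(X[idx], codes[idx], model == "saturated")
        # a saturated linear model reproduces stratum means exactly for any
        # outcome type, so use the identity link there (no separation issues)
        res = _fit_glm(design, y[idx], binary and model != "saturated")
        preds = {}
        for a in (a1, a0):
            forced = np.full(len(idx), lvl_code[a])
            d = _gcomp_design(X[idx], forced, model == "saturated")
            preds[a] = float(np.mean(res.predict(d)))
        return preds[a1] - preds[a0]

    all_idx = np.arange(len(y))
    psi = estimate(all_idx)

    rng = np.random.default_rng(seed)
    villages = pd.unique(cluster_ids)
    by_village = {v: all_idx[cluster_ids == v] for v in villages}
    boots = []
    for _ in range(n_boot):
        draw = rng.choice(villages, size=len(villages), replace=True)
        idx = np.concatenate([by_village[v] for v in draw])
        try:
            boots.append(estimate(idx))
        except RuntimeError:
            continue
    boots = np.asarray(boots)
    if a1 == a0 or len(boots) == 0 or np.allclose(boots, boots[0]):
        lo = hi = psi
        se = 0.0
    else:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        se = float(boots.std(ddof=1))
    return ATEEstimate(
        psi=psi,
        se=se,
        ci_lower=float(min(lo, psi)),
        ci_upper=float(max(hi, psi)),
        n_used=len(y),
        n_clusters=len(villages),
        diagnostics={"n_boot_ok": int(len(boots)), "model": model},
    )
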