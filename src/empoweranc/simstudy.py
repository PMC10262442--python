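"""Monte-Carlo validation harness.

Replicated generate -> analyze experiments against the generator's known
counterfactual truth: parameter recovery (bias, SE calibration, CI
coverage), the double-robustness property of TMLE under deliberate
nuisance misspecification, and exact-equivalence oracle checks on a
discrete toy cohort where TMLE, G-computation and hand standardization
must coincide.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import synthdata as sd
from .estimators import (
    OUTCOME_SPECS,
    gcomp_ate,
    saturated_nuisances,
    scale_count,
    standardized_means,
    tmle_pairwise_ates,
)
from .nuisance import FAST_LIBRARY, estimate_nuisances
from .pipeline import ANALYSIS_COVARIATES, derive_analysis_table, impute_median_with_indicators

#: covariates entering the misspecified (confounder-omitting) nuisances.
#: the omitted variable is chosen as the strongest confounder of the DGP.
def strongest_confounder(config: sd.DGPConfig) -> str:
    products = {
        k: abs(config.confounding_coefficients.get(k, 0.0))
        * abs(config.outcome_coefficients.get(k, 0.0))
        for k in config.confounding_coefficients
    }
    return max(products, key=products.get)


@dataclass
class ExperimentResult:
    """Summary of one replicated experiment cell."""

    estimator: str
    n: int
    replicates: int
    truth: float
    bias: float
    empirical_sd: float
    mean_se: float
    rmse: float
    coverage: float
    estimates: np.ndarray
    ses: np.ndarray

    @classmethod
    def from_replicates(cls, estimator, n, truth, psis, ses) -> "ExperimentResult":
        psis = np.asarray(psis, dtype=float)
        ses = np.asarray(ses, dtype=float)
        bias = float(psis.mean() - truth)
        # ddof=0 so that rmse^2 == bias^2 + sd^2 holds as an identity
        sdv = float(psis.std(ddof=0))
        cover = float(
            np.mean((psis - 1.96 * ses <= truth) & (truth <= psis + 1.96 * ses))
        )
        rmse = float(np.sqrt(np.mean((psis - truth) ** 2)))
        return cls(
            estimator=estimator,
            n=n,
            replicates=len(psis),
            truth=float(truth),
            bias=bias,
            empirical_sd=sdv,
            mean_se=float(ses.mean()),
            rmse=rmse,
            coverage=cover,
            estimates=psis,
            ses=ses,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["estimates"] = self.estimates.tolist()
        d["ses"] = self.ses.tolist()
        return d


def _replicate_seeds(master_seed: int, n_reps: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_reps)]


def _analyze_once(
    config: sd.DGPConfig,
    rep_seed: int,
    outcome_spec: str,
    comparison: tuple[str, str],
    library,
    n_folds: int,
    drop_confounder_from: str | None = None,
    estimator: str = "tmle",
):
    """One generate -> derive -> estimate cycle. Returns (psi, se)."""
    cfg = dataclasses.replace(config, seed=rep_seed)
    cohort = sd.generate_cohort(cfg, truth_draws=None)
    table = derive_analysis_table(cohort.records)
    table, _ = impute_median_with_indicators(table, list(ANALYSIS_COVARIATES))

    spec = OUTCOME_SPECS[outcome_spec]
    mask = spec.subsample_mask(table["anc_visits"].to_numpy())
    sub = table.loc[mask]
    exposure = sub["cat_aggregate"].to_numpy()
    y_raw = spec.outcome(sub["anc_visits"].to_numpy())
    y_fit = y_raw
    loss = "nll"
    if spec.kind == "count":
        y_fit, _ = scale_count(y_raw)
        loss = "mse"

    feature_cols = list(ANALYSIS_COVARIATES)
    omitted_cols = feature_cols
    if drop_confounder_from is not None:
        omit = strongest_confounder(cfg)
        omit = "wealth_pc1" if omit == "wealth_latent" else omit
        omitted_cols = [c for c in feature_cols if c != omit]

    if estimator == "gcomp":
        est = gcomp_ate(
            sub[feature_cols].to_numpy(), exposure, y_raw, comparison,
            sub["village_id"].to_numpy(), outcome_kind=spec.kind,
            n_boot=200, seed=rep_seed,
        )
        return est.psi, est.se

    q_cols = omitted_cols if drop_confounder_from in ("outcome", "both") else feature_cols
    g_cols = omitted_cols if drop_confounder_from in ("propensity", "both") else feature_cols

    from .nuisance import bound_propensity, fit_outcome_regression, fit_propensity
    from .nuisance import NuisanceEstimates

    qbar, qbar_obs, _, degen = fit_outcome_regression(
        sub[q_cols].to_numpy(), exposure, y_fit, library=library,
        n_folds=n_folds, loss=loss, seed=rep_seed,
    )
    g_raw, _ = fit_propensity(
        sub[g_cols].to_numpy(), exposure, library=library, n_folds=n_folds,
        seed=rep_seed,
    )
    g, trunc = bound_propensity(g_raw)
    nuis = NuisanceEstimates(
        qbar=qbar, qbar_obs=qbar_obs, g=g, g_bounds=(0.025, 0.975),
        g_truncated_fraction=trunc, degenerate_outcome=degen,
    )

    if estimator == "plugin":
        # naive substitution estimator: average the untargeted outcome
        # regression, no influence-curve correction
        rng = 1.0
        if spec.kind == "count":
            _, (_, rng) = scale_count(y_raw)
        a1, a0 = comparison
        psi = float(np.mean(qbar[a1]) - np.mean(qbar[a0])) * rng
        return psi, float("nan")

    ates = tmle_pairwise_ates(
        exposure, y_raw, nuis, sub["village_id"].to_numpy(),
        outcome_kind=spec.kind, comparisons=(comparison,),
    )
    est = ates[comparison]
    return est.psi, est.se


def run_recovery(
    config: sd.DGPConfig,
    estimator: str = "tmle",
    n: int = 2000,
    n_reps: int = 300,
    seed: int = 7,
    outcome_spec: str = "ge4_vs_1to3",
    comparison: tuple[str, str] = ("high", "low"),
    library=FAST_LIBRARY,
    n_folds: int = 2,
    truth_mc: int = 1_000_000,
) -> ExperimentResult:
    """Parameter recovery: replicated analyses against the MC truth."""
    config = dataclasses.replace(config, n_mothers=n)
    truth = sd.true_ate(config, comparison, outcome_spec, n_mc=truth_mc)
    psis, ses = [], []
    for rep_seed in _replicate_seeds(seed, n_reps):
        psi, se = _analyze_once(
            config, rep_seed, outcome_spec, comparison, library, n_folds,
            estimator=estimator,
        )
        psis.append(psi)
        ses.append(se)
    return ExperimentResult.from_replicates(estimator, n, truth, psis, ses)


def run_double_robustness(
    config: sd.DGPConfig,
    which_misspecified: str = "outcome",
    n: int = 5000,
    n_reps: int = 200,
    seed: int = 11,
    outcome_spec: str = "ge4_vs_1to3",
    comparison: tuple[str, str] = ("high", "low"),
    library=FAST_LIBRARY,
    n_folds: int = 2,
    truth_mc: int = 1_000_000,
) -> dict[str, ExperimentResult]:
    """TMLE vs the naive plug-in under nuisance misspecification.

    ``which_misspecified`` in {outcome, propensity, both, neither}. The
    misspecification device omits the DGP's strongest confounder from the
    chosen nuisance. The plug-in always uses the (possibly misspecified)
    outcome regression alone, so when the outcome model is broken the
    plug-in inherits the full confounding bias while TMLE's propensity
    update removes it.
    """
    if which_misspecified not in ("outcome", "propensity", "both", "neither"):
        raise ValueError(f"unknown misspecification {which_misspecified!r}")
    drop = None if which_misspecified == "neither" else which_misspecified
    config = dataclasses.replace(config, n_mothers=n)
    truth = sd.true_ate(config, comparison, outcome_spec, n_mc=truth_mc)

    out: dict[str, list] = {"tmle": [[], []], "plugin": [[], []]}
    for rep_seed in _replicate_seeds(seed, n_reps):
        for name in ("tmle", "plugin"):
            psi, se = _analyze_once(
                config, rep_seed, outcome_spec, comparison, library, n_folds,
                drop_confounder_from=drop, estimator=name,
            )
            out[name][0].append(psi)
            out[name][1].append(se)
    return {
        name: ExperimentResult.from_replicates(name, n, truth, psis, ses)
        for name, (psis, ses) in out.items()
    }


# --- discrete toy cohort and oracle equivalence --------------------------

def toy_cohort() -> pd.DataFrame:
    """The 18-row discrete fixture: one binary covariate, all three
    exposure levels in both strata, binary outcome, singleton villages.

    Stratum means: W=0 -> (1/3, 2/3, 1) and W=1 -> (0, 1/3, 2/3) for
    (low, medium, high), each stratum-level cell holding 3 mothers, so
    the standardized counterfactual means are 1/6, 1/2 and 5/6.
    """
    w = np.repeat([0, 1], 9)
    a = np.tile(np.repeat(["low", "medium", "high"], 3), 2)
    y = np.array(
        [0, 0, 1, 0, 1, 1, 1, 1, 1,   # W=0: low, medium, high
         0, 0, 0, 0, 0, 1, 0, 1, 1]   # W=1: low, medium, high
    )
    return pd.DataFrame(
        {"w": w, "exposure": a, "y": y, "village_id": np.arange(1, 19)}
    )


def check_saturated_equivalence(fixture: pd.DataFrame | None = None) -> float:
    """Max absolute discrepancy between TMLE, G-computation and direct
    standardization on a discrete cohort with saturated nuisances.

    Should be below 1e-6; anything larger means an estimator defect.
    """
    df = toy_cohort() if fixture is None else fixture
    X = df[["w"]].to_numpy()
    a = df["exposure"].to_numpy()
    y = df["y"].to_numpy().astype(float)
    for lvl in ("low", "medium", "high"):
        for s in np.unique(X[:, 0]):
            if not ((a == lvl) & (X[:, 0] == s)).any():
                raise ValueError(f"empty stratum (w={s}, a={lvl})")

    nuis = saturated_nuisances(X, a, y)
    tmle = tmle_pairwise_ates(a, y, nuis, df["village_id"].to_numpy())
    hand = standardized_means(X, a, y)

    disc = 0.0
    for a1, a0 in ((("high", "low")), ("high", "medium"), ("medium", "low")):
        psi_hand = hand[a1] - hand[a0]
        psi_tmle = tmle[(a1, a0)].psi
        gc = gcomp_ate(
            X, a, y, (a1, a0), df["village_id"].to_numpy(),
            model="saturated", n_boot=0, seed=0,
        )
        disc = max(disc, abs(psi_tmle - psi_hand), abs(gc.psi - psi_hand))
    return disc
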