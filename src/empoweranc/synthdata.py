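"""Synthetic survey cohorts with known causal structure.

The generator emulates the statistical shape of a rural Bangladesh
mother-child survey: village-clustered households, covariates matched to
the study's descriptive marginals, 15 ordinal empowerment items driven by
a confounded latent construct, and a zero-inflated antenatal-care (ANC)
visit count whose log-mean carries additive effects of the empowerment
category. Because the exposure effect enters a known structural equation,
every causal contrast the analysis estimates has a Monte-Carlo-computable
ground truth, which is what makes the estimation machinery testable
without the access-restricted study data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .indices import ItemSchema, categorize_quantile, default_schema, score_weai

#: covariates entering the structural (confounding and outcome) equations.
#: all are observable in the survey; household wealth enters through the
#: asset count so the analysis covariate set satisfies no-unmeasured-
#: confounding (the asset-PCA wealth score is an essentially lossless
#: transform of it)
COVARIATES = (
    "age",
    "cesd",
    "education",
    "edu_differential",
    "child_age_months",
    "household_members",
    "children_under15",
    "asset_count",
)

#: exposure levels in increasing order of empowerment
LEVELS = ("low", "medium", "high")

#: the four outcome specifications of the analysis, by name
OUTCOME_SPECS = ("ge4_vs_1to3", "none_vs_1to3", "ge4_vs_none", "count")


def _marginal_defaults() -> dict[str, tuple[float, float]]:
    # mean/SD targets from the study's descriptive table (full sample)
    return {
        "age": (25.8, 5.5),
        "cesd": (13.8, 8.9),
        "education": (6.6, 3.5),
        "edu_differential": (1.1, 3.8),
        "child_age_months": (13.5, 5.3),
        "household_members": (5.2, 1.9),
        "children_under15": (1.9, 0.8),
        # derived analytically from the asset model (latent N(0,1), spread
        # item difficulties); used only to standardize the structural index
        "asset_count": (4.0, 1.95),
    }


def _confounding_defaults() -> dict[str, float]:
    # weights of standardized covariates on the latent empowerment construct
    return {
        "age": 0.25,
        "cesd": -0.30,
        "education": 0.35,
        "edu_differential": 0.10,
        "household_members": -0.20,
        "children_under15": -0.15,
        "asset_count": 0.30,
    }


def _outcome_coef_defaults() -> dict[str, float]:
    # weights of standardized covariates on the log-mean visit count
    return {
        "age": 0.05,
        "cesd": -0.08,
        "education": 0.10,
        "edu_differential": 0.03,
        "household_members": -0.03,
        "children_under15": -0.05,
        "asset_count": 0.10,
    }


def _missing_defaults() -> dict[str, float]:
    # the study median-imputed 17/1609 education differentials and 1/1609 CESD
    return {"edu_differential": 17 / 1609, "cesd": 1 / 1609}


@dataclass
class DGPConfig:
    """Parameters of the data-generating process.

    ``intercept`` (log baseline visit count), ``zero_inflation`` (structural
    zero mass) and the two log-scale exposure effects are calibrated by
    forward simulation so that the default cohort reproduces the study's
    observed visit distribution (mean ~3.1, ~14% zeros) and a
    high-vs-low contrast of 0.15 on the probability of >=4 visits among
    attenders. ``effect_medium``/``effect_high`` are additive effects of
    the forced exposure category (vs low) on the log-mean.
    """

    n_mothers: int = 1609
    n_villages: int = 109
    seed: int = 2019
    covariate_marginals: dict[str, tuple[float, float]] = field(
        default_factory=_marginal_defaults
    )
    item_schema: ItemSchema = field(default_factory=default_schema)
    confounding_coefficients: dict[str, float] = field(
        default_factory=_confounding_defaults
    )
    outcome_coefficients: dict[str, float] = field(
        default_factory=_outcome_coef_defaults
    )
    # calibrated; see docs/methods.md
    intercept: float = 1.0965
    effect_medium: float = 0.0956
    effect_high: float = 0.2310
    zero_inflation: float = 0.0985
    village_sd: float = 0.15
    item_noise_sd: float = 1.2
    latent_noise_sd: float = 1.0
    sanitation_rate: float = 0.68
    income_log_mean: float = 4.827
    income_log_sd: float = 0.8
    n_wealth_assets: int = 8
    missing_rates: dict[str, float] = field(default_factory=_missing_defaults)

    def __post_init__(self) -> None:
        if self.n_mothers <= 0 or self.n_villages <= 0:
            raise ValueError("n_mothers and n_villages must be positive")
        if self.n_villages > self.n_mothers:
            raise ValueError("cannot have more villages than mothers")
        for name, (m, s) in self.covariate_marginals.items():
            if s < 0:
                raise ValueError(f"negative SD for covariate {name}")
        if not (0.0 <= self.zero_inflation < 1.0):
            raise ValueError("zero_inflation must be in [0, 1)")
        for name, r in self.missing_rates.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"missing rate for {name} outside [0, 1]")
        if min(self.village_sd, self.item_noise_sd, self.latent_noise_sd) < 0:
            raise ValueError("SD parameters must be nonnegative")

    @property
    def effects(self) -> dict[str, float]:
        return {"low": 0.0, "medium": self.effect_medium, "high": self.effect_high}


@dataclass
class SyntheticCohort:
    """A generated cohort plus its causal ground truth.

    ``records`` has one row per mother (see :data:`RECORD_COLUMNS`);
    ``truth`` maps each outcome specification to the Monte-Carlo
    counterfactual mean per forced exposure level; ``latent_scores`` holds
    the per-mother latent empowerment values the items were cut from.
    """

    records: pd.DataFrame
    truth: dict[str, dict[str, float]]
    latent_scores: np.ndarray
    config: DGPConfig

    def to_csv(self, path, truth_path=None) -> None:
        self.records.to_csv(path, index=False)
        if truth_path is not None:
            import dataclasses as _dc
            import json

            payload = {
                "truth": self.truth,
                "config": {
                    k: v
                    for k, v in _dc.asdict(self.config).items()
                    if k != "item_schema"
                },
            }
            with open(truth_path, "w") as fh:
                json.dump(payload, fh, indent=2, default=list)


ITEM_COLS = [f"item_{j + 1:02d}" for j in range(15)]
ASSET_COLS = [f"asset_{k + 1}" for k in range(8)]

RECORD_COLUMNS = (
    ["mother_id", "village_id"]
    + ITEM_COLS
    + list(COVARIATES)
    + ["n_other_adults", "water", "sanitation"]
    + ASSET_COLS
    + ["income_monthly", "anc_visits"]
)


def _standardize(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return (values - mean) / sd if sd > 0 else values - mean


def _draw_covariates(config: DGPConfig, rng: np.random.Generator, n: int) -> pd.DataFrame:
    m = config.covariate_marginals
    cov = {}
    cov["age"] = np.clip(rng.normal(*m["age"], n), 15, 49)
    cov["cesd"] = np.clip(rng.normal(*m["cesd"], n), 0, 60)
    cov["education"] = np.clip(np.round(rng.normal(*m["education"], n)), 0, 16)
    cov["edu_differential"] = np.clip(
        np.round(rng.normal(*m["edu_differential"], n)), -12, 12
    )
    cov["child_age_months"] = np.clip(rng.normal(*m["child_age_months"], n), 6, 24)
    cov["household_members"] = np.clip(
        np.round(rng.normal(*m["household_members"], n)), 2, 15
    )
    cov["children_under15"] = np.clip(
        np.round(rng.normal(*m["children_under15"], n)), 1, 6
    )
    wealth_latent = rng.normal(0.0, 1.0, n)
    assets = _draw_assets(config, rng, wealth_latent)
    cov["asset_count"] = assets.sum(axis=1)
    df = pd.DataFrame(cov)
    df.attrs["assets"] = assets
    return df


def _linear_index(
    cov: pd.DataFrame, coefs: dict[str, float], marginals: dict[str, tuple[float, float]]
) -> np.ndarray:
    eta = np.zeros(len(cov))
    for name, beta in coefs.items():
        mean, sd = marginals[name]
        eta += beta * _standardize(cov[name].to_numpy(), mean, sd)
    return eta


def _draw_visits(
    config: DGPConfig,
    rng: np.random.Generator,
    eta_cov: np.ndarray,
    village_effect: np.ndarray,
    category: np.ndarray,
) -> np.ndarray:
    """Zero-inflated Poisson visit counts given the structural log-mean."""
    category = np.asarray(category)
    effect = np.zeros(len(category))
    effect[category == "medium"] = config.effect_medium
    effect[category == "high"] = config.effect_high
    mu = np.exp(
        np.clip(config.intercept + eta_cov + village_effect + effect, None, 3.4)
    )
    counts = rng.poisson(mu)
    zero = rng.random(len(mu)) < config.zero_inflation
    counts[zero] = 0
    return counts


def generate_cohort(
    config: DGPConfig, truth_draws: int | None = 100_000
) -> SyntheticCohort:
    """Generate one survey cohort.

    The pipeline is: covariates -> latent empowerment (linear in
    standardized covariates plus noise) -> ordinal items (latent plus
    item noise cut at equally spaced thresholds) -> observational exposure
    category (25/75 quantiles of the WEAI-style score) -> zero-inflated
    Poisson visit count with village random effects.

    ``truth_draws`` sets the Monte-Carlo size of the counterfactual oracle
    populating ``truth``; pass ``None`` to skip it (e.g. inside replicated
    simulation studies that call :func:`true_ate` once instead).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.n_mothers

    cov = _draw_covariates(config, rng, n)
    village_id = rng.integers(1, config.n_villages + 1, size=n)
    village_effects = rng.normal(0.0, config.village_sd, config.n_villages)
    b_v = village_effects[village_id - 1]

    latent = _linear_index(
        cov, config.confounding_coefficients, config.covariate_marginals
    ) + rng.normal(0.0, config.latent_noise_sd, n)
    items = _draw_items(config, rng, latent)

    scores = score_weai(items, config.item_schema)
    category, _ = categorize_quantile(scores.aggregate)

    eta_cov = _linear_index(
        cov, config.outcome_coefficients, config.covariate_marginals
    )
    visits = _draw_visits(config, rng, eta_cov, b_v, category)

    records = pd.DataFrame({"mother_id": np.arange(1, n + 1), "village_id": village_id})
    records[ITEM_COLS] = items
    records[list(COVARIATES)] = cov
    records["n_other_adults"] = rng.poisson(1.3, n)
    records["water"] = np.ones(n, dtype=int)
    records["sanitation"] = (rng.random(n) < config.sanitation_rate).astype(int)
    records[ASSET_COLS] = cov.attrs["assets"]
    records["income_monthly"] = np.round(
        np.exp(rng.normal(config.income_log_mean, config.income_log_sd, n)), 2
    )
    records["anc_visits"] = visits

    truth: dict[str, dict[str, float]] = {}
    if truth_draws:
        truth = counterfactual_truth(config, n_mc=truth_draws)
        _validate_truth(truth)
    return SyntheticCohort(
        records=records[RECORD_COLUMNS], truth=truth, latent_scores=latent, config=config
    )


def _draw_items(
    config: DGPConfig, rng: np.random.Generator, latent: np.ndarray
) -> np.ndarray:
    """Ordinal-threshold model: latent + item noise, cut at equally spaced
    thresholds (in units of the item-latent SD) spanning roughly +/-1 SD."""
    n = latent.shape[0]
    schema = config.item_schema
    t_sd = np.sqrt(np.var(latent) + config.item_noise_sd**2) or 1.0
    items = np.zeros((n, 15), dtype=int)
    for j, item in enumerate(schema.items):
        t = latent + rng.normal(0.0, config.item_noise_sd, n)
        L = len(item.levels)
        cuts = (-1.0 + 2.0 * np.arange(1, L) / L) * t_sd
        items[:, j] = np.asarray(item.levels)[np.searchsorted(cuts, t)]
    return items


def _draw_assets(
    config: DGPConfig, rng: np.random.Generator, wealth: np.ndarray
) -> np.ndarray:
    n = wealth.shape[0]
    k = config.n_wealth_assets
    # spread asset difficulty so ownership prevalence varies across items
    intercepts = np.linspace(-1.2, 1.2, k)
    p = 1.0 / (1.0 + np.exp(-(wealth[:, None] + intercepts[None, :])))
    return (rng.random((n, k)) < p).astype(int)


# --- counterfactual oracle ----------------------------------------------

def _counterfactual_outcome_means(
    config: DGPConfig, level: str, n_mc: int, rng: np.random.Generator
) -> dict[str, float]:
    cov = _draw_covariates(config, rng, n_mc)
    # the estimand marginalizes over the village-effect distribution, so
    # draw effects i.i.d. per simulated mother (villages are exchangeable);
    # reusing a finite set of village draws would leave cluster-level MC
    # noise in the "truth"
    b_v = rng.normal(0.0, config.village_sd, n_mc)
    eta_cov = _linear_index(
        cov, config.outcome_coefficients, config.covariate_marginals
    )
    y = _draw_visits(config, rng, eta_cov, b_v, np.repeat(level, n_mc))

    def frac(event, sub):
        return float(event[sub].mean()) if sub.any() else float("nan")

    attender = y >= 1
    le3 = y <= 3
    none_or_ge4 = (y == 0) | (y >= 4)
    return {
        "count": float(y.mean()),
        "ge4_vs_1to3": frac(y >= 4, attender),
        "none_vs_1to3": frac(y == 0, le3),
        "ge4_vs_none": frac(y >= 4, none_or_ge4),
    }


def counterfactual_truth(
    config: DGPConfig, n_mc: int = 100_000
) -> dict[str, dict[str, float]]:
    """True counterfactual mean per outcome spec and forced exposure level.

    Deterministic given ``config.seed`` (a fixed seed stream separate from
    the one used to generate cohorts).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    by_level = {lvl: _counterfactual_outcome_means(config, lvl, n_mc, rng) for lvl in LEVELS}
    return {
        spec: {lvl: by_level[lvl][spec] for lvl in LEVELS} for spec in OUTCOME_SPECS
    }


def _validate_truth(truth: dict[str, dict[str, float]]) -> None:
    for spec, means in truth.items():
        if spec == "count":
            continue
        for lvl, m in means.items():
            if not (0.0 < m < 1.0):
                raise ValueError(
                    f"effect parameters drive the {spec} counterfactual mean "
                    f"for level {lvl} to {m}, outside (0, 1)"
                )


def true_ate(
    config: DGPConfig,
    comparison: tuple[str, str] = ("high", "low"),
    outcome_spec: str = "ge4_vs_1to3",
    n_mc: int = 1_000_000,
) -> float:
    """True average treatment effect E[Y(a1)] - E[Y(a0)] by forced-assignment
    Monte Carlo simulation of the structural outcome model."""
    if n_mc < 10**5:
        raise ValueError("n_mc must be at least 1e5 for a stable oracle")
    a1, a0 = comparison
    if a1 not in LEVELS or a0 not in LEVELS:
        raise ValueError(f"unknown exposure levels in comparison {comparison}")
    if outcome_spec not in OUTCOME_SPECS:
        raise ValueError(f"unknown outcome spec {outcome_spec!r}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    m1 = _counterfactual_outcome_means(config, a1, n_mc, rng)[outcome_spec]
    m0 = _counterfactual_outcome_means(config, a0, n_mc, rng)[outcome_spec]
    return m1 - m0


def inject_missingness(cohort: SyntheticCohort, config: DGPConfig) -> SyntheticCohort:
    """Mask covariate values completely at random at the configured rates.

    Items, the outcome and the village id are never masked (the study had
    complete data there). Returns a new cohort; the input is not mutated.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    records = cohort.records.copy()
    for name, rate in config.missing_rates.items():
        if name not in COVARIATES:
            raise ValueError(f"can only inject missingness into covariates, not {name}")
        if rate > 0:
            mask = rng.random(len(records)) < rate
            records.loc[mask, name] = np.nan
    return replace(cohort, records=records)
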