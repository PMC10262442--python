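"""End-to-end study analysis.

Orchestrates the full workflow on a survey table (real CSV or synthetic
cohort): median imputation with indicator columns, derivation of the
exposure indices and antenatal-care outcomes, TMLE average treatment
effects for the three pairwise empowerment comparisons across the four
outcome specifications, WAMI-tercile and risk-subgroup stratifications,
and the G-computation and PCA-index robustness analyses. Results are
written as a tidy CSV plus a JSON bundle with provenance (config hash,
seed, package versions).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import indices as idx
from . import synthdata as sd
from .estimators import (
    CANONICAL_COMPARISONS,
    OUTCOME_SPECS,
    gcomp_ate,
    scale_count,
    tmle_pairwise_ates,
)
from .nuisance import FAST_LIBRARY, estimate_nuisances

logger = logging.getLogger(__name__)

ANALYSIS_COVARIATES = (
    "age",
    "cesd",
    "education",
    "edu_differential",
    "child_age_months",
    "household_members",
    "children_under15",
    "wealth_pc1",
)

ALL_INDICES = ("aggregate", "decision", "movement", "assets", "pca1", "pca2", "pca3")


@dataclass
class AnalysisConfig:
    """Everything a run needs; YAML-serializable."""

    input_csv: str | None = None
    dgp: sd.DGPConfig | None = None
    indices: tuple[str, ...] = ALL_INDICES
    outcome_specs: tuple[str, ...] = ("ge4_vs_1to3", "none_vs_1to3", "ge4_vs_none", "count")
    comparisons: tuple[tuple[str, str], ...] = CANONICAL_COMPARISONS
    outcome_library: tuple[str, ...] = FAST_LIBRARY
    propensity_library: tuple[str, ...] = FAST_LIBRARY
    n_folds: int = 5
    g_bounds: tuple[float, float] = (0.025, 0.975)
    seed: int = 0
    run_subgroups: bool = True
    stratify_indices: tuple[str, ...] = ("aggregate",)
    run_gcomp: bool = True
    gcomp_boot: int = 1000
    min_stratum_size: int = 100
    cesd_cutoff: float = 18.0
    caregiver_column: str | None = None  # restrict to biological mothers if present
    output_dir: str | None = None

    def content_hash(self) -> str:
        content = dataclasses.asdict(self)
        content.pop("output_dir", None)  # where results land is not what they are
        payload = json.dumps(content, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


# --- data preparation ----------------------------------------------------

def impute_median_with_indicators(
    table: pd.DataFrame, covariates
) -> tuple[pd.DataFrame, list[str]]:
    """Median-impute missing covariates, appending 0/1 indicator columns.

    The median is computed on the observed values of each column. An
    indicator column ``<name>_imputed`` is appended for every listed
    covariate (all zeros when nothing was missing); model building should
    include only the indicators that are actually nonzero. Outcomes and
    exposure items are never touched.
    """
    table = table.copy()
    indicator_cols = []
    for name in covariates:
        col = table[name]
        if not pd.api.types.is_numeric_dtype(col):
            raise TypeError(f"covariate {name!r} is not numeric")
        missing = col.isna()
        if missing.all():
            raise ValueError(f"covariate {name!r} is entirely missing")
        ind = f"{name}_imputed"
        table[ind] = missing.astype(int)
        indicator_cols.append(ind)
        if missing.any():
            table[name] = col.fillna(col.median())
    return table, indicator_cols


def categorize_anc(visits) -> np.ndarray:
    """Visit count -> {none, 1-3, >=4} per national guidelines (>= 4
    recommended visits). The three pairwise binary outcomes and their
    subsample masks live in :data:`empoweranc.estimators.OUTCOME_SPECS`."""
    visits = np.asarray(visits)
    if (visits < 0).any():
        raise ValueError("negative visit counts")
    return np.where(visits == 0, "none", np.where(visits <= 3, "1-3", ">=4"))


def derive_analysis_table(
    table: pd.DataFrame, schema: idx.ItemSchema | None = None
) -> pd.DataFrame:
    """Append every derived column the analysis uses.

    Adds the wealth PC, WEAI aggregate + subscale scores and their
    low/medium/high categories (cutpoints computed on this sample and
    reused everywhere downstream, including strata), the three PCA
    indices with the same categorization rule, the WAMI score/tercile,
    and the ANC category.
    """
    schema = schema or idx.default_schema()
    out = table.copy()
    items = out[sd.ITEM_COLS].to_numpy()
    assets = out[sd.ASSET_COLS].to_numpy()

    out["wealth_pc1"] = idx.wealth_pca(assets)

    scores = idx.score_weai(items, schema)
    out["score_aggregate"] = scores.aggregate
    for d in idx.DOMAINS:
        out[f"score_{d}"] = scores.subscale(d)
    pca = idx.score_swper_pca(items, schema)
    for k in range(3):
        out[f"score_pca{k + 1}"] = pca.scores[:, k]

    for name in ALL_INDICES:
        cats, cuts = idx.categorize_quantile(out[f"score_{name}"].to_numpy())
        out[f"cat_{name}"] = cats
        out.attrs[f"cutpoints_{name}"] = cuts
    out.attrs["pca_matched_subscales"] = pca.matched_subscale

    wami = idx.score_wami(
        out["water"].to_numpy(),
        out["sanitation"].to_numpy(),
        assets[:, :8],
        out["education"].to_numpy(),
        out["income_monthly"].to_numpy(),
    )
    out["wami_score"] = wami.score
    out["wami_tercile"] = wami.category
    out["anc_category"] = categorize_anc(out["anc_visits"].to_numpy())
    return out


def subgroup_masks(table: pd.DataFrame, cesd_cutoff: float = 18.0) -> dict[str, np.ndarray]:
    """High-risk subgroup membership.

    adolescent: gave birth before age 20 (current age minus child age);
    multiple_children: more than one child under 15 in the household;
    inlaws: any adult in the household beyond the woman and her husband;
    high_depression: CESD above the cutoff (default 18, the study's
    realized top quartile).
    """
    age_at_birth = table["age"] - table["child_age_months"] / 12.0
    return {
        "adolescent": (age_at_birth < 20).to_numpy(),
        "multiple_children": (table["children_under15"] > 1).to_numpy(),
        "inlaws": (table["n_other_adults"] >= 1).to_numpy(),
        "high_depression": (table["cesd"] > cesd_cutoff).to_numpy(),
    }


def describe_sample(
    table: pd.DataFrame,
    category_col: str = "cat_aggregate",
    numeric_fields: tuple[str, ...] = (
        "age", "cesd", "education", "edu_differential", "wealth_pc1",
        "income_monthly", "wami_score", "household_members", "children_under15",
        "n_other_adults", "child_age_months", "score_aggregate", "anc_visits",
    ),
    binary_fields: tuple[str, ...] = ("water", "sanitation"),
) -> pd.DataFrame:
    """Descriptive table, overall and by exposure category: mean (SD) for
    numeric fields, n (%) for binary fields, plus ANC category counts."""
    cats = table[category_col]
    groups = {"full_sample": table}
    groups.update({f"{c}": table[cats == c] for c in ("low", "medium", "high")})

    rows: dict[str, dict[str, str]] = {}
    for gname, g in groups.items():
        col: dict[str, str] = {"n": str(len(g))}
        for f in numeric_fields:
            if f in g:
                col[f] = f"{g[f].mean():.1f} ({g[f].std(ddof=1):.1f})"
        for f in binary_fields:
            if f in g:
                n1 = int(g[f].sum())
                pct = 100.0 * n1 / len(g) if len(g) else 0.0
                col[f] = f"{n1} ({pct:.0f}%)"
        for anc in ("none", "1-3", ">=4"):
            n1 = int((g["anc_category"] == anc).sum())
            pct = 100.0 * n1 / len(g) if len(g) else 0.0
            col[f"anc_{anc}"] = f"{n1} ({pct:.0f}%)"
        rows[gname] = col
    return pd.DataFrame(rows)


# --- the analysis driver -------------------------------------------------

def _one_tmle(
    table: pd.DataFrame,
    feature_cols: list[str],
    index_name: str,
    spec_name: str,
    config: AnalysisConfig,
    seed: int,
) -> dict[tuple[str, str], object] | None:
    spec = OUTCOME_SPECS[spec_name]
    visits = table["anc_visits"].to_numpy()
    mask = spec.subsample_mask(visits)
    sub = table.loc[mask]
    exposure = sub[f"cat_{index_name}"].to_numpy()
    if min((exposure == lvl).sum() for lvl in ("low", "medium", "high")) < 10:
        logger.warning(
            "skipping %s/%s: an exposure level has <10 observations",
            index_name, spec_name,
        )
        return None

    y_raw = spec.outcome(sub["anc_visits"].to_numpy())
    y_fit = y_raw
    loss = "nll"
    if spec.kind == "count":
        # nuisances are fit on the min-max scaled outcome; the targeting
        # step rescales identically and back-transforms the estimate
        y_fit, _ = scale_count(y_raw)
        loss = "mse"
    nuis = estimate_nuisances(
        sub[feature_cols].to_numpy(),
        exposure,
        y_fit,
        outcome_library=config.outcome_library,
        propensity_library=config.propensity_library,
        n_folds=config.n_folds,
        outcome_loss=loss,
        g_bounds=config.g_bounds,
        seed=seed,
    )
    ates = tmle_pairwise_ates(
        exposure, y_raw, nuis, sub["village_id"].to_numpy(),
        outcome_kind=spec.kind, comparisons=config.comparisons,
    )
    for est in ates.values():
        est.diagnostics["g_truncated_fraction"] = nuis.g_truncated_fraction
    return ates


def run_analysis(config: AnalysisConfig) -> dict:
    """Run the full study analysis; returns the result bundle.

    The bundle is a plain dict: ``meta`` (provenance), ``descriptives``,
    ``estimates`` (list of tidy rows), and the generator ``truth`` when
    the input is synthetic. If ``config.output_dir`` is set the bundle is
    also written to disk (JSON + CSV).
    """
    rng_seed = int(config.seed)
    truth = {}
    if config.input_csv is not None:
        table = pd.read_csv(config.input_csv)
    elif config.dgp is not None:
        cohort = sd.generate_cohort(config.dgp)
        cohort = sd.inject_missingness(cohort, config.dgp)
        table = cohort.records
        truth = cohort.truth
    else:
        raise ValueError("config needs either input_csv or a DGPConfig")

    if config.caregiver_column and config.caregiver_column in table:
        n0 = len(table)
        table = table[table[config.caregiver_column] == "biological_mother"]
        logger.info("restricted to biological mothers: %d -> %d", n0, len(table))

    table = derive_analysis_table(table)
    table, indicator_cols = impute_median_with_indicators(
        table, list(ANALYSIS_COVARIATES)
    )
    active_indicators = [c for c in indicator_cols if table[c].sum() > 0]
    feature_cols = list(ANALYSIS_COVARIATES) + active_indicators

    rows: list[dict] = []

    def collect(index_name, spec_name, stratum, ates, estimator="tmle"):
        if ates is None:
            return
        items = ates.items() if isinstance(ates, dict) else ates
        for cmp, est in items:
            rows.append(
                {
                    "estimator": estimator,
                    "index": index_name,
                    "outcome": spec_name,
                    "comparison": f"{cmp[0]}_vs_{cmp[1]}",
                    "stratum": stratum,
                    **{
                        k: v
                        for k, v in est.to_dict().items()
                        if k != "diagnostics"
                    },
                    "diagnostics": est.diagnostics,
                }
            )

    # full-sample TMLE per index x outcome
    for index_name in config.indices:
        for spec_name in config.outcome_specs:
            ates = _one_tmle(
                table, feature_cols, index_name, spec_name, config, rng_seed
            )
            collect(index_name, spec_name, "full_sample", ates)

    # stratified analyses (exposure cutpoints stay those of the full sample)
    if config.run_subgroups:
        strata: dict[str, np.ndarray] = {
            f"wami_{t}": (table["wami_tercile"] == t).to_numpy()
            for t in ("low", "medium", "high")
        }
        strata.update(subgroup_masks(table, config.cesd_cutoff))
        for index_name in config.stratify_indices:
            for sname, smask in strata.items():
                if smask.sum() < config.min_stratum_size:
                    logger.warning(
                        "skipping stratum %s (n=%d < %d)",
                        sname, int(smask.sum()), config.min_stratum_size,
                    )
                    continue
                for spec_name in config.outcome_specs:
                    ates = _one_tmle(
                        table.loc[smask], feature_cols, index_name, spec_name,
                        config, rng_seed,
                    )
                    collect(index_name, spec_name, sname, ates)

    # G-computation robustness for the aggregate index
    if config.run_gcomp and "aggregate" in config.indices:
        for spec_name in config.outcome_specs:
            spec = OUTCOME_SPECS[spec_name]
            mask = spec.subsample_mask(table["anc_visits"].to_numpy())
            sub = table.loc[mask]
            gc = {}
            for cmp in config.comparisons:
                gc[cmp] = gcomp_ate(
                    sub[feature_cols].to_numpy(),
                    sub["cat_aggregate"].to_numpy(),
                    spec.outcome(sub["anc_visits"].to_numpy()),
                    cmp,
                    sub["village_id"].to_numpy(),
                    outcome_kind=spec.kind,
                    n_boot=config.gcomp_boot,
                    seed=rng_seed,
                )
            collect("aggregate", spec_name, "full_sample", gc, estimator="gcomp")

    import sklearn
    import statsmodels

    bundle = {
        "meta": {
            "config_hash": config.content_hash(),
            "seed": rng_seed,
            "n_analysis": int(len(table)),
            "cutpoints": {
                name: table.attrs.get(f"cutpoints_{name}") for name in config.indices
            },
            "imputed_covariates": active_indicators,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "sklearn": sklearn.__version__,
                "statsmodels": statsmodels.__version__,
            },
        },
        "descriptives": describe_sample(table).to_dict(),
        "estimates": rows,
        "truth": truth,
    }
    if config.output_dir:
        save_bundle(bundle, config.output_dir)
    return bundle


def results_frame(bundle: dict) -> pd.DataFrame:
    """Tidy one-row-per-estimate view of a result bundle."""
    rows = []
    for r in bundle["estimates"]:
        r = dict(r)
        r.pop("diagnostics", None)
        rows.append(r)
    return pd.DataFrame(rows)


def save_bundle(bundle: dict, output_dir) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "results.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=_json_default)
    results_frame(bundle).to_csv(out / "results.csv", index=False)


def load_bundle(output_dir) -> dict:
    with open(Path(output_dir) / "results.json") as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    return str(obj)
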