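"""Exposure and stratification indices.

Constructs the variables the analysis conditions on or contrasts:

* a WEAI-style aggregate empowerment score (three equally weighted domains
  -- household decision making, freedom of movement, control over assets --
  rescaled to 0-100) with its three domain subscales,
* low / medium / high categorization by sample quantiles (bottom 25%,
  middle 50%, top 25%),
* SWPER-style principal-component empowerment indices from the same items,
* the WAMI household socioeconomic index (water/sanitation, assets,
  maternal education, monthly income; 0-32 points) with its published
  fixed tercile cut-offs, and
* an asset-wealth first principal component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DOMAINS = ("decision", "movement", "assets")

CATEGORY_LEVELS = ("low", "medium", "high")


@dataclass(frozen=True)
class Item:
    """One survey item: its empowerment domain and ordered response codes."""

    domain: str
    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if len(self.levels) < 2:
            raise ValueError("an item needs at least 2 response levels")
        if list(self.levels) != sorted(set(self.levels)):
            raise ValueError("levels must be strictly increasing")


@dataclass(frozen=True)
class ItemSchema:
    """The 15-item empowerment questionnaire: 7 decision-making items,
    3 freedom-of-movement items, 5 control-over-assets items.

    Higher response codes always indicate greater empowerment. The exact
    per-item response scales are configurable (the field instruments vary);
    the default gives decision and asset items three levels (0-2) and
    movement items four (0-3).
    """

    items: tuple[Item, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 15:
            raise ValueError("schema must contain exactly 15 items")
        counts = {d: sum(1 for it in self.items if it.domain == d) for d in DOMAINS}
        if counts != {"decision": 7, "movement": 3, "assets": 5}:
            raise ValueError(
                f"expected 7 decision / 3 movement / 5 assets items, got {counts}"
            )

    def domain_indices(self, domain: str) -> np.ndarray:
        return np.array([i for i, it in enumerate(self.items) if it.domain == domain])

    def domain_max(self, domain: str) -> int:
        return int(sum(it.levels[-1] for it in self.items if it.domain == domain))

    def domain_min(self, domain: str) -> int:
        return int(sum(it.levels[0] for it in self.items if it.domain == domain))

    @property
    def n_levels(self) -> np.ndarray:
        return np.array([len(it.levels) for it in self.items])


def default_schema() -> ItemSchema:
    items = (
        tuple(Item("decision", (0, 1, 2)) for _ in range(7))
        + tuple(Item("movement", (0, 1, 2, 3)) for _ in range(3))
        + tuple(Item("assets", (0, 1, 2)) for _ in range(5))
    )
    return ItemSchema(items)


@dataclass
class EmpowermentScores:
    """WEAI-style scores: 0-100 aggregate plus raw per-domain sums.

    Categories and cutpoints are attached by :func:`categorize_quantile`;
    they are ``None`` until then.
    """

    aggregate: np.ndarray
    decision: np.ndarray
    movement: np.ndarray
    assets: np.ndarray
    categories: np.ndarray | None = None
    cutpoints: tuple[float, float] | None = None

    def subscale(self, domain: str) -> np.ndarray:
        return getattr(self, domain)


def _validate_responses(responses: np.ndarray, schema: ItemSchema) -> np.ndarray:
    responses = np.atleast_2d(np.asarray(responses))
    if responses.shape[1] != 15:
        raise ValueError(f"expected 15 item columns, got {responses.shape[1]}")
    for j, item in enumerate(schema.items):
        col = responses[:, j]
        bad = ~np.isin(col, item.levels)
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"invalid response {col[i]!r} for item {j} "
                f"(allowed levels {item.levels})"
            )
    return responses


def score_weai(responses, schema: ItemSchema | None = None) -> EmpowermentScores:
    """Score the 15 items into the aggregate empowerment index.

    Each domain score is the domain's summed response codes divided by its
    maximum attainable sum; the aggregate is 100 times the equally weighted
    mean of the three domain scores, so it spans exactly 0 to 100. The raw
    per-domain sums are returned as the three subscales.
    """
    schema = schema or default_schema()
    responses = _validate_responses(responses, schema)

    sums = {}
    fracs = []
    for d in DOMAINS:
        idx = schema.domain_indices(d)
        s = responses[:, idx].sum(axis=1).astype(float)
        sums[d] = s
        lo, hi = schema.domain_min(d), schema.domain_max(d)
        fracs.append((s - lo) / (hi - lo))
    aggregate = 100.0 * np.mean(fracs, axis=0)
    return EmpowermentScores(
        aggregate=aggregate,
        decision=sums["decision"],
        movement=sums["movement"],
        assets=sums["assets"],
    )


def categorize_quantile(
    scores, lower: float = 0.25, upper: float = 0.75
) -> tuple[np.ndarray, tuple[float, float]]:
    """Split scores into low / medium / high at sample quantiles.

    ``low`` is score < lower cutpoint, ``high`` is score >= upper cutpoint,
    ``medium`` otherwise; ties at a cutpoint therefore go to the higher
    category. Cutpoints are linear-interpolation sample quantiles. With
    heavy ties the realized shares deviate from 25/50/25 -- that is a
    property of the data, not an error.

    Returns ``(categories, (q_lower, q_upper))``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1:
        raise ValueError("scores must be one-dimensional")
    if np.unique(scores).size < 2:
        raise ValueError("scores are constant; nothing to categorize")
    if np.unique(scores).size < 4:
        raise ValueError("need at least 4 distinct score values")
    q_lo, q_hi = np.quantile(scores, [lower, upper])
    categories = np.where(
        scores < q_lo, "low", np.where(scores >= q_hi, "high", "medium")
    )
    return categories, (float(q_lo), float(q_hi))


@dataclass
class PcaIndices:
    """SWPER-style principal-component indices.

    ``scores`` holds the first three component scores per respondent,
    ordered by variance explained and sign-aligned so each correlates
    positively with the WEAI subscale it best matches.
    """

    scores: np.ndarray                      # (n, 3)
    loadings: np.ndarray                    # (n_items_kept, 3)
    variance_explained: np.ndarray          # (3,)
    sign_flipped: np.ndarray                # (3,) bool
    matched_subscale: tuple[str, str, str]
    dropped_items: tuple[int, ...] = ()


def score_swper_pca(
    item_matrix, schema: ItemSchema | None = None
) -> PcaIndices:
    """PCA-based empowerment indices from the same 15 items.

    Items are standardized (zero mean, unit variance) and the correlation
    matrix eigendecomposed; the first three components are retained. Zero
    variance items are dropped with a warning recorded in ``dropped_items``.
    Each component is matched to the WEAI subscale with which it is most
    strongly correlated and its sign flipped if that correlation is
    negative, fixing the orientation ambiguity of PCA.
    """
    schema = schema or default_schema()
    X = _validate_responses(item_matrix, schema).astype(float)
    if X.shape[0] < 15:
        raise ValueError("need at least 15 complete rows for the PCA indices")

    sd = X.std(axis=0, ddof=0)
    dropped = tuple(int(j) for j in np.nonzero(sd == 0)[0])
    if dropped:
        import warnings

        warnings.warn(f"dropping zero-variance items {dropped} from PCA")
    keep = np.nonzero(sd > 0)[0]
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    corr = (Z.T @ Z) / Z.shape[0]
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1][:3]
    loadings = eigvec[:, order]
    var_explained = eigval[order] / eigval.sum()
    comp = Z @ loadings

    weai = score_weai(item_matrix, schema)
    subs = np.column_stack([weai.subscale(d) for d in DOMAINS])
    flipped = np.zeros(3, dtype=bool)
    matched = []
    for k in range(3):
        with np.errstate(invalid="ignore"):
            r = np.array(
                [np.corrcoef(comp[:, k], subs[:, j])[0, 1] for j in range(3)]
            )
        r = np.nan_to_num(r)
        j = int(np.argmax(np.abs(r)))
        matched.append(DOMAINS[j])
        if r[j] < 0:
            comp[:, k] = -comp[:, k]
            loadings[:, k] = -loadings[:, k]
            flipped[k] = True

    return PcaIndices(
        scores=comp,
        loadings=loadings,
        variance_explained=var_explained,
        sign_flipped=flipped,
        matched_subscale=tuple(matched),
        dropped_items=dropped,
    )


# --- WAMI socioeconomic index -------------------------------------------

@dataclass(frozen=True)
class WamiWeights:
    """Point allocation mapping the four WAMI components onto 0-32.

    Each component contributes up to 8 points: improved water and improved
    sanitation 4 points each, the eight asset indicators one point each,
    and education / income banded by ordered cutpoints (the subscore is
    the number of cutpoints at or below the value, so 8 bands each).
    """

    water_points: float = 4.0
    sanitation_points: float = 4.0
    asset_points: float = 1.0
    education_cutpoints: tuple[float, ...] = (1, 3, 5, 7, 9, 11, 13, 15)
    income_cutpoints: tuple[float, ...] = (30, 60, 90, 120, 160, 200, 250, 300)

    @property
    def max_score(self) -> float:
        return (
            self.water_points
            + self.sanitation_points
            + 8 * self.asset_points
            + len(self.education_cutpoints)
            + len(self.income_cutpoints)
        )


WAMI_HIGH_CUTOFF = 21.0
WAMI_MEDIUM_CUTOFF = 17.0


@dataclass
class WamiScore:
    score: np.ndarray
    category: np.ndarray


def categorize_wami(score) -> np.ndarray:
    """Fixed published tercile cut-offs: >=21 high, >=17 & <21 medium, <17 low."""
    score = np.asarray(score, dtype=float)
    return np.where(
        score >= WAMI_HIGH_CUTOFF,
        "high",
        np.where(score >= WAMI_MEDIUM_CUTOFF, "medium", "low"),
    )


def score_wami(
    water,
    sanitation,
    assets,
    education_years,
    income,
    weights: WamiWeights | None = None,
) -> WamiScore:
    """WAMI household socioeconomic index on the published 0-32 scale.

    Parameters are vectors (or scalars): binary improved water and
    sanitation, an (n, 8) matrix of binary asset indicators, maternal
    education in years and monthly household income. Components are
    equally weighted (8 points each).
    """
    w = weights or WamiWeights()
    water = np.atleast_1d(np.asarray(water, dtype=float))
    sanitation = np.atleast_1d(np.asarray(sanitation, dtype=float))
    assets = np.atleast_2d(np.asarray(assets, dtype=float))
    education_years = np.atleast_1d(np.asarray(education_years, dtype=float))
    income = np.atleast_1d(np.asarray(income, dtype=float))

    for name, arr in (("water", water), ("sanitation", sanitation)):
        if not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError(f"{name} must be binary 0/1")
    if assets.shape[1] != 8 or not np.isin(assets, (0.0, 1.0)).all():
        raise ValueError("assets must be an (n, 8) binary matrix")
    if (education_years < 0).any() or (income < 0).any():
        raise ValueError("education and income must be nonnegative")

    edu_cut = np.asarray(w.education_cutpoints)
    inc_cut = np.asarray(w.income_cutpoints)
    score = (
        w.water_points * water
        + w.sanitation_points * sanitation
        + w.asset_points * assets.sum(axis=1)
        + (education_years[:, None] >= edu_cut[None, :]).sum(axis=1)
        + (income[:, None] >= inc_cut[None, :]).sum(axis=1)
    ).astype(float)
    return WamiScore(score=score, category=categorize_wami(score))


def wealth_pca(asset_indicators) -> np.ndarray:
    """First principal component of household asset ownership.

    The standard DHS-style wealth proxy: leading eigenvector of the asset
    covariance structure (computed on standardized indicators), scores
    zero-centered and oriented so that owning more assets raises the score.
    """
    X = np.atleast_2d(np.asarray(asset_indicators, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("need at least 2 asset columns")
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all asset columns are constant")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    corr = (Z.T @ Z) / Z.shape[0]
    eigval, eigvec = np.linalg.eigh(corr)
    v = eigvec[:, -1]
    scores = Z @ v
    total = X.sum(axis=1)
    if total.std() > 0 and np.corrcoef(scores, total)[0, 1] < 0:
        scores = -scores
    return scores


def append_index_columns(
    table: pd.DataFrame,
    item_cols: list[str],
    schema: ItemSchema | None = None,
    prefix: str = "emp",
) -> pd.DataFrame:
    """Convenience: score items in ``table`` and append index columns."""
    schema = schema or default_schema()
    scores = score_weai(table[item_cols].to_numpy(), schema)
    out = table.copy()
    out[f"{prefix}_aggregate"] = scores.aggregate
    for d in DOMAINS:
        out[f"{prefix}_{d}"] = scores.subscale(d)
    return out
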