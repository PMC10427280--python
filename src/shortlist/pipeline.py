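"""Empirical analysis chain for ratings-derived collections.

The chain mirrors how sets of movie collections are analysed: filter the
ratings dump, build the presence matrix, test for content-biased selection
(frequency-rating correlation), test for the shortlist effect (a logistic
regression where the advantage of appeal shrinks with collection size),
compute drift scores (how far an item's rating sits from the one its
frequency predicts), and regress nestedness contributions on frequency,
release year and drift.  Model comparisons use AIC with the conventional
"more informative" threshold of Delta AIC > 2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .matrix import PresenceMatrix, from_ratings

logger = logging.getLogger(__name__)

__all__ = [
    "ShortlistFit",
    "ContributionRegression",
    "filter_dataset",
    "content_bias_correlation",
    "minmax_normalize",
    "shortlist_test",
    "reported_interaction",
    "drift_scores",
    "contribution_regression",
    "run_pipeline",
]

AIC_THRESHOLD = 2.0


@dataclass(frozen=True)
class ShortlistFit:
    """Baseline-vs-test logistic comparison for the shortlist effect.

    The *baseline* model predicts presence from item frequency, item appeal
    and collection size; the *test* model adds the size x appeal
    interaction.  The effect is a ``hit`` when the test model is more
    informative (Delta AIC > 2) and the interaction runs opposite in sign
    to the appeal main effect (appeal matters less in big collections).
    """

    baseline_aic: float
    test_aic: float
    delta_aic: float
    coefficients: dict
    hit: bool
    converged: bool = True
    flags: tuple = ()


@dataclass(frozen=True)
class ContributionRegression:
    """Nested linear models for per-item nestedness contributions.

    Frequency first; release year retained only if it is more informative
    (Delta AIC > 2); drift score added last.  ``hit`` when adding drift is
    more informative and its coefficient is negative — items whose rating
    departs from what their frequency predicts contribute less to
    nestedness.  VIFs of the final design are reported as a collinearity
    diagnostic, not used as a gate.
    """

    aic_frequency: float
    aic_year: float | None
    aic_drift: float
    year_retained: bool
    delta_aic_drift: float
    drift_coefficient: float
    drift_ci: tuple[float, float]
    hit: bool
    vif: dict = field(default_factory=dict)
    flags: tuple = ()


def filter_dataset(
    ratings: pd.DataFrame,
    top_collection_frac: float = 1.0,
    top_item_frac: float = 1.0,
    min_item_count: int = 0,
    n_sample_collections: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Apply the standard inclusion filters to a long ratings table.

    In order: items rated by at most ``min_item_count`` users are dropped
    (inclusive threshold); the top ``top_collection_frac`` of users by
    collection size is kept; the top ``top_item_frac`` of items by
    frequency is kept; finally ``n_sample_collections`` users are sampled
    at random.  Counts removed at each stage are logged.
    """
    if not (0 < top_collection_frac <= 1 and 0 < top_item_frac <= 1):
        raise ValueError("fractions must be in (0, 1]")
    if min_item_count < 0:
        raise ValueError("min_item_count must be >= 0")
    out = ratings.drop_duplicates(subset=["user_id", "item_id"])
    if min_item_count > 0:
        freq = out.groupby("item_id", sort=False)["user_id"].nunique()
        keep = freq[freq > min_item_count].index
        before = out["item_id"].nunique()
        out = out[out["item_id"].isin(keep)]
        logger.info("min-count filter removed %d items", before - len(keep))
    if top_collection_frac < 1 and not out.empty:
        sizes = out.groupby("user_id", sort=False)["item_id"].nunique()
        n_keep = max(1, int(np.ceil(top_collection_frac * len(sizes))))
        keep = sizes.sort_values(ascending=False, kind="stable").index[:n_keep]
        logger.info("collection-size filter kept %d of %d users", n_keep, len(sizes))
        out = out[out["user_id"].isin(keep)]
    if top_item_frac < 1 and not out.empty:
        freq = out.groupby("item_id", sort=False)["user_id"].nunique()
        n_keep = max(1, int(np.ceil(top_item_frac * len(freq))))
        keep = freq.sort_values(ascending=False, kind="stable").index[:n_keep]
        logger.info("item-frequency filter kept %d of %d items", n_keep, len(freq))
        out = out[out["item_id"].isin(keep)]
    if n_sample_collections is not None and not out.empty:
        users = out["user_id"].drop_duplicates().to_numpy()
        if len(users) > n_sample_collections:
            if rng is None:
                rng = np.random.default_rng()
            chosen = rng.choice(users, size=n_sample_collections, replace=False)
            out = out[out["user_id"].isin(chosen)]
            logger.info("sampled %d of %d users", n_sample_collections, len(users))
    if out.empty:
        raise ValueError("no records survive filters")
    return out.reset_index(drop=True)


def content_bias_correlation(frequencies, ratings) -> float:
    """Spearman rank correlation between item frequency and item rating.

    Positive values indicate content-biased selection (popular items are
    also highly rated).  NaN (with a warning) when either series has zero
    variance.
    """
    frequencies = np.asarray(frequencies, dtype=float)
    ratings = np.asarray(ratings, dtype=float)
    if len(frequencies) < 3:
        raise ValueError("need at least 3 items")
    if np.ptp(frequencies) == 0 or np.ptp(ratings) == 0:
        warnings.warn("zero variance: Spearman correlation undefined")
        return float("nan")
    return float(stats.spearmanr(frequencies, ratings).statistic)


def minmax_normalize(values) -> np.ndarray:
    """Min-max normalization onto [0, 1]; constant series map to zeros."""
    values = np.asarray(values, dtype=float)
    if values.size == 0 or not np.isfinite(values).all():
        raise ValueError("need at least one finite value, no NaN/inf")
    lo, hi = values.min(), values.max()
    if hi == lo:
        warnings.warn("constant series: min-max normalization returns zeros")
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def shortlist_test(
    m: PresenceMatrix,
    item_ratings,
    normalize_ratings: bool = True,
) -> ShortlistFit:
    """Test whether small collections are more selective for appeal.

    Expands the presence matrix to one record per (collection, item) with
    presence as outcome and min-max normalized item frequency, item appeal
    (rating; normalization optional as a robustness toggle) and collection
    size as predictors.  Fits the baseline logistic model and the test
    model with the size x appeal interaction by maximum likelihood and
    applies the Delta AIC > 2 opposite-sign hit rule.

    ``item_ratings`` maps item id -> rating (mapping or pandas Series);
    every item in the matrix must be covered.
    """
    ratings = pd.Series(item_ratings)
    missing = [i for i in m.item_ids if i not in ratings.index]
    if missing:
        raise ValueError(f"items without ratings: {missing[:5]}")
    n_coll, n_items = m.shape
    freq = minmax_normalize(m.cells.sum(axis=0))
    size = minmax_normalize(m.cells.sum(axis=1))
    appeal_raw = ratings.loc[list(m.item_ids)].to_numpy(dtype=float)
    flags = []
    if np.ptp(appeal_raw) == 0:
        return ShortlistFit(
            baseline_aic=float("nan"), test_aic=float("nan"), delta_aic=float("nan"),
            coefficients={}, hit=False, converged=False,
            flags=("constant_appeal: interaction inestimable",),
        )
    appeal = minmax_normalize(appeal_raw) if normalize_ratings else appeal_raw
    y = m.cells.ravel().astype(float)
    X_base = np.column_stack([
        np.ones(n_coll * n_items),
        np.tile(freq, n_coll),
        np.tile(appeal, n_coll),
        np.repeat(size, n_items),
    ])
    X_test = np.column_stack([X_base, X_base[:, 3] * X_base[:, 2]])
    names = ["intercept", "frequency", "appeal", "size", "size_x_appeal"]

    def _fit(X):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        return res

    try:
        base = _fit(X_base)
        test = _fit(X_test)
    except (np.linalg.LinAlgError, ValueError) as exc:
        return ShortlistFit(
            baseline_aic=float("nan"), test_aic=float("nan"), delta_aic=float("nan"),
            coefficients={}, hit=False, converged=False, flags=(f"fit failed: {exc}",),
        )
    converged = bool(base.mle_retvals["converged"] and test.mle_retvals["converged"])
    if not converged:
        flags.append("non-convergence")
    coefs = dict(zip(names, test.params))
    delta = base.aic - test.aic
    appeal_main = coefs["appeal"]
    interaction = coefs["size_x_appeal"]
    hit = (
        converged
        and delta > AIC_THRESHOLD
        and np.sign(interaction) != np.sign(appeal_main)
        and interaction != 0
    )
    return ShortlistFit(
        baseline_aic=float(base.aic), test_aic=float(test.aic), delta_aic=float(delta),
        coefficients=coefs, hit=bool(hit), converged=converged, flags=tuple(flags),
    )


def reported_interaction(fit: ShortlistFit) -> float:
    """Presentation transform for the interaction estimate.

    When the appeal main effect is negative the interaction is negated, so
    a shortlist-consistent estimate always plots negative.
    """
    c = fit.coefficients
    return -c["size_x_appeal"] if c["appeal"] < 0 else c["size_x_appeal"]


def drift_scores(
    frequencies, ratings, normalize_frequency: bool = False
) -> np.ndarray:
    """Absolute residuals of rating regressed (OLS) on frequency.

    A large drift score marks an item whose rating is far from the one its
    frequency predicts — under-rated hits or over-rated rarities; success
    and appeal are misaligned.  ``normalize_frequency`` min-max normalizes
    frequency first (the residuals, hence the scores, are identical up to
    the fit's numerical tolerance).
    """
    frequencies = np.asarray(frequencies, dtype=float)
    ratings = np.asarray(ratings, dtype=float)
    if len(frequencies) < 3:
        raise ValueError("need at least 3 items")
    if np.ptp(frequencies) == 0:
        raise ValueError("zero variance in frequencies: drift undefined")
    x = minmax_normalize(frequencies) if normalize_frequency else frequencies
    X = sm.add_constant(x)
    res = sm.OLS(ratings, X).fit()
    return np.abs(res.resid)


def contribution_regression(
    contributions, frequencies, drift, years=None
) -> ContributionRegression:
    """Nested regressions of nestedness contributions on item covariates.

    Fits contribution ~ frequency, optionally + year (kept only when Delta
    AIC > 2), then + drift score; reports whether drift is informative with
    a negative weight, its 95% CI, and the VIFs of the final design.
    """
    c = np.asarray(contributions, dtype=float)
    f = np.asarray(frequencies, dtype=float)
    d = np.asarray(drift, dtype=float)
    if not (len(c) == len(f) == len(d)):
        raise ValueError("series must be aligned")
    X1 = sm.add_constant(f)
    m1 = sm.OLS(c, X1).fit()
    aic_year = None
    year_retained = False
    X_pre = X1
    aic_pre = m1.aic
    if years is not None:
        yr = np.asarray(years, dtype=float)
        X2 = np.column_stack([X1, yr])
        m2 = sm.OLS(c, X2).fit()
        aic_year = float(m2.aic)
        if m1.aic - m2.aic > AIC_THRESHOLD:
            year_retained = True
            X_pre = X2
            aic_pre = m2.aic
    X3 = np.column_stack([X_pre, d])
    m3 = sm.OLS(c, X3).fit()
    drift_idx = X3.shape[1] - 1
    drift_coef = float(m3.params[drift_idx])
    ci = m3.conf_int()[drift_idx]
    delta = float(aic_pre - m3.aic)
    flags = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vif_names = (["frequency"] + (["year"] if year_retained else []) + ["drift"])
        vifs = {}
        for pos, name in enumerate(vif_names, start=1):
            v = variance_inflation_factor(X3, pos)
            vifs[name] = float(v)
            if not np.isfinite(v):
                flags.append(f"infinite VIF: {name}")
    hit = delta > AIC_THRESHOLD and drift_coef < 0
    return ContributionRegression(
        aic_frequency=float(m1.aic),
        aic_year=aic_year,
        aic_drift=float(m3.aic),
        year_retained=year_retained,
        delta_aic_drift=delta,
        drift_coefficient=drift_coef,
        drift_ci=(float(ci[0]), float(ci[1])),
        hit=bool(hit),
        vif=vifs,
        flags=tuple(flags),
    )


def run_pipeline(
    ratings: pd.DataFrame,
    seed: int | None = None,
    min_items_per_collection: int = 2,
    top_collection_frac: float = 1.0,
    top_item_frac: float = 1.0,
    min_item_count: int = 0,
    n_sample_collections: int | None = None,
    n_sims: int = 200,
    n_rand: int = 100,
    normalize_ratings: bool = True,
) -> dict:
    """End-to-end analysis of one ratings table.

    Filters the table, builds the presence matrix, measures NODF with its
    R1 significance, per-item contributions, the content-bias correlation,
    the shortlist interaction test, drift scores, and the contribution
    regression.  Returns a JSON-serializable dict of all results keyed by
    stage; per-item tables are pandas DataFrames.
    """
    from .contributions import all_contributions
    from .nodf import nodf as _nodf
    from .nulls import nodf_significance

    rng = np.random.default_rng(seed)
    filtered = filter_dataset(
        ratings,
        top_collection_frac=top_collection_frac,
        top_item_frac=top_item_frac,
        min_item_count=min_item_count,
        n_sample_collections=n_sample_collections,
        rng=rng,
    )
    m = from_ratings(filtered, min_items_per_collection=min_items_per_collection)
    nodf_res = _nodf(m)
    signif = nodf_significance(m, n_sims=n_sims, seed=seed)
    contribs = all_contributions(m, n_rand=n_rand, seed=seed)
    c_map = {r.item_id: r.c_i for r in contribs}

    freq = pd.Series(m.cells.sum(axis=0), index=list(m.item_ids))
    mean_rating = filtered.groupby("item_id", sort=False)["rating"].mean()
    mean_rating = mean_rating.loc[list(m.item_ids)]
    rho_bias = content_bias_correlation(freq.to_numpy(), mean_rating.to_numpy())
    fit = shortlist_test(m, mean_rating, normalize_ratings=normalize_ratings)
    drift = drift_scores(freq.to_numpy(), mean_rating.to_numpy())
    years = None
    if "year" in filtered.columns:
        years = (
            filtered.groupby("item_id", sort=False)["year"].first()
            .loc[list(m.item_ids)]
            .to_numpy(dtype=float)
        )
    reg = contribution_regression(
        np.array([c_map[i] for i in m.item_ids]), freq.to_numpy(), drift, years=years
    )
    items_table = pd.DataFrame(
        {
            "item_id": list(m.item_ids),
            "frequency": freq.to_numpy(),
            "mean_rating": mean_rating.to_numpy(),
            "contribution": [c_map[i] for i in m.item_ids],
            "drift": drift,
        }
    )
    return {
        "seed": seed,
        "n_collections": m.shape[0],
        "n_items": m.shape[1],
        "nodf": nodf_res,
        "significance": signif,
        "content_bias_spearman": rho_bias,
        "shortlist": fit,
        "contribution_regression": reg,
        "items": items_table,
    }
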