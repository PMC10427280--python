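"""Synthetic ratings datasets with known ground truth.

Emulates a MovieLens/Netflix-style ratings dump whose statistical structure
matches the adoption model: items carry a latent appeal correlated with
their latent prevalence at a chosen level, users have exogenous capacities,
presence follows the adoption probability, and observed star ratings are
noisy readings of appeal.  A controlled number of *hidden gems* (high
appeal forced to low prevalence) and *accidental hits* (low appeal forced
to high prevalence) is planted, so detection pipelines can be evaluated
against truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import AdoptionParams, adoption_probability, draw_pools

__all__ = ["SyntheticSpec", "DetectionReport", "generate_ratings", "evaluate_detection"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic ratings dataset.

    Defaults mirror the simulation study's conditions: 200 items, 500
    users (the collection-sample size used for contribution analyses),
    e = s = 1 (shortlist effect active at full strength), a mid-level
    selection rho = 0.5, a 1-5 star scale, and rater noise of half a star.
    """

    n_users: int = 500
    n_items: int = 200
    e: float = 1.0
    s: float = 1.0
    rho: float = 0.5
    rating_scale: tuple[float, float] = (1.0, 5.0)
    rating_noise_sd: float = 0.5
    n_gems: int = 5
    n_hits: int = 5
    year_range: tuple[int, int] | None = (1950, 2020)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_users < 2 or self.n_items < 2:
            raise ValueError("need at least 2 users and 2 items")
        if self.rating_noise_sd < 0:
            raise ValueError("rating_noise_sd must be >= 0")
        if self.rating_scale[0] >= self.rating_scale[1]:
            raise ValueError("rating scale min must be below max")
        if self.n_gems < 0 or self.n_hits < 0:
            raise ValueError("planted counts must be >= 0")
        if self.n_gems + self.n_hits > self.n_items:
            raise ValueError("cannot plant more outliers than items")


@dataclass(frozen=True)
class DetectionReport:
    """How well planted outliers separate from ordinary items.

    ``separation_*`` are AUC - 0.5 statistics (rank-based): the probability
    that a random planted outlier out-drifts (or under-contributes
    relative to) a random frequency-matched control, minus chance.
    """

    mean_contribution: dict
    mean_drift: dict
    separation_drift: float
    separation_contribution: float
    n_outliers: int


def generate_ratings(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a long-format ratings table plus its ground truth.

    Returns ``(ratings, truth)``: ratings with columns user_id, item_id,
    rating (and year if requested); truth with one row per item carrying
    the latent appeal, prevalence, and outlier label.  Gems are drawn from
    the top appeal quartile and forced into the bottom prevalence quartile
    (quartiles over the unplanted pool); hits are the converse.  Each
    present (user, item) pair gets an independent noisy rating, clipped to
    the scale.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    params = AdoptionParams(
        e=spec.e, s=spec.s, rho=spec.rho,
        n_items=spec.n_items, n_collections=spec.n_users,
    )
    items, cols = draw_pools(params, rng)
    prevalence = items.prevalence.copy()
    appeal = items.appeal.copy()
    labels = np.array(["none"] * spec.n_items, dtype=object)

    q_lo, q_hi = np.quantile(prevalence, [0.25, 0.75])
    a_lo, a_hi = np.quantile(appeal, [0.25, 0.75])
    order = rng.permutation(spec.n_items)
    gem_pool = [i for i in order if appeal[i] >= a_hi][: spec.n_gems]
    hit_pool = [i for i in order if appeal[i] <= a_lo and i not in gem_pool][: spec.n_hits]
    if len(gem_pool) < spec.n_gems or len(hit_pool) < spec.n_hits:
        raise ValueError("not enough quartile candidates to plant outliers")
    for i in gem_pool:
        prevalence[i] = rng.uniform(0.0, q_lo)
        labels[i] = "hidden_gem"
    for i in hit_pool:
        prevalence[i] = rng.uniform(q_hi, 1.0)
        labels[i] = "accidental_hit"

    P = adoption_probability(
        cols.capacity[:, None], prevalence[None, :], appeal[None, :], spec.e, spec.s
    )
    present = rng.random(P.shape) < P
    users_idx, items_idx = np.nonzero(present)

    lo, hi = spec.rating_scale
    base = lo + appeal * (hi - lo)
    ratings_val = base[items_idx]
    if spec.rating_noise_sd > 0:
        ratings_val = ratings_val + spec.rating_noise_sd * rng.standard_normal(
            len(items_idx)
        )
    ratings_val = np.clip(ratings_val, lo, hi)

    item_ids = np.array([f"i{j:04d}" for j in range(spec.n_items)], dtype=object)
    user_ids = np.array([f"u{j:04d}" for j in range(spec.n_users)], dtype=object)
    ratings = pd.DataFrame(
        {
            "user_id": user_ids[users_idx],
            "item_id": item_ids[items_idx],
            "rating": ratings_val,
        }
    )
    if spec.year_range is not None:
        years = rng.integers(spec.year_range[0], spec.year_range[1] + 1, spec.n_items)
        ratings["year"] = years[items_idx]
    truth = pd.DataFrame(
        {
            "item_id": item_ids,
            "appeal": appeal,
            "prevalence": prevalence,
            "label": labels,
        }
    )
    return ratings, truth


def _auc_minus_half(outliers: np.ndarray, controls: np.ndarray) -> float:
    if len(outliers) == 0 or len(controls) == 0:
        return 0.0
    u = stats.mannwhitneyu(outliers, controls, alternative="two-sided").statistic
    return float(u / (len(outliers) * len(controls)) - 0.5)


def evaluate_detection(
    ground_truth: pd.DataFrame,
    contributions,
    drift,
    frequencies=None,
) -> DetectionReport:
    """Score how planted outliers behave in contribution and drift space.

    ``contributions`` and ``drift`` are aligned with ``ground_truth`` rows
    (mapping/Series keyed by item_id, or plain arrays in row order).
    Controls are frequency-matched ordinary items (nearest frequency per
    outlier, without replacement; latent prevalence is used when realized
    frequencies are not supplied).  Positive ``separation_drift`` means
    outliers out-drift their controls; negative ``separation_contribution``
    means they contribute less to nestedness.
    """
    truth = ground_truth.reset_index(drop=True)

    def _align(values) -> np.ndarray:
        if isinstance(values, (dict, pd.Series)):
            s = pd.Series(values)
            return s.loc[truth["item_id"]].to_numpy(dtype=float)
        return np.asarray(values, dtype=float)

    c = _align(contributions)
    d = _align(drift)
    match_on = (
        np.asarray(frequencies, dtype=float)
        if frequencies is not None
        else truth["prevalence"].to_numpy(dtype=float)
    )
    labels = truth["label"].to_numpy()
    mean_contribution = {
        lab: float(np.nanmean(c[labels == lab])) for lab in np.unique(labels)
    }
    mean_drift = {lab: float(np.nanmean(d[labels == lab])) for lab in np.unique(labels)}
    out_idx = np.nonzero(labels != "none")[0]
    ord_idx = list(np.nonzero(labels == "none")[0])
    controls = []
    for i in out_idx:
        if not ord_idx:
            break
        j = min(ord_idx, key=lambda k: abs(match_on[k] - match_on[i]))
        controls.append(j)
        ord_idx.remove(j)
    controls = np.asarray(controls, dtype=int)
    ok = ~np.isnan(c[out_idx]) if len(out_idx) else np.array([], dtype=bool)
    return DetectionReport(
        mean_contribution=mean_contribution,
        mean_drift=mean_drift,
        separation_drift=_auc_minus_half(d[out_idx], d[controls]),
        separation_contribution=_auc_minus_half(c[out_idx][ok], c[controls]),
        n_outliers=int(len(out_idx)),
    )
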