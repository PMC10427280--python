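"""Null models for nestedness inference.

Two randomizations are provided.  The whole-matrix R1 null keeps each row's
total fixed and redraws the positions of its ones with probability
proportional to the original column totals; it is the middle ground between
the unconstrained and fully margin-fixed nulls and drives the significance
test for NODF.  The per-item probabilistic null redraws a single focal
column cell-by-cell from the margins of the observed matrix, with

    p_ic = (n_i / C + n_c / I) / 2,

the mean of the item's relative frequency and the collection's relative
size; it underlies the per-item nestedness contributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import MatrixMargins, PresenceMatrix, margins
from .nodf import nodf

__all__ = [
    "SignificanceResult",
    "r1_randomize",
    "cell_probability",
    "item_null_probabilities",
    "randomize_item",
    "randomize_collection",
    "nodf_significance",
]


@dataclass(frozen=True)
class SignificanceResult:
    """One-sided NODF significance against the R1 null.

    ``p_empirical`` uses the add-one estimator (1 + #{null >= observed}) /
    (n_sims + 1), so it is never exactly zero; with 200 simulations the
    smallest attainable value is 1/201 < 0.005.  ``z`` is NaN and
    ``degenerate`` True when the null ensemble has zero spread.
    """

    observed_nodf: float
    null_mean: float
    null_sd: float
    z: float
    p_empirical: float
    n_sims: int
    seed: int | None
    degenerate: bool = False


def r1_randomize(m: PresenceMatrix, rng: np.random.Generator) -> PresenceMatrix:
    """One draw from the column-proportional, row-fixed (R1) null.

    Each row keeps exactly its observed number of ones; their columns are
    drawn without replacement with probability proportional to the ORIGINAL
    matrix's column totals.  Columns empty in the original matrix can never
    receive a 1.
    """
    cells = m.cells
    col_totals = cells.sum(axis=0).astype(float)
    n_cols = cells.shape[1]
    positive = int((col_totals > 0).sum())
    weights = col_totals / col_totals.sum() if col_totals.sum() else col_totals
    out = np.zeros_like(cells)
    for r, row in enumerate(cells):
        k = int(row.sum())
        if k == 0:
            continue
        if k > positive:
            raise ValueError(
                f"row {m.collection_ids[r]!r} needs {k} ones but only "
                f"{positive} columns have positive weight"
            )
        chosen = rng.choice(n_cols, size=k, replace=False, p=weights)
        out[r, chosen] = 1
    return PresenceMatrix(out, m.collection_ids, m.item_ids)


def cell_probability(margins_: MatrixMargins, item: int, collection: int) -> float:
    """Null probability that ``item`` is present in ``collection``.

    Arguments are integer indices into the margins arrays.  The probability
    is the arithmetic mean of the item's relative frequency n_i/C and the
    collection's relative size n_c/I; it is monotone in both margins and
    bounded in [0, 1].
    """
    return float(
        (margins_.n_i[item] / margins_.C + margins_.n_c[collection] / margins_.I) / 2.0
    )


def item_null_probabilities(margins_: MatrixMargins, item: int) -> np.ndarray:
    """Vector of ``cell_probability`` over all collections for one item."""
    return (margins_.n_i[item] / margins_.C + margins_.n_c / margins_.I) / 2.0


def randomize_item(m: PresenceMatrix, item, rng: np.random.Generator) -> PresenceMatrix:
    """Redraw one focal item's column under the margins-based null.

    Every cell of the focal column becomes an independent Bernoulli draw
    with the margins-based probability computed from the observed matrix;
    all other columns keep their true values.
    """
    j = m.item_index(item)
    p = item_null_probabilities(margins(m), j)
    out = m.cells.copy()
    out[:, j] = (rng.random(m.shape[0]) < p).astype(np.int64)
    return PresenceMatrix(out, m.collection_ids, m.item_ids)


def randomize_collection(
    m: PresenceMatrix, collection, rng: np.random.Generator
) -> PresenceMatrix:
    """Row-side mirror of :func:`randomize_item` (one focal collection)."""
    hits = np.nonzero(m.collection_ids == collection)[0]
    if len(hits) == 0:
        raise KeyError(f"unknown collection id: {collection!r}")
    r = int(hits[0])
    mg = margins(m)
    p = (mg.n_i / mg.C + mg.n_c[r] / mg.I) / 2.0
    out = m.cells.copy()
    out[r, :] = (rng.random(m.shape[1]) < p).astype(np.int64)
    return PresenceMatrix(out, m.collection_ids, m.item_ids)


def nodf_significance(
    m: PresenceMatrix,
    n_sims: int = 200,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    **nodf_kwargs,
) -> SignificanceResult:
    """One-sided NODF significance test against the R1 null.

    Generates ``n_sims`` R1 draws, scores each with the same NODF settings
    as the observed matrix, and reports the empirical upper-tail probability
    of the observed score.  Pass either ``seed`` (recorded in the result) or
    an explicit ``rng``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = nodf(m, **nodf_kwargs).nodf_total
    null = np.empty(n_sims)
    for i in range(n_sims):
        null[i] = nodf(r1_randomize(m, rng), **nodf_kwargs).nodf_total
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_sims > 1 else 0.0
    degenerate = null_sd == 0.0
    z = float("nan") if degenerate else (observed - null_mean) / null_sd
    p = (1 + int((null >= observed).sum())) / (n_sims + 1)
    return SignificanceResult(
        observed_nodf=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=z,
        p_empirical=p,
        n_sims=n_sims,
        seed=seed,
        degenerate=degenerate,
    )
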