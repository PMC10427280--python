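"""Presence/absence matrix data model.

A *collection* is the set of items associated with one agent (all movies a
user rated, the books in a library, the technologies of a society).  A set of
collections is a binary incidence matrix: collections as rows, items as
columns, cell 1 iff the item is in the collection.  Every metric in this
package consumes this object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PresenceMatrix",
    "MatrixMargins",
    "from_ratings",
    "margins",
    "sort_canonical",
    "drop_empty",
]


@dataclass(frozen=True)
class PresenceMatrix:
    """Binary collections x items incidence grid.

    Parameters
    ----------
    cells
        2-D array of 0/1, one row per collection, one column per item.
    collection_ids, item_ids
        Unique labels for rows and columns.
    """

    cells: np.ndarray
    collection_ids: np.ndarray = field(default=None)
    item_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells)
        if cells.ndim != 2:
            raise ValueError("cells must be a 2-D array")
        if cells.size and not np.isin(cells, (0, 1)).all():
            raise ValueError("cells must contain only 0 and 1")
        object.__setattr__(self, "cells", cells.astype(np.int64))
        n_rows, n_cols = cells.shape
        cids = self.collection_ids
        iids = self.item_ids
        if cids is None:
            cids = np.array([f"c{r}" for r in range(n_rows)], dtype=object)
        if iids is None:
            iids = np.array([f"i{c}" for c in range(n_cols)], dtype=object)
        cids = np.asarray(cids, dtype=object)
        iids = np.asarray(iids, dtype=object)
        if len(cids) != n_rows:
            raise ValueError("collection_ids length does not match row count")
        if len(iids) != n_cols:
            raise ValueError("item_ids length does not match column count")
        for name, ids in (("collection_ids", cids), ("item_ids", iids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"{name} must be unique")
        object.__setattr__(self, "collection_ids", cids)
        object.__setattr__(self, "item_ids", iids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    def item_index(self, item_id) -> int:
        """Column index of ``item_id``; raises ``KeyError`` if unknown."""
        hits = np.nonzero(self.item_ids == item_id)[0]
        if len(hits) == 0:
            raise KeyError(f"unknown item id: {item_id!r}")
        return int(hits[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells, index=list(self.collection_ids), columns=list(self.item_ids)
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, PresenceMatrix):
            return NotImplemented
        return (
            self.cells.shape == other.cells.shape
            and (self.cells == other.cells).all()
            and (self.collection_ids == other.collection_ids).all()
            and (self.item_ids == other.item_ids).all()
        )


@dataclass(frozen=True)
class MatrixMargins:
    """Marginal totals of a :class:`PresenceMatrix`.

    ``n_i`` counts, per item, the collections containing it (item frequency);
    ``n_c`` counts, per collection, the items it contains (collection size);
    ``I`` and ``C`` are the item and collection totals; ``fill`` the fraction
    of 1-cells.
    """

    n_i: np.ndarray
    n_c: np.ndarray
    I: int
    C: int
    fill: float


def from_ratings(ratings: pd.DataFrame, min_items_per_collection: int = 0) -> PresenceMatrix:
    """Collapse a long-format ratings table into a presence matrix.

    Everything a user has rated forms their collection; rating values are
    ignored, only membership matters.  Duplicate (user, item) records are
    deduplicated silently (count logged).  Users with fewer than
    ``min_items_per_collection`` distinct items are removed, and items rated
    by no retained user do not appear.
    """
    if ratings.empty:
        raise ValueError("ratings table is empty")
    if min_items_per_collection < 0:
        raise ValueError("min_items_per_collection must be >= 0")
    pairs = ratings[["user_id", "item_id"]].drop_duplicates()
    n_dup = len(ratings) - len(pairs)
    if n_dup:
        logger.info("deduplicated %d repeated (user, item) records", n_dup)
    sizes = pairs.groupby("user_id", sort=False)["item_id"].nunique()
    keep_users = sizes[sizes >= min_items_per_collection].index
    pairs = pairs[pairs["user_id"].isin(keep_users)]
    if pairs.empty:
        raise ValueError("no collections survive filters")
    # pivot preserving first-appearance order of users and items
    users = pairs["user_id"].drop_duplicates().to_numpy()
    items = pairs["item_id"].drop_duplicates().to_numpy()
    u_idx = pd.Categorical(pairs["user_id"], categories=users).codes
    i_idx = pd.Categorical(pairs["item_id"], categories=items).codes
    cells = np.zeros((len(users), len(items)), dtype=np.int64)
    cells[u_idx, i_idx] = 1
    return PresenceMatrix(cells, users.astype(object), items.astype(object))


def margins(m: PresenceMatrix) -> MatrixMargins:
    """Row/column totals, dimensions and fill of a presence matrix."""
    cells = m.cells
    C, I = cells.shape
    n_i = cells.sum(axis=0)
    n_c = cells.sum(axis=1)
    fill = float(cells.mean()) if cells.size else 0.0
    return MatrixMargins(n_i=n_i, n_c=n_c, I=I, C=C, fill=fill)


def sort_canonical(m: PresenceMatrix) -> PresenceMatrix:
    """Order rows and columns by decreasing marginal totals.

    The most populated collections end up on top and the most widespread
    items on the left, the ordering NODF expects.  Ties keep their input
    order (stable sort), which never changes the NODF score because tied
    pairs fail decreasing fill and score zero regardless of order.
    """
    cells = m.cells
    row_order = np.argsort(-cells.sum(axis=1), kind="stable")
    col_order = np.argsort(-cells.sum(axis=0), kind="stable")
    return PresenceMatrix(
        cells[np.ix_(row_order, col_order)],
        m.collection_ids[row_order],
        m.item_ids[col_order],
    )


def drop_empty(m: PresenceMatrix) -> PresenceMatrix:
    """Remove all-zero rows and columns, keeping survivor ids."""
    keep_rows = m.cells.sum(axis=1) > 0
    keep_cols = m.cells.sum(axis=0) > 0
    return PresenceMatrix(
        m.cells[np.ix_(keep_rows.nonzero()[0], keep_cols.nonzero()[0])],
        m.collection_ids[keep_rows],
        m.item_ids[keep_cols],
    )
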