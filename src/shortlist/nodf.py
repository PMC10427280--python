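"""NODF: Nestedness metric based on Overlap and Decreasing Fill.

For every pair of rows (and of columns) taken top-vs-bottom (left-vs-right)
on the canonically ordered matrix, the pair scores 0 unless the lower member
is strictly less populated than the upper one, in which case it scores the
percentage of the lower member's 1-cells that coincide with 1-cells of the
upper member.  Pair scores are averaged per axis; the two axis averages are
combined into a total score on the 0-100 scale.

All unordered pairs enter the average, as in the standard formulation of the
metric used by ecological software; nestedness of the whole matrix, not just
neighbouring lines, is what the score summarises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import PresenceMatrix, drop_empty as _drop_empty, sort_canonical

__all__ = ["NodfResult", "pair_overlap_score", "nodf"]

_VARIANTS = ("mean_of_means", "pooled_pairs")


@dataclass(frozen=True)
class NodfResult:
    """NODF scores for one matrix.

    ``nodf_total`` combines the row and column averages either as their
    plain mean (``mean_of_means``) or weighted by pair counts
    (``pooled_pairs``, the convention of the standard ecology
    implementations).  The two coincide on square matrices.
    """

    nodf_rows: float
    nodf_cols: float
    nodf_total: float
    n_row_pairs: int
    n_col_pairs: int
    variant: str


def pair_overlap_score(upper: np.ndarray, lower: np.ndarray) -> float:
    """Score one (upper, lower) pair of binary vectors on the 0-100 scale.

    Zero unless the lower vector has strictly fewer ones than the upper
    (decreasing fill) and at least one 1; otherwise the percentage of the
    lower vector's ones that overlap ones of the upper vector.
    """
    upper = np.asarray(upper)
    lower = np.asarray(lower)
    if upper.shape != lower.shape:
        raise ValueError("pair members must have equal length")
    f_up = int(upper.sum())
    f_lo = int(lower.sum())
    if f_lo >= f_up or f_lo == 0:
        return 0.0
    return 100.0 * int((upper & lower).sum()) / f_lo


def _axis_scores(cells: np.ndarray) -> tuple[float, int]:
    """Mean pair score over all (upper, lower) row pairs of ``cells``."""
    fills = cells.sum(axis=1)
    n = len(fills)
    overlap = cells @ cells.T
    iu, ju = np.triu_indices(n, k=1)
    f_up, f_lo = fills[iu], fills[ju]
    scores = np.zeros(len(iu))
    ok = (f_lo < f_up) & (f_lo > 0)
    scores[ok] = 100.0 * overlap[iu, ju][ok] / f_lo[ok]
    return float(scores.sum()), len(iu)


def nodf(
    m: PresenceMatrix,
    order: bool = True,
    variant: str = "mean_of_means",
    keep_empty: bool = False,
) -> NodfResult:
    """Compute NODF of a presence matrix.

    Parameters
    ----------
    m
        Presence matrix (any row/column order).
    order
        Sort rows and columns by decreasing totals first (the canonical NODF
        ordering).  With ``order=False`` the matrix is scored as given.
    variant
        ``"mean_of_means"`` (default): total = (rows + cols) / 2.
        ``"pooled_pairs"``: total weighted by pair counts.
    keep_empty
        Retain all-zero rows/columns (they score 0 against every partner and
        depress the metric); by default they are dropped first.

    Raises
    ------
    ValueError
        If fewer than 2 rows or 2 columns remain.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}")
    if not keep_empty:
        m = _drop_empty(m)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError(
            f"NODF needs at least a 2x2 matrix, got {m.shape[0]}x{m.shape[1]}"
        )
    if order:
        m = sort_canonical(m)
    row_sum, n_row_pairs = _axis_scores(m.cells)
    col_sum, n_col_pairs = _axis_scores(m.cells.T)
    nodf_rows = row_sum / n_row_pairs
    nodf_cols = col_sum / n_col_pairs
    if variant == "mean_of_means":
        total = (nodf_rows + nodf_cols) / 2.0
    else:
        total = (row_sum + col_sum) / (n_row_pairs + n_col_pairs)
    return NodfResult(
        nodf_rows=nodf_rows,
        nodf_cols=nodf_cols,
        nodf_total=total,
        n_row_pairs=n_row_pairs,
        n_col_pairs=n_col_pairs,
        variant=variant,
    )
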