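import numpy as np
import pandas as pd
import pytest

from shortlist import PresenceMatrix


@pytest.fixture
def worked_matrix() -> PresenceMatrix:
    """4x4 matrix whose NODF is 500/6 = 83.33 by hand enumeration."""
    return PresenceMatrix(
        np.array(
            [
                [1, 1, 1, 1],
                [1, 1, 0, 0],
                [1, 0, 1, 0],
                [1, 0, 0, 0],
            ]
        )
    )


@pytest.fixture
def triangular():
    """Strictly triangular (perfectly nested) matrix factory."""

    def make(n: int) -> PresenceMatrix:
        return PresenceMatrix(np.tril(np.ones((n, n), dtype=int)))

    return make


@pytest.fixture
def tiny_ratings() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "user_id": ["u1", "u1", "u2"],
            "item_id": ["a", "b", "a"],
            "rating": [4.0, 3.0, 5.0],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240517)


def brute_nodf(cells: np.ndarray, variant: str = "mean_of_means") -> float:
    """Independent NODF oracle: explicit double loops over all pairs.

    Sorts by decreasing marginal totals (stable), then scores every
    (upper, lower) / (left, right) pair with set logic.
    """
    cells = np.asarray(cells)
    cells = cells[np.argsort(-cells.sum(axis=1), kind="stable"), :]
    cells = cells[:, np.argsort(-cells.sum(axis=0), kind="stable")]

    def pair(u, v) -> float:
        ones_u = {k for k, x in enumerate(u) if x}
        ones_v = {k for k, x in enumerate(v) if x}
        if len(ones_v) >= len(ones_u) or not ones_v:
            return 0.0
        return 100.0 * len(ones_u & ones_v) / len(ones_v)

    row_scores = []
    for i in range(cells.shape[0]):
        for j in range(i + 1, cells.shape[0]):
            row_scores.append(pair(cells[i], cells[j]))
    col_scores = []
    for i in range(cells.shape[1]):
        for j in range(i + 1, cells.shape[1]):
            col_scores.append(pair(cells[:, i], cells[:, j]))
    if variant == "mean_of_means":
        return (np.mean(row_scores) + np.mean(col_scores)) / 2.0
    return float(np.mean(row_scores + col_scores))
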