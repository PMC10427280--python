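"""Reading and writing the package's plain-text formats.

Presence matrices travel as dense CSV/TSV (first column = collection id,
header = item ids, cells 0/1) or as sparse triplet text (one
"collection_id item_id" pair per line).  Ratings are long CSV with header
``user_id,item_id,rating`` plus optional ``year`` and ``genre``.  Reports
are JSON or CSV and always echo seeds, parameters and package version.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .matrix import PresenceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_ratings",
    "write_ratings",
    "write_report",
]

_RATINGS_REQUIRED = ("user_id", "item_id", "rating")
_RATINGS_OPTIONAL = ("year", "genre")


def read_matrix(path, fmt: str = "dense") -> PresenceMatrix:
    """Read a presence matrix from ``path`` (``dense`` or ``triplet``)."""
    path = Path(path)
    if fmt == "dense":
        return _read_dense(path)
    if fmt == "triplet":
        return _read_triplet(path)
    raise ValueError("format must be 'dense' or 'triplet'")


def _read_dense(path: Path) -> PresenceMatrix:
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows or len(rows[0]) < 2:
        raise ValueError(f"{path}:1: malformed header (need id column + items)")
    item_ids = [tok.strip() for tok in rows[0][1:]]
    collection_ids, cells = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not tok.strip() for tok in row):
            continue
        if len(row) != len(item_ids) + 1:
            raise ValueError(f"{path}:{lineno}: expected {len(item_ids) + 1} fields")
        collection_ids.append(row[0].strip())
        vals = []
        for col, tok in enumerate(row[1:], start=2):
            tok = tok.strip()
            if tok not in ("0", "1"):
                raise ValueError(
                    f"{path}:{lineno}: non-binary cell {tok!r} in field {col}"
                )
            vals.append(int(tok))
        cells.append(vals)
    return PresenceMatrix(
        np.array(cells, dtype=np.int64).reshape(len(cells), len(item_ids)),
        np.array(collection_ids, dtype=object),
        np.array(item_ids, dtype=object),
    )


def _read_triplet(path: Path) -> PresenceMatrix:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.replace(",", " ").split()
            if len(toks) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'collection item' pair")
            pairs.append(tuple(toks))
    if not pairs:
        raise ValueError(f"{path}: no presence pairs found")
    n_dup = len(pairs) - len(dict.fromkeys(pairs))
    if n_dup:
        logger.warning("%s: %d duplicate pairs collapsed", path, n_dup)
    pairs = list(dict.fromkeys(pairs))
    coll = list(dict.fromkeys(p[0] for p in pairs))
    items = list(dict.fromkeys(p[1] for p in pairs))
    c_pos = {c: i for i, c in enumerate(coll)}
    i_pos = {it: j for j, it in enumerate(items)}
    cells = np.zeros((len(coll), len(items)), dtype=np.int64)
    for c, it in pairs:
        cells[c_pos[c], i_pos[it]] = 1
    return PresenceMatrix(cells, np.array(coll, dtype=object), np.array(items, dtype=object))


def write_matrix(m: PresenceMatrix, path, fmt: str = "dense") -> None:
    path = Path(path)
    if fmt == "dense":
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter=sep)
            w.writerow(["collection_id", *m.item_ids])
            for cid, row in zip(m.collection_ids, m.cells):
                w.writerow([cid, *row.tolist()])
    elif fmt == "triplet":
        with open(path, "w") as fh:
            for cid, row in zip(m.collection_ids, m.cells):
                for iid in m.item_ids[row.astype(bool)]:
                    fh.write(f"{cid} {iid}\n")
    else:
        raise ValueError("format must be 'dense' or 'triplet'")


def read_ratings(path) -> pd.DataFrame:
    """Read a long-format ratings CSV; optional columns detected by header."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"user_id": str, "item_id": str})
    for col in _RATINGS_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    unknown = [c for c in df.columns if c not in _RATINGS_REQUIRED + _RATINGS_OPTIONAL]
    if unknown:
        logger.warning("%s: ignoring unknown columns %s", path, unknown)
        df = df.drop(columns=unknown)
    ratings = pd.to_numeric(df["rating"], errors="coerce")
    bad = ratings.isna() & df["rating"].notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}:{row}: non-numeric rating {df['rating'][bad.idxmax()]!r}")
    if ratings.isna().any() or not np.isfinite(ratings).all():
        raise ValueError(f"{path}: ratings must be finite")
    df["rating"] = ratings.astype(float)
    if "year" in df.columns:
        df["year"] = pd.to_numeric(df["year"], errors="raise")
    return df


def write_ratings(ratings: pd.DataFrame, path) -> None:
    ratings.to_csv(path, index=False)


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_report(results, path, fmt: str = "json", config: dict | None = None) -> None:
    """Write a result object (dataclass, dict, or record list) to disk.

    JSON reports are wrapped with the package version and the echoed run
    configuration so every output records its seeds and parameters.
    """
    path = Path(path)
    if fmt == "json":
        payload = {
            "version": __version__,
            "config": _jsonify(config or {}),
            "results": _jsonify(results),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    elif fmt == "csv":
        records = _jsonify(results)
        if isinstance(records, dict):
            records = [records]
        pd.DataFrame.from_records(records).to_csv(path, index=False)
    else:
        raise ValueError("format must be 'json' or 'csv'")
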