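"""Flat-file serialization and preprocessing helpers.

Wide twin tables are comma-separated text with a header row::

    family_id,zygosity,y1,y2,x1_1,...,x1_K,x2_1,...,x2_K

Missing cells are written as ``NA``; on read both ``NA`` (case-sensitive)
and empty cells are accepted.  Zygosity tokens are ``MZ``/``DZ``,
case-insensitive on read.  The format round-trips values and missingness
masks losslessly (numbers are written with 17 significant digits).
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd

from .data import TwinDataset
from .params import Zygosity

__all__ = [
    "read_twin_table",
    "write_twin_table",
    "dataset_to_frame",
    "frame_to_dataset",
    "dummy_code",
    "standardize",
    "summarize_missingness",
]

_MISSING_TOKEN = "NA"


def _column_names(K: int) -> list[str]:
    return (
        ["family_id", "zygosity", "y1", "y2"]
        + [f"x1_{j}" for j in range(1, K + 1)]
        + [f"x2_{j}" for j in range(1, K + 1)]
    )


def _parse_cell(token: str, path, line_no: int, col: str) -> float:
    token = token.strip()
    if token == "" or token == _MISSING_TOKEN:
        return np.nan
    try:
        val = float(token)
    except ValueError:
        raise ValueError(
            f"{path}:{line_no}: non-numeric cell {token!r} in column {col!r}"
        ) from None
    if not np.isfinite(val):
        raise ValueError(f"{path}:{line_no}: non-finite value in column {col!r}")
    return val


def read_twin_table(path) -> TwinDataset:
    """Read a wide twin table; K is inferred from the header."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        n_x = sum(1 for h in header if h.startswith("x1_"))
        if n_x < 1:
            raise ValueError(f"{path}: header defines no covariate columns (x1_*)")
        expected = _column_names(n_x)
        if header != expected:
            raise ValueError(
                f"{path}: unexpected header {header!r}; expected {expected!r}"
            )
        fam, zyg, ys, xs = [], [], [], []
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(expected):
                raise ValueError(
                    f"{path}:{line_no}: expected {len(expected)} cells, got {len(row)}"
                )
            fam.append(row[0].strip())
            zyg.append(Zygosity.from_token(row[1]))
            y = [_parse_cell(row[2 + i], path, line_no, expected[2 + i]) for i in range(2)]
            x = [
                _parse_cell(row[4 + i], path, line_no, expected[4 + i])
                for i in range(2 * n_x)
            ]
            ys.append(y)
            xs.append(np.asarray(x).reshape(2, n_x))
    if not fam:
        raise ValueError(f"{path}: no data rows")
    return TwinDataset(fam, zyg, np.asarray(ys), np.stack(xs))


def write_twin_table(data: TwinDataset, path) -> None:
    """Write a dataset in the wide format; missing cells become ``NA``."""
    K = data.K
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_column_names(K))
        vals = data.stacked_values()
        for i in range(len(data)):
            cells = [data.family_id[i], data.zygosity[i].value]
            cells += [
                _MISSING_TOKEN if np.isnan(v) else format(v, ".17g") for v in vals[i]
            ]
            writer.writerow(cells)


def dataset_to_frame(data: TwinDataset) -> pd.DataFrame:
    """Dataset as a pandas frame in the wide column layout."""
    cols = _column_names(data.K)
    frame = pd.DataFrame(data.stacked_values(), columns=cols[2:])
    frame.insert(0, "zygosity", [z.value for z in data.zygosity])
    frame.insert(0, "family_id", data.family_id)
    return frame


def frame_to_dataset(frame: pd.DataFrame) -> TwinDataset:
    """Inverse of :func:`dataset_to_frame`."""
    n_x = sum(1 for c in frame.columns if str(c).startswith("x1_"))
    if n_x < 1:
        raise ValueError("frame defines no covariate columns (x1_*)")
    y = frame[["y1", "y2"]].to_numpy(dtype=float)
    xcols = [f"x1_{j}" for j in range(1, n_x + 1)] + [f"x2_{j}" for j in range(1, n_x + 1)]
    X = frame[xcols].to_numpy(dtype=float).reshape(len(frame), 2, n_x)
    return TwinDataset(frame["family_id"].tolist(), frame["zygosity"].tolist(), y, X)


# ---------------------------------------------------------------------------
# preprocessing helpers
# ---------------------------------------------------------------------------

def dummy_code(column: pd.Series, categories=None) -> pd.DataFrame:
    """``c - 1`` 0/1 indicator columns, largest category as reference.

    Ties on category size are broken by sort order of the category labels.
    A missing input cell propagates to missing values in every indicator.
    """
    column = pd.Series(column)
    counts = column.value_counts(dropna=True)
    present = list(counts.index) if categories is None else [
        c for c in categories if c in set(counts.index)
    ]
    if len(present) < 2:
        raise ValueError("dummy coding requires at least two observed categories")
    reference = max(sorted(present, key=str), key=lambda c: counts[c])
    others = [c for c in present if c != reference]
    out = {}
    name = column.name or "cat"
    for cat in others:
        ind = (column == cat).astype(float)
        ind[column.isna()] = np.nan
        out[f"{name}_{cat}"] = ind
    return pd.DataFrame(out, index=column.index)


def standardize(column: pd.Series) -> pd.Series:
    """Center/scale the observed values to mean 0, sample variance 1.

    Missing cells are untouched.  Idempotent: standardizing a standardized
    column returns it unchanged.
    """
    column = pd.Series(column).astype(float)
    obs = column.dropna()
    if len(obs) < 2:
        raise ValueError("standardize requires at least two non-missing values")
    sd = obs.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("standardize requires nonzero variance")
    return (column - obs.mean()) / sd


def summarize_missingness(table) -> dict:
    """Per-covariate and total missing counts and the overall fraction.

    Accepts a :class:`TwinDataset` (covariate masks over both twins) or a
    pandas DataFrame of individual-level covariate columns.  The total
    fraction is total missing / (K x number of individuals).
    """
    if isinstance(table, TwinDataset):
        miss = np.isnan(table.X)  # (n, 2, K)
        per = {f"x_{j + 1}": int(miss[:, :, j].sum()) for j in range(table.K)}
        n_individuals = 2 * len(table)
        k = table.K
    else:
        frame = pd.DataFrame(table)
        per = {str(c): int(frame[c].isna().sum()) for c in frame.columns}
        n_individuals = len(frame)
        k = frame.shape[1]
    total = int(sum(per.values()))
    denom = k * n_individuals
    return {
        "per_covariate": per,
        "total_missing": total,
        "n_individuals": n_individuals,
        "n_covariates": k,
        "fraction": total / denom if denom else 0.0,
    }
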