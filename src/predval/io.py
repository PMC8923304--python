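"""Readers and writers for delimited observed/calculated tables.

Input files are CSV or TSV with a header row.  The observed and calculated
columns are selected *by name only* — never by position — because the axis
convention (observed on y, calculated on x) is fixed, and silently swapped
columns would change every statistic that involves a fitted line.  Rows
with missing values in the required columns are rejected with their row
numbers listed.
"""

from __future__ import annotations

import os
from typing import Iterable

import pandas as pd

from .core import PairedPredictions, StatReport, ValidationError
from .report import reports_to_frame

__all__ = ["read_pairs", "read_grouped", "write_pairs", "write_reports_csv"]


def _read_frame(path: str | os.PathLike, sep: str | None) -> pd.DataFrame:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


def _extract_pairs(
    frame: pd.DataFrame,
    observed: str,
    calculated: str,
    id_col: str | None,
    group: str | None,
) -> PairedPredictions:
    for col in (observed, calculated) + ((id_col,) if id_col else ()):
        if col not in frame.columns:
            raise ValidationError(
                f"column {col!r} not found; available columns: "
                f"{list(frame.columns)}"
            )
    missing = frame.index[
        frame[observed].isna() | frame[calculated].isna()
    ].tolist()
    if missing:
        # +2: one for the header line, one for 1-based numbering
        rows = ", ".join(str(i + 2) for i in missing)
        raise ValidationError(
            f"missing values in rows (file line numbers): {rows}"
        )
    ids = tuple(frame[id_col].astype(str)) if id_col else None
    return PairedPredictions(
        y_obs=frame[observed].to_numpy(dtype=float),
        x_calc=frame[calculated].to_numpy(dtype=float),
        ids=ids,
        group=group,
    )


def read_pairs(
    path: str | os.PathLike,
    observed: str = "observed",
    calculated: str = "calculated",
    id_col: str | None = None,
    group: str | None = None,
    sep: str | None = None,
) -> PairedPredictions:
    """Read one dataset from a delimited file.

    ``observed`` and ``calculated`` name the columns holding the measured
    and predicted values; there is no positional fallback.  ``sep`` is
    inferred from the extension (``.tsv``/``.tab``/``.txt`` → tab,
    otherwise comma) unless given.
    """
    return _extract_pairs(_read_frame(path, sep), observed, calculated, id_col, group)


def read_grouped(
    path: str | os.PathLike,
    group_col: str,
    observed: str = "observed",
    calculated: str = "calculated",
    id_col: str | None = None,
    sep: str | None = None,
) -> list[PairedPredictions]:
    """Read a file holding several datasets distinguished by a group column.

    Returns one PairedPredictions per group, in order of first appearance.
    """
    frame = _read_frame(path, sep)
    if group_col not in frame.columns:
        raise ValidationError(
            f"group column {group_col!r} not found; available columns: "
            f"{list(frame.columns)}"
        )
    datasets = []
    for label in frame[group_col].drop_duplicates():
        sub = frame[frame[group_col] == label]
        datasets.append(
            _extract_pairs(sub, observed, calculated, id_col, str(label))
        )
    return datasets


def write_pairs(pairs: PairedPredictions, path: str | os.PathLike) -> None:
    """Write one dataset as CSV with columns id (optional), observed, calculated."""
    data: dict[str, object] = {}
    if pairs.ids is not None:
        data["id"] = list(pairs.ids)
    data["observed"] = pairs.y_obs
    data["calculated"] = pairs.x_calc
    if pairs.group is not None:
        data["group"] = pairs.group
    pd.DataFrame(data).to_csv(path, index=False)


def write_reports_csv(reports: Iterable[StatReport], path: str | os.PathLike) -> None:
    """Write reports as machine-readable CSV at full precision."""
    reports_to_frame(reports).to_csv(path, index=False)
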