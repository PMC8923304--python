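"""Batch evaluation and tabular reports for many grouped datasets.

Renders comparison tables in the conventional layout for this kind of QC
work: one row per dataset, columns ordered r²_Pearson, r²_bias, r²_val,
RMSE_Pearson, RMSE_bias, RMSE_val, bias.  Statistics are printed to two
decimals; machine-readable CSV output keeps full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core import DofConvention, PairedPredictions, StatReport, evaluate

__all__ = [
    "GroupFailure",
    "batch_evaluate",
    "diagnose",
    "reports_to_frame",
    "format_table",
]

DIAGNOSIS_LABELS = ("none", "bias", "tilt", "bias_and_tilt")


@dataclass(frozen=True)
class GroupFailure:
    """A per-group evaluation failure, reported without aborting the batch."""

    group: str | None
    error: Exception


def batch_evaluate(
    datasets: Sequence[PairedPredictions],
    dof_convention: DofConvention = "n",
) -> tuple[list[StatReport], list[GroupFailure]]:
    """Evaluate many datasets, collecting per-group failures.

    Returns the reports for the groups that evaluated cleanly (in input
    order) and a list of failures; a bad group never aborts the batch.
    """
    reports: list[StatReport] = []
    failures: list[GroupFailure] = []
    for pairs in datasets:
        try:
            reports.append(evaluate(pairs, dof_convention))
        except Exception as exc:  # noqa: BLE001 - failures are data, not bugs
            failures.append(GroupFailure(group=pairs.group, error=exc))
    return reports, failures


def diagnose(report: StatReport, gap_threshold: float = 0.05) -> str:
    """Classify the systematic-error regime from the r² gaps.

    The gap r²_bias − r²_val responds to a constant offset (bias); the gap
    r²_Pearson − r²_bias responds to a slope distortion (tilt).  A gap
    larger than ``gap_threshold`` flags the corresponding error.  The 0.05
    default is a heuristic, not a published cutoff; tune it to the noise
    level of the data at hand.

    Returns one of ``"none"``, ``"bias"``, ``"tilt"``, ``"bias_and_tilt"``.
    """
    if gap_threshold <= 0:
        raise ValueError(f"gap_threshold must be > 0, got {gap_threshold}")
    bias_gap = report.r2_bias - report.r2_val
    tilt_gap = report.r2_pearson - report.r2_bias
    has_bias = bias_gap > gap_threshold
    has_tilt = tilt_gap > gap_threshold
    if has_bias and has_tilt:
        return "bias_and_tilt"
    if has_bias:
        return "bias"
    if has_tilt:
        return "tilt"
    return "none"


def reports_to_frame(reports: Iterable[StatReport]) -> pd.DataFrame:
    """Assemble reports into a DataFrame in the standard column order."""
    rows = [r.to_dict() for r in reports]
    return pd.DataFrame(rows, columns=list(StatReport.COLUMNS))


def format_table(reports: Iterable[StatReport]) -> str:
    """Human-readable aligned table, statistics rounded to two decimals."""
    frame = reports_to_frame(reports)
    if frame.empty:
        return "(no results)"
    frame["group"] = [g if g is not None else "-" for g in frame["group"]]
    return frame.to_string(
        index=False,
        float_format=lambda v: f"{v:.2f}",
        na_rep="-",
    )
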