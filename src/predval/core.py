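"""Constrained-regression validation statistics for observed-vs-calculated data.

A prediction model for a physical property (here, log10 of aqueous intrinsic
solubility, log S0) is judged from a scatter plot of observed values against
calculated values.  The axis convention is fixed and non-configurable:

    *observed* values are the dependent variable (y-axis),
    *calculated* values are the independent variable (x-axis).

Swapping the axes silently changes every statistic that involves a fitted
line, so the readers in :mod:`predval.io` require explicitly named columns.

Three nested least-squares fits of the line y = a + b·x define three
families of r² and RMSE statistics:

``VAL``
    a = 0 and b = 1 fixed (the identity line).  Residuals measure absolute
    predictive agreement; this is "model validation" r²/RMSE.
``BIAS``
    b = 1 fixed, a fitted (closed form: a = mean(y − x)).  A constant offset
    ("bias") between prediction and measurement is forgiven.
``PEARSON``
    a and b both fitted (ordinary least squares).  Offset and slope
    distortion ("tilt") are both forgiven; the resulting r² equals the
    square of Pearson's product-moment correlation.

Because the fits are nested, SS_res(PEARSON) ≤ SS_res(BIAS) ≤ SS_res(VAL),
hence r²_Pearson ≥ r²_bias ≥ r²_val and (with a common denominator)
RMSE_Pearson ≤ RMSE_bias ≤ RMSE_val.  All three r² use the same total sum
of squares about the mean observed value, so r²_val and r²_bias can be
negative for poor models; they are reported as-is, never clamped.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "DegenerateDataError",
    "ConstraintCase",
    "PairedPredictions",
    "LineFit",
    "StatReport",
    "DofConvention",
    "fit_line",
    "r_squared",
    "rmse",
    "pearson_r",
    "evaluate",
]


class ValidationError(ValueError):
    """Raised when input data violate the PairedPredictions contract."""


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined for the data (e.g. zero variance)."""


class ConstraintCase(enum.Enum):
    """Constraint scheme applied to the regression line y = a + b·x."""

    VAL = "val"  # a = 0, b = 1: identity line, no free parameters
    BIAS = "bias"  # b = 1, a fitted: unit-slope line with free intercept
    PEARSON = "pearson"  # a and b fitted: ordinary least squares

    @property
    def n_free_parameters(self) -> int:
        return {"val": 0, "bias": 1, "pearson": 2}[self.value]


#: RMSE denominator rule.  ``"n"`` divides every residual sum of squares by
#: the pair count; it is the default because it keeps the exact decomposition
#: RMSE_val² = RMSE_bias² + bias² and a strict ordering across cases.
#: ``"see"`` emulates the "standard error of estimate" printed by common
#: regression software: plain n for the identity line (no fit is performed),
#: n − 2 for any fitted line — the software's model is y = a + b·x with two
#: parameters, whether or not the slope is constrained to 1.
DofConvention = Literal["n", "see"]

_DOF_CONVENTIONS = ("n", "see")


def _as_float_array(values: Sequence[float], name: str) -> np.ndarray:
    try:
        arr = np.asarray(values, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{name} could not be converted to floats: {exc}") from exc
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class PairedPredictions:
    """Paired (observed, calculated) values for one dataset.

    Parameters
    ----------
    y_obs
        Observed values (log10 mol/L for solubility work; any common log
        scale is fine).  Dependent variable, y-axis.
    x_calc
        Calculated (predicted) values on the same scale.  Independent
        variable, x-axis.
    ids
        Optional per-pair labels (compound identifiers); if given, must be
        unique and match the pair count.
    group
        Optional label for the dataset as a whole (e.g. ``"acids"`` or
        ``"Test Set 2"``), carried through to reports.
    """

    y_obs: np.ndarray
    x_calc: np.ndarray
    ids: tuple[str, ...] | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        y = _as_float_array(self.y_obs, "y_obs")
        x = _as_float_array(self.x_calc, "x_calc")
        object.__setattr__(self, "y_obs", y)
        object.__setattr__(self, "x_calc", x)
        problems: list[str] = []
        if y.size != x.size:
            problems.append(
                f"y_obs and x_calc differ in length ({y.size} vs {x.size})"
            )
        if y.size < 3:
            problems.append(f"need at least 3 pairs, got {y.size}")
        if not np.all(np.isfinite(y)):
            problems.append("y_obs contains non-finite values")
        if not np.all(np.isfinite(x)):
            problems.append("x_calc contains non-finite values")
        if self.ids is not None:
            ids = tuple(str(i) for i in self.ids)
            object.__setattr__(self, "ids", ids)
            if len(ids) != y.size:
                problems.append(
                    f"ids length {len(ids)} does not match pair count {y.size}"
                )
            elif len(set(ids)) != len(ids):
                problems.append("ids are not unique")
        if problems:
            raise ValidationError("; ".join(problems))

    @property
    def n(self) -> int:
        return int(self.y_obs.size)

    def __len__(self) -> int:
        return self.n


@dataclass(frozen=True)
class LineFit:
    """Result of fitting y = a + b·x under one constraint case.

    ``ss_res`` is the residual sum of squares about the fitted line and
    ``ss_tot`` the total sum of squares about the mean observed value; both
    are stored so the derived statistics need no refit.
    """

    a: float  # intercept = bias, log units
    b: float  # slope = tilt, dimensionless
    case: ConstraintCase
    n: int
    ss_res: float
    ss_tot: float

    def residuals(self, pairs: PairedPredictions) -> np.ndarray:
        return pairs.y_obs - (self.a + self.b * pairs.x_calc)


@dataclass(frozen=True)
class StatReport:
    """The full 3×(r², RMSE) block for one dataset, plus bias and slope.

    ``bias`` is the fitted intercept of the unit-slope (BIAS-case) line;
    ``slope`` is the fitted slope of the unconstrained (PEARSON-case) line.
    r²_val and r²_bias may be negative for poor models and are reported
    as-is.
    """

    r2_val: float
    r2_bias: float
    r2_pearson: float
    rmse_val: float
    rmse_bias: float
    rmse_pearson: float
    bias: float
    slope: float
    n: int
    group: str | None = None
    dof_convention: str = "n"

    #: Column order used in human-readable and CSV reports.
    COLUMNS = (
        "group",
        "n",
        "r2_pearson",
        "r2_bias",
        "r2_val",
        "rmse_pearson",
        "rmse_bias",
        "rmse_val",
        "bias",
        "slope",
    )

    def to_dict(self) -> dict[str, object]:
        return {c: getattr(self, c) for c in self.COLUMNS}


def fit_line(pairs: PairedPredictions, case: ConstraintCase) -> LineFit:
    """Fit y = a + b·x to the pairs under the given constraint case.

    VAL fixes a = 0, b = 1; BIAS fixes b = 1 and takes the least-squares
    intercept a = mean(y − x); PEARSON is ordinary least squares in closed
    form.  ``ss_tot`` is always the sum of squares of y about its mean.

    Raises
    ------
    DegenerateDataError
        Under PEARSON when x_calc has zero variance (the slope is not
        identifiable).
    """
    y = pairs.y_obs
    x = pairs.x_calc
    ss_tot = float(np.sum((y - y.mean()) ** 2))

    if case is ConstraintCase.VAL:
        a, b = 0.0, 1.0
    elif case is ConstraintCase.BIAS:
        a, b = float(np.mean(y - x)), 1.0
    elif case is ConstraintCase.PEARSON:
        dx = x - x.mean()
        s_xx = float(np.sum(dx * dx))
        if s_xx == 0.0:
            raise DegenerateDataError(
                "x_calc has zero variance; the unconstrained slope is not "
                "identifiable"
            )
        b = float(np.sum(dx * (y - y.mean())) / s_xx)
        a = float(y.mean() - b * x.mean())
    else:  # pragma: no cover - exhaustive over the enum
        raise ValueError(f"unknown constraint case {case!r}")

    ss_res = float(np.sum((y - (a + b * x)) ** 2))
    return LineFit(a=a, b=b, case=case, n=pairs.n, ss_res=ss_res, ss_tot=ss_tot)


def _check_fit_matches(pairs: PairedPredictions, fit: LineFit) -> None:
    if fit.n != pairs.n:
        raise ValidationError(
            f"fit was produced from {fit.n} pairs but the data have {pairs.n}"
        )


def r_squared(pairs: PairedPredictions, fit: LineFit) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot for the fit's own line.

    The residuals are taken about the fit's line (identity, unit-slope, or
    unconstrained) while SS_tot is always about the mean observed value, so
    the three cases are directly comparable.  For the VAL and BIAS cases the
    value can be negative; it is never clamped.

    Raises
    ------
    DegenerateDataError
        If the observed values are constant (SS_tot = 0).
    """
    _check_fit_matches(pairs, fit)
    if fit.ss_tot == 0.0:
        raise DegenerateDataError(
            "observed values are constant (zero total sum of squares); "
            "r-squared is undefined"
        )
    return 1.0 - fit.ss_res / fit.ss_tot


def _denominator(fit: LineFit, dof_convention: str) -> int:
    if dof_convention not in _DOF_CONVENTIONS:
        raise ValueError(
            f"dof_convention must be one of {_DOF_CONVENTIONS}, got "
            f"{dof_convention!r}"
        )
    if dof_convention == "n":
        return fit.n
    # "see": standard-error-of-estimate emulation.  The identity line
    # involves no fit, so plain n; any fitted line is treated by regression
    # software as the two-parameter model y = a + b·x even when the slope is
    # constrained, so n − 2.
    return fit.n if fit.case is ConstraintCase.VAL else fit.n - 2


def rmse(
    pairs: PairedPredictions, fit: LineFit, dof_convention: DofConvention = "n"
) -> float:
    """Root-mean-square error sqrt(SS_res / d) about the fit's line.

    With the default ``dof_convention="n"`` the denominator d is the pair
    count for all three cases, which preserves the exact decomposition
    RMSE_val² = RMSE_bias² + bias².  With ``"see"`` the denominator is n − 2
    for the BIAS and PEARSON cases (the "standard error of estimate" that
    curve-fitting software prints for a fitted line) and n for VAL.

    Raises
    ------
    ValueError
        If the denominator is not positive.  Valid pairs have n ≥ 3, so
        this can only happen for a hand-built LineFit with a smaller n.
    """
    _check_fit_matches(pairs, fit)
    d = _denominator(fit, dof_convention)
    if d <= 0:
        raise ValueError(
            f"non-positive RMSE denominator {d} (n={fit.n}, "
            f"convention={dof_convention!r})"
        )
    return math.sqrt(fit.ss_res / d)


def pearson_r(pairs: PairedPredictions) -> float:
    """Pearson product-moment correlation between x_calc and y_obs.

    r = Σ(x−<x>)(y−<y>) / sqrt(Σ(x−<x>)² · Σ(y−<y>)²), clipped to [−1, 1]
    only against floating-point overshoot.  Its square equals the
    PEARSON-case r².

    Raises
    ------
    DegenerateDataError
        If either column has zero variance.
    """
    x = pairs.x_calc
    y = pairs.y_obs
    dx = x - x.mean()
    dy = y - y.mean()
    s_xx = float(np.sum(dx * dx))
    s_yy = float(np.sum(dy * dy))
    if s_xx == 0.0 or s_yy == 0.0:
        which = "x_calc" if s_xx == 0.0 else "y_obs"
        raise DegenerateDataError(
            f"{which} has zero variance; Pearson's r is undefined"
        )
    r = float(np.sum(dx * dy) / math.sqrt(s_xx * s_yy))
    return min(1.0, max(-1.0, r))


def evaluate(
    pairs: PairedPredictions, dof_convention: DofConvention = "n"
) -> StatReport:
    """Compute the full statistics block for one dataset.

    Runs all three constrained fits and assembles r² and RMSE for each,
    plus the bias (BIAS-case intercept) and slope (PEARSON-case slope).
    Errors raised by an individual fit or statistic are re-raised with the
    offending case named.
    """
    fits: dict[ConstraintCase, LineFit] = {}
    r2: dict[ConstraintCase, float] = {}
    rm: dict[ConstraintCase, float] = {}
    for case in ConstraintCase:
        try:
            f = fit_line(pairs, case)
            r2[case] = r_squared(pairs, f)
            rm[case] = rmse(pairs, f, dof_convention)
        except (DegenerateDataError, ValidationError, ValueError) as exc:
            raise type(exc)(f"[case {case.value}] {exc}") from exc
        fits[case] = f
    return StatReport(
        r2_val=r2[ConstraintCase.VAL],
        r2_bias=r2[ConstraintCase.BIAS],
        r2_pearson=r2[ConstraintCase.PEARSON],
        rmse_val=rm[ConstraintCase.VAL],
        rmse_bias=rm[ConstraintCase.BIAS],
        rmse_pearson=rm[ConstraintCase.PEARSON],
        bias=fits[ConstraintCase.BIAS].a,
        slope=fits[ConstraintCase.PEARSON].b,
        n=pairs.n,
        group=pairs.group,
        dof_convention=dof_convention,
    )
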