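"""Ferrozine-style iron chelation activity from absorbance readings.

Chelation activity of a test solution is the fractional loss of the
iron-ferrozine complex absorbance relative to a compound-free control,

    activity = 100 * (A_control - A_x) / A_control   [percent]

so 0% means no chelation (A_x = A_control) and 100% complete chelation
(A_x = 0). A line of best fit of activity against log10 concentration
gives the concentration at 50% activity by inversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ChelationResult", "chelation_activity", "chelation_curve"]


@dataclass(frozen=True)
class ChelationResult:
    """Fitted activity line and the 50%-activity concentration.

    ``conc_at_50`` is None (with ``in_range`` False) when the fitted
    line's 50% crossing falls more than one decade outside the tested
    concentration range, or when the line is too flat to cross at all.
    """

    table: pd.DataFrame
    slope: float
    intercept: float
    r_value: float
    conc_at_50: float | None
    in_range: bool


def chelation_activity(a_control, a_x):
    """Percent chelation activity from control and compound absorbances.

    Accepts scalars or arrays; negative activity (A_x above control) is
    reported as-is so a pro-chromogenic artifact remains visible.
    """
    a_control = np.asarray(a_control, dtype=float)
    a_x = np.asarray(a_x, dtype=float)
    if np.any(a_control <= 0):
        raise ValueError("control absorbance must be > 0")
    out = 100.0 * (a_control - a_x) / a_control
    return float(out) if out.ndim == 0 else out


def chelation_curve(
    concentrations,
    activities,
    scale: str = "log10",
) -> ChelationResult:
    """OLS line of activity on (log) concentration and its 50% crossing.

    ``scale="log10"`` (default) regresses on log10 molar concentration,
    appropriate for series spanning decades; ``scale="linear"`` uses the
    raw concentration.
    """
    conc = np.asarray(concentrations, dtype=float)
    act = np.asarray(activities, dtype=float)
    if conc.size != act.size or conc.size < 3:
        raise ValueError("need >= 3 paired (concentration, activity) points")
    if scale not in ("log10", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    if scale == "log10":
        if np.any(conc <= 0):
            raise ValueError("log10 scale requires positive concentrations")
        x = np.log10(conc)
    else:
        x = conc
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the concentration predictor")

    fit = stats.linregress(x, act)
    slope, intercept = float(fit.slope), float(fit.intercept)

    conc_at_50: float | None = None
    in_range = False
    if slope != 0:
        x50 = (50.0 - intercept) / slope
        if scale == "log10":
            # allow one decade of extrapolation beyond the tested range
            if x.min() - 1.0 <= x50 <= x.max() + 1.0:
                conc_at_50 = float(10.0 ** x50)
                in_range = True
        else:
            span = np.ptp(x)
            if x.min() - span <= x50 <= x.max() + span and x50 > 0:
                conc_at_50 = float(x50)
                in_range = True
    table = pd.DataFrame({"concentration_molar": conc, "activity_pct": act})
    return ChelationResult(table=table, slope=slope, intercept=intercept,
                           r_value=float(fit.rvalue), conc_at_50=conc_at_50,
                           in_range=in_range)
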