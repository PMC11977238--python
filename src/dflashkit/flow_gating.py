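"""Event-level gating of dual-fluorescence flow distributions.

The positivity threshold is the empirical top-1% quantile of the
negative-control Tomato distribution; percent positive and MFI fold
changes of a treated sample follow from it. Histograms are binned in
log10 intensity and normalized to mode (peak bin scaled to 1), the
standard presentation for cytometry overlays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GateResult",
    "HistogramResult",
    "derive_positive_threshold",
    "gate_summary",
    "mode_normalised_histogram",
]


@dataclass(frozen=True)
class GateResult:
    """Gate threshold and the summary statistics it implies."""

    threshold: float
    pct_positive: float
    mfi_control: float
    mfi_treated: float
    fold_mfi: float
    n_control: int
    n_treated: int


@dataclass(frozen=True)
class HistogramResult:
    """Mode-normalized log10-intensity histogram.

    ``n_dropped_nonpositive`` flags events that could not be log-scaled
    and were excluded from binning.
    """

    bin_edges_log10: np.ndarray
    heights: np.ndarray
    n_dropped_nonpositive: int


def _tomato(events) -> np.ndarray:
    if isinstance(events, pd.DataFrame):
        return events["tomato"].to_numpy(float)
    return np.asarray(events, dtype=float)


def derive_positive_threshold(control_events, top_fraction: float = 0.01
                              ) -> float:
    """Positivity cut at the (1 - top_fraction) control quantile.

    Linear-interpolation quantile of the control Tomato intensities;
    requires at least 1/top_fraction events so the quantile is supported
    by the sample.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    tom = _tomato(control_events)
    if tom.size < math.ceil(1.0 / top_fraction):
        raise ValueError(
            f"too few control events ({tom.size}) for the top "
            f"{100 * top_fraction:g}% quantile")
    return float(np.quantile(tom, 1.0 - top_fraction))


def gate_summary(
    control_events,
    treated_events,
    gfp_gate: float | None = None,
    top_fraction: float = 0.01,
    mfi_stat: str = "median",
) -> GateResult:
    """Gate a treated sample against its paired negative control.

    With ``gfp_gate`` given, events below it are dropped from both
    samples first (reporter-positive pre-gate on the internal control
    channel). ``mfi_stat`` selects median (robust, default) or mean
    fluorescence.
    """
    if mfi_stat not in ("median", "mean"):
        raise ValueError(f"unknown mfi_stat {mfi_stat!r}")
    control = control_events
    treated = treated_events
    if gfp_gate is not None:
        if not isinstance(control, pd.DataFrame):
            raise ValueError("gfp_gate requires event tables with a gfp column")
        control = control[control["gfp"] >= gfp_gate]
        treated = treated[treated["gfp"] >= gfp_gate]
        if len(control) == 0 or len(treated) == 0:
            raise ValueError("gfp_gate removed all events from a sample")
    tom_c = _tomato(control)
    tom_t = _tomato(treated)
    if tom_c.size == 0 or tom_t.size == 0:
        raise ValueError("both samples must be non-empty")
    threshold = derive_positive_threshold(tom_c, top_fraction)
    stat = np.median if mfi_stat == "median" else np.mean
    mfi_c = float(stat(tom_c))
    mfi_t = float(stat(tom_t))
    return GateResult(
        threshold=threshold,
        pct_positive=float(100.0 * np.mean(tom_t > threshold)),
        mfi_control=mfi_c,
        mfi_treated=mfi_t,
        fold_mfi=mfi_t / mfi_c if mfi_c > 0 else math.nan,
        n_control=int(tom_c.size),
        n_treated=int(tom_t.size),
    )


def mode_normalised_histogram(events, bins: int = 64) -> HistogramResult:
    """log10-binned intensity histogram with the peak bin scaled to 1."""
    x = _tomato(events)
    if x.size < 1:
        raise ValueError("need at least one event")
    positive = x[x > 0]
    dropped = int(x.size - positive.size)
    if positive.size == 0:
        raise ValueError("all intensities non-positive; cannot log-scale")
    logx = np.log10(positive)
    if logx.min() == logx.max():  # single distinct value -> one full bin
        edges = np.array([logx.min() - 0.5, logx.min() + 0.5])
        return HistogramResult(edges, np.array([1.0]), dropped)
    counts, edges = np.histogram(logx, bins=bins)
    return HistogramResult(edges, counts / counts.max(), dropped)
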