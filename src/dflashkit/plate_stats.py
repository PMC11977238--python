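"""Plate-level screening robustness metrics and kinetics summaries.

The screening-window statistic Z' = 1 - 3(sigma+ + sigma-)/|mu+ - mu-|
(Zhang's separation-window form, sample SDs) and the positive/negative
fold change are computed per plate on a configurable reporter value —
the Tomato/EGFP ratio by default, raw Tomato optionally. A Z' above 0.5
conventionally denotes an excellent assay window.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlateQC",
    "KineticsSeries",
    "zprime",
    "fold_change",
    "plate_qc",
    "robustness_summary",
    "kinetics_summary",
]


@dataclass(frozen=True)
class PlateQC:
    """Control statistics and quality metrics for one plate."""

    plate: str
    mu_pos: float
    mu_neg: float
    sigma_pos: float
    sigma_neg: float
    zprime: float
    fold_change: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class KineticsSeries:
    """Per-(group, timepoint) mean +/- sem and the detected onset time.

    ``onset_h`` is the earliest timepoint from which the induced group's
    mean exceeds vehicle mean + 3 vehicle SD at that and every later
    timepoint; None when separation is never sustained.
    """

    table: pd.DataFrame
    onset_h: float | None


def _control_arrays(pos_values, neg_values):
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need >= 2 values per control group")
    return pos, neg


def zprime(pos_values, neg_values) -> float:
    """Screening-window score 1 - 3(s+ + s-)/|m+ - m-| (sample SDs)."""
    pos, neg = _control_arrays(pos_values, neg_values)
    mu_p, mu_n = pos.mean(), neg.mean()
    if mu_p == mu_n:
        raise ValueError("zero separation: control means are equal")
    s_p = pos.std(ddof=1)
    s_n = neg.std(ddof=1)
    return float(1.0 - 3.0 * (s_p + s_n) / abs(mu_p - mu_n))


def fold_change(pos_values, neg_values) -> float:
    """Positive/negative control mean ratio."""
    pos, neg = _control_arrays(pos_values, neg_values)
    mu_n = neg.mean()
    if mu_n <= 0:
        raise ValueError(f"non-positive negative-control mean ({mu_n:g})")
    return float(pos.mean() / mu_n)


def plate_qc(
    wells: pd.DataFrame,
    layout: pd.DataFrame | None = None,
    value_col: str = "ratio",
    pos_role: str = "positive",
    neg_role: str = "vehicle",
) -> list[PlateQC]:
    """Per-plate Z' and fold change from a well table.

    ``wells`` needs plate/well/``value_col`` columns and a role column
    either in place or joined from ``layout``. ``value_col`` selects the
    reporter value — the Tomato/EGFP ratio by default, or ``tom_mean``
    for a raw-Tomato reading. Wells with a ``sufficient_n`` flag set to
    False are dropped with a warning.
    """
    df = wells
    if "role" not in df.columns:
        if layout is None:
            raise ValueError("wells lack a role column and no layout given")
        df = df.merge(layout[["plate", "well", "role"]], on=["plate", "well"],
                      how="left")
    if value_col not in df.columns:
        raise ValueError(f"well table has no column {value_col!r}")
    if "sufficient_n" in df.columns:
        bad = ~df["sufficient_n"].astype(bool)
        if bad.any():
            warnings.warn(
                f"dropping {int(bad.sum())} well(s) failing the minimum "
                "nucleus count", stacklevel=2)
            df = df[~bad]

    out: list[PlateQC] = []
    for plate, grp in df.groupby("plate", sort=True):
        pos = grp.loc[grp["role"] == pos_role, value_col].to_numpy(float)
        neg = grp.loc[grp["role"] == neg_role, value_col].to_numpy(float)
        if pos.size < 2 or neg.size < 2:
            raise ValueError(
                f"plate {plate}: need >= 2 usable wells per control role "
                f"(got {pos.size} {pos_role}, {neg.size} {neg_role})")
        out.append(PlateQC(
            plate=str(plate),
            mu_pos=float(pos.mean()),
            mu_neg=float(neg.mean()),
            sigma_pos=float(pos.std(ddof=1)),
            sigma_neg=float(neg.std(ddof=1)),
            zprime=zprime(pos, neg),
            fold_change=fold_change(pos, neg),
            n_pos=int(pos.size),
            n_neg=int(neg.size),
        ))
    return out


def robustness_summary(plates: list[PlateQC]) -> tuple[pd.DataFrame, dict]:
    """Tabulate per-plate QC and summarize mean/min Z' and mean FC."""
    if not plates:
        raise ValueError("no plates to summarize")
    table = pd.DataFrame([vars(p) for p in plates])
    summary = {
        "n_plates": len(plates),
        "mean_zprime": float(table["zprime"].mean()),
        "min_zprime": float(table["zprime"].min()),
        "mean_fold_change": float(table["fold_change"].mean()),
    }
    return table, summary


def kinetics_summary(
    wells: pd.DataFrame,
    induced_group: str = "induced",
    vehicle_group: str = "vehicle",
    value_col: str = "ratio",
) -> KineticsSeries:
    """Mean +/- sem per (group, timepoint) and a sustained-onset estimate.

    Onset is called at the earliest timepoint from which the induced
    mean stays above vehicle mean + 3 vehicle SD through the end of the
    series; with no induced group (or no sustained separation) onset is
    None.
    """
    for col in ("group", "timepoint_h", value_col):
        if col not in wells.columns:
            raise ValueError(f"kinetics table has no column {col!r}")
    present = set(wells["group"])
    if vehicle_group not in present:
        raise ValueError(f"group {vehicle_group!r} absent from data")
    has_induced = induced_group in present

    agg = (wells.groupby(["group", "timepoint_h"])[value_col]
           .agg(mean="mean", sem=stats.sem, n="size").reset_index())
    if (agg["n"] < 2).any():
        raise ValueError("need >= 2 replicates per (group, timepoint)")

    onset: float | None = None
    if has_induced:
        veh = (wells[wells["group"] == vehicle_group]
               .groupby("timepoint_h")[value_col].agg(["mean", "std"]))
        ind = (wells[wells["group"] == induced_group]
               .groupby("timepoint_h")[value_col].mean())
        times = np.array(sorted(set(veh.index) & set(ind.index)))
        separated = np.array([
            ind.loc[t] > veh.loc[t, "mean"] + 3.0 * veh.loc[t, "std"]
            for t in times])
        # earliest time from which separation is sustained to the end
        sustained = np.logical_and.accumulate(separated[::-1])[::-1]
        if sustained.any():
            onset = float(times[np.argmax(sustained)])
    return KineticsSeries(table=agg, onset_h=onset)
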