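"""Bimodal compound-screen hit calling.

Two sequential phases are screened on the same compound wells: phase 1
(unstimulated) calls activators, phase 2 (all wells stimulated) calls
inhibitors. Normalized reporter output (Tomato/EGFP ratio) and EGFP MFI
are z-scored against the compound-well population of each phase and
replicate; compounds whose EGFP z leaves the +/-2 SD window are excluded
as fluorescence artifacts regardless of reporter z, then activators are
called at ratio z >= +2 and inhibitors at ratio z <= -2. Replicate
screens are intersected to give confirmed hits, and replicate
consistency is assessed by Pearson correlation of the z-scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreenResult",
    "zscore_wells",
    "classify_compounds",
    "hit_rate",
    "run_bimodal_screen",
    "intersect_replicates",
    "replicate_correlation",
]

CALL_CLASSES = ("activator", "inhibitor", "excluded_fluorescent", "inactive")


def zscore_wells(values, reference, robust: bool = False) -> np.ndarray:
    """z-scores of ``values`` against a reference population.

    Classical: (x - mean)/sd (sample SD). Robust mode centres on the
    median and scales by 1.4826 * MAD, which keeps gross outliers from
    inflating the scale.
    """
    x = np.asarray(values, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if ref.size < 3:
        raise ValueError("reference population needs >= 3 values")
    if robust:
        centre = np.median(ref)
        scale = 1.4826 * np.median(np.abs(ref - centre))
    else:
        centre = ref.mean()
        scale = ref.std(ddof=1)
    if scale <= 0:
        raise ValueError("reference population has zero spread")
    return (x - centre) / scale


def classify_compounds(
    phase_table: pd.DataFrame,
    mode: str,
    z_ratio_threshold: float = 2.0,
    z_egfp_threshold: float = 2.0,
) -> pd.Series:
    """Per-compound call from precomputed z-scores.

    ``phase_table`` needs ``z_ratio`` and ``z_egfp`` columns. The EGFP
    artifact exclusion takes precedence: |z_egfp| > threshold means
    ``excluded_fluorescent`` whatever the ratio does. Otherwise activator
    mode calls ratio z >= +t, inhibitor mode ratio z <= -t; boundary
    values count as hits so behaviour at exactly 2.0 is defined.
    """
    if mode not in ("activator", "inhibitor"):
        raise ValueError(f"unknown mode {mode!r}")
    if z_ratio_threshold <= 0 or z_egfp_threshold <= 0:
        raise ValueError("z thresholds must be positive")
    z_ratio = phase_table["z_ratio"].to_numpy(float)
    z_egfp = phase_table["z_egfp"].to_numpy(float)
    calls = np.full(len(phase_table), "inactive", dtype=object)
    if mode == "activator":
        calls[z_ratio >= z_ratio_threshold] = "activator"
    else:
        calls[z_ratio <= -z_ratio_threshold] = "inhibitor"
    calls[np.abs(z_egfp) > z_egfp_threshold] = "excluded_fluorescent"
    return pd.Series(calls, index=phase_table.index, name="call")


def hit_rate(n_hits: int, n_compounds: int, decimals: int = 1) -> float:
    """Percent of the screened library called as hits (one decimal)."""
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    return round(100.0 * n_hits / n_compounds, decimals)


@dataclass(frozen=True)
class ScreenResult:
    """Everything the bimodal screen produces.

    ``calls``: long table (compound_id, phase, replicate, z_ratio,
    z_egfp, z_tom, call). ``phase_summary``: hits and hit rates per
    phase x replicate. ``confirmed``: replicate-intersected hits per
    phase; ``combined_hit_rate``: their rate over the library.
    ``pearson``: replicate-consistency correlations per phase/subset.
    """

    calls: pd.DataFrame
    phase_summary: pd.DataFrame
    confirmed: dict[int, list[str]]
    combined_hit_rate: dict[int, float]
    pearson: pd.DataFrame
    n_compounds: int

    def hits(self, phase: int, replicate: int) -> list[str]:
        target = "activator" if phase == 1 else "inhibitor"
        sel = self.calls[(self.calls["phase"] == phase)
                         & (self.calls["replicate"] == replicate)
                         & (self.calls["call"] == target)]
        return sorted(sel["compound_id"])


def _compound_rows(table: pd.DataFrame) -> pd.DataFrame:
    if "role" in table.columns:
        table = table[table["role"] == "compound"]
    missing = [c for c in ("compound_id", "egfp_mean", "tom_mean", "ratio")
               if c not in table.columns]
    if missing:
        raise ValueError(f"screen table missing column(s): {missing}")
    return table.reset_index(drop=True)


def run_bimodal_screen(
    phase1_tables: list[pd.DataFrame],
    phase2_tables: list[pd.DataFrame],
    z_ratio_threshold: float = 2.0,
    z_egfp_threshold: float = 2.0,
    robust: bool = False,
) -> ScreenResult:
    """Classify both phases across replicate screens and summarize.

    Each tables list holds one well table per replicate screen (singlet
    compound wells). The z reference is the compound-well population of
    that phase and replicate. Raises if the compound sets differ between
    any two tables, listing the mismatch.
    """
    if len(phase1_tables) != len(phase2_tables) or not phase1_tables:
        raise ValueError("need the same (nonzero) replicate count per phase")
    prepared: dict[tuple[int, int], pd.DataFrame] = {}
    ref_ids: set[str] | None = None
    for phase, tables in ((1, phase1_tables), (2, phase2_tables)):
        for rep, table in enumerate(tables, start=1):
            df = _compound_rows(table)
            ids = set(df["compound_id"])
            if ref_ids is None:
                ref_ids = ids
            elif ids != ref_ids:
                diff = sorted(ids.symmetric_difference(ref_ids))
                raise ValueError(
                    f"compound sets differ (phase {phase}, replicate {rep}); "
                    f"mismatched ids: {diff[:20]}"
                    + (" ..." if len(diff) > 20 else ""))
            prepared[(phase, rep)] = df
    assert ref_ids is not None
    n_compounds = len(ref_ids)
    n_reps = len(phase1_tables)

    call_frames = []
    summary_rows = []
    for (phase, rep), df in sorted(prepared.items()):
        mode = "activator" if phase == 1 else "inhibitor"
        z = pd.DataFrame({
            "compound_id": df["compound_id"],
            "phase": phase,
            "replicate": rep,
            "z_ratio": zscore_wells(df["ratio"], df["ratio"], robust),
            "z_egfp": zscore_wells(df["egfp_mean"], df["egfp_mean"], robust),
            "z_tom": zscore_wells(df["tom_mean"], df["tom_mean"], robust),
        })
        z["call"] = classify_compounds(z, mode, z_ratio_threshold,
                                       z_egfp_threshold)
        call_frames.append(z)
        n_hits = int((z["call"] == mode).sum())
        summary_rows.append({
            "phase": phase,
            "replicate": rep,
            "mode": mode,
            "n_compounds": n_compounds,
            "n_hits": n_hits,
            "hit_rate_pct": hit_rate(n_hits, n_compounds),
            "n_excluded_fluorescent":
                int((z["call"] == "excluded_fluorescent").sum()),
        })
    calls = pd.concat(call_frames, ignore_index=True)
    phase_summary = pd.DataFrame(summary_rows)

    confirmed: dict[int, list[str]] = {}
    combined_rate: dict[int, float] = {}
    for phase in (1, 2):
        target = "activator" if phase == 1 else "inhibitor"
        per_rep = [set(calls[(calls["phase"] == phase)
                             & (calls["replicate"] == r)
                             & (calls["call"] == target)]["compound_id"])
                   for r in range(1, n_reps + 1)]
        confirmed[phase] = intersect_replicates(per_rep)
        combined_rate[phase] = hit_rate(len(confirmed[phase]), n_compounds,
                                        decimals=2)

    pearson_rows = []
    if n_reps >= 2:
        for phase in (1, 2):
            target = "activator" if phase == 1 else "inhibitor"
            wide = calls[calls["phase"] == phase].pivot(
                index="compound_id", columns="replicate", values="z_ratio")
            try:
                r, p = replicate_correlation(wide[1], wide[2])
            except ValueError:
                r, p = math.nan, math.nan
            pearson_rows.append({"phase": phase, "subset": "all",
                                 "n": len(wide), "r": r, "p": p})
            by_call = calls[(calls["phase"] == phase)
                            & (calls["call"] == target)]
            subset = sorted(set(by_call["compound_id"]))  # union over reps
            if len(subset) >= 3:
                sub = wide.loc[subset]
                try:
                    r, p = replicate_correlation(sub[1], sub[2])
                except ValueError:
                    r, p = math.nan, math.nan
            else:
                r, p = math.nan, math.nan
            pearson_rows.append({"phase": phase, "subset": target,
                                 "n": len(subset), "r": r, "p": p})
    pearson = pd.DataFrame(pearson_rows,
                           columns=["phase", "subset", "n", "r", "p"])
    return ScreenResult(calls=calls, phase_summary=phase_summary,
                        confirmed=confirmed, combined_hit_rate=combined_rate,
                        pearson=pearson, n_compounds=n_compounds)


def intersect_replicates(hit_sets: list[set[str]]) -> list[str]:
    """Hits confirmed in every replicate (sorted set intersection)."""
    if not hit_sets:
        return []
    confirmed = set(hit_sets[0])
    for s in hit_sets[1:]:
        confirmed &= set(s)
    return sorted(confirmed)


def replicate_correlation(z1, z2) -> tuple[float, float]:
    """Pearson r (with two-sided p) between paired replicate z-scores."""
    a = np.asarray(z1, dtype=float)
    b = np.asarray(z2, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need >= 3 paired values")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a replicate vector")
    with warnings.catch_warnings():
        # near-constant input degrades to the zero-variance error path
        warnings.simplefilter("error", stats.ConstantInputWarning)
        try:
            res = stats.pearsonr(a, b)
        except stats.ConstantInputWarning as exc:
            raise ValueError("zero variance in a replicate vector") from exc
    return float(res.statistic), float(res.pvalue)
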