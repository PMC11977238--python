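"""Synthetic dual-reporter data with planted ground truth.

Every input the analysis stages consume — two-channel nuclear image
fields, 96-well plates, two-phase compound screens, induction kinetics,
agonist dose-response tables and flow-cytometry event lists — can be
generated here with full knowledge of the truth that was planted, so the
whole pipeline is testable without any instrument data.

Intensity model: per-cell EGFP and basal Tomato are lognormal; signal
induction multiplies Tomato by a configured fold in the responding
fraction of cells. Well-level summaries add a size factor shared by both
channels (cancelled by the Tomato/EGFP ratio) plus a smaller independent
per-channel residual. All tabular noise is mean-preserving Gaussian
multiplicative, ``x * (1 + cv * N(0,1))``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import SimConfig

__all__ = [
    "ImageField",
    "GroundTruth",
    "PlacementError",
    "simulate_image_field",
    "hts_layout",
    "simulate_plate",
    "ScreenTruth",
    "simulate_screen",
    "fold_for_z",
    "ratio_cv",
    "egfp_cv",
    "simulate_kinetics",
    "default_doses",
    "simulate_dose_response",
    "simulate_flow_events",
    "fourpl",
]

TRUTH_COLUMNS = [
    "id", "row", "col", "radius", "true_egfp", "true_tom",
    "border_flag", "cluster_flag", "abnormal_flag", "induced_flag",
]

VALID_ROLES = frozenset({"vehicle", "positive", "compound"})

LAYOUT_COLUMNS = ["plate", "well", "role", "treatment",
                  "compound_id", "dose", "phase"]


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed at the requested density."""


@dataclass(frozen=True)
class ImageField:
    """Co-registered two-channel field: EGFP (control) and Tomato (signal)."""

    egfp: np.ndarray
    tom: np.ndarray

    def __post_init__(self) -> None:
        if self.egfp.shape != self.tom.shape:
            raise ValueError("channels must be co-registered (same shape)")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for one field: label mask plus per-nucleus table.

    ``label_mask`` holds 0 for background and k for nucleus k; rows of
    ``table`` are in bijection with the nonzero labels.
    """

    label_mask: np.ndarray
    table: pd.DataFrame


def _rand_radius(rng: np.random.Generator, cfg: SimConfig) -> float:
    mean, sd = cfg.nucleus_radius
    return max(2.0, float(rng.normal(mean, sd)))


def _disk_pixels(shape, row, col, radius):
    """Integer pixel coordinates with centre distance <= radius, clipped."""
    h, w = shape
    r0 = max(0, int(math.floor(row - radius)))
    r1 = min(h - 1, int(math.ceil(row + radius)))
    c0 = max(0, int(math.floor(col - radius)))
    c1 = min(w - 1, int(math.ceil(col + radius)))
    rr, cc = np.mgrid[r0:r1 + 1, c0:c1 + 1]
    inside = (rr - row) ** 2 + (cc - col) ** 2 <= radius ** 2
    return rr[inside], cc[inside]


def simulate_image_field(
    config: SimConfig,
    induced: bool = False,
    seed: int = 0,
) -> tuple[ImageField, GroundTruth]:
    """Render one two-channel field and its planted per-nucleus truth.

    Nuclei are uniform disks (optionally Gaussian-blurred via
    ``config.blur_sigma``); the per-channel mean over each nucleus mask
    equals the planted truth value exactly when blur and noise are off.
    ``induced=True`` multiplies Tomato truth by ``induction_fold`` in
    responder cells. Placement is rejection-sampled with bounded retries.
    """
    rng = np.random.default_rng(seed)
    h, w = config.field_shape
    n = config.n_nuclei_per_field

    empty_truth = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        TRUTH_COLUMNS,
        [int, float, float, float, float, float, bool, bool, bool, bool])})

    if n == 0:
        egfp = np.full((h, w), config.background_level, dtype=float)
        tom = egfp.copy()
        if config.noise_sd > 0:
            egfp = egfp + rng.normal(0, config.noise_sd, (h, w))
            tom = tom + rng.normal(0, config.noise_sd, (h, w))
        return (ImageField(np.clip(egfp, 0, None), np.clip(tom, 0, None)),
                GroundTruth(np.zeros((h, w), dtype=np.int32), empty_truth))

    n_cluster = int(round(config.cluster_fraction * n / 2)) * 2
    n_rest = n - n_cluster
    n_border = min(n_rest, int(round(config.border_fraction * n)))
    n_abnormal = min(n_rest - n_border,
                     int(round(config.abnormal_fraction * n)))
    n_interior = n_rest - n_border - n_abnormal

    placed: list[tuple[float, float, float]] = []  # (row, col, radius)
    flags: list[tuple[bool, bool, bool]] = []      # (border, cluster, abn)
    max_tries = 200 * n

    def clear_of_others(row, col, radius, skip_last=0):
        pool = placed[:len(placed) - skip_last] if skip_last else placed
        for (pr, pc, prad) in pool:
            if (pr - row) ** 2 + (pc - col) ** 2 < (prad + radius + 3) ** 2:
                return True
        return False

    def place_one(radius, border=False):
        for _ in range(max_tries):
            if border:
                edge = rng.integers(4)
                along = rng.uniform(radius + 1, (w if edge < 2 else h) - radius - 2)
                off = rng.uniform(0, max(radius - 1.5, 0.0))
                if edge == 0:
                    row, col = off, along
                elif edge == 1:
                    row, col = h - 1 - off, along
                elif edge == 2:
                    row, col = along, off
                else:
                    row, col = along, w - 1 - off
            else:
                row = rng.uniform(radius + 1.5, h - radius - 2.5)
                col = rng.uniform(radius + 1.5, w - radius - 2.5)
            if not clear_of_others(row, col, radius):
                return row, col
        raise PlacementError(
            f"failed to place {n} nuclei of mean radius "
            f"{config.nucleus_radius[0]:.1f} px in a {h}x{w} field; "
            "reduce n_nuclei_per_field or enlarge field_shape")

    # largest footprints first so rejection sampling does not jam
    for _ in range(n_cluster // 2):
        # pair members at the mean radius with 1.4 r separation: the
        # merged component's area is ~1.8x a single nucleus, cleanly
        # above the unseparated-cluster cutoff yet below two singles
        radius = config.nucleus_radius[0]
        for _ in range(max_tries):
            row, col = place_one(2 * radius)  # clearance for the pair
            theta = rng.uniform(0, 2 * math.pi)
            sep = 1.4 * radius
            row2 = row + sep * math.sin(theta)
            col2 = col + sep * math.cos(theta)
            if (radius + 1 < row2 < h - radius - 2
                    and radius + 1 < col2 < w - radius - 2):
                break
        else:  # pragma: no cover - bounded by place_one already
            raise PlacementError("failed to place overlapping pair")
        placed.append((row, col, radius))
        flags.append((False, True, False))
        placed.append((row2, col2, radius))
        flags.append((False, True, False))

    for _ in range(n_abnormal):
        radius = config.abnormal_radius_factor * config.nucleus_radius[0]
        row, col = place_one(radius)
        placed.append((row, col, radius))
        flags.append((False, False, True))

    for _ in range(n_border):
        radius = _rand_radius(rng, config)
        row, col = place_one(radius, border=True)
        placed.append((row, col, radius))
        flags.append((True, False, False))

    for _ in range(n_interior):
        radius = _rand_radius(rng, config)
        row, col = place_one(radius)
        placed.append((row, col, radius))
        flags.append((False, False, False))

    n_total = len(placed)
    true_egfp = rng.lognormal(config.egfp_mu, config.egfp_sigma, n_total)
    true_tom = rng.lognormal(config.basal_tom_mu, config.basal_tom_sigma,
                             n_total)
    if induced:
        induced_flag = rng.random(n_total) < config.responder_fraction
        true_tom = np.where(induced_flag,
                            true_tom * config.induction_fold, true_tom)
    else:
        induced_flag = np.zeros(n_total, dtype=bool)

    label_mask = np.zeros((h, w), dtype=np.int32)
    egfp_fg = np.zeros((h, w), dtype=float)
    tom_fg = np.zeros((h, w), dtype=float)
    for k, (row, col, radius) in enumerate(placed, start=1):
        rr, cc = _disk_pixels((h, w), row, col, radius)
        label_mask[rr, cc] = k
        egfp_fg[rr, cc] = true_egfp[k - 1]
        tom_fg[rr, cc] = true_tom[k - 1]

    if config.blur_sigma > 0:
        egfp_fg = ndimage.gaussian_filter(egfp_fg, config.blur_sigma)
        tom_fg = ndimage.gaussian_filter(tom_fg, config.blur_sigma)

    egfp = config.background_level + egfp_fg
    tom = config.background_level + tom_fg
    if config.noise_sd > 0:
        egfp = egfp + rng.normal(0, config.noise_sd, (h, w))
        tom = tom + rng.normal(0, config.noise_sd, (h, w))

    table = pd.DataFrame({
        "id": np.arange(1, n_total + 1),
        "row": [p[0] for p in placed],
        "col": [p[1] for p in placed],
        "radius": [p[2] for p in placed],
        "true_egfp": true_egfp,
        "true_tom": true_tom,
        "border_flag": [f[0] for f in flags],
        "cluster_flag": [f[1] for f in flags],
        "abnormal_flag": [f[2] for f in flags],
        "induced_flag": induced_flag,
    })
    return (ImageField(np.clip(egfp, 0, None), np.clip(tom, 0, None)),
            GroundTruth(label_mask, table))


# ---------------------------------------------------------------------------
# plates
# ---------------------------------------------------------------------------

def _well_name(index: int) -> str:
    """A01..H12 for a 96-well plate, row-major."""
    row, col = divmod(index, 12)
    if row > 7:
        raise ValueError("96-well plate has only 96 wells")
    return f"{chr(ord('A') + row)}{col + 1:02d}"


def hts_layout(n_plates: int = 10, n_positive: int = 6, n_vehicle: int = 6,
               treatment: str = "DMOG") -> pd.DataFrame:
    """Plate map for a control-only HTS robustness run.

    Each plate carries ``n_vehicle`` vehicle and ``n_positive``
    positive-control (stimulated) wells; no compound wells.
    """
    rows = []
    for plate in range(1, n_plates + 1):
        idx = 0
        for _ in range(n_vehicle):
            rows.append((f"P{plate:02d}", _well_name(idx), "vehicle",
                         "vehicle", "", np.nan, 1))
            idx += 1
        for _ in range(n_positive):
            rows.append((f"P{plate:02d}", _well_name(idx), "positive",
                         treatment, "", np.nan, 1))
            idx += 1
    return pd.DataFrame(rows, columns=LAYOUT_COLUMNS)


def _validate_layout(layout: pd.DataFrame) -> None:
    missing = [c for c in ("plate", "well", "role") if c not in layout.columns]
    if missing:
        raise ValueError(f"layout missing column(s): {', '.join(missing)}")
    bad = set(layout["role"]) - VALID_ROLES
    if bad:
        raise ValueError(
            f"unknown well role(s): {', '.join(map(str, sorted(bad)))}; "
            f"valid roles are {', '.join(sorted(VALID_ROLES))}")


def _tabular_well(rng, cfg: SimConfig, tom_multiplier: float,
                  egfp_multiplier: float = 1.0):
    """One well's (egfp_mean, tom_mean) draw.

    Noise is parameterized on the internal control and on the normalized
    reporter value: a size factor common to both channels (CV =
    ``well_cv``), a residual on EGFP (CV = ``residual_cv``) and an
    independent Gaussian residual on the Tomato/EGFP ratio (CV =
    sqrt(2) * ``residual_cv``); Tomato is their product. The ratio — the
    quantity every downstream statistic consumes — therefore carries
    exactly Gaussian mean-preserving noise, and all channel means are
    exact (independent factors).
    """
    rc = cfg.residual_cv
    f = 1.0 + cfg.well_cv * rng.normal()
    egfp = cfg.egfp_mean * egfp_multiplier * f * (1.0 + rc * rng.normal())
    ratio_expect = (cfg.basal_tom_mean * tom_multiplier
                    / (cfg.egfp_mean * egfp_multiplier))
    ratio = ratio_expect * (1.0 + math.sqrt(2.0) * rc * rng.normal())
    return egfp, egfp * ratio


def simulate_plate(
    config: SimConfig,
    layout: pd.DataFrame,
    mode: str = "tabular",
    seed: int = 0,
    n_fields_per_well: int = 1,
):
    """Simulate the wells of a plate map.

    ``tabular`` mode draws well-level EGFP/Tomato means directly around
    role-determined expectations (positive wells' expected Tomato is
    ``induction_fold`` times vehicle for full responders) — the fast path
    for statistics. ``image`` mode renders fields per well.

    Returns ``(wells_df, expectations_df)`` in tabular mode, or
    ``(fields_dict, layout)`` in image mode where ``fields_dict`` maps
    ``(plate, well)`` to a list of ``(ImageField, GroundTruth)``.
    """
    _validate_layout(layout)
    if mode not in ("tabular", "image"):
        raise ValueError(f"unknown mode {mode!r}; use 'tabular' or 'image'")
    rng = np.random.default_rng(seed)
    pos_mult = config.induced_tom_multiplier()

    if mode == "tabular":
        rows, expect = [], []
        for rec in layout.itertuples(index=False):
            mult = pos_mult if rec.role == "positive" else 1.0
            egfp, tom = _tabular_well(rng, config, mult)
            rows.append((rec.plate, rec.well, rec.role, egfp, tom,
                         tom / egfp))
            expect.append((rec.plate, rec.well, rec.role, config.egfp_mean,
                           config.basal_tom_mean * mult))
        wells = pd.DataFrame(rows, columns=[
            "plate", "well", "role", "egfp_mean", "tom_mean", "ratio"])
        expected = pd.DataFrame(expect, columns=[
            "plate", "well", "role", "expected_egfp", "expected_tom"])
        return wells, expected

    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(layout) * n_fields_per_well) % (2 ** 31)
    fields: dict[tuple[str, str], list] = {}
    i = 0
    for rec in layout.itertuples(index=False):
        f = 1.0 + config.well_cv * rng.normal()
        f = max(f, 0.05)
        well_cfg = dataclasses.replace(
            config,
            egfp_mu=config.egfp_mu + math.log(f),
            basal_tom_mu=config.basal_tom_mu + math.log(f),
        )
        well_fields = []
        for _ in range(n_fields_per_well):
            well_fields.append(simulate_image_field(
                well_cfg, induced=(rec.role == "positive"),
                seed=int(child_seeds[i])))
            i += 1
        fields[(rec.plate, rec.well)] = well_fields
    return fields, layout


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

SCREEN_CLASSES = ("inactive", "activator", "inhibitor",
                  "artifact_egfp_up", "artifact_egfp_down")

DEFAULT_EFFECT_FOLDS = {
    "activator": 2.0,
    "inhibitor": 0.4,
    "artifact_egfp_up": 1.5,
    "artifact_egfp_down": 0.6,
}


@dataclass(frozen=True)
class ScreenTruth:
    """Planted per-compound truth for a simulated screen.

    ``table`` columns: compound_id, true_class, tom_effect (multiplicative
    on Tomato in the phase where the class acts), egfp_effect.
    """

    table: pd.DataFrame

    def class_counts(self) -> pd.Series:
        return self.table["true_class"].value_counts()


def ratio_cv(config: SimConfig) -> float:
    """Small-noise CV of the well Tomato/EGFP ratio (shared factor cancels)."""
    return math.sqrt(2.0) * config.residual_cv


def egfp_cv(config: SimConfig) -> float:
    """Small-noise CV of the raw well EGFP mean (shared factor remains)."""
    return math.hypot(config.well_cv, config.residual_cv)


def fold_for_z(config: SimConfig, z: float, channel: str = "ratio") -> float:
    """Multiplicative effect producing an expected z of ``z`` on a channel.

    The z reference is the (mostly inactive) compound population, whose SD
    fraction is ``ratio_cv`` or ``egfp_cv`` of the baseline.
    """
    cv = ratio_cv(config) if channel == "ratio" else egfp_cv(config)
    return 1.0 + z * cv


def simulate_screen(
    config: SimConfig,
    n_compounds: int = 1595,
    proportions: dict[str, float] | None = None,
    n_replicate_screens: int = 2,
    seed: int = 0,
    effect_folds: dict[str, float] | None = None,
    compounds_per_plate: int = 84,
    phase1_controls: tuple[int, int] = (4, 4),
    phase2_controls: tuple[int, int] = (4, 8),
):
    """Simulate a two-phase (activator then inhibitor) compound screen.

    Phase 1 wells are unstimulated — activator compounds raise Tomato;
    phase 2 wells are all stimulated — inhibitors lower Tomato; artifact
    compounds perturb EGFP in both phases. Replicate screens share the
    planted effects with independent noise. Controls per plate default to
    4 vehicle + 4 positive (phase 1) and 4 vehicle + 8 positive (phase 2).

    Returns ``(phase1_tables, phase2_tables, truth)`` where each tables
    element is one replicate's well DataFrame.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    proportions = dict(proportions or {})
    bad = set(proportions) - set(SCREEN_CLASSES)
    if bad:
        raise ValueError(f"unknown screen class(es): {sorted(bad)}")
    if any(p < 0 for p in proportions.values()):
        raise ValueError("class proportions must be >= 0")
    if sum(proportions.values()) > 1.0 + 1e-12:
        raise ValueError(
            f"class proportions sum to {sum(proportions.values()):.3f} > 1")
    folds = dict(DEFAULT_EFFECT_FOLDS)
    folds.update(effect_folds or {})

    rng = np.random.default_rng(seed)
    classes = np.array(["inactive"] * n_compounds, dtype=object)
    start = 0
    for cls in SCREEN_CLASSES[1:]:
        count = int(round(proportions.get(cls, 0.0) * n_compounds))
        classes[start:start + count] = cls
        start += count
    rng.shuffle(classes)

    ids = [f"C{i + 1:05d}" for i in range(n_compounds)]
    tom_effect = np.ones(n_compounds)
    egfp_effect = np.ones(n_compounds)
    for i, cls in enumerate(classes):
        if cls in ("activator", "inhibitor"):
            tom_effect[i] = folds[cls]
        elif cls in ("artifact_egfp_up", "artifact_egfp_down"):
            egfp_effect[i] = folds[cls]
    truth = ScreenTruth(pd.DataFrame({
        "compound_id": ids,
        "true_class": classes,
        "tom_effect": tom_effect,
        "egfp_effect": egfp_effect,
    }))

    pos_mult = config.induced_tom_multiplier()
    n_plates = math.ceil(n_compounds / compounds_per_plate)

    def one_phase(phase: int, rep_rng) -> pd.DataFrame:
        n_veh, n_pos = phase1_controls if phase == 1 else phase2_controls
        rows = []
        for p in range(n_plates):
            plate = f"S{p + 1:02d}"
            lo = p * compounds_per_plate
            hi = min(lo + compounds_per_plate, n_compounds)
            idx = 0
            for _ in range(n_veh):
                egfp, tom = _tabular_well(rep_rng, config, 1.0)
                rows.append((plate, _well_name(idx), "vehicle", "",
                             egfp, tom, tom / egfp))
                idx += 1
            for _ in range(n_pos):
                egfp, tom = _tabular_well(rep_rng, config, pos_mult)
                rows.append((plate, _well_name(idx), "positive", "",
                             egfp, tom, tom / egfp))
                idx += 1
            for i in range(lo, hi):
                base = pos_mult if phase == 2 else 1.0
                mult = base
                if phase == 1 and classes[i] == "activator":
                    mult = base * tom_effect[i]
                elif phase == 2 and classes[i] == "inhibitor":
                    mult = base * tom_effect[i]
                egfp, tom = _tabular_well(rep_rng, config, mult,
                                          egfp_multiplier=egfp_effect[i])
                rows.append((plate, _well_name(idx), "compound", ids[i],
                             egfp, tom, tom / egfp))
                idx += 1
        df = pd.DataFrame(rows, columns=[
            "plate", "well", "role", "compound_id",
            "egfp_mean", "tom_mean", "ratio"])
        df["phase"] = phase
        return df

    phase1_tables, phase2_tables = [], []
    rep_seeds = np.random.SeedSequence(seed).generate_state(
        2 * n_replicate_screens) % (2 ** 31)
    for r in range(n_replicate_screens):
        phase1_tables.append(
            one_phase(1, np.random.default_rng(int(rep_seeds[2 * r]))))
        phase2_tables.append(
            one_phase(2, np.random.default_rng(int(rep_seeds[2 * r + 1]))))
    return phase1_tables, phase2_tables, truth


# ---------------------------------------------------------------------------
# kinetics, dose-response, flow
# ---------------------------------------------------------------------------

def _induction_course(cfg: SimConfig, t: np.ndarray) -> np.ndarray:
    """Expected Tomato fold over vehicle at times ``t`` (hours).

    Logistic rise anchored so 5% of the rise has occurred at
    ``kinetics_onset_h`` (midpoint at onset + ln(19)/rate); as
    rate -> inf this tends to a step at the onset.
    """
    plateau = cfg.kinetics_plateau
    if math.isinf(cfg.kinetics_rate):
        frac = (t >= cfg.kinetics_onset_h).astype(float)
    else:
        t_mid = cfg.kinetics_onset_h + math.log(19.0) / cfg.kinetics_rate
        frac = 1.0 / (1.0 + np.exp(-cfg.kinetics_rate * (t - t_mid)))
    return 1.0 + (plateau - 1.0) * frac


def simulate_kinetics(
    config: SimConfig,
    groups: dict[str, bool] | None = None,
    timepoints_h=None,
    n_reps: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Well-level induction time course for named groups.

    ``groups`` maps group name -> induced?; defaults to
    ``{"vehicle": False, "induced": True}``. Each (group, timepoint,
    replicate) is an independent well draw around the logistic course.
    """
    groups = groups if groups is not None else {"vehicle": False,
                                                "induced": True}
    t = np.asarray([] if timepoints_h is None else timepoints_h, dtype=float)
    if timepoints_h is None:
        t = np.arange(0.0, 38.1, 2.0)
    if t.size == 0:
        raise ValueError("timepoints_h must be non-empty")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints_h must be strictly ascending")
    rng = np.random.default_rng(seed)
    course = _induction_course(config, t)
    rows = []
    for name, induced in groups.items():
        for j, tp in enumerate(t):
            mult = course[j] if induced else 1.0
            for rep in range(1, n_reps + 1):
                egfp, tom = _tabular_well(rng, config, mult)
                rows.append((name, tp, rep, egfp, tom, tom / egfp))
    return pd.DataFrame(rows, columns=[
        "group", "timepoint_h", "replicate", "egfp_mean", "tom_mean",
        "ratio"])


def fourpl(x, floor: float, ceiling: float, hill: float, ec50: float):
    """Four-parameter log-logistic response at dose ``x`` (> 0)."""
    x = np.asarray(x, dtype=float)
    return floor + (ceiling - floor) / (1.0 + (ec50 / x) ** hill)


def default_doses(n: int = 9) -> np.ndarray:
    """Log-spaced agonist doses 0.01–100 nM (molar units)."""
    return np.logspace(math.log10(0.01e-9), math.log10(100e-9), n)


def simulate_dose_response(
    config: SimConfig,
    doses=None,
    n_reps: int = 8,
    seed: int = 0,
) -> pd.DataFrame:
    """Normalized responses on a 4PL curve with multiplicative noise.

    Ground truth: floor 0, ceiling 1, ``hill_true``, ``ec50_true``; at the
    true EC50 with noise off the response is exactly 0.5.
    """
    doses = default_doses() if doses is None else np.asarray(doses, float)
    if np.any(doses <= 0):
        raise ValueError("doses must be > 0 (molar)")
    rng = np.random.default_rng(seed)
    rows = []
    for dose in doses:
        y0 = fourpl(dose, 0.0, 1.0, config.hill_true, config.ec50_true)
        for rep in range(1, n_reps + 1):
            y = float(y0) * (1.0 + config.dr_noise_cv * rng.normal())
            rows.append((dose, rep, y))
    return pd.DataFrame(rows, columns=["dose_molar", "replicate", "response"])


def simulate_flow_events(
    config: SimConfig,
    n_events: int = 10_000,
    responder_fraction: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-event GFP/Tomato intensities for a control and a treated sample.

    Control events are lognormal in both channels; treated events are a
    two-component Tomato mixture in which the responder fraction is
    shifted up by ``induction_fold``. The 10,000-event default matches
    routine cytometer acquisition per sample.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    frac = (config.responder_fraction if responder_fraction is None
            else responder_fraction)
    if not 0.0 <= frac <= 1.0:
        raise ValueError("responder_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    frames = []
    for sample in ("control", "treated"):
        gfp = rng.lognormal(config.egfp_mu, config.egfp_sigma, n_events)
        tom = rng.lognormal(config.basal_tom_mu, config.basal_tom_sigma,
                            n_events)
        if sample == "treated":
            responders = rng.random(n_events) < frac
            tom = np.where(responders, tom * config.induction_fold, tom)
        frames.append(pd.DataFrame(
            {"sample": sample, "gfp": gfp, "tomato": tom}))
    return pd.concat(frames, ignore_index=True)
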