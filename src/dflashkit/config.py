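"""Configuration objects shared across the simulation and analysis stages.

All tunable parameters of the synthetic-data generator and of nuclear
segmentation live here, so a single frozen object pins down a study
condition and (together with a seed) makes every run bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic dual-reporter generator.

    Intensities are in arbitrary fluorescence units (AU); lengths in
    pixels; times in hours; concentrations in molar.

    Per-cell EGFP and basal Tomato intensities are lognormal
    (``exp(N(mu, sigma))``); signal induction multiplies Tomato by
    ``induction_fold`` in the responding fraction of cells. Well-level
    variation decomposes into a size factor common to both channels
    (CV = ``well_cv``) — which the Tomato/EGFP ratio cancels — plus an
    independent per-channel residual (CV = ``well_residual_cv``,
    defaulting to ``0.3 * well_cv``).
    """

    seed: int = 0
    field_shape: tuple[int, int] = (256, 256)
    n_nuclei_per_field: int = 50
    #: (mean, sd) of the nuclear radius in pixels
    nucleus_radius: tuple[float, float] = (7.0, 0.5)
    #: lognormal location/scale of per-cell EGFP intensity (log AU)
    egfp_mu: float = 6.9
    egfp_sigma: float = 0.2
    #: lognormal location/scale of uninduced Tomato intensity (log AU)
    basal_tom_mu: float = 5.3
    basal_tom_sigma: float = 0.2
    #: multiplicative Tomato fold change in induced cells
    induction_fold: float = 10.0
    #: fraction of cells that respond to induction (1.0 for clones, ~0.5 pools)
    responder_fraction: float = 1.0
    #: additive camera background (AU) and Gaussian read noise sd (AU)
    background_level: float = 100.0
    noise_sd: float = 5.0
    #: fraction of nuclei touching the field edge / in overlapping pairs /
    #: rendered as oversized "abnormal" blobs
    border_fraction: float = 0.05
    cluster_fraction: float = 0.05
    abnormal_fraction: float = 0.02
    #: abnormal nuclei are rendered at this multiple of the mean radius
    abnormal_radius_factor: float = 5.0
    #: optional Gaussian optical blur (px); 0 renders hard-edged disks so
    #: mask means equal planted truth exactly
    blur_sigma: float = 0.0
    #: CV of the shared well-level size factor
    well_cv: float = 0.10
    #: CV of the per-channel residual; None -> 0.3 * well_cv
    well_residual_cv: float | None = None
    #: logistic induction kinetics: onset (h), rate (1/h), plateau fold
    kinetics_onset_h: float = 10.0
    kinetics_rate: float = 0.5
    kinetics_plateau: float = 10.0
    #: dose-response ground truth: EC50 (molar), Hill slope, noise CV
    ec50_true: float = 0.2e-9
    hill_true: float = 1.0
    dr_noise_cv: float = 0.05

    def __post_init__(self) -> None:
        pos = {
            "induction_fold": self.induction_fold,
            "background_level": self.background_level,
            "ec50_true": self.ec50_true,
            "kinetics_plateau": self.kinetics_plateau,
        }
        for name, value in pos.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value!r}")
        nonneg = {
            "noise_sd": self.noise_sd,
            "well_cv": self.well_cv,
            "dr_noise_cv": self.dr_noise_cv,
            "blur_sigma": self.blur_sigma,
            "egfp_sigma": self.egfp_sigma,
            "basal_tom_sigma": self.basal_tom_sigma,
        }
        for name, value in nonneg.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value!r}")
        for name in ("responder_fraction", "border_fraction",
                     "cluster_fraction", "abnormal_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value!r}")
        if self.nucleus_radius[0] <= 0 or self.nucleus_radius[1] < 0:
            raise ValueError("nucleus_radius mean must be > 0 and sd >= 0")
        if self.n_nuclei_per_field < 0:
            raise ValueError("n_nuclei_per_field must be >= 0")
        if self.well_residual_cv is not None and self.well_residual_cv < 0:
            raise ValueError("well_residual_cv must be >= 0")
        if self.kinetics_rate <= 0:
            raise ValueError("kinetics_rate must be > 0 (math.inf allowed)")

    @property
    def residual_cv(self) -> float:
        """Resolved per-channel residual CV (0.3 * well_cv by default)."""
        if self.well_residual_cv is not None:
            return self.well_residual_cv
        return 0.3 * self.well_cv

    @property
    def egfp_mean(self) -> float:
        """Population mean per-cell EGFP intensity (lognormal mean)."""
        return math.exp(self.egfp_mu + self.egfp_sigma ** 2 / 2)

    @property
    def basal_tom_mean(self) -> float:
        """Population mean uninduced Tomato intensity (lognormal mean)."""
        return math.exp(self.basal_tom_mu + self.basal_tom_sigma ** 2 / 2)

    def induced_tom_multiplier(self) -> float:
        """Expected well-level Tomato multiplier under full stimulation.

        A responder_fraction < 1 dilutes the induction fold at the well
        mean: ``1 + f * (fold - 1)``.
        """
        f = self.responder_fraction
        return 1.0 + f * (self.induction_fold - 1.0)


@dataclass(frozen=True)
class SegmentationParams:
    """Nuclear-segmentation QC thresholds.

    Area bounds and the solidity floor define "abnormal" components;
    components larger than ``cluster_area_factor`` times the median
    candidate area are treated as unseparated neighbours and excluded
    rather than split.
    """

    min_area: int = 50
    max_area: int = 2500
    solidity_min: float = 0.85
    cluster_area_factor: float = 1.6
    #: 2 = 8-connectivity (scikit-image convention)
    connectivity: int = 2

    def __post_init__(self) -> None:
        if self.min_area < 1 or self.max_area <= self.min_area:
            raise ValueError("need 1 <= min_area < max_area")
        if not 0 < self.solidity_min <= 1:
            raise ValueError("solidity_min must be in (0, 1]")
        if self.cluster_area_factor <= 1:
            raise ValueError("cluster_area_factor must be > 1")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 (4-conn) or 2 (8-conn)")


def config_from_dict(data: dict, cls=SimConfig):
    """Build a config dataclass from a plain dict, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} field(s): {', '.join(sorted(unknown))}")
    coerced = dict(data)
    for key in ("field_shape", "nucleus_radius"):
        if key in coerced and isinstance(coerced[key], (list, tuple)):
            coerced[key] = tuple(coerced[key])
    return cls(**coerced)
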