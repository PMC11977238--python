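# Methods

This note documents the statistical model behind `dflashkit`'s synthetic
data, the quantification and calling rules, the numerical choices made
where the design was genuinely open, and what the test suite does and
does not establish about real data.

## The reporter model

A dual-fluorescent reporter couples a signal-responsive nuclear Tomato
transgene with a constitutive nuclear EGFP internal control at the same
locus. The analysis quantity throughout is the **Tomato/EGFP ratio**:
any factor acting on both channels equally — cell size, well seeding
density, focus, integration-site effects — cancels in the ratio, while
pathway activity moves Tomato alone. Signal induction is modelled as a
multiplicative fold change (`induction_fold`, default 10) applied to
Tomato in the responding fraction of cells (`responder_fraction`,
default 1 for clonal lines, ~0.5 for selected pools). The 10-fold
default sits inside the 9.3–12.4-fold window routinely achieved by
clonal reporter lines of this design; the 0.2 nM dose-response EC50 and
the 2000-nuclei well-sufficiency rule are likewise the platform's
operating points.

## Synthetic image fields

Per-cell intensities are **lognormal** (`exp(N(mu, sigma))`, sigma 0.2
by default, i.e. ~20% CV): reporter flow histograms are unimodal on a
log axis, and a lognormal keeps intensities positive under any scale.
Nuclei are rendered as uniform disks (radius N(7, 0.5) px, floored at
2 px) on an additive background (100 AU) with optional Gaussian read
noise (5 AU). The rendering guarantees that the mean over each nucleus
mask equals the planted per-cell truth exactly when blur is off, which
is what makes the segmentation oracle ("MFIs within 2% of truth")
checkable by construction. An optional `blur_sigma` softens edges for
realism studies; it is off by default because edge blur biases
mask-mean recovery by several percent and the package treats planted
truth recovery as the generator's contract.

QC features are planted explicitly: a configurable fraction of nuclei
touch the field edge (5%), form overlapping pairs (5%), or are rendered
as oversized blobs (2%, at 5x the mean radius). Overlapping pairs use
fixed mean-radius members at 1.4 r separation so the merged component's
area (~1.8x a single nucleus) sits cleanly above the unseparated-cluster
cutoff (1.6x the median candidate area) while the largest plausible
single nucleus (+3 sigma radius, ~1.24x area ratio squared = 1.5x) stays below
it. Large footprints are placed before small ones; placement is
rejection-sampled with bounded retries and fails loudly with the
offending density. The intensity CV is kept at 20% so that the dimmest
cells (−3 sigma, ~0.55x the population mean) remain above the intermeans
detection limit (~0.5x the mean); with a broader CV the generator would
plant nuclei the prescribed global threshold provably cannot see.

What the generator does **not** emulate: optics (PSF, chromatic shift),
illumination gradients, stage drift, 3-D structure, cell-cycle intensity
coupling, or debris. Tests passing on these fields show the pipeline's
rules are implemented correctly, not that the segmentation would be
accurate on any particular instrument's images.

## Well-level (tabular) simulation

Statistics modules are testable without rendering images. Well-level
noise decomposes into:

- a **size factor** common to both channels, CV = `well_cv` (default
  0.10) — cancelled by the ratio;
- an independent EGFP residual, CV = `well_residual_cv` (default
  0.3 x `well_cv` = 0.03);
- an independent **ratio residual**, CV = sqrt(2) x `well_residual_cv`
  (~4.2%), drawn directly on the Tomato/EGFP ratio; Tomato is the
  product of EGFP and the ratio.

All three are mean-preserving Gaussian factors `(1 + cv * N(0,1))`; at
these CVs a negative draw is a >10-sigma event. Drawing the ratio
residual directly (rather than noising Tomato and dividing) keeps the
reporter value exactly Gaussian, so the nominal 2.28% per-tail mass
beyond ±2 SD — the quantity the hit-calling type-I tests assert — holds
without skew corrections. The decomposition itself encodes the design
premise of the internal control: most well-to-well variation is common
mode. Under these defaults a 6+6-well control plate has an expected
Z' ≈ 0.85 at 10-fold induction, and the minimum over 10 plates stays
above 0.7 — consistent with screening-grade reporter assays (Z' > 0.5).

## Segmentation and QC rules

The EGFP channel is thresholded with the **isodata intermeans fixed
point**: T ← (mean(x ≤ T) + mean(x > T))/2 from the sample midrange,
converged at |ΔT| < 0.5 AU or 100 iterations; a constant image is a
degenerate-histogram error. Foreground components (8-connected) are
classified with precedence **border > abnormal > unseparated >
included**, so every component carries exactly one status:

- *border*: any pixel on the image edge;
- *abnormal*: area outside [50, 2500] px or solidity < 0.85;
- *unseparated*: area > 1.6 x the median area of the remaining
  candidates. Unseparated clusters are excluded, not watershed-split:
  the platform's QC philosophy is that nuclei which cannot be reliably
  separated should not contribute, and splitting would manufacture
  per-nucleus intensities the data cannot support.

MFIs are means over the component mask after subtracting the per-field
median of sub-threshold pixels, floored at zero. Wells aggregate
included nuclei only; the reporter value is the **ratio of well means**
(Tomato mean over EGFP mean), which is less sensitive to dim-nucleus
ratio noise than the mean of per-nucleus ratios (available via
`ratio_mode="mean_of_ratios"`). Wells need `min_nuclei` included nuclei
(default 2000) to count as sufficient; desk-scale runs override this.

## Plate statistics

Z' = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋| with sample SDs (n−1). This is the
standard separation-window form: the σ terms **sum**, making Z' ≤ 1,
scale- and shift-invariant, and strictly decreasing in either control
SD. Fold change is the positive/negative control mean ratio. Kinetics
summaries report mean ± sem per (group, timepoint); the onset is the
earliest timepoint from which the induced mean exceeds vehicle mean +
3 vehicle SD at that and every later timepoint — a sustained-separation
rule chosen so single-timepoint noise cannot fire it. The simulated
induction course is logistic in time, anchored so 5% of the rise has
occurred at `kinetics_onset_h` (midpoint at onset + ln19/rate); this
makes the curve flat before the nominal onset, tend to a step as the
rate grows, and lets the 3-SD rule recover the onset within one
sampling interval.

## Hit calling

z-scores are computed against the **compound-well population** of each
phase and replicate (plate controls are for visual QC; with singlet
compound wells the compound population is the larger, more stable
reference). A robust variant (median / 1.4826 MAD) is available for
heavily contaminated libraries. Calls per compound:

1. |z_EGFP| > 2 → `excluded_fluorescent` (precedence: a compound that
   perturbs the control channel is uninterpretable whatever its ratio
   does — note that an EGFP-only artifact *does* shift the ratio, which
   is exactly why the exclusion must precede calling);
2. otherwise phase 1 (unstimulated, activator mode): z_ratio ≥ +2 →
   `activator`; phase 2 (stimulated, inhibitor mode): z_ratio ≤ −2 →
   `inhibitor`; else `inactive`. Boundaries are closed so behaviour at
   exactly 2.0 is defined.

Hit rates are percent of the screened library (one decimal); confirmed
hits are the per-class intersection across replicate screens; replicate
consistency is Pearson r on paired z_ratio vectors, over all compounds
and over each per-class hit union (undefined below 3 pairs).

A structural property worth knowing: because each hit's EGFP z is a
standard-normal draw, the artifact exclusion removes a true hit with
probability ~4.55% per replicate. This false-negative rate is inherent
to the ±2 SD exclusion rule itself, not to any implementation choice;
power guarantees in the test suite are therefore stated on the ratio
z-score detection, with the exclusion's cost documented here.

## Dose response

The four-parameter log-logistic y = d + (c − d)/(1 + (EC50/x)^h) is fit
by unweighted least squares with replicate points entering
individually. Initialization scans EC50 over a 25-point log grid
spanning the dose range crossed with Hill slopes {±0.5, ±1, ±2}; the
best grid point seeds a trust-region refinement parameterized in
log(EC50), which keeps the estimate positive and makes the fit covary
correctly with dose units. Asymptotes are free by default (min/max
normalization is affine, so a free-limits fit recovers the same EC50
from raw or normalized responses); `fix_limits=(0, 1)` pins them after
normalization. Fewer than 5 distinct doses, or a failed refinement,
returns a fit flagged `converged=False` rather than raising, so batch
screens survive bad wells. Negative Hill slopes describe inhibition
curves with EC50 still positive.

## Flow gating

The positivity threshold is the linear-interpolation (1 − f) quantile
of the negative-control Tomato sample, f = 0.01 by default, requiring
at least 1/f events. Percent positive is the treated fraction above the
threshold; MFI fold change uses the median by default (robust on
log-scale data; the arithmetic mean is available). An optional EGFP
pre-gate drops reporter-negative events from both samples first.
Histograms bin log10 intensity and scale the peak bin to 1;
non-positive intensities cannot be log-scaled and are dropped with a
count reported. Scatter-based debris/singlet gating is not simulated —
the generator emits pre-cleaned events, since scatter channels carry no
information used by any downstream statistic here.

## Chelation

Activity = 100·(A_control − A_x)/A_control; it is 0% when the compound
leaves the iron-complex absorbance unchanged and 100% at complete
chelation, and deliberately *not* clipped below zero so
pro-chromogenic artifacts stay visible. The 50%-activity concentration
comes from inverting an OLS line of activity on log10 concentration
(standard for series spanning decades; a linear-scale option exists).
The crossing is reported only within one decade of the tested range;
beyond that the line is extrapolating and the result is flagged
undefined.

## Problem sizes and determinism

Test and demo runs use desk-scale sizes chosen to keep the full suite
fast while leaving every statistical check well-powered: fields of
~30–50 nuclei at 160–256 px, 10-plate robustness runs, 1595-compound
screens with 1–2 replicates, 10,000 flow events, 8-replicate dose
series, and 20-fit Monte-Carlo recovery checks. All generators consume
a `numpy.random.default_rng` seed and are bit-reproducible for a fixed
(config, seed); the CLI serializes the resolved configuration and seed
alongside every run's outputs.

## Known limitations

- Synthetic images are geometric idealizations; segmentation accuracy
  on real microscopy is not established by this suite.
- The classical z reference degrades when a large fraction (≳5%) of the
  library carries strong true effects; use the robust mode there.
- The 4PL fit assumes a monotone response spanning the inflection;
  doses clustered on one asymptote return poorly identified Hill
  slopes (flagged by convergence diagnostics only insofar as the
  optimizer reports them).
- Flow simulation omits spectral spillover/compensation and acquisition
  artifacts; FCS binary parsing is out of scope (events travel as CSV).
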