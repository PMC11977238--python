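# dflashkit

Analytics for **dual-fluorescent transcription-factor reporter screens**:
assays in which a signal-responsive enhancer drives a nuclear Tomato
reporter while a constitutive promoter at the same locus drives nuclear
EGFP as an internal control. Dividing Tomato by EGFP cancels cell-to-cell
and well-to-well variation, which is what makes these reporters robust
enough for high-content imaging (HCI) and arrayed small-molecule
screening.

The package is aimed at screening scientists and image analysts who need
the full quantitative path from raw two-channel images to confirmed
compound hits — and at method developers who want every stage testable
against planted ground truth. It provides:

- **Synthetic data with ground truth** (`dflashkit.synthetic`) — nuclear
  image fields, 96-well plates, two-phase compound screens, induction
  kinetics, dose-response tables and flow-cytometry events, all
  deterministic given a seed.
- **Image quantification** (`dflashkit.image_quant`) — isodata
  (intermeans) thresholding on the EGFP channel, 8-connected labelling,
  QC exclusion of edge / abnormal / unseparated nuclei, per-nucleus
  background-subtracted MFIs, and well aggregation with a minimum-nucleus
  sufficiency rule (2000 by default).
- **Plate statistics** (`dflashkit.plate_stats`) — the screening-window
  statistic

  Z′ = 1 − 3(σ₊ + σ₋) / |μ₊ − μ₋|

  together with positive/negative fold change and induction-kinetics
  summaries (mean ± sem, sustained-onset detection).
- **Bimodal hit calling** (`dflashkit.hit_calling`) — z-scoring of the
  Tomato/EGFP ratio and EGFP MFI against the compound-well population;
  compounds with |z_EGFP| > 2 are excluded as fluorescence artifacts,
  then activators are called at z_ratio ≥ +2 on unstimulated wells
  (phase 1) and inhibitors at z_ratio ≤ −2 on stimulated wells
  (phase 2); replicate screens are intersected and their consistency
  quantified by Pearson correlation.
- **Dose-response** (`dflashkit.dose_response`) — per-experiment min/max
  normalization and four-parameter log-logistic fitting,
  y = d + (c − d)/(1 + (EC50/x)^h), with grid-seeded least squares.
- **Flow gating** (`dflashkit.flow_gating`) — positivity threshold at
  the top 1% of the negative-control population, percent positive, MFI
  fold change, and mode-normalized log10 histograms.
- **Chelation** (`dflashkit.chelation`) — iron-chelation activity
  100·(A_control − A_x)/A_control and the 50%-activity concentration
  from a line of best fit on log10 concentration.
- **CLI** (`dflashkit` console script) — `simulate`, `quantify`,
  `plate-stats`, `screen`, `dose`, `flow`, `chelation`, `all`, each
  writing CSV outputs, a run log and the resolved configuration.

## Worked example

```python
from dflashkit import (SimConfig, hts_layout, simulate_plate, plate_qc,
                       robustness_summary, simulate_screen,
                       run_bimodal_screen, simulate_dose_response, fit_4pl)

cfg = SimConfig()   # 10-fold induction, 10% well CV, EC50 0.2 nM, ...

# 1. plate-level assay quality on 10 simulated HTS control plates
layout = hts_layout(n_plates=10, n_positive=6, n_vehicle=6)
wells, _ = simulate_plate(cfg, layout, mode="tabular", seed=42)
table, summary = robustness_summary(plate_qc(wells))
print(f"min Z' = {summary['min_zprime']:.3f}, "
      f"mean Z' = {summary['mean_zprime']:.3f}, "
      f"mean fold change = {summary['mean_fold_change']:.1f}")

# 2. a 1595-compound bimodal screen with planted hits
p1, p2, truth = simulate_screen(
    cfg, n_compounds=1595,
    proportions={"activator": 0.01, "inhibitor": 0.02,
                 "artifact_egfp_up": 0.005},
    seed=42)
result = run_bimodal_screen(p1, p2)
print(result.phase_summary[["phase", "replicate", "n_hits",
                            "hit_rate_pct"]].to_string(index=False))
print("confirmed activators:", len(result.confirmed[1]),
      "| confirmed inhibitors:", len(result.confirmed[2]))

# 3. agonist EC50 from a noisy synthetic dose series
dr = simulate_dose_response(cfg, n_reps=8, seed=42)
fit = fit_4pl(dr["dose_molar"], dr["response"])
print(f"EC50 = {fit.ec50 * 1e9:.3f} nM (true 0.200 nM), "
      f"hill = {fit.hill:.2f}, converged = {fit.converged}")
```

Output:

```
min Z' = 0.716, mean Z' = 0.859, mean fold change = 10.1
 phase  replicate  n_hits  hit_rate_pct
     1          1      14           0.9
     1          2      16           1.0
     2          1      32           2.0
     2          2      31           1.9
confirmed activators: 14 | confirmed inhibitors: 31
EC50 = 0.195 nM (true 0.200 nM), hill = 1.02, converged = True
```

Every plate keeps Z′ above the 0.5 "excellent assay" bound at a 10-fold
window; the screen calls roughly the planted 1%/2% of activators and
inhibitors per replicate (hit rates are percent of the library, to one
decimal) and confirms them by replicate intersection; the 4PL fit
recovers the 0.2 nM ground-truth EC50 within a few percent at 5%
multiplicative noise.

The same stages run from the shell:

```sh
dflashkit --seed 7 --outdir demo all
```

## Documentation

`docs/methods.md` describes the statistical model behind the synthetic
data generator, the QC and calling rules, numerical choices in the 4PL
fit, and known limitations.
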