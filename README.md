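# vinespec

Predicting grapevine water status from on-the-go near-infrared spectroscopy.

Midday stem water potential (ψ<sub>s</sub>, MPa, negative) is the
gold-standard indicator of vine water stress, but Scholander
pressure-chamber readings are destructive and slow — a few dozen leaves per
day, far too sparse to map the water-status variability of a vineyard plot.
`vinespec` implements the alternative: a spectrometer on a moving vehicle
streams canopy absorbance spectra (1100–2100 nm, 4 nm resolution, 24 Hz at
5 km/h), and a partial least squares (PLS) calibration links averaged leaf
spectra — dominated by the O–H water bands near 1450 and 1940 nm — to
pressure-chamber references, so that ψ<sub>s</sub> can be predicted and
mapped plot-wide.

The package covers the full workflow, plus a synthetic campaign generator
so that every stage is testable without field data:

- **`vinespec.synthetic`** — seeded generation of a complete monitoring
  campaign: a completely randomized block design (4 blocks × 3 irrigation
  regimes, 12 replicates, 3 tagged vines each), per-treatment ψ<sub>s</sub>
  trajectories over 9 (or 6) dates, environmental covariates (air T, RH,
  Tetens VPD), and raw 24 Hz spectral streams with wood/metal/gap
  contamination, baseline and scatter effects.
- **`vinespec.spectra`** — wavelength grids, spectra batches, wide-CSV I/O,
  positional stream allocation into 5-vine sub-replicate units, averaging.
- **`vinespec.preprocess`** — standard normal variate (SNV) and
  Savitzky–Golay smoothing/derivatives (`"SNV+D1W15"` shorthand), and
  leaf-signature filtering of the raw stream.
- **`vinespec.qc`** — PCA-based atypical-sample removal via Q residuals
  (Jackson–Mudholkar limit) and Hotelling T² with its F-distribution bound
  T²<sub>p,n,α</sub> = p(n−1)/(n−p) · F<sub>p,n−p,α</sub>.
- **`vinespec.pls`** — NIPALS PLS1 with mean centering, latent-variable
  selection by minimum cross-validated RMSE, and R²/RMSE metrics.
- **`vinespec.validation`** — stratified 80/20 calibration/external split,
  10-fold venetian-blind and leave-one-day-out cross-validation, balanced
  east&west merging, and the end-to-end pipeline.
- **`vinespec.mapping`** — multilevel B-spline approximation
  (Lee–Wolberg–Shin) of predicted ψ<sub>s</sub> onto a raster, exported as
  ESRI ASCII grids.

## Worked example

```python
from vinespec import simulate_campaign
from vinespec.validation import run_campaign

campaign = simulate_campaign("2015", sides=("east",), seed=1)
result = run_campaign(campaign)           # SNV+D1W15, QC, 80/20, both CVs
print(result.report)
```

prints

```
[2015 east sub_unit SNV+D1W15 LV=1]  RMSEC=0.140 Rc2=0.79  10-fold CV-RMSE=0.142 Rcv2=0.79  LODO CV-RMSE=0.147 Rcv2=0.77  RMSEP=0.130 Rp2=0.77
```

Reading the row: 324 sub-replicate samples were assembled from the east-side
stream; after Q/T² screening the calibration model (1 latent variable was
optimal for this synthetic campaign) fits with calibration RMSE 0.140 MPa
(R²c 0.79); internal 10-fold venetian-blind cross-validation gives CV-RMSE
0.142 MPa, while holding out whole days (LODO) is slightly harder
(0.147 MPa), as expected when conditions drift between dates; on the
never-touched external 20% the model predicts ψ<sub>s</sub> with RMSE
0.130 MPa and R²p 0.77.

The same pipeline runs from the shell:

```sh
vinespec simulate --outdir camp --seed 1        # streams + reference CSVs
vinespec fit --config run.yaml                  # full pipeline, artifacts on disk
vinespec predict --model run/model.json --spectra batch.csv --out pred.csv
vinespec map --points pred_points.csv --out psi.asc
```

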