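# Methods

## The estimation problem

A vehicle-mounted NIR spectrometer streams canopy absorbance spectra
(1100–2100 nm, 4 nm steps, 251 channels; 24 Hz at 5 km/h ≈ 17.3 spectra per
row metre) along vineyard rows. The quantity of interest is midday stem
water potential ψs (MPa, negative), measured by pressure chamber on one
tagged, dark-adapted leaf per 5-vine sub-replicate unit. The calibration
task is a PLS1 regression of averaged, pretreated sub-unit spectra on the
tagged-leaf ψs, validated internally by cross-validation and externally on
a held-out 20% of samples, then deployed to map predicted ψs over the plot.

## Synthetic campaign generator

Because the method is calibrated on in-field streams, the package ships a
generator that emulates the whole campaign:

- **Design.** Completely randomized block design: 4 blocks × 3 irrigation
  regimes (T0 full, T1 moderate, T2 none) = 12 replicates of three adjacent
  rows (25 vines each, 1.20 m vine / 2.60 m row spacing); only the middle
  row's middle 15 vines are measured, as three 5-vine sub-units each holding
  one randomly tagged vine. 9 campaign dates in the "2015" season and 6 in
  "2016" give 324 and 216 reference slots.
- **ψs trajectories.** Per treatment and date, ψs is drawn as
  `N(mean_d, sd_d)` clipped to treatment bounds. Date means follow the
  seasonal drydown-and-recovery shape (irrigated vines dip toward
  mid-August and partially recover after early-September rain; unirrigated
  vines decline steadily); per-date SDs are solved so the *pooled*
  per-treatment mean/SD/min/max match the campaign summary statistics
  (e.g. 2015 T0: mean −0.85, SD 0.161, range −1.35…−0.55 MPa). The pooled
  statistics are what the Monte-Carlo test asserts.
- **Spectra.** A leaf spectrum is
  `baseline + scatter · (matrix(λ) + depth(ψ) · bands(λ)) + ε`, with
  `bands(λ)` two Gaussians at 1450 nm (σ 40 nm) and 1940 nm (σ 60 nm,
  relative amplitude 1.2), a fixed leaf-matrix background (gentle slope plus
  broad minor bands at 1250/1750 nm), and the affine depth model
  `depth = α0 + α1·ψ` (α0 = 0.9, α1 = 0.25 absorbance/MPa, α1 > 0 so wetter
  vines absorb more). Baseline is uniform in ±0.05, scatter in 0.9–1.1,
  channel noise SD 0.02 absorbance.
- **Structured variability.** Two error scales do *not* average out over a
  pass and therefore set the attainable model quality: a per-(date,
  replicate, sub-unit) canopy mismatch between the sampled foliage and the
  single tagged leaf (`canopy_psi_sd`, default 0.12 MPa) and a shared
  per-date drift of band depth (`date_effect_sd`, 0.07 MPa-equivalent),
  emulating environmental conditions. The defaults were fixed once so the
  reference pipeline's external R²p sits near 0.8, i.e. in the middle of
  the performance envelope the method is expected to reach on real
  campaigns; the date effect also reproduces the qualitative pattern that
  leave-one-day-out validation is harder than interleaved 10-fold.
- **Contamination.** 15% of stream spectra are replaced by archetypes:
  wood (broad 1200 nm band), trellis metal (low flat absorbance), canopy
  gaps (near-zero signal, noise SD 0.10). Every spectrum carries its true
  class and sub-unit tag so filters can be scored against ground truth.
- **Determinism.** One seed controls everything; sub-seeds are derived via
  `numpy.random.SeedSequence`, and identical seeds give bit-identical
  campaigns and reports.

What the generator does **not** emulate: radiative-transfer leaf optics,
3-D canopy geometry, within-day ψs dynamics, speed variation of the
vehicle, or instrument drift. Passing the simulation-based checks therefore
demonstrates that the pipeline recovers a band-depth signal under realistic
noise, contamination and date structure — not that any particular accuracy
will be reached on real vineyards.

## Pipeline stages and numerical choices

1. **Trim and filter.** Each (date, replicate) pass covers the full 25-vine
   row (518 spectra at the stated geometry); the central 15/25 of the
   stream is kept positionally (constant speed assumption), then each raw
   spectrum is compared against a static leaf signature: Pearson
   correlation of SNV-normalized spectra ≥ 0.90 *and* raw mean absorbance
   in 0.15–1.5. Filtering precedes averaging because its purpose is to keep
   gaps, wood and metal out of the leaf averages.
2. **Allocate and average.** Survivors are split into three contiguous,
   order-preserving groups (remainder to the earliest groups) — one per
   sub-unit — and averaged channel-wise.
3. **Pretreatment.** `SNV+D1W15` by default: per-spectrum standard normal
   variate (sample SD, n−1), then a Savitzky–Golay first derivative,
   window 15 channels, polynomial order 2, scaled per nm; the window−1 edge
   channels are dropped rather than padded (251 → 237 channels).
4. **QC.** PCA (SVD, mean-centered, loading signs fixed by the
   largest-magnitude element) retains components for ≥ 95% cumulative
   variance, capped at 10. A sample is removed when Q > Q_limit
   (Jackson–Mudholkar; empirical training quantile as fallback when the
   eigenvalue moments degenerate) **or** T² > p(n−1)/(n−p)·F at α = 0.95.
   Removal is a single pass on the full dataset before splitting. Note a
   structural property: SNV divides by the per-spectrum SD, so low-band-depth
   (dry) spectra get their channel noise amplified, Q is heteroscedastic,
   and the removal rate on the default campaign (~15–20%) exceeds the
   nominal rate and preferentially trims the dry extreme. This mimics — in
   stronger form — the range shrinkage any score-distance QC applies to a
   calibration that spans a wide response range.
5. **Split.** Stratified pseudorandom 80/20 by date × treatment × side;
   per-stratum external count is `round(n·0.2)` (27 strata of 12 → 54
   external samples); strata under 2 samples stay in calibration.
6. **Cross-validation.** 10-fold venetian blinds (position k → fold
   k mod 10, samples ordered by date/side/replicate/sub-unit) and
   leave-one-day-out. Predictions are pooled over folds before computing
   CV-RMSE/R²cv. The latent-variable count (search capped at 15) minimizes
   the venetian CV-RMSE, ties toward fewer; LODO is reported at that count.
   Pretreatments act per spectrum and model means are refit per fold, so no
   held-out information enters training.
7. **Model.** NIPALS PLS1, mean-centered, never variance-scaled
   (conventional for derivative spectra). PLS1 components are closed-form;
   extraction stops early if X or y deflates to numerical zero
   (`1e-14`-scaled threshold). Coefficients `B = W(PᵀW)⁻¹q`;
   `ŷ = (x − x̄)B + ȳ`. R² is 1 − SS_res/SS_tot about the evaluation set's
   own mean, not a squared correlation. On the default synthetic campaign
   one latent variable is typically selected — the affine depth model is
   rank-1 in signal; real leaf optics need more.
8. **Scales and sides.** The field-replicate scale averages the three
   sub-unit spectra and ψs per replicate (108 samples) and reruns the
   identical pipeline. The east&west model draws equal per-(side,
   treatment, date) cell counts (±1) from both sides, ending at one side's
   size.
9. **Mapping.** Predicted ψs is attached to sub-unit centroids in a local
   plot frame (metres; row-along x, row-across y). Multilevel B-spline
   approximation: uniform cubic lattices from 4 × 4 control cells, dyadic
   refinement, each level fitted by the local least-squares BA rule to the
   previous residuals; the data mean is removed first so unsupported
   regions relax to the mean and constant fields are reproduced exactly.
   Eight levels reproduce 50 scattered points to within 10⁻³ of the value
   range. Export is ESRI ASCII (17-significant-digit values for lossless
   round trips).

## Known limitations

- The stream-to-sub-unit allocation is purely positional; variable vehicle
  speed would misassign spectra (the generator assumes constant speed).
- The Q limit's Gaussian assumptions are violated by SNV-induced
  heteroscedasticity (see QC note); α should be raised if range retention
  matters more than strict screening.
- The signature filter's correlation threshold (0.90) was chosen against
  the generator's archetypes; real contaminant families may need retuning.
- MBA residual decrease across levels is monotone empirically, not by
  proof; severe data conflicts within one coarse cell could locally stall
  refinement.
- CSV I/O is the only spectra interchange format; vendor binary formats
  and reflectance↔absorbance conversion are out of scope.
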