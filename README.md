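# trfdr

Synthetic time-resolved fluorescence + diffuse reflectance (TRF-DR) tissue
measurements and the full classification pipeline built on them: simulate
patient sample grids with pathologist-style composition annotations, extract
the 13 optical features, and classify tumor vs. no-tumor regions with
PCA + class-weighted logistic regression under patient leave-one-out
cross-validation.

## What is in the box

| module | purpose |
| --- | --- |
| `trfdr.synthetic` | Forward diffusion reflectance model, phantom-style look-up table, pure-tissue optical library (versioned YAML), raw TRF/DR simulators, seeded patient-cohort generator |
| `trfdr.trf_features` | Pulse averaging, single-exponential lifetime fits, band-averaged lifetimes, NADH-peak-normalized band intensities |
| `trfdr.dr_features` | Background/standard spectrum correction, chi-square LUT inversion (parametric chromophore-basis mode plus a per-wavelength comparison mode) |
| `trfdr.preprocess` | Eligibility filtering, single-pass IQR outlier screen, log10 + standardization, covariance-eigendecomposition PCA |
| `trfdr.classify` | Class-weight formula (`0.5 * n_samples / n_class`), IRLS weighted logistic regression, 50% decision boundary, patient LOOCV, composition-stratified subsets |
| `trfdr.report` | Composition accounting tables, posterior-vs-composition records, misclassification breakdowns |

The five TRF features are the collagen/NADH/FAD band-averaged lifetimes and
the collagen/FAD integrated intensities normalized by the integrated 460 nm
signal; the eight DR features are corrected reflectance at 520/560 nm and
inverted mu_a / mu_s' at 540/560/576 nm.

## CLI

```sh
trfdr simulate --n-patients 20 --seed 1 --out cohort.h5 --annotations-csv annotations.csv
trfdr build-lut --size 50 --out lut.json
trfdr extract --n-patients 20 --seed 1 --lut lut.json --out features.csv
trfdr classify --features features.csv --subset total --pcs 4 --out results/
trfdr report --results results/cv_result.csv --out report/
```

Subsets for `classify`: `total`, `heterogeneous_only`, `low`, `medium`,
`high` (tumor-area bands `<25`, `25-<75`, `>=75`, each evaluated against all
no-tumor regions with an independently trained model).  `--leakage-mode`
and `--weight-mode` switch standardization/PCA fitting and class weights
between per-fold and global computation.

## Notes

- Everything downstream of the generator is deterministic under a fixed
  seed; per-cell measurements are re-simulated on demand from spawned child
  seeds, so arbitrarily large cohorts stream in flat memory.
- The forward model is a steady-state diffusion dipole at a 0.64 mm
  source-detector separation; diffusion validity is marginal at sub-mm
  distances, which is acceptable here because generator and inverter only
  need to be self-consistent.
- The pure-tissue optical library (`trfdr/synthetic/tissue_library.yaml`)
  contains generator parameters chosen for plausible contrast, not measured
  tissue constants.
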