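# oxishelf

Shelf-life estimation for stored commodities from lipid-oxidation
kinetics and FTIR-style chemometrics, plus a synthetic study generator
so the whole pipeline is testable with known ground truth.

The package models an accelerated-storage experiment: a product is held
at several temperatures, lipid-oxidation markers (peroxide value, PV,
meq/kg; TBARS-derived malondialdehyde, nmol/g) are tracked over storage
days, and mid-IR absorbance spectra are collected per sample. From this
it computes:

- **assays** — assay arithmetic: moisture % (wet basis), peroxide value
  from iodometric titration, MDA from 532/600 nm absorbance
  (ε = 155 mM⁻¹cm⁻¹), with an nmol/g → mg/kg conversion helper.
- **kinetics** — zero/first-order rate fits per temperature, Arrhenius
  fit (ln k vs 1/T, R = 8.3144 J K⁻¹ mol⁻¹), and shelf-life prediction
  to a configurable endpoint, with replicate-refit SD estimates.
- **preprocess** — standard normal variate (SNV) and Savitzky–Golay
  first derivative (window 11, order 2 by default, physical cm⁻¹ units),
  chained through a registered-recipe runner.
- **chemometrics** — hand-rolled NIPALS PLS1 with leave-one-out
  cross-validation (RMSECV, R², RPD), auto-prediction metrics, Wold VIP
  scores with VIP ≥ 1 band-interval selection, PCA via SVD, and a
  robust-residual outlier flagger.
- **synthetic** — deterministic generator for the full study design
  (2 processes × 3 temperatures × 4 stored timepoints + 2 day-0
  controls, 26 distinct samples × 3 replicates = 78 spectra on a
  1869-channel 401–4000 cm⁻¹ grid), with Gaussian bands whose
  amplitudes follow the latent PV/TBARS state, corrupted by
  multiplicative scatter, baseline drift and channel noise.
- **pipeline / CLI** — end-to-end orchestration with YAML config, CSV
  outputs and a reproducibility manifest (seed + config hash).

## CLI

```sh
# full synthetic pipeline (default design, deterministic under --seed)
oxishelf run --seed 7 --out out/

# individual stages
oxishelf simulate --seed 3 --out sim/
oxishelf assays --kind pv --in titrations.csv --out derived.csv
oxishelf kinetics --oxidation sim/oxidation.csv \
    --endpoint PV=2.0 --endpoint TBARS=10.0 --out shelf_life.csv
oxishelf preprocess --spectra sim/spectra.csv --metadata sim/spectra_metadata.csv \
    --recipe snv,deriv1 --out prep/
oxishelf pls --spectra sim/spectra.csv --metadata sim/spectra_metadata.csv \
    --responses sim/sample_responses.csv --response PV --lv 10 --out pls/
oxishelf pca --spectra sim/spectra.csv --metadata sim/spectra_metadata.csv --out pca/
```

`run` writes a shelf-life table (one row per process × response ×
temperature), a PLS summary (n, processing, LVs, RMSECV/R²/RPD for
LOOCV and auto-prediction), per-channel VIP scores, VIP ≥ 1 band
intervals, observed-vs-predicted values, PCA scores/explained variance,
and `manifest.json`. Re-running with an identical config reproduces
every file bit-for-bit.

Spectra travel as plain CSV (wide: `wavenumber_cm1` + one column per
sample; or long: `sample_id,wavenumber_cm1,absorbance`) with a metadata
sidecar `sample_id,process,temperature_C,day,replicate`. Oxidation
tables use `process,response,temperature_C,day,replicate,value`.

## Shelf-life endpoints

The endpoint (critical marker value defining end of shelf life) is
always an explicit parameter — there is no hidden constant. Defaults in
`RunConfig` are PV = 2.0 meq/kg and TBARS = 10.0 nmol/g, chosen to give
shelf lives of realistic magnitude on the default synthetic kinetics;
every output table echoes the endpoint used.

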