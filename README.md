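# tremormpp

Quantification pipeline for drug-suppression experiments in a pharmacological
mouse tremor assay. The package covers three stages, each usable on its own:

1. **`tremormpp.signal_model`** — synthetic load-platform motion traces for a
   full cohort design (epochs B, H1, H2, E1–E4 at 128 Hz; dose groups;
   wild-type vs knockout genotypes; Emax/Hill dose–response on the tremor
   component with per-drug clearance profiles). A single latent per-animal
   trait drives baseline and tremor-epoch individuality, giving cohorts the
   compound-symmetry covariance the downstream model assumes. Generation is
   deterministic per animal from a master seed.
2. **`tremormpp.spectral_mpp`** — Welch power spectral densities (8-s Hann
   windows, 50% overlap by default) and the **motion power percentage**:
   `MPP = 100 × (9–16 Hz band power) / (0.25–32 Hz band power)`, one value
   per animal-epoch.
3. **`tremormpp.rm_stats`** — repeated-measures mixed ANOVA (fixed dose,
   epoch, dose×epoch; per-animal random intercept, fitted in closed form via
   the split-plot stratum decomposition, equivalent to REML under compound
   symmetry), Shapiro–Wilk residual diagnostics with quantile-plot
   coordinates, model-based cell means with pooled SEs, and *protected*
   Fisher-LSD dose-vs-vehicle comparisons at each post-injection epoch.

`tremormpp.pipeline` ties the stages together behind a YAML-serializable
`ExperimentConfig`; `make_published_defaults(drug, line)` reproduces the
published design cells (doses, group sizes, schedule) for
`{alcohol, ganaxolone} × {delta, alpha6}`.

## CLI

```bash
tremor-mpp defaults --drug alcohol --line delta --out config.yaml
tremor-mpp run --config config.yaml --seed 1 --out results/
tremor-mpp simulate --config config.yaml --out sim/          # traces + manifest
tremor-mpp quantify --traces sim/traces --out mpp.csv --window-s 8 --overlap 0.5
tremor-mpp analyze --mpp mpp.csv --alpha 0.05 --out results/
```

`run` writes `mpp.csv`, `results.csv` (per-epoch dose comparisons with
significance stars), `curves.csv` (mean ± pooled SE per dose × epoch),
`summary.txt` (omnibus F tests and variance components), per-genotype
quantile-plot coordinates, and a provenance block (config hash, seed,
versions). Reruns with the same config are bit-identical.

Trace files are plain text: two columns (`time_s`, `force`) plus a
`.meta` sidecar of `key: value` pairs; cohort manifests and MPP tables are
CSV.

## Notes

- The generator's default calibration places drug-free baseline MPP near
  32% and tremor-epoch MPP near 79% (tremor variance ratio 2.24 obtained by
  inverting the closed-form MPP expectation).
- Figure-legend conventions elsewhere sometimes print star thresholds as
  `P > 0.05` etc.; this package uses the standard reading (`p ≤ 0.05/0.01/0.001`
  for `*`/`**`/`***`), applied only to comparisons that pass the protected-LSD
  rule.
- The optional hardware band-pass (1–70 Hz, 2nd-order Butterworth) is off by
  default; its upper corner is clipped below the Nyquist frequency at 128 Hz
  sampling.
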