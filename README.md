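# afrisk

Hourly RR-interval heart-rate-variability analysis and three-class atrial-
fibrillation (AF) risk classification, with a synthetic postoperative Holter
cohort simulator and a full case/control diagnostic-accuracy evaluation
protocol.

The pipeline ingests beat-to-beat RR series (CSV, one beat per row), cleans
artifacts, segments recordings into one-hour windows, computes time-domain
(SDNN, RMSSD, pNN50), Poincaré (SD1/SD2, normalized successive-difference
dispersion, qualitative COMET/SCATTERED/DISPERSED pattern) and Lomb–Scargle
LF/HF spectral descriptors, and classifies every analyzable hour:

- **Risk 0** — sinus rhythm
- **Risk 1** — increased paroxysmal-AF risk (ectopy burden / scattered
  Poincaré pattern / elevated dispersion)
- **Risk 2** — AF present (a detected irregular stretch of ≥ 30 s)

A study-protocol layer selects case segments (the 24 h preceding AF onset)
and control segments (postoperative day 2), applies the
two-or-more-positive-hours patient-level rule to the first-3-hours and
pre-onset-3-hours windows, and produces 2×2 contingency tables with the
seven standard accuracy statistics (sensitivity, specificity, PPV, NPV,
accuracy, LR+, LR−) plus group-comparison tests (t / Mann–Whitney,
Fisher / chi-squared).

Because no public recordings exist for the validation study this mirrors,
`afrisk.synth` generates cohorts with the statistical structure the analysis
assumes: LF/HF-modulated sinus rhythm, premature atrial complexes, a
pre-onset ramp of ectopy density and HF modulation, and AF episodes of
serially uncorrelated Gamma intervals, at ~28% prevalence peaking on
postoperative day 2 — with ground truth for every injected event.

## CLI

```sh
afrisk run --n 114 --prevalence 0.28 --seed 20230315 --outdir results/run
afrisk simulate --n 10 --seed 7 --outdir results/cohort
afrisk classify --input results/cohort/P000.csv --out results/risk.csv
afrisk evaluate --indir results/cohort --outdir results/eval
afrisk verify-reference
```

`run` simulates a cohort in memory, classifies every hour, applies the
case/control protocol and writes `segments.csv`, `report.txt` (contingency
tables, window positivity rates, autonomic HF/LF contrast), a run manifest,
the frozen classifier configuration, and Poincaré figures for flagged
segments. All outputs carry the seed and a configuration hash; reruns are
byte-identical.

`verify-reference` recomputes all accuracy statistics from the published
validation-study contingency tables (hard-coded fixtures) and checks them
against the printed values at their rendered precision.

## Configuration

Every classifier threshold lives in `afrisk.classifier.ClassifierConfig`
(YAML round-trip via `to_yaml`/`from_yaml`). The defaults are documented
stand-ins for an undisclosed commercial decision matrix: they were tuned
once against the default synthetic cohort (seed 20230315) and then frozen.
On that cohort the frozen defaults give segment-level sensitivity ≈ 0.69 and
specificity ≈ 0.86, and the group-I pre-onset 3-hour positivity rate exceeds
the first-3-hours rate — bracketing the published operating point without
claiming to replicate the proprietary system.
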