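# ewas-screen

Environment-wide association screening for matched case-control
questionnaire studies.

The package implements a complete screening pipeline for studies in which
one case is matched to one or two controls and exposures come from a large
mixed binary/ordinal questionnaire:

* **`ewas_screen.questionnaire_model`** — declarative questionnaire spec
  (kind, ordered levels, orientation), encoding of responses onto `[0, 1]`
  (binary → {0, 1}; an L-level ordinal item → k/(L−1), equally spaced), a
  staged exclusion cascade (response missingness > 50 %, reference age
  outside [0.5, 15.5] years, diagnosis-to-questionnaire delay > 10 years,
  inconsistent primary-school attendance), matched and propensity sample
  builders, and the within-sample standard-deviation filter (sd ≥ 0.1).
* **`ewas_screen.matched_analysis`** — per-variable tests over matched
  strata: Cochran–Mantel–Haenszel (binary; Mantel–Haenszel common OR with
  Robins–Breslow–Greenland 95 % CI) and conditional logistic regression
  (ordinal; the exposure enters linearly on its [0, 1] encoding so
  exp(coefficient) is the odds ratio between the two extreme responses).
* **`ewas_screen.propensity_analysis`** — unmatched screen: per exposure, a
  random-forest regression predicts the exposure from covariates (reference
  age, parental-profession class, urban-unit index, percent farmers, large
  recruitment centers); its out-of-bag predictions are the propensity
  score; the sample is cut into score deciles and the exposure–status
  association tested within those strata.
* **`ewas_screen.discovery`** — Holm/Bonferroni and Benjamini–Hochberg
  thresholds, the dual discovery rule (FDR-passed in the matched analysis
  AND family-wise-passed in the propensity analysis), and plot-ready
  volcano/comparison tables.
* **`ewas_screen.synthetic_data`** — a generator of matched case-control
  studies with known ground truth: covariate-driven confounding, true
  log-odds effects by retrospective exposure tilting, configurable
  missingness, and a matching-fidelity knob for how much of the case's
  environment its controls share.
* **`ewas_screen.pipeline`** — orchestration with a reconciled run manifest.
* **`ewas_screen.validation`** — replicated error-control / confounding /
  recovery experiments used by the acceptance suite.

## Command line

```bash
# generate a synthetic study with known truth
ewas simulate --config sim.yaml --seed 1 --out study/

# run the full screen (both analyses) on input files
ewas run --participants study/participants.csv \
         --responses study/responses.csv \
         --spec study/questionnaire.yaml \
         --out results/ --seed 1

# rebuild plot tables (and optional PNGs) from saved results
ewas report --results results/ --png
```

`ewas run` writes `encoded_matrix.tsv`, `exclusions.tsv`,
`matched_results.tsv`, `propensity_results.tsv`, `discovery_report.tsv`,
`volcano_*.tsv`, `comparison.tsv` and `manifest.json`. `--no-matched` /
`--no-propensity` restrict the run to one analysis. An optional YAML config
overrides the exclusion thresholds (`missingness_max`, `age_min`, `age_max`,
`delay_max`, `school_age_cut`, `sd_min`), the test level `alpha`, the
stratum count `propensity_k`, and the forest size `rf_n_trees`.

Input formats: `participants.csv` (one row per participant: id, case/control
status, matched-set id, reference age, delay, SES class 0/1/2, urban-unit
index, percent farmers, center id, primary-school flag), `responses.csv`
(wide, level labels as text, blank = missing), `questionnaire.yaml` (one
entry per variable: kind, levels, orientation).

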