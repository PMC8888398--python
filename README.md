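# scdpk

Stratum-corneum (SC) tape-strip dermatopharmacokinetics as a reusable
pipeline:

* **data_model** — domain types (tape records, assayed strip groups,
  chromameter readings, assay/stopping configuration) and lossless CSV
  readers/writers with schema validation.
* **synthetic** — a seeded synthetic study generator: Fickian uptake into a
  finite membrane (eigenfunction series with an exact slab antiderivative),
  uniform first-order clearance, lognormal tape-stripping with a
  TEWL-driven stopping rule, assay noise + below-LOQ censoring, and a
  skin-blanching response model with non-responders.
* **sc_profile** — depth profiles (mass/area/density → thickness) and
  per-site areal drug totals Q with configurable BLQ policy.
* **dpk_metrics** — input flux `J = (Q_up − Q_cl)/Δt`, first-order
  elimination rate `k = −ln(Q_cl/Q_up)/Δt`, relative depletion, percent of
  dose recovered, single-pass two-sided Grubbs outlier screen, and
  t-based 95 % CI summaries.
* **blanching** — control-corrected Δa\* normalisation and the signed
  trapezoidal AAEC (0–22 h) statistic with responder classification.
* **power_stats** — exact noncentral-t power and minimal sample size for a
  two-sided one-sample t test on a fractional change in a metric mean.
* **cli** — `scdpk` subcommands tying the stages into reproducible runs.

## CLI

```bash
# generate a full synthetic study (deterministic per seed)
scdpk simulate --seed 42 --out-dir study

# depth profiles, per-site Q, per-subject metrics, dose-level aggregates
scdpk analyze-sc --strips study/strips.csv --treatments study/treatments.csv \
    --out-dir analysis --blq-policy zero

# blanching AAEC and the responder matrix
scdpk analyze-sb --chromameter study/chromameter.csv --out-dir analysis

# power / sample-size table from metric summaries (metric, dose, mean, sd, n)
scdpk power --summaries summaries.csv --out power.csv

# everything end to end
scdpk report --seed 42 --out-dir report
```

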