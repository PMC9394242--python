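# dictatime

Timestamp-based dictation-time analytics for radiology workflows.

A Radiology Information System (RIS) logs the start of report dictation and
the first saving of the report. The interval between the two — the
*dictation time* — is a cheap, large-scale proxy for radiological reading
time, but it is contaminated by contextual outliers: interrupted reports
saved prematurely (too short) and reports paused and resumed later, e.g.
overnight (too long). `dictatime` provides:

- **Ingest** (`dictatime.io`): read timestamp CSV exports with configurable
  column names, compute dictation times in fractional minutes, exclude
  records saved at or before dictation start, and pool exams by canonical
  anatomical region via a configurable pattern map.
- **Outlier model** (`dictatime.mixture`): a contaminated-normal mixture —
  Normal(µ, σ) true-reading component with weight λ plus a fixed uniform
  background — fitted two ways: a reference EM algorithm and an iterative
  stochastic parameter-vector search (default 1000 iterations, candidate
  vector size 100 per parameter, geometrically shrinking search ranges).
  Records are labelled norm/outlier by the posterior probability of the
  normal component.
- **Reporting statistics** (`dictatime.stats`): mean/SD/median, adjusted
  skewness and excess kurtosis with exact small-sample standard errors,
  Kolmogorov–Smirnov normality test, Welch t test, exact/asymptotic
  Mann–Whitney U, and the CI-width sample-size rule
  `N = 4σ²(z_crit + z_pwr)²/D²`.
- **Synthetic data** (`dictatime.simulate`): labelled datasets with the
  four-component structure (short interrupts, normal reading, long
  continuations, unknown), emitted either as duration vectors or as
  round-trip-exact timestamp CSVs with optional save-before-start rows.
- **Pipeline** (`dictatime.pipeline` / the `dictatime` CLI): ingest → fit →
  classify → summarize, producing a per-region summary table
  (region, n_total, n_norm, mean/SD/median in minutes) with a pooled
  "All" row, per-region fit artifacts, and a reproducible, seed-stamped
  run log.

## CLI

```sh
# synthetic end-to-end run
dictatime simulate --n 5000 --seed 1 --region head --out sim/
dictatime run --input sim/timestamps.csv --method both --seed 1 --out run/

# individual stages
dictatime ingest --input sim/timestamps.csv --out ingest/
dictatime fit --input ingest/durations.csv --region head --method search --out fits/
dictatime classify --input ingest/durations.csv --region head \
    --fit fits/head_fit_search.json --out classified.csv
dictatime summarize --input ingest/durations.csv

# sample size for a mean CI of total width 1.5 min at SD 4.2, power 0.9
dictatime samplesize --sigma 4.2 --width 1.5

# two-group comparison (Welch t + Mann-Whitney U)
dictatime compare --a groupA.csv --b groupB.csv
```

Real exports with different column names are handled via `format_spec`
(Python API) and custom region maps via `--region-map map.yaml`
(label → list of regex patterns; unmatched codes pool into `other`).

## Reproducibility

Every stochastic routine takes a single integer seed; pipeline reruns with
an identical configuration produce byte-identical artifacts, stamped with
a configuration hash and the seed.
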