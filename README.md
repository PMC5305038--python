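# lickstat

Analysis toolkit for lickometry (automated recording of individual tongue
contacts during drinking) in two-group rodent studies. It covers the full
path from raw lick timestamps to a statistical report:

- **`lickstat.simulate`** — generative model of clustered licking
  (gamma within-cluster inter-lick intervals, shifted-lognormal pauses,
  lognormal per-lick volumes, 0.01 s timestamp quantisation) emulating a
  30-control vs 22-lesion design with 4 daily 15-min sessions.
- **`lickstat.microstructure`** — event-stream parsing, pause-criterion
  cluster segmentation, and the seven microstructure measures: total
  consumption, total licks, lick volume (mL per 1000 licks), licks per
  cluster, cluster count, mean inter-lick interval (ILI), and ILI
  variability (CV %).
- **`lickstat.inference`** — pooled-variance two-sample t, Mann–Whitney U
  (exact enumeration for small samples), one-way ANOVA with pooled-t
  post-hoc contrasts, Pearson correlation, Bonferroni family-wise control,
  the JZS (Jeffreys–Zellner–Siow) default Bayes factor for two-sample
  contrasts, and coefficient-of-variation comparison.
- **`lickstat.power`** — per-group sample size for a hypothetical
  treatment effect via the noncentral-t power function.
- **`lickstat.pipeline`** — one-config orchestration of
  simulate → summarize → compare with JSON/CSV reports and provenance.

## Documented analysis assumptions

Values the analysis needs but that are not uniquely fixed by convention are
exposed as flags and logged with every run:

- pause criterion **0.5 s** (`--criterion`) — a gap ≥ criterion starts a
  new cluster;
- ILI artifact floor **0.05 s** (`--artifact-floor`) — shorter intervals
  are treated as spurious double contacts and dropped from ILI statistics;
- JZS Cauchy prior scale **1.0** (`--rscale`) — the original two-sample
  default; this is the scale under which the package reproduces published
  K values computed the same way;
- subject-level values are the unweighted mean of the per-session values
  (not a re-pooling of raw licks);
- simulator group parameters (per-lick volume, cluster sizes, pause
  distribution) are plausible rat drinking values, not estimates from any
  particular dataset.

## CLI

```sh
# generate a synthetic cohort (events.csv + sessions.csv)
lickstat simulate --config cohort.toml --out data/ --seed 1

# per-subject microstructure summaries
lickstat summarize --events data/events.csv --sessions data/sessions.csv \
    --criterion 0.5 --artifact-floor 0.05 --out subject_summaries.csv

# seven-measure battery: t / Mann-Whitney, Bonferroni, Bayes factors
lickstat compare --summaries subject_summaries.csv \
    --family 7 --alpha 0.05 --rscale 1.0 --out report.json

# sample size for a treatment study (50% recovery toward control)
lickstat power --control-mean 100 --mcao-mean 0 --mcao-sd 100 \
    --improvement 0.5 --alpha 0.05 --power 0.8

# everything end to end from one TOML config
lickstat run --config run.toml
```

`cohort.toml` holds `CohortConfig` fields (`n_control`, `n_mcao`,
`sessions_per_subject`, `master_seed`, plus `[control_params]` /
`[mcao_params]` tables); `run.toml` nests the cohort under `[cohort]` and
adds analysis settings (`pause_criterion`, `artifact_floor`, `family`,
`alpha`, `rscale`, `out_dir`). See `tests/test_pipeline.py` and
`tests/test_cli.py` for complete examples.

## File formats

- `events.csv`: `subject_id,group,session_index,lick_time_s` — one row per
  lick, timestamps fixed-point at the recorder resolution (2 decimals at
  0.01 s).
- `sessions.csv`: `subject_id,group,lesion_subtype,session_index,consumption_ml`.
- `subject_summaries.csv`: subject metadata followed by the seven measures.

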