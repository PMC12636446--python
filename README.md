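# behaveseq

Behavioral age-detection and minute-resolution developmental transcriptome
reconstruction for single animals.

Isolated individuals are tracked as XY centroid trajectories; quiescence
bouts at larval-stage transitions are detected from smoothed displacement
speed, yielding each individual's hatch time, three stage-transition times
and a precise developmental age at collection. Single-animal expression
profiles are then sorted by that age to reconstruct smooth, minute-scale
gene-expression trajectories, cluster temporal patterns, compare genotypes
per developmental hour, and train a small neural network that predicts an
individual's age from its expression profile. A synthetic-data generator
with planted ground truth (stage schedules, temporal archetypes, genotype
effects) backs every stage with testable truth.

## Modules

| module | role |
| --- | --- |
| `behaveseq.synthetic_data` | locomotion tracks and expression cohorts with planted truth |
| `behaveseq.behavior_staging` | speed series, hatch detection, quiescence bouts, timelines |
| `behaveseq.expression_io` | counts ingest, RPM normalization, active-gene filter, age joining |
| `behaveseq.reconstruction` | gap-correlation curves, alignment comparison, trajectory smoothing, t-SNE, hourly pooling, reference comparison |
| `behaveseq.clustering` | hour-bin transform chain, correlation-distance Ward clustering, representatives |
| `behaveseq.differential` | per-hour-bin Mann-Whitney tests with BH FDR, fold changes, persistence |
| `behaveseq.age_model` | MAE-loss MLP age regression, feature sweeps, marker evaluation, subset search |
| `behaveseq.pipeline` / `behaveseq.cli` | end-to-end orchestration with config, seeds and provenance |

## Command line

```sh
behaveseq simulate --out run/ --seed 1 --n-individuals 20
behaveseq stage --tracks run/tracks --out run/timelines.tsv --threshold-frac 0.1
behaveseq normalize --counts run/counts.tsv --out run/rpm.tsv
behaveseq filter-active --counts run/counts.tsv --out run/active.txt
behaveseq reconstruct --rpm run/rpm.tsv --samples run/samples.tsv --out run/gap_curve.tsv --align l4
behaveseq pool --rpm run/rpm.tsv --samples run/samples.tsv --out run/pooled.tsv
behaveseq compare-ref --pooled run/pooled.tsv --reference ref.tsv --offset-hours 2
behaveseq cluster --rpm run/rpm.tsv --samples run/samples.tsv --out run/clusters --preset profiles --k 20
behaveseq diffexp --cond-rpm mut.tsv --cond-samples mut_samples.tsv --ref-rpm wt.tsv --ref-samples wt_samples.tsv --out de.tsv
behaveseq agepredict --rpm run/rpm.tsv --samples run/samples.tsv --out run/age_trials.tsv --trials 10
behaveseq run-all --config pipeline.yaml --out run/ --seed 1
```

Exit codes: 0 ok, 2 validation error, 3 compute error.

## Key conventions

- Speed is trailing-window displacement over 10 s; smoothing is a centered
  225-frame moving average. Quiescence threshold defaults to 0.1 x the
  median smoothed speed (scale-free).
- RPM = counts / per-sample total x 1e6, computed after dropping all-zero
  or missing genes. Active genes have >= 7 reads in >= 30% of samples
  (ceiling rule on the sample threshold).
- Clustering transform chain: hour-bin means, log2(n+1), per-gene z-score,
  optional first-bin normalization; distance D = 2(1 - Pearson r) treated
  as presquared for Ward (preset `profiles`), or 1 - r as the metric
  (preset `markers`).
- The age model is a 4-2-1 MLP with mean-absolute-error loss and L2
  penalty 7.3e-5 on weights; inputs are log2(x+1) standardized with
  training-set statistics. All randomness flows from explicit seeds.

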