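# ownflow

Analysis pipeline for **continuous body-ownership rating time series** (e.g.
rubber-hand-illusion experiments with a 0–1000 potentiometer readout sampled
at 1 Hz over 240 s: 120 s of visuo-tactile stimulation + 120 s
post-stimulation, four conditions per participant).

The pipeline covers:

- **Ingestion & preprocessing** (`ownflow.data_model`): long-format CSV
  validation, non-responder exclusion (never above 0 during rubber-hand
  synchronous stimulation), masking of the first 10 post-stimulation seconds,
  phase/block averages, proprioceptive drift, questionnaire component scores.
- **Changepoint analysis** (`ownflow.changepoint`): sync-minus-async
  "ownership effect" signals, 5-s centered moving average, and **exact**
  fixed-k (k ≤ 2) piecewise-linear least-squares segmentation — globally
  SSE-optimal via exhaustive search with O(1) prefix-statistic segment fits,
  verified against a brute-force oracle.
- **Estimation statistics** (`ownflow.estimation`): paired mean/median
  differences with 95% bias-corrected-accelerated (BCa) bootstrap intervals
  (5000 resamples, participant-level resampling) and qualitative evidence
  labels (none/weak/moderate/strong).
- **Individual differences** (`ownflow.association`): boxplot-criterion
  (1.5·IQR) outlier filtering, Spearman correlations with BCa intervals, and
  uncapped Bonferroni correction over the six-correlation family.
- **Synthetic cohorts** (`ownflow.synthetic`): piecewise-linear latent
  trajectories (onset → slow growth → plateau → two-rate decay) with
  condition gains, Gaussian noise, bounded/quantized readout, a non-responder
  subpopulation, and full ground truth for parameter-recovery tests.
- **Orchestration** (`ownflow.pipeline`, `ownflow.cli`): one-call/one-command
  full analysis with a deterministic JSON report bundle plus CSV tables.

## CLI

```bash
# generate a synthetic 30-participant study (CSV + ground-truth JSON)
ownflow simulate --n 30 --seed 7 --out simulated/

# run the full analysis
ownflow -v analyze \
    --ratings simulated/ratings.csv \
    --judgments simulated/judgments.csv \
    --questionnaire simulated/questionnaires.csv \
    --seed 1 --out analysis/

# segment a single effect signal (CSV with columns time_s,value)
ownflow changepoints --input signal.csv --k 2 --window 5

# re-render a JSON report bundle to CSV tables
ownflow report --input analysis/report.json --out analysis/
```

`analyze` writes `report.json` (full bundle: config echo, exclusions,
whole-phase and block-wise contrasts, group and per-participant changepoints
with landmark rate-of-change tables, six correlations, drift/questionnaire
summaries) plus `contrasts.csv`, `individual_changepoints.csv`, and
`correlations.csv`. Everything is deterministic under a fixed `--seed`.

### Input formats

- ratings: CSV `participant_id,condition,time_s,rating`, condition ∈
  {rh_sync, rh_async, wood_sync, wood_async}, time_s ∈ 1..240, rating ∈
  [0, 1000] (missing seconds allowed, never imputed)
- judgments: CSV `participant_id,condition,baseline_cm,post_cm`
- questionnaires: CSV `participant_id,condition,item_id,response`
  (Likert −3..+3); component→item maps are YAML-configurable
  (`ownflow.data_model.ComponentMap`)

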