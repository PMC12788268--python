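# jugglekit

Tools for decomposing early three-ball juggling skill into three measurable
sub-skills — **Sequencing** (rhythmic 120° phase coordination of the balls),
**Prediction** (catching a transiently occluded ball), and **Accuracy**
(spatial consistency of catch locations) — and for modeling day-level
juggling performance as a joint function of the three with a Gamma GLM.

It is aimed at motor-learning researchers who record juggling (or similar
rhythmic multi-object tasks) with video and motion capture and want a
tested, reproducible pipeline from frame-wise detections to a fitted
performance model. Because raw recordings of this kind are rarely shareable,
the package ships a first-class synthetic-data generator that emulates the
statistical structure of such a study with full ground truth, so every
stage of the pipeline is testable end to end without any download.

## The indices and the model

**Sequencing.** For each ball `b`, the smoothed, mean-subtracted vertical
position `ỹ_b(t)` is converted to an instantaneous phase via the analytic
signal, `φ_b(t) = arg(ỹ_b(t) + i H{ỹ_b(t)})`, with `H` the Hilbert
transform. For every window spanning three consecutive flight apexes from
three distinct balls, the window score is

    S_w = (1/K) Σ_k [ 1 − (δ12 + δ13 + δ23) / (3·180°) ],

where `δ_ij` is the circular distance of the pairwise phase difference from
the ideal ±120° offset, folded to [0°, 180°]. `S_w = 1` means perfectly
maintained 120° spacing; the day-level index `S` is the mean of all pooled
window scores. Days with too few windows (below
`exp(mean(log N) − 3·sd(log N))`) are excluded as unstable.

**Prediction.** `P = N_succ / N_valid`: the fraction of valid two-ball
occlusion trials in which both hands complete the second catch.

**Accuracy.** Second-catch positions are expressed in a wrist-centred frame;
per hand and block a 95% probability ellipsoid is fitted
(`V = (4/3)π c^{3/2} √det Σ̂`, `c = χ²₃(0.95) ≈ 7.815`), and `A` is the
geometric mean of the stable volumes. Smaller `A` = tighter clustering.

**Performance model.** After monotone transforms (logit for `P`, −log for
`A`) and robust z-scoring (`z = (x − median)/(1.4826·MAD)`), day-level
performance (mean catch count over the ten best trials) is modeled as

    Perf ~ Gamma(μ, φ),   log μ = β0 + β_P Z_P + β_A Z_A + β_S Z_S,

fitted by IRLS, with Wald inference, AIC / Cox–Snell pseudo-R², day-wise
metrics, leave-one-subject-out cross-validation (LOSO-CV), and a ladder of
sensitivity models (interactions, Group/Day fixed effects, participant
intercepts). A Normal-Identity GLM is fitted alongside as the comparator.

## Worked example

Run the full synthetic study (20 participants × Days 1/5/10, two training
groups) and fit the model:

```bash
jugglekit run --seed 1 --out demo_out
```

or from Python:

```python
from jugglekit import pipeline

cfg = pipeline.StudyConfig(seed=1)
result = pipeline.run_pipeline(cfg, out_dir="demo_out")
print(result["report"]["glm"]["gamma_log"]["coefficients"])
```

With seed 1 this prints (abridged) the Gamma-Log coefficient table

| predictor | β | SE | z | p | exp(β) |
|---|---|---|---|---|---|
| Intercept | 2.6175 | 0.1091 | 23.98 | <0.001 | — |
| Z_P | 0.3397 | 0.1127 | 3.01 | 0.0026 | 1.404 |
| Z_A | 0.1085 | 0.1190 | 0.91 | 0.362 | 1.115 |
| Z_S | 0.6195 | 0.1549 | 4.00 | <0.001 | 1.858 |

together with fit metrics (log-likelihood −211.08, AIC 430.16, Cox–Snell
pseudo-R² 0.625, R² 0.669, RMSE 15.97, LOSO R² 0.623) and the Normal
comparator (AIC 508.06). Read: a one-robust-SD gain in Sequencing
multiplies expected performance by ~1.86, Prediction by ~1.40, while
Accuracy's unique contribution is small and not significant — the
generative coefficients behind this dataset were (2.5563, 0.4073, 0.1669,
0.5279), and the fit recovers them within sampling error. The run also
writes `day_indices.csv` / `.parquet`, per-window scores, group medians
with IQR, a machine-readable exclusion log, and `report.json`.

Stage-level subcommands (`simulate`, `track`, `sequencing`, `occlusion`,
`transform`, `fit`) operate on CSV/parquet tables, so real detection or
trial tables can be substituted for the synthetic ones at any point.

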