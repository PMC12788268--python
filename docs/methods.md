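# Methods

This note documents the models, algorithms and numerical choices behind
jugglekit, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic cascade kinematics

The generator emulates the raw streams of a juggling training study rather
than any particular recording. A three-ball cascade trial is built from a
jittered throw schedule: ball `b` is thrown at `b·T/3 + c·T` (cycle period
`T`, default 1.35 s) plus Gaussian timing noise with sd
`phase_jitter_sd · T / 2π` seconds, so `phase_jitter_sd` is interpreted
directly in radians of cycle phase. Consecutive throws of one ball are
floored at one flight time plus a short dwell apart — a ball cannot be
re-thrown before it lands. Each flight is ballistic under the configured
gravity (fractions of 9.81 m/s² model the reduced-gravity training
conditions); between catch and re-throw the ball follows a constant-
acceleration hand-carry arc that matches position and velocity at both
ends. With the default dwell fraction of 0.5 the flight and carry arcs are
mirror parabolas, giving a C1-continuous, near-sinusoidal periodic
waveform. We model the carry explicitly (rather than freezing the ball in
the hand) because a flat hold injects harmonics into the vertical series
that are an artifact of the simplification, not of juggling, and those
harmonics corrupt Hilbert phases. A one-dwell warm-up before the first
throw starts every ball mid-carry, so trials open in steady-state motion.

Lateral geometry follows the cascade "scoop": balls are released near the
midline (±0.06 m) and caught outside (±0.34 m). This matters: with equal
throw and catch positions the two flight arcs intersect in both space and
time and the simulated balls collide, which no real cascade does. Hands
rest at the catch position and carry their held ball; after a final catch
a ball rests in the hand with a small per-ball offset (two balls held in
one hand are a ball-diameter apart, not coincident).

Per-throw drops are Bernoulli with a configurable hazard; a drop truncates
the trial at the failed catch, and the trial's catch count is the number
of completed catches before it. Ground truth (nominal phases, event times,
catch counts) is returned alongside.

The detection-corruption stage turns clean tracks into unordered per-frame
candidate lists: each ball survives with probability `1 − dropout`,
perturbed by isotropic Gaussian noise; Poisson false positives are uniform
in the frame; candidate order is shuffled. An optional pixel calibration
(400 px/m, 720-pixel frame, y down-positive) projects to camera
coordinates; everything downstream works in metres with vertical
up-positive, and pixel frames are flipped once on ingest.

The occlusion-session generator draws, per trial, a joint both-hands catch
success (Bernoulli; `success_prob` is the probability that *both* hands
succeed, which is what the Prediction index measures) and, for successful
catches, a 3-D catch position equal to the wrist position plus a draw from
`N(0, catch_cov)`. Shutter intervals follow the trial condition:
apex-locked (0.5 s from the flight apex), none, or uniformly random over
the flight (the uniform law is our choice; nothing constrains it).

The whole-study generator assigns the first half of participants to the
Low-g group and gives each participant three independent log-normal skill
factors (sd 0.25 on the log scale), one per sub-skill — the premise of the
decomposition is that the three indices are separable abilities, and
independent factors also keep predictor collinearity at realistic levels
(VIF well below 2). Day schedules make timing jitter fall (0.9 → 0.35 rad),
catch success rise (0.55 → 0.92) and catch scatter tighten (9 → 5 cm sd)
across Days 1/5/10; these values were chosen once as plausible early-
learning magnitudes. Modeled performance is then drawn from the Gamma-Log
generative model (default β = (2.5563, 0.4073, 0.1669, 0.5279), dispersion
φ = 0.6) given the standardized indices computed from the simulated
kinematics, so the pipeline's final stage is a parameter-recovery problem
with known truth. The kinematic catch-count performance (top-ten rule) is
computed and written as well.

## Tracking and event labeling

Frame-to-frame association is greedy globally-cheapest assignment: per
frame, (track, candidate) pairs are consumed in order of distance between
the candidate and the track's constant-velocity prediction, gated at
`max_jump` metres per elapsed frame (default 0.15). Unmatched tracks coast
up to `max_gap` frames (default 5) and close; unmatched candidates seed
new tracks; the `n_balls` longest tracks are kept. Greedy assignment was
chosen over the Hungarian algorithm for transparency; with a gate it is
exact on non-crossing fixtures, and on the default cascade it keeps
identities through path crossings because the velocity prediction
disambiguates them. A warning is emitted when retained tracks cover less
than 80% of frames.

Throws are labeled when a held ball leaves the hand's neighbourhood
(default radius 0.1 m) with upward velocity; catches when the ball enters
the opposite hand's neighbourhood and stays for `min_hold` frames (default
3 at 60 Hz). Radius and hold are config-exposed since no canonical values
exist. A pick-up at a trial edge sets the holding hand without emitting an
event, so labeled events always alternate throw/catch.

Trial trimming on detection tables uses two height lines: a segment opens
when ≥2 candidates rise above the knee line, is confirmed when any
candidate crosses the shoulder line, and closes after a 1 s lull. This is
a rule-based reconstruction operating on detection tables, not on pixels.

## Sequencing numerics

The vertical series is low-pass filtered with a zero-phase (forward–
backward) 4th-order Butterworth and mean-subtracted before the Hilbert
transform. The default cutoff is 2 Hz at 60 Hz sampling: the cascade
fundamental is ~0.7–0.8 Hz, and the purpose of the filter is to isolate
the rhythmic component whose phase Eq.-style scoring assumes; a wider band
(e.g. 5 Hz) retains flight/carry harmonics that ripple the analytic-signal
phase and depress the score of a perfectly sequenced cascade for reasons
unrelated to sequencing. The cutoff is config-exposed.

Apexes are downward zero-crossings of the (gradient-estimated) vertical
velocity with negative acceleration, refined by linear interpolation of
the crossing, with a quarter-cycle refractory and an amplitude floor of
half the series SD (flight apexes sit near the top of the oscillation; the
floor rejects filter ripples around resting balls). Windows are maximal
runs of three consecutive apexes with pairwise-distinct ball labels and
overlap by sliding one apex at a time — whether windows should overlap or
tile is genuinely open; overlapping uses all the data and is what we
implement.

Because no ball ordering is privileged, the pairwise deviation `δ_ij` is
the circular distance from the raw difference `φ_j − φ_i` to the *nearest*
of +120° and −120°, folded to [0°, 180°]; this makes the score invariant
to ball relabeling and to common phase rotation (property-tested). The
first and last full cycle of each trial are excluded from usable samples
to avoid Hilbert and filtfilt edge effects; phases are computed per trial
and windows never span trials. Hand-evaluated anchors: exact 120° spacing
scores 1; three in-phase balls score 1/3; one ball off by ε scores
1 − ε/270. The implementation is tested against a naive loop oracle to
1e−12 on random phase fixtures.

The day-level index is the arithmetic mean of pooled window scores.
Participant-days whose window count falls below
`exp(mean(log N) − 3·sd(log N))` (computed over positive counts, pooled
across the study; zero-count days always excluded) are set missing, since
a mean over a handful of windows has unusable variance.

## Occlusion indices

The 95% probability ellipsoid is the Gaussian coverage ellipsoid of the
sample covariance (n−1 normalisation, no small-sample F correction — the
common reading; a correction would rescale volumes by a known factor),
`V = (4/3)π c^{3/2} √det Σ̂` with `c = χ²₃(0.95)`. Fits are unstable, and
excluded from Accuracy, when n < 4 or the covariance eigenvalue ratio
falls below 1e−6. Accuracy is the geometric mean of the stable volumes
over both hands and all blocks — identical to the `1/(2|B|)`-exponent
product when every block is stable for both hands, and a plain geometric
mean of the survivors otherwise. All occlusion conditions contribute to P
and A unless filtered by config; which conditions the indices should use
is not determinable and the choice is exposed.

## Transforms

Prediction is clipped to [1e−4, 1−1e−4] and logit-transformed (it is
bounded and ceiling-prone); Accuracy is −log-transformed (positive,
right-skewed, and the sign flip makes larger better); Sequencing is used
raw. Each is robust z-scored with median/MAD (consistency constant 1.4826)
over the pooled participant-day table. When MAD is zero (more than half
the values tied) the sample SD is substituted and flagged; a fully
constant column is an error that the pipeline surfaces as a skipped GLM
stage with a message — this is the expected behaviour of a zero-noise
configuration, where P ≡ 1 carries no information to standardize.
Day-level Perf is the mean of the ten largest per-trial catch counts; with
fewer than ten trials the mean of all is used (the short-day behaviour had
to be chosen; using all trials is the least surprising option).

## GLM estimation and evaluation

The Gamma-Log GLM is fitted by IRLS. Under the log link the working
weights are identically one, so each iteration regresses the working
response `η + (y − μ)/μ` on X; iterations stop when the maximum
coefficient change drops below 1e−10 (relative), with step-halving
whenever a full step would increase the deviance and a linear-predictor
clip at ±300 for numerical safety on extreme inputs. The dispersion used
for Wald standard errors is the Pearson estimator
`φ = Σ((y−μ)/μ)²/(n−k)`; the reported log-likelihood profiles the Gamma
shape numerically at the fitted means (shape 1/φ, scale μφ), and both
dispersions are reported. AIC counts the k regression coefficients only,
the convention under which `AIC = −2ℓ + 2k` matches the arithmetic of
standard GLM output for this family; confidence intervals use the fixed
normal multiplier 1.96. The Normal-Identity family reduces to ordinary
least squares (its ML variance SSE/n is used in the log-likelihood, the
unbiased SSE/(n−k) for standard errors). The IRLS path is verified in
tests against an independent numerical maximizer of the Gamma likelihood
and against statsmodels' GLM to ~1e−7.

Cox–Snell pseudo-R² is `1 − exp((2/n)(ℓ₀ − ℓ₁))` with ℓ₀ from an
intercept-only fit of the same family. Day-wise R²/RMSE evaluate the
pooled fit inside each day; negative within-day R² is reported as 0.000
and flagged, the truncation convention for subsets a pooled model cannot
explain. LOSO-CV refits on all-but-one participant, pools held-out
predictions, and scores them with SST about the pooled observed mean (the
definition is not canonical; pooled SST is ours). The residual summary
reports median and median-absolute residual over rows with observed
response at or below `median + 3·1.4826·MAD`, excluding the upper tail
that a right-skewed response produces.

Factors use treatment coding (Group reference Normal-g; Day and
Participant reference their smallest level). The sensitivity ladder fits:
base; base + pairwise skill interactions; + Group and Day fixed effects;
+ participant fixed intercepts (which absorb the between-subject Group
factor — including both is rank deficient by construction); and, when a
pre-exclusion table is supplied, the base model on the full data with
missing Z_S imputed at the standardized median (0). Rank-deficient or
non-convergent extended designs are reported as failed rows, not fatal.

## Pipeline, sizes, determinism

`run_pipeline` composes generation → tracking → event labeling →
sequencing → occlusion indices → transforms → performance generation →
GLM reports, writing CSV (float format `%.10g`), a parquet copy of the
merged table, JSON reports with sorted keys, and an exclusion log whose
day-level rows correspond one-to-one with excluded participant-days. All
randomness flows from `numpy` `SeedSequence`s spawned per participant/day
from the master seed, so a re-run with the same config is byte-identical.
Group summaries use medians and type-7 (linear-interpolation) quantiles
for the IQR.

The default study is 20 participants × 3 days with 4 cascade trials of 10
cycles and 60 occlusion trials per participant-day (~60 modeled rows,
matching the scale at which the model is meant to operate); the
occlusion-heavy test-day protocol (4 × 75 trials) is available through the
config. Test-suite simulations use 6-participant studies and the
parameter-recovery harness draws standardized indices directly (500
datasets of 57 rows), which exercises the estimator at study scale without
re-simulating kinematics.

## What passing tests do and do not show

The generator reproduces the statistical structure the analysis assumes —
ballistic periodic trajectories, per-cycle timing noise, Bernoulli catch
outcomes with Gaussian scatter, Gamma-distributed day performance — with
known ground truth, and the suite shows the pipeline recovers that truth
(phases to <1°, events to ±2 frames, tracker identity ≈99–100%, GLM
coefficients unbiased with ~95% CI coverage). It does not emulate real
video failure modes (motion blur, lighting, occlusion by the body,
pose-estimation bias), marker dropout structure, or non-Gaussian timing
noise; the throw-timing law in particular is Gaussian by choice, since no
distributional model of real throw jitter is available. Conclusions about
real recordings therefore rest on the correctness of the operations, not
on the realism of every noise source. Known limitations: the two-ball
Accuracy index is a proxy for spatial control in the three-ball task; the
base model treats participant-days as independent (participant intercepts
are a sensitivity check, not a mixed model); and no Tweedie or
inverse-Gaussian alternatives are implemented.
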