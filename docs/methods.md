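# Methods

## Model and procedure

The package decodes internal-attention states from whole-brain multivoxel
fMRI patterns, one subject at a time.

**Step 1 — classifier training.** For each of the five task conditions
(Breath, Feet, MW, Self, Sounds) a binary logistic regression (that condition
vs. the rest) is fit on the labeled volumes of the internal-attention task.
The objective is the regularized negative log-likelihood
`sum(log-loss) + lambda * ||w||^2` with `lambda = 0.01`; intercepts are
unpenalized. Because scikit-learn parameterizes the same objective as
`C * sum(log-loss) + ||w||^2 / 2`, the fits use `C = 1 / (2 * lambda)` (= 50
at the default penalty) — results are therefore directly comparable with
implementations that use either convention. Fits use lbfgs with tolerance
1e-6 and are deterministic given the data. Each model emits an *evidence*
value `sigmoid(w.x + b)` per volume, clipped into the open unit interval at
1e-12; the five evidences are independent and deliberately not normalized to
sum to 1. The categorical decision is the argmax; exact ties are broken by
condition declaration order (Breath, Feet, MW, Self, Sounds) with a warning,
which makes decisions deterministic and auditable.

Condition labels are shifted 6 s later in time before training and testing,
within block only, to account for hemodynamic lag; volumes vacated at the
block start become unlabeled and labels pushed past the block end are
dropped. Unlabeled volumes (baselines, 2-s auditory instructions) never
enter training or accuracy denominators.

Accuracy is estimated with leave-one-block-out cross-validation: six folds,
each trained on the 1,800 labeled volumes of five blocks and tested on the
held-out block's 360, so each of the 2,160 labeled volumes is tested exactly
once by a model that never saw its block. Per condition, a chi-square
goodness-of-fit test compares correct/incorrect counts to the exact chance
split (0.2 n, 0.8 n) = (86.4, 345.6) for n = 432; printed counts elsewhere
that round these to 87/345 are treated as display rounding, not test
parameters. A subject is *included* for meditation decoding when at least
two of the three meditation-relevant conditions (Breath, MW, Self) are
classified above chance at p < 0.001. Group accuracy is a two-sided
one-sample t-test against 20% with Cohen's d; when every subject sits
exactly at chance, t and d are defined as 0.

**Ratings.** Trial-level accuracy (mean correct decisions over a trial's
shifted volumes) is correlated with the subject's 1–4 attention ratings
(Pearson), transformed with Fisher's r-to-Z, and tested against zero across
subjects. Subjects with zero variance in either variable have an undefined
correlation and are excluded from the group test with a warning.

**Importance maps.** A voxel's importance for a condition is its classifier
weight times its z-scored average activation during the condition's volumes.
Each voxel's time series is z-scored across all volumes of the run, then
averaged over the condition's labeled volumes; an alternative mode z-scores
the raw condition means across voxels instead (`zscore_axis="voxels"`), since
either axis is defensible and both are exposed. Voxels where weight and
activation are both positive form the positive-importance class, both
negative the negative class; mixed-sign voxels belong to neither class and
are never retained — only the two concordant classes are meaningful
(a mixed-sign product says the voxel's activation opposes its weight).
Thresholding z-scores the importances across voxels and retains concordant
voxels with |z| >= 2 (about 4.55% under a Gaussian). Frequency maps count,
per voxel, the subjects retaining it (positive and negative pooled by
default, separable by flag); mask overlap is the percentage of retained
voxels inside a user-supplied binary mask. Spatial normalization and
smoothing are out of scope: group maps require a shared voxel grid, which
synthetic subjects have by construction.

**Step 2 — meditation decoding.** The model trained on all five conditions
(2,160 volumes) is applied to each decodable meditation volume and
restricted to Breath/MW/Self by taking the argmax over those three
evidences; Feet and Sounds are never emitted. A singleton decision — a run
of length 1 whose two flanking runs share one state and each have at least
`min_flank = 2` volumes — is relabeled to the flanking state, so the merged
run has at least 5 volumes and is necessarily an event. The flanking
requirement of 2 is the default reading of "a lone decision between two
events of the same type"; stricter (>= 3) and looser (>= 1) readings are
config options. Smoothing is a single left-to-right pass evaluated on the
original run structure; an iterative mode that rescans after merging exists
but is off by default (with the default flank requirement the two coincide,
because a length-1 flank can never grow without already qualifying). Mental
events are maximal same-state runs of `min_event_length = 3` or more
decisions; shorter runs are excluded and reported as a percentage. Runs are
truncated at the boundary between the two meditation blocks: a state cannot
be observed across a scan gap. Alternate event lengths (2, 4) and smoothing
on/off are exposed for sensitivity analyses but are not part of the default
output.

**Step 3 — attention metrics.** Per state: percentage time engaged
(event volumes over all decodable volumes), number of events, mean event
duration, and sample SD of durations (n−1 denominator; undefined below two
events, reported as missing rather than 0). Using all decodable volumes as
the denominator makes the identity
`sum(pct_time) + pct_excluded = 100` exact; an event-time-only denominator
is available as a flag-equivalent (normalize from the reported quantities).
Group contrasts are a one-way repeated-measures ANOVA (subject as blocking
factor, matching the paired follow-ups) per metric, followed by planned
paired t-tests of Breath − MW and Breath − Self. The ANOVA is computed from
the classical sum-of-squares decomposition rather than delegated, so that
degenerate inputs resolve explicitly: zero between-state variation gives
F = 0 (even when the residual is also zero), zero residual with real state
differences gives infinite F; the implementation is cross-checked against
statsmodels' repeated-measures ANOVA on non-degenerate data in the test
suite. Subjects with missing values for a metric are dropped from that
metric's ANOVA with a warning; paired t-tests use pairwise-complete
subjects, and identically-zero difference vectors give t = 0.

## Synthetic data

The generator emulates the study conditions of the internal-attention task
so the pipeline can be validated end to end.

**Task design.** Six blocks of 13 trials (3 each Breath/Feet/Sounds, 2 each
MW/Self), each block flanked by 20-s baselines, each trial preceded by a 2-s
unlabeled instruction. Short-condition durations are even values in 16–32 s;
across the experiment each value is used exactly twice per condition, and a
seeded backtracking search partitions each condition's 18 durations into six
triples of 72 s. MW/Self durations are even values in 22–50 s paired to
72 s per block, with first elements spread over the range. These constraints
make every block deliver exactly 72 s per condition (432 s per condition and
2,160 labeled seconds over the experiment). Block counts that are not
multiples of 3 cannot balance the duration pool and raise an error. The
four stimulus-order sets of the original protocol are unpublished, so four
order permutation sets are generated pseudo-randomly per seed and
`order_set` selects among them. Ratings are eligible only for trials in the
last half of the experiment and never for MW trials (subjects instructed to
stop attending are not asked how well they attended): 33 of 39 trials in the
default design.

**Signal model.** Each condition has a fixed multivoxel pattern with i.i.d.
Gaussian entries of SD `snr * noise_sd` on the active voxel subset
(`active_fraction = 1` by default; sparse patterns support importance-map
recovery tests). During a trial the pattern is added with a pure 6-s onset
delay — mirroring the analysis-side label shift; HRF convolution is left as
an extension — and scaled by a per-trial attention fidelity drawn uniformly
from (0.7, 1.0) by default, a modest waxing and waning of attention. Noise
is AR(1) Gaussian (phi = 0.3, marginal SD `noise_sd = 1`) plus a per-voxel
linear drift with maximum excursion `drift_scale = 1` noise-SD per block:
the minimal noise structure that exercises detrending and temporal
autocorrelation without claiming physiological realism. `snr` is therefore
the per-voxel pattern amplitude in noise-SD units, and `snr = 0` removes all
condition-dependent signal — the null pipeline's cross-validated accuracy
calibrates at 20% chance (checked to within 2 points over 5 seeds).

**Meditation run.** The hidden state sequence is a semi-Markov chain over
the states in the requested occupancy: dwell times are `min_dwell = 3` plus
a geometric tail with state-specific mean proportional to occupancy, and
successors are uniform among the other states, so visit frequencies are
uniform and long-run occupancy matches the target (default Breath 0.5,
MW 0.25, Self 0.25 — a practitioner mostly on the breath; mean dwell 10 s).
The run is split into two blocks (4- and 6-min proportions); each block is
prefixed with 8 s of instruction volumes (6-s instruction + 2-s reminder)
flagged non-decodable, so exactly 600 decodable volumes remain. Emission
uses the subject's own condition patterns at fidelity 1 with the same noise
and drift model, and applies no hemodynamic delay — decoding applies no
label shift either, so the two conventions cancel; a lagged emission would
only shift the decoded sequence by 6 s without changing occupancy.

**Ratings.** A trial's rating is a rank-quartile discretization of
`coupling * fidelity + Gaussian noise`, which is monotone in the latent
attention score, always spans 1–4, and becomes independent of fidelity at
`coupling = 0`.

**What the generator does not emulate** — spatial smoothness and
inter-voxel correlation, physiological (cardiac/respiratory) confounds,
susceptibility artifacts, HRF shape, and head motion. Passing tests
therefore demonstrate the correctness and calibration of the analysis chain
under a known generative model, not performance on real scanner data, where
preprocessing quality and pattern stability dominate.

## Numerical choices and problem sizes

- Detrending is per block (blocks are separate scanner runs); it and
  confound regression are idempotent to 1e-10 and are checked as such.
- Confound regression adds an intercept and falls back to a pseudo-inverse
  with a warning when the design is rank-deficient.
- Non-integer lag/TR ratios round to the nearest volume with a warning;
  negative lags are rejected.
- Logistic fits: lbfgs, tol 1e-6, max 2,000 iterations.
- Validation problem sizes were chosen to keep the suite fast while leaving
  no statistical ambiguity: 500 voxels and 5 seeds for the chance-level
  calibration, 100–200 voxels elsewhere, 10,000 random sequences for the
  segmentation cross-check against the brute-force reference.

## Known limitations

- Per-block detrending removes each block's mean pattern. With a
  heterogeneous state sequence this preserves between-state contrasts
  (occupancy recovery at snr = 2 is within 5 percentage points), but a
  meditation run spent entirely in a single state is unidentifiable after
  demeaning — the pure-single-state contract holds for decoding the raw
  emission.
- The dwell-time floor slightly distorts occupancy for extremely skewed
  targets (mean dwell clamped at `min_dwell`).
- Group importance maps assume a shared voxel grid; registration of real
  data to a common space is the caller's responsibility, and anatomical
  masks are user-supplied.
- The repeated-measures ANOVA assumes sphericity and applies no correction;
  with three levels and the intended planned contrasts this is the
  conventional choice.
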