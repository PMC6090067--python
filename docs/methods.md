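# Methods

This note documents the statistical model behind `swa-brainage`, its
defaults and numerical choices, and what the synthetic benchmark does and
does not establish.

## The signal

The unit of analysis is one mouse's NREM slow-wave activity (SWA) profile:
EEG power in the delta band (default 0.75–4.0 Hz, reported in μV²/0.5 Hz),
averaged per hour over the 12-h baseline light period — a 12-dimensional
vector `s`. Six experimental groups are compared: ages A ∈ {6, 18, 24}
months crossed with exercise E ∈ {running wheel (RW), sedentary control};
the class variable is C = (A, E).

Two facts make SWA a candidate "brain age" marker: it rises with age and
falls with long-term voluntary exercise, with control-minus-RW offsets of
47, 24.8 and 60.44 μV²/0.5 Hz at 6, 18 and 24 months in the light-period
mean.

## Spectral reduction

Epoch-level inputs are power spectra of 4-s epochs on a 0.5–25 Hz grid at
0.25 Hz resolution, each epoch labelled WAKE/NREM/REM with an artifact
flag. Band power sums the per-bin values across the band — inclusive of
both edges, which matches "between 0.75 and 4.0 Hz" on a discrete grid —
and rescales to power per 0.5 Hz (`sum * 0.5 / bandwidth`). Hour h averages
the band power of artifact-free NREM epochs whose offsets fall in
`[h·3600, (h+1)·3600)` s from lights-on, with equal weight per epoch. An
hour with fewer than `min_epochs` usable epochs (default 45, i.e. 3 min of
NREM) is flagged undefined, and an incomplete profile is ineligible for
profiling and clustering; nothing is imputed.

## Supervised stage: templates, perceived information, success rate

Profiles are reduced by PCA (default d = 3, configurable 1–12; directions
from the SVD of the centered profiling matrix, sign fixed by each loading's
largest-magnitude entry). Each class is modelled as a multivariate normal
*template* N(μ_c, Σ_c) in the projected space.

**Template estimation.** μ_c is the projected sample mean. For Σ_c the raw
sample covariance (n−1 denominator) is a poor estimator at this package's
operating point — 4 to 11 profiles per class in 3 dimensions — because the
smallest eigenvalue of a low-degree-of-freedom Wishart is severely biased
toward zero, and a maximum-likelihood template with a spuriously collapsed
direction assigns vanishing likelihood to its own class's held-out signals.
The default estimator therefore applies Ledoit–Wolf shrinkage toward the
spherical target, with the shrinkage intensity estimated from the same data
(parameter-free; heavy shrinkage at n = 4, negligible at n = 500). On top of
that a diagonal ridge of `regularization × mean(diag)` (default 10⁻⁶) is
added and escalated by factors of 10 until the covariance is
positive-definite with condition number ≤ 100. `shrinkage=None` and
`max_condition=inf` recover the plain sample-covariance template; that mode
is exactly affine-covariant and is used to verify the affine invariance of
the Bayes machinery in the tests.

**Perceived information.** PI(S;C) = H(C) − H(C|S), where the conditional
entropy uses the *model* posterior (Bayes' rule over the six templates)
evaluated under the *true* conditional distribution, sampled empirically
from held-out data. Evaluation is leave-one-out: for each signal, the
projection and all templates are refit on the remaining signals (no
leakage; the ordering of PCA and partitioning is deliberately leakage-free),
and the log₂ posterior of the signal's true class is recorded. Pooled over
all rounds, each class's test set is its full membership, so
Pr_true[s|c] = 1/n_c and

    PI = H(C) + Σ_c Pr[c] (1/n_c) Σ_{s∈c} log₂ Pr_model[c|s].

This is reported as the mean of per-partition values
`H(C) + (N·Pr[c]/n_c)·log₂ Pr_model[c|s]`; the alternative reading that
treats every singleton partition as a complete test distribution
(Pr_true = 1) is not used because it does not vanish in the
no-information limit. Class priors default to uniform (H(C) = log₂6 ≈
2.585 bits); empirical priors (group sizes / total) are an option. All
likelihoods live in log space with log-sum-exp normalization; posteriors
are floored at 10⁻³⁰⁰ before log₂ so the sum is finite for any input.

A percentile bootstrap CI resamples the per-partition values (default 100
resamples, CI endpoints at the 5th and 95th percentiles of the resample
means), seeded.

**Known behavior of PI.** PI ≤ H(C) always, with equality only under
perfect posteriors. Under *imperfect* templates PI underestimates the
mutual information and can be negative: E[log₂ p] < log₂ E[p] whenever the
posterior fluctuates (Jensen). At n = 9/class and d = 3 the measured null
bias (all classes one distribution) is ≈ −0.5 bits with shrinkage templates
(≈ −1.8 without), decaying to ≈ −0.1 at n = 40/class. A near-zero null PI at
these cohort sizes is therefore not achievable by the estimator itself; the
corresponding test documents this expectation honestly.

**Success rate.** Each class is split into ⌈n/2⌉ profiling and ⌊n/2⌋ test
signals (stratified, seeded; the split stream is keyed by the class's
member indices so relabelling groups permutes reports without changing the
partitions). Templates are fitted on the pooled profiling halves and each
test signal is assigned by maximum template likelihood; exact ties go to
the lowest class index with a warning. The report carries the 6×6 confusion
matrix and the fraction correct. A single split is the default; `repeats`
accumulates several seeded splits.

## Unsupervised stage: k-means, Gap statistic, brain age

Profiles are reduced by class-blind pooled PCA to d = 3 and clustered by
Lloyd's k-means: prototypes sampled without replacement from the
observations, nearest-centroid assignment (ties to the lowest index), empty
clusters reseeded from the point farthest from its centroid, iteration
until the relative change of the within-cluster sum of squares W_k is below
10⁻⁸ (cap 300 iterations), best of `restarts` runs by W_k (default 1000,
mirroring the source procedure's 1000 repetitions read as restarts).

The cluster count is selected by the Gap statistic:
`Gap[k] = mean_b log W_k^(b) − log W_k` over B reference sets (default 100)
drawn uniformly over the feature-wise bounding box of the points (the
simpler of Tibshirani's two reference schemes; the principal-axes-aligned
box is available as `reference="pca_box"`). k* is the global maximizer of
Gap over k = 1..k_max (default 6); the conventional 1-SE rule is available
but off by default. Reference sets use 25 k-means restarts — uniform box
samples have no delicate optima, and this keeps the stage fast; the data
clustering uses the full restart budget. Degenerate input (all points
identical) yields k* = 1 with a warning.

Group centroids (k-means centroids mapped to groups by majority vote when
the mapping is bijective, per-group means otherwise) feed a pairwise
Euclidean distance matrix, reported to 2 decimals in text outputs and at
full precision in JSON. Taking the young-RW group as the healthy reference,
the distance of each group's centroid from the reference centroid is a 1-D
"brain age"; for each age with both conditions present the percent
attenuation `100·(d_control − d_RW)/d_control` (rounded to the nearest
integer) quantifies how far exercise moves a group back toward the
reference. On the published centroid coordinates this machinery reproduces
the published distance table to 2 decimals and a 24-month attenuation of
19.94% → 20%; the 18-month value recomputes to 30.5%, which this package
rounds to 31 (the original report prints 30; the discrepancy is a rounding
convention in the source, so only the 24-month value is asserted exactly).

## Synthetic cohort generator

The generator draws each mouse's profile from its class's 12-dim
multivariate normal — the same distributional assumption the templates
make. Defaults encode what is externally constrained: group sizes 11, 8, 9
(controls) and 9, 9, 8 (RW); control light-period means rising with age;
control-minus-RW offsets 47 / 24.8 / 60.44 μV²/0.5 Hz. Absolute levels are
not externally constrained, so the young-control anchor is a documented
free parameter (600 μV²/0.5 Hz, with 680 and 760 for aged controls). The
within-day time course is a multiplicative linear decline of ±15% across
the light period (homeostatic dissipation; mean exactly 1, flat shape
available) — its shape affects realism only. Within-class covariance is
exchangeable-correlation 0.3 with per-hour SD equal to 8% of the hourly
mean, scaled by a single `scale` factor; draws are floored at 1 μV²/0.5 Hz
(SWA is a power; the floor is far below any default mean). One root seed
fans out to per-class child streams, so resizing one group never perturbs
another's draws.

`well_separated_spec()` fixes `scale = 0.0015`, the value at which the
smallest between-class mean distance (≈68 μV²/0.5 Hz, 18-month control vs
24-month RW) exceeds ten times the largest within-class SD along any
direction (measured ratio ≈ 13.8). This is the "separation greatly exceeds
scatter" regime in which the supervised benchmarks are defined; at the
default `scale = 1` the groups overlap substantially (adjacent classes
≈1.7 SD apart) and neither perfect classification nor the PI ceiling is
expected.

The epoch-level generator exists to exercise the spectral stage end to end:
a bout-structured hypnogram (geometric bout lengths, defaults 2 min WAKE /
5 min NREM / 1 min REM with REM following half of NREM bouts, ≈⅔ NREM
overall), NREM delta-band power set so the band integral equals the class's
hourly mean times a mean-one lognormal noise factor, reduced delta power in
WAKE/REM, a 1/f background elsewhere, and i.i.d. artifact flags. With zero
noise and no artifacts the extraction stage recovers the generative hourly
means exactly.

**What the synthetic benchmark does not show.** Real SWA is not exactly
multivariate normal, group covariances are neither exchangeable nor
proportional to the mean, epochs are autocorrelated within bouts, and real
class separation is far weaker than the separated regime. Passing the
separated-cohort benchmarks demonstrates that the estimators are correct
and numerically sound, not that real cohorts are perfectly classifiable.

## Problem sizes and determinism

Default analyses run on the 54-mouse cohort in seconds; the test suite uses
reduced k-means restarts (50–200) and reference counts (B = 10–100) where
the quantity under test is insensitive to them, and the full defaults
(restarts = 1000, B = 100) in the end-to-end pipeline. Every random choice
flows from an explicit integer seed (NumPy `default_rng` with structured
seed sequences), and the pipeline regenerates all output files
byte-identically for a fixed config and seed.
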