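# Methods

## The problem

Bilateral coordination — two limbs (or two segments of one limb) tracing
spatio-temporally congruent trajectories — is hard to quantify from any
single kinematic variable. This package implements an accelerometry-based
approach: each arm wears three 9-axis inertial sensors (upper arm,
forearm, hand), a task is repeated for ten trials, and coordination is
measured as the *temporal extent* over which the two limbs' trial-averaged
acceleration trajectories are congruent up to a similarity transform.

## Procrustes dissimilarity

A trajectory is a k×3 matrix of acceleration samples (x, y, z in g; the
positive y axis points along the reaching direction). Conforming a curve
Y to a reference X finds the translation c, positive scale b and
orthogonal matrix T (rotation, or rotation/reflection) minimizing

    ‖X − (b·(Y − Ȳ)·T + c)‖²,   c = X̄.

T comes from the SVD of Yc′Xc (reflections allowed by default; a config
flag restricts to det T = +1), and b = tr Σ / ‖Yc‖². The dissimilarity
index standardizes the residual by the centered reference:

    D = ‖Xc − b·Yc·T‖² / ‖Xc‖²  =  1 − (tr Σ)² / (‖Xc‖²‖Yc‖²).

D = 0 iff Y is an exact similarity transform of X, and D ≤ 1 whenever the
scale is optimized (it is a squared-cosine complement). D is normalized
by X and is deliberately not symmetric in its arguments; the right/
dominant limb (or the proximal segment) is always the reference. The
equations are stated for the planar case in the source analysis; the SVD
minimizer implemented here is the standard generalization, and tests
verify it coincides with a dense rotation-angle grid search in 2-D.

## Expanding Procrustes

Given two equal-length representative curves:

1. **Scan** — a window of w = max(2, round(0.10·N)) samples slides with
   step 1; D is recorded for every windowed pair. A window in which the
   reference has zero spatial variance is recorded as D = 1 with a
   warning.
2. **Seed** — the window with minimal D (earliest on ties).
3. **Expand** — if the seed window's D exceeds the threshold τ = 0.15 the
   pair reports an empty interval (0% similarity). Otherwise the right
   edge grows one sample at a time — with a full Procrustes re-fit of the
   grown segment after every step — while D ≤ τ, then the left edge
   grows the same way. The passes repeat until neither edge can move, so
   the result is locally maximal: any single-sample extension pushes D
   above τ. (A single forward-then-backward sweep cannot guarantee this,
   because backward growth changes the fit and can re-enable forward
   growth.)

The localized interval [min_idx, max_idx] yields

* **percent similarity** = 100·(max_idx − min_idx + 1)/N (0 for empty),
* **coordination score** = percent / max(D, ε), ε = 1e−6 (0 if percent
  is 0; a fully congruent pair saturates at 1e8 instead of dividing by
  zero),
* **log score** = ln(1 + score), an order-preserving normalization that
  maps zero-similarity subjects to 0 rather than −∞.

τ = 0.15 is the average dissimilarity between stages of a simple reaching
task in the calibration data the method inherits; it is a configuration
default, not a constant.

For intra-limb analysis a **temporal gate** discards intervals that do
not overlap any task movement stage: congruent shapes occurring outside
the task's stages of movement do not count as coordination. Stages
default to contiguous runs where the arm's forward-acceleration magnitude
exceeds 10% of its peak on the representative curve.

## Segmentation

Recordings are 10 Hz streams; trial boundaries are detected on the right
upper arm's forward (y) acceleration and the same index windows are
sliced from all six placements, guaranteeing the equal-length pairs the
algorithm requires. Local maxima are found with prominence ≥ 10% of the
series range and minimum separation 5 samples; boundary minima are the
minima between consecutive maxima (and in the flanking regions) that
return within 15% of the range above the series minimum — the neutral
position. The depth filter makes the rules well-posed: within a trial
the acceleration dips between pulses stay elevated (movement is
continuous) while between trials it rests at the neutral level, so the
two reach pulses or four button pulses are not over-segmented. All
quantities are range-relative, so detection is invariant to constant
offsets. Per task:

* reach — a maximum preceded and followed by neutral minima (min–max–min);
* button/unbutton — a neutral minimum to the last maximum before the next
  one (neutral position to the highest button);
* cabinet — between two consecutive neutral minima.

Dropouts are repaired before detection: interior missing runs by linear
interpolation between flanking samples, leading/trailing runs by nearest
observed value (one-sided interpolation is undefined), a fully missing
channel is an error.

Unequal trial lengths are harmonized by per-axis linear resampling onto
N = round(mean trial length) equispaced points of normalized time before
point-wise averaging (`resample_policy` can fix N instead). Durations are
computed from raw segment lengths before resampling, which would distort
time.

## Statistics

Two balanced groups of ten subjects (younger than 30 vs 35–75 years) are
compared with pooled-variance one-tailed independent t-tests — the ageing
hypotheses are directional; the hypothesized direction is an explicit
argument. Zero pooled variance with equal means yields p = 0.5 with a
warning. Coordination scores are log-normalized and fed to a balanced
two-way ANOVA with interaction, computed by the classical cell-mean
decomposition (under balance, all sum-of-squares types coincide);
unbalanced designs are refused rather than silently approximated. Q-Q
points pair sorted residuals with standard-normal quantiles at plotting
positions (i − 0.5)/n.

`reproduce_printed_statistics` recomputes every published group summary
and headline comparison from the embedded per-subject tables and flags,
per cell, agreement at printed precision — within one unit in the last
printed digit, which accommodates the source's truncation-vs-rounding
convention. A handful of published prose summaries are internally
inconsistent with the published per-subject values (the task-3 intra-limb
group means, and one roll-angle mean off by 0.01); those rows are flagged
`known_discrepancy`, reported, and excluded from the pass/fail verdict.
The published two-way ANOVA tables are not reproduction targets: their
printed degrees of freedom are inconsistent with the design (a two-level
age factor listed with 3 df), so the ANOVA is validated against
hand-partitioned oracles and statsmodels instead.

## Synthetic data

No raw recordings are deposited, so the generator emulates the study
conditions: 10 trials per task at 10 Hz; sensor quantization 0.005 g,
0.61 °/s, 0.05°; trial lengths matching the published mean durations
(reach 3.3 s, button ≈ 16 s, cabinet 6 s); Gaussian acceleration lobes on
the y axis with the tasks' characteristic pulse counts (two for reaching,
four for buttoning ending at the highest button, one on the dominant and
two on the non-dominant arm for the cabinet task); small correlated x/z
components; a broad movement envelope keeping within-trial dips above the
resting baseline; near-zero rest baselines between trials; 5% default
trial-to-trial time/amplitude jitter; 0.01 g additive noise. Gyro and
angle channels are scaled transforms of the acceleration profile —
sufficient surrogates for peak-feature extraction, not biomechanically
derived. Everything is deterministic given a seed.

Pairs with planted ground truth place a similarity-transformed copy of
the base curve (plus noise) inside a known index range and an independent
dense lobe train outside. The outside signal is deliberately structured:
two *smooth, low-complexity* independent curves are often congruent under
a similarity transform over short windows, which would make any planted
span unrecoverable in principle. Calibration (checked by test): 2%
in-span noise keeps the span's dissimilarity well under τ; at 5% noise
the median Jaccard overlap between recovered and planted intervals over
50 seeds is 1.0 (about a quarter of seeds still lock onto a spurious
outside match — an inherent property of the method, mirroring the nonzero
"similarity" the study reports even for independently moving limbs).

What passing these tests does *not* show: robustness to gravity
artifacts, sensor drift, multi-joint dynamics, or movement variability
beyond jittered repetitions of one template — none of which the generator
models.

## Numerical choices

Orthogonality and reconstruction are asserted at 1e−10; D is clamped to
[0, 1] against round-off; grid-oracle comparisons use 1e−4 (the grid
resolution bound); degenerate point sets (fewer than two points, zero
variance) raise typed errors except inside the scan, where a degenerate
window records D = 1 with a warning; window ties break to the earliest
start; trials shorter than the minimum separation are discarded.

## Problem sizes

Tests and the acceptance script use 200-sample curves (20 s at 10 Hz) for
planted-interval recovery, 50-seed simulation batches, 500-case
invariance sweeps, and single simulated subjects (10 trials × 6
placements) for end-to-end runs.
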