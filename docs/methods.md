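# Methods

## Task model

Three visuomotor contexts map hand displacement **h** to cursor
displacement **c = T h** in left-handed screen coordinates (x rightward,
y downward, so "up" is (0, −1)):

    T(−90°) = [[0, 1], [−1, 0]]     T(+90°) = [[0, −1], [1, 0]]
    T(mirror) = [[−1, 0], [0, 1]]

The movement a subject must produce for on-screen direction **v** is
T⁻¹ **v**; only this coordinate convention reproduces the task's stated
correspondences (−90°: visual up ↔ hand right; +90°: visual up ↔ hand
left; mirror: vertical unchanged, horizontal inverted).

A session holds 15 blocks — each context five times, uniformly permuted —
and each block holds 17 erasing trials (3.5-s trial window, 6-s ITI) with
an 8-s preparation cue before the trials and a 4-s score display after
them; block termination is modeled as an instantaneous event at score
offset. The preparation period is placed strictly before the first trial.
Trial order is a type-1 index-1 continuous-carryover sequence over the four
directions: for four conditions, a random relabeling of the canonical
17-element template; for general n, an Eulerian circuit of the complete
digraph with self-loops (Hierholzer), giving every ordered condition pair
exactly once among the n² transitions. The direction that receives the
fifth (extra) trial is whatever the relabeling yields; no cross-block
balancing is attempted.

## Behavior model

A trial presents seven 16-px dots in a line starting 16 px from the cursor,
extending along the visual direction (contiguous 112-px line; the dot
spacing is our choice, consistent with the 1.5-line-length outlier rule).
A dot is erased when the cursor center is strictly inside its square, in
strict sequence. Erasing speed = dots erased / trial duration, with
duration equal to the last-erasure time for completed trials and the full
3.5-s window otherwise — completed fast trials thereby score higher, as a
proficiency measure should. Trials whose cursor path exceeds
1.5 × 7 × 16 = 168 px (strict) are outliers; they are excluded from task
regressors but kept in behavioral summaries by default (flag-controlled).

The cohort's mover policy is a constant-speed, angular-jittered straight
mover along the required movement direction. Hand speeds (px/s) are drawn
per subject, N(27.4, 2.5) for rotation contexts and N(38.3, 2.5) for
mirror, with per-trial jitter (SD 3 px/s, 0.25-rad step noise) and a 4%
chance of a fast meandering "exploration" trial that trips the outlier
rule. These speeds were calibrated once, by simulation, so cohort mean
erasing speeds land near 1.7 dots/s (rotation) and 2.4 dots/s (mirror) —
the regime where rotation trials typically leave ~1 dot unerased at the
deadline while mirror trials complete early — and the rotation–mirror gap
is ≈ 0.7 dots/s. No within-session learning is modeled; proficiency is a
cohort parameter.

## Synthetic neural data

Volumes live on a small 3-mm grid (default 24 × 24 × 18) with an
ellipsoidal brain mask and four disjoint cubic regions (default 4³ voxels)
near the in-plane corners: visual, movement, context, null. On the default
grid the regions are separated by more than the 9-mm searchlight radius;
on smaller grids spheres straddle regions and read-outs blur across them,
which the tests account for.

Per subject, the beta volume of block *b* (context *c*) and visual
direction *v* is

    β = A_vis P_vis(v)·1[visual region] + A_mov P_mov(m(c,v))·1[movement region]
      + A_ctx P_ctx(c)·1[context region] + ε,    ε ~ N(0, σ²) i.i.d. in-mask,

with m(c,v) = T_c⁻¹ v, direction patterns P drawn i.i.d. standard normal
per subject (shared across contexts), and defaults A_vis = A_mov = 1,
A_ctx = A_prep = 0.7, σ = 1. Preparation betas carry the context pattern
at amplitude A_prep; the block's null (first-trial) regressor carries
noise only.

**Commonality.** The two rotation-context patterns share a latent factor:
P(−90) = √ρ·z + √(1−ρ)·e₁ and likewise P(+90), giving population
correlation ρ between them; the mirror pattern correlates ρ_mir with the
standardized rotation-family mean. Correlated pairs use Gaussian mixing
(p₂ = ρp₁ + √(1−ρ²)e), the simplest construction with exact population
correlation. The links are affine and clipped: ρ_rot = clip(perf_rot − 1)
and ρ_mir = clip(0.55·perf_mir − 0.85), so typical cohorts span ρ_rot
≈ 0.5–0.9 and ρ_mir ≈ 0.3–0.55. Amplitudes and σ were calibrated once so
that context-decoding accuracy is far off ceiling over that ρ range
(roughly 35 → 10 percentage points above chance as ρ rises), which is what
lets the negative accuracy–performance slope surface at n ≈ 8–22.

Betas may be generated directly (fast path) or pushed through the BOLD
forward model Y = Xβ + ε with AR(1) noise, random-walk motion parameters
(rotations scaled to contribute comparably on a 50-mm sphere), and
plantable FD or global-signal spikes; the noiseless round trip through the
first-level GLM recovers planted betas to solver tolerance.

## First-level GLM

The HRF is the canonical double-gamma (peak 6 s, undershoot 16 s, ratio 6,
length 32 s), peak-normalized, convolved at 0.1-s resolution and sampled
at scan times (TR 2.3 s). The MVPA design models each block separately:
four direction regressors (excluding the first trial and outlier trials),
a null regressor for the first trial, and per-block preparation, score and
termination regressors. The mass-univariate design pools erasing trials
into one regressor per context. Both add one regressor per outlier trial
(an outlier first trial is modeled once, as an outlier), six motion
parameters with backward-difference gradients, one spike regressor per
flagged scan (FD > 0.9 mm on a 50-mm sphere, or |z| of the global signal
> 5), and a discrete-cosine drift basis up to 1/128 Hz — high-pass as
regressors rather than pre-filtering, equivalent under OLS and simpler to
test. Fits are voxelwise OLS with no pre-whitening; with AR(1) noise the
betas stay unbiased but their nominal variances are optimistic, a
deliberate simplification. Rank-deficient designs are rejected with the
collinear columns named.

## Decoding

Features are per-block direction betas inside 9-mm searchlight spheres
(voxel-center distance ≤ radius; 123 voxels at 3-mm voxels for interior
centers). The classifier is a linear soft-margin SVM (C = 1, libsvm via
scikit-learn) with per-sphere train-mean centering as the only scaling.
The searchlight driver calls the libsvm binding directly to avoid per-call
estimator overhead; a test pins its exact agreement with the public SVC
route.

Pair enumeration follows each analysis's published counting convention:
the visual and movement analyses enumerate directed pairs (every ordered
context pair × axis whose other-level directions differ: 12 each), while
the context analyses enumerate unordered set-pairs (train matched on a
visual direction, test matched on a compatible movement direction: 8 for
−90 vs +90, 16 for rotation vs mirror) and evaluate each in both
directions, averaging the two accuracies. A `directed` flag exposes the
other convention. Erasing-context analyses subdivide each pair by
leave-two-block-out CV over the five repetitions; the correlation-analysis
variant skips the subdivision to preserve between-subject accuracy
variance. Preparation decoding uses leave-two-out CV (5 folds; 5 + 5 = 10
for rotation vs mirror). Sphere accuracy is averaged over pairs and folds
before subtracting the 50% chance level.

**Anti-generalization.** Cross-classification guarantees that an untargeted
level cannot produce *above*-chance transfer, but it can produce
systematic *below*-chance transfer: e.g. with only movement signal
planted, the visual analysis's −90/+90 pairs swap the movement labels
exactly, so the classifier is consistently wrong near the movement region.
This is a known property of cross-decoding designs and is harmless under
the one-sided (positive) group tests used throughout; the specificity
tests therefore assert chance-level behavior away from the planted site
and the absence of positive effects anywhere.

## Group inference

Group maps are voxelwise OLS t-statistics; the confound construction of
the source analyses is preserved exactly: the confound (the uncentered
absolute rotation–mirror performance gap) enters as a column and the test
is one-sided on the intercept. FWE control is by max-statistic permutation
of the TFCE-transformed t-map (E = 0.5, H = 2, dh = max/100,
26-connectivity): sign-flipping for intercept tests, Freedman–Lane
residual permutation for covariate tests (the scheme choice for covariate
tests is ours; sign-flipping is invalid there), with
p = (1 + #{max ≥ obs}) / (1 + n_perm). BH FDR q-values provide the weaker
control. Permutation inference replaces random-field-theory cluster
correction for the mass-univariate maps as well — a deliberate
substitution; RFT smoothness estimation is out of scope. Zero-variance
voxels receive a large finite t (±10⁶) rather than ±∞. The pipeline
smooths accuracy maps (8-mm FWHM) before group statistics; library-level
tests operate on unsmoothed maps.

## What the generator does and does not emulate

It emulates the design's combinatorics and timing, context-dependent
visual↔movement couplings, per-subject proficiency with its
rotation–mirror gap, patterned multi-voxel signal with tunable
cross-context commonality tied to behavior, AR(1) noise and scan
artifacts. It does not emulate anatomy, spatial autocorrelation of noise,
physiological noise beyond AR(1) + spikes, within-session learning, or
nonlinear representational geometry. Passing tests therefore demonstrate
that the analysis machinery recovers planted effects with correct error
control at desk scale — not that real data would show those effects.

## Numerical and scale choices

Tests run cohorts of 5–12 subjects on the default grid (ROI-restricted
sphere centers where only a regional read-out is asserted) and reduced
permutation counts (99–500); the acceptance script uses 8–12 subjects and
10 correlation replicates. TFCE thresholds include a small relative
tolerance so the top step is never dropped to float accumulation. Stochastic
assertions use seeded generators with bounds set at ≥ 3 Monte-Carlo
standard errors. The single-CPU end-to-end run of the acceptance script
completes in a few minutes.

## Known limitations

* No pre-whitening in the first-level GLM (see above).
* The erasing-speed formula's "trial duration" is our reading (last-erasure
  time for completed trials); an alternative fixed-window reading would
  compress the mirror–rotation gap.
* Whether outlier trials enter behavioral means is unstated in the source
  design; we include them (flag-controlled).
* Anti-generalization (below-chance transfer) is inherent to the planted
  linear pattern geometry; real cortex need not behave this way.
* The commonality link is affine and deterministic; subject-level
  variability in the link itself is not modeled.
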