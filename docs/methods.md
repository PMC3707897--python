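# Methods

## The decorrelation statistic

Per voxel, the measured modulation index compares the response to combined
center-plus-surround stimulation with the unweighted sum of the component
responses, d_M = ((C + S) − m)/(C + S), in percent-BOLD units.  It can take
any real value; extreme values (|d_M| > 1) arise when the denominator
approaches zero and are retained, never discarded.  Only voxels whose
denominator is *exactly* zero are undefined and excluded from VOI means;
voxels with |C + S| below `denom_epsilon` (default 1e−9 %BOLD) are flagged
and counted but kept.  Where an analysis needs a noise-robust mean (the
shared-noise bias analysis below), the flag threshold is raised so that
near-pole voxels — whose index is numerically meaningless — are excluded,
and the exclusion count is reported.

The theoretical coefficient d_T is the scalar that decorrelates
C′ = C − d·S and S′ = S − d·C.  Setting cov(C′, S′) = 0 gives the quadratic
(1 + d²)·cov − d·(var(C) + var(S)) = 0; of its two roots (reciprocals of one
another) the one inside [−1, 1] is returned, computed in the rationalized
form d_T = 2·cov/(V + sqrt(V² − 4·cov²)), V = var(C) + var(S), which is
numerically stable as cov → 0 and is polished by one Newton step (residual
pattern correlations are then ~1e−15).  cov = 0 returns exactly 0.  Sample
(n−1) moments are used throughout; d_T depends only on moment ratios, so the
normalization convention cancels.  `d_T_oracle` verifies the closed form
independently: a 1e−4 grid over d ∈ [−1, 1] minimizing the literal Pearson
correlation of the mixed patterns, refined by bisection on the correlation's
sign change; the correlation at d = ±1 is 2·cov ∓ V, whose signs bracket the
root for any non-degenerate pair, so the bisection always converges.

As a function of the pattern correlation r, d_T depends on the variances
only through their ratio ρ = var(S)/var(C):
d_T(r, ρ) = 2·r·sqrt(ρ) / ((1 + ρ) + sqrt((1 + ρ)² − 4r²ρ)), reducing for
equal variances to (1 − sqrt(1 − r²))/r with the continuous extension 0 at
r = 0.  This is the parameter-free curve the model comparison scores.

## Synthetic study

The generator emulates the study design at the level of condition-wise
response estimates (no time series, no 3-D geometry; eccentricity is the
only spatial coordinate).  Defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_subjects | 15 | subjects |
| areas | V1, V2, V3 | functional areas |
| ring borders | 1, 2.3, 4.0, 6.1, 8.7, 12 deg | five eccentricity rings |
| stimuli | C 1–2.3°, S_N 2.5–4°, S_F 8.7–12° | annular extents |
| voxels_per_ring_per_area | 50 | ≈250/area, near the reported ~270 active voxels per area |
| peak_amplitude | 1.0 %BOLD | typical percent-signal-change scale; the source figures fix no amplitude, so this is a free choice |
| spread_sigma_mm | 6 mm | positive-lobe width of the cortical point spread |
| negative_lobe_gain, wide_lobe_ratio | 0.3, 3 | negative lobe relative gain and width |
| noise_sd | 0.1 %BOLD | independent measurement noise, 10% of peak |
| shared_noise_sd | 0 | temporally correlated noise component |
| amplitude_jitter, offset_jitter_mm | 0.15, 1.5 mm | per-subject variability |
| magnification a, k | 1 deg, 17 mm | log mapping x = k·ln((E+a)/a) |

Voxel eccentricities are drawn uniformly in *cortical position* within each
ring (approximately uniform cortical sampling under the magnification
mapping), exactly `voxels_per_ring_per_area` per ring.  The noiseless
response to a stimulus annulus is a difference of two Gaussians of the
cortical distance to the nearest stimulus edge — a narrow positive lobe
(σ mm) minus a wide shallow one (gain g, width w·σ) — normalized so voxels
inside the stimulus sit at the positive peak.  This is the minimal form
producing the observed phenomenology: maximal response at the retinotopic
representation, positive spread over many millimetres, then a sign flip to
negative BOLD at the analytic distance σ·w·sqrt(2·ln(1/g)/(w² − 1)) from the
edge.  Per-subject variability enters as lognormal amplitude jitter and a
Gaussian cortical-offset jitter applied per condition, which yields the
between-subject spread of pattern correlations the group scatter needs.
With `target_correlation` set, σ is tuned by grid-plus-golden-section search
so the noiseless C/S_N template correlation over suprathreshold grid voxels
(|response| ≥ 0.1·peak) matches the target within ±0.05; the reachable range
under the default geometry is roughly −0.6 to +0.9.

The combined responses follow the configured rule — CD:
m = (C − d·S) + (S − d·C) = (1 − d)(C + S); LINEAR: C + S; MAX / AVERAGE:
voxel-wise.  `d_true="auto"` resolves d per subject to the d_T of that
subject's noiseless patterns pooled across areas (separately for near and
far surround), so generated data sit exactly on the CD identity —
this is what makes parameter-recovery tests exact.  Independent N(0,
noise_sd) noise is added to each of the five condition estimates; an
optional single shared draw per voxel is added once to C, S and m alike.
Because that draw enters the d_M denominator twice and the numerator once,
the index of a noise-dominated voxel tends to 1/2, biasing means toward 0.5
as the shared level grows.  All draws flow from one seed through named
`SeedSequence` substreams keyed by (subject, area), so enlarging the area
list does not perturb existing subjects (note that `d_true="auto"` pools
statistics across areas and therefore legitimately depends on the area
set).

What the generator does *not* emulate: GLM estimation and its t-statistics
(activity selection uses an absolute-response threshold θ, default
0.25·peak), draining-vein and vascular point-spread structure,
between-area amplitude differences, spatial noise correlations, and any
behavioral data.  Passing tests therefore establish correctness of the
analysis machinery under the stated generative assumptions, not fMRI
realism.

## Volumes of interest

Three selection families mirror the study's scheme: condition-active sets
(VOI_C, VOI_SN, VOI_SF on their defining condition; VOI_AVA on the union of
all five), ring sets VOI_RING1–5 (ring label plus the union activity
criterion, so θ = 0 partitions the table), and area sets (VOI_V1, ...).
Raising θ never grows a VOI.

## Model comparison

Four models of the per-subject (r, mean d_M) scatter: the parameter-free CD
curve (k = 0), the slope-one identity line d = r (k = 0), an OLS line
(k = 2) and a 3rd-order polynomial (k = 4).  Goodness of fit uses
orthogonal distances (both axes carry measurement error): the numerator of
R² is the summed squared minimum Euclidean distance from each point to the
curve (dense 1e−3 grid plus bounded refinement to 1e−6; r and d are
commensurate, both in [−1, 1]), the denominator the summed squared distance
of the points to their centroid.  Leave-one-out error refits the
parametric models on n−1 points and records the held-out point's vertical
absolute error (the orthogonal metric is available via a switch); for
parameter-free models LOO equals the plain mean error.  Per-VOI error
normalization scales each group's maximum to exactly 1.

Information criterion: least-squares AIC = n·ln(RSS/n) + 2k by default.
For model-*recovery* simulations at n ≈ 15 points the small-sample
corrected AICc = AIC + 2k(k+1)/(n − k − 1) is used (`criterion="aicc"`):
with plain AIC the probability that a nested 2-parameter fit beats the true
parameter-free model is P(χ²₂ > n(e^{4/n} − 1)) ≈ 0.15 regardless of
implementation, capping identity-line recovery near 78%; AICc restores
consistent recovery (≈88–100% per rule in a 400-replicate design analysis)
while leaving reported AIC values untouched.  Pairwise winners are decided
by the lower criterion value, ties toward fewer parameters.  The voxel-level
MAX and AVERAGE models predict m directly as max(C, S) and (C + S)/2 and are
compared through the Euclidean norm of the prediction error; the CD
counterpart is (1 − d_T)(C + S) with d_T from the same voxels.

## BOLD spread and cortical distances

Eccentricity profiles take ring means at the arithmetic midpoints of the
ring borders (1.65, 3.15, 5.05, 7.4, 10.35°; a log-midpoint option exists),
with subject-level SE across voxels and group-level SE across subjects
(group means are means of subject means).  The sign change of a profile is
the real root of a 2nd-degree polynomial fit nearest the stimulus edge in
the travel direction; profiles that never cross in the sampled range are
censored as "<1°" / ">12°", never raised as errors.  The 95% CI is a
percentile bootstrap over subjects (default 1000 resamples, seeded);
censored bootstrap crossings propagate as infinities so the percentiles
censor correctly.  Visual-field extents convert to cortical mm by
differencing k·ln((E+a)/a) at the crossing and the reference edge; censored
crossings yield "greater-than" lower bounds evaluated at the range border.
Note that direct evaluation of this mapping with a = 1, k = 17 gives
≈16.5 mm for a 2.3°→7.7° extent; published group tables built from
per-subject averaging can differ from the direct formula value, and this
implementation always reports the direct value.

Fixed-size resampling (default 20 voxels, 100 repeats, seeded) computes
(mean d_M − d_T)² per resample with d_T evaluated on the same sampled
voxels, making errors comparable across VOIs of different sizes.  Even on
noiseless CD data this error is small but nonzero (~3e−3): the subsample's
finite-sample d_T differs from the pooled coefficient that generated the
data; it vanishes as the resample grows.  Under increasing measurement
noise the error *decreases* — noise attenuates the measured pattern
correlation, pulling the subsample d_T toward the noise-robust mean d_M.

## Interaction statistics

The sign contingency classifies VOI voxels by sign(C)·sign(S) (same vs.
different) and by d_M sign (suppressive > 0, facilitative < 0); voxels with
an exactly zero response or a zero/undefined index are excluded and
counted, making the classification exhaustive and exclusive.  The tests are
the exact two-sided binomial sign test (zeros dropped), Mann–Whitney U
(exact when n·m ≤ 400 with no ties, otherwise normal approximation with tie
correction), two-sample Kolmogorov–Smirnov (asymptotic p) and the Friedman
test (fully tied data return statistic 0, p = 1).  The behavioral
chance-level helper returns 100/n percent for n equiprobable alternatives
(25% for the four-letter report task).

## Pipeline and problem sizes

`run_pipeline` chains generation (or table loading) → per-VOI modulation →
per-subject scatter + four-model comparison → spread report → sign report,
writing comma-separated tables plus a JSON manifest with package and
library versions, the seed and a configuration hash; reruns with the same
seed are byte-identical, and outputs are never overwritten without an
explicit flag.  The acceptance script runs the same machinery at sizes
chosen for a desk machine: 300 random pairs for the oracle check, 10
recovery seeds at 210 voxels, 25 model-recovery replicates per rule, 200
bootstrap resamples for the crossing CI, and the full 15-subject default
study for the spread and sign analyses.

## Known limitations

The far-surround condition of the default generator produces strongly
negative C/S_F pattern correlations (the negative point-spread lobes
anti-align the templates), where the study's far-surround correlations
clustered near zero; the CD analysis itself is agnostic to this, but
absolute far-surround numbers from the synthetic default should not be read
as calibrated to the source data.  Percent-change amplitudes are
uncalibrated.  Censored crossing CIs inherit the bootstrap's
subject-resampling assumptions.  The NIfTI adapter imports values only; it
performs no registration or resampling.
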