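# cortexdecorr

Analysis of center–surround contextual modulation in visual-cortex BOLD
voxel patterns under the cortical-decorrelation (CD) model, together with a
synthetic multi-subject data generator that reproduces the study's
retinotopic, correlational and interaction structure.

## The scientific problem

When a visual "center" stimulus (an annulus at 1–2.3° eccentricity) and a
"surround" stimulus (near: 2.5–4°, or far: 8.7–12°) are shown together, the
combined cortical response m(C, S) is not the sum of the responses to the
components shown alone.  Per voxel, the **measured modulation index**

    d_M = ((C + S) − m(C, S)) / (C + S)

quantifies this interaction: d_M = 0 means linear summation, d_M = 1 full
suppression (m = 0), d_M = −1 response doubling; positive values are
suppressive, negative facilitative.  The CD model explains the interaction
as decorrelation of the two macroscopic activation patterns: the combined
response is modelled as C′ + S′ with C′ = C − d·S, S′ = S − d·C, and a
single scalar

    d_T = [var(C) + var(S) − sqrt((var(C)+var(S))² − 4·cov(C,S)²)] / (2·cov(C,S)) ∈ [−1, 1]

removes the correlation between any two response vectors exactly.  The model
is parameter-free: from the correlation r between the C and S patterns of a
set of voxels it predicts the mean modulation those voxels will show (for
equal variances, d_T(r) = (1 − sqrt(1 − r²))/r).

The package implements the full analysis around this statistic:

* **synthetic data** – multi-subject voxel tables (15 subjects, areas
  V1–V3, five eccentricity rings) with difference-of-Gaussians cortical
  point spread (positive response turning negative with distance),
  controllable C/S pattern correlation, and a ground-truth interaction rule
  (CD / LINEAR / MAX / AVERAGE) plus independent and shared (temporally
  correlated) noise;
* **decorrelation core** – d_M, d_T, decorrelated patterns, pattern
  correlations, a brute-force verification oracle;
* **model comparison** – the CD curve against a slope-one identity line, a
  free line and a 3rd-order polynomial, scored by orthogonal-distance R²,
  leave-one-out error and AIC/AICc, plus voxel-level MAX and AVERAGE
  response models;
* **retinotopic spread** – eccentricity profiles, polynomial zero crossings
  of the BOLD sign with bootstrap CIs, and conversion to cortical mm via
  the magnification mapping x = k·ln((E + a)/a), a = 1°, k = 17 mm;
* **interaction statistics** – response-sign × modulation-sign contingency,
  sign test, Mann–Whitney U, Kolmogorov–Smirnov, Friedman test.

## Worked example

```python
from cortexdecorr import theoretical_d, cd_curve, pearson_correlation

C = [1.0, 2.0, 3.0, 4.0]
S = [2.0, 1.0, 4.0, 3.0]
print(pearson_correlation(C, S))   # 0.6
sol = theoretical_d(C, S)
print(sol.d_T)                     # 0.3333333333333333
print(sol.residual_correlation)    # ~1e-16 (C', S' fully decorrelated)
print(cd_curve(0.6))               # 0.3333333333333333 (equal-variance curve)
```

The two patterns correlate at r = 0.6; mixing them with d = 1/3 removes the
correlation entirely, and the parameter-free CD curve predicts exactly this
modulation from the correlation alone.

The numbered drivers under `analysis/` run the study end to end on synthetic
data and write their tables under `results/`:

```sh
python analysis/01_generate_study.py --seed 0   # 11250 voxels, 15 subjects
python analysis/02_modulation.py                # per-VOI mean d_M, r, d_T
python analysis/03_model_comparison.py          # four-model ranking per condition
python analysis/04_spread.py                    # zero crossings + cortical mm
python analysis/05_signs.py                     # sign contingency + Mann-Whitney
```

With the default seed the center VOI shows mean d_M = 0.367 at pattern
correlation r = 0.49 for the near surround (suppression where patterns
overlap), the CD model wins 11 of 12 pairwise AIC comparisons against the
three alternatives, the group V1 center response turns negative at 5.6°
(11.9 mm of cortex beyond the 2.3° stimulus edge), and suppressive voxels
concentrate where center and surround responses share a BOLD sign (odds
ratio ≈ 4.3, Mann–Whitney p < 1e−34).

The same pipeline is scriptable through the `cortexdecorr` CLI
(`generate`, `modulation`, `compare`, `spread`, `signs`, `run`), and an
optional NIfTI adapter (`import_nifti_summary`) extracts masked
percent-change volumes into the canonical table schema.

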