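# Methods

## Signal model and relaxometry

Each voxel of a multi-slice multi-echo spin-echo (MSME) acquisition is
modeled as a monoexponential echo-train decay,

    SI(TE) = A · e^(−TE/T2),   A = K · PD · (1 − e^(−TR/T1)),

with K the scanner gain. Because TR is fixed, the T1 saturation factor
is identical at every echo and is absorbed into the amplitude rather
than estimated; T1 is never mapped. A is therefore *PD-weighted*, not
absolute PD — every downstream quantity is a ratio to the pre-delivery
scan, in which the weighting cancels exactly.

Fitting is done in linear signal space by Levenberg–Marquardt (LM),
vectorized across voxels: the 2×2 damped normal equations are solved in
closed form per voxel, with per-voxel damping factors, so a masked
volume fits in a single pass (≈10⁵ voxels/s on one core). A log-linear
ordinary-least-squares fit of ln SI on TE supplies starting values;
it is initialization only, because log-space fitting reweights noise
toward the late, low-SNR echoes. Non-positive signals are excluded from
the log-linear step but retained in the LM objective.

Numerical choices: convergence when the relative RSS change falls below
1e−10 or the relative parameter step below 1e−8; at most 200 iterations,
with voxels hitting the cap flagged unconverged rather than raising;
T2 clamped to [1e−3, 1e7] ms and A to [0, ∞) (a fully damped step that
cannot improve the objective at a clamp is accepted as a constrained
minimum). All-zero echo trains are flagged with amplitude 0; constant
positive trains get a +∞ T2 sentinel from the initializer and are
refit from a generic start. Voxels outside the fitted mask carry NaN
parameters and `converged=False`, never silent zeros.

No Rician bias correction is applied in the fitter; for bias-sensitive
validation the generator can emit Gaussian noise instead.

## Edema indices

The ROI-mean amplitude (converged voxels only; exclusions are logged)
is tracked across scan times and converted to the fractional change
ΔPD(t) = (PD(t) − PD(0)) / PD(0), which is exactly 0 at t = 0 and
invariant to rescaling all amplitudes.

* **DLE** is the slope of the linear trend ΔPD(t) = a·t + b, fitted by
  LM (`scipy.optimize.least_squares`, method `lm`); for a linear model
  this coincides with closed-form OLS, which the tests verify to 1e−10.
  The pre-delivery point is included by default (ΔPD(0) = 0 is a real
  observation); a flag excludes it for a post-delivery-only fit.
* **ULE** is ∫₀⁵ ΔPD(τ) dτ. The trajectory is only sampled at the scan
  times, so the integral is evaluated by the trapezoidal rule on the
  piecewise-linear interpolant — the lowest-assumption quadrature
  consistent with the sampling. On the default grid (samples at 0 and
  5 min) this reduces to 2.5 · ΔPD(5). ΔPD is kept as a fraction
  (not percent) throughout.

A per-voxel ULE image is available as a visualization overlay; it makes
no inferential claims.

## Group statistics

Endpoints (MAP reduction, ULE, DLE) are three independent ANOVA
families with no cross-endpoint multiplicity correction. Descriptives
are mean±SD±SEM with the n−1 SD denominator and SEM = SD/√n. Variance
homogeneity uses the classic mean-centered Levene test (the SPSS
default; not the median-centered Brown–Forsythe variant): a one-way
ANOVA on absolute deviations from group means. Post-hoc pairwise
comparisons are gated on it at α = 0.05 (configurable): Bonferroni
(pairwise pooled-variance t, p multiplied by the number of comparisons,
capped at 1) when homogeneous, otherwise Tamhane's T2 — Welch t with
Satterthwaite degrees of freedom and a Šidák-style adjustment
p_adj = 1 − (1 − p)^m over the m = k(k−1)/2 pairs ("Tamhane" is
interpreted as SPSS's Tamhane T2, not T3). A summary-statistics ANOVA
(SS_between from n-weighted group means, MS_within pooling (nᵢ−1)sᵢ²)
reproduces the raw-data F exactly and lets published group tables be
re-analyzed without raw data. p-values below 1e−300 are reported as
"< 1e−300" rather than floored silently; degenerate inputs (zero
within-group variance) yield F = 0 when groups coincide and F = ∞
otherwise.

## Synthetic study generator

The generator emulates the animal experiment the pipeline targets:
three arms (solvent, L-CCB, T&L-CCB) of 16 spontaneously hypertensive
rats each, scanned with a 128×128, 50×50 mm², 18-slice, TR 2500 ms,
12-echo (TE = 6.5·k ms) MSME protocol before delivery and at
{5, 15, 25, 35, 45, 55} min after — the six post-delivery scans are
known to span 5–55 min; even spacing is this package's choice. The ROI
covers the muscle tissue of 9 contiguous central slices.

* **Anatomy**: two elliptical thigh-muscle cross-sections per slice
  with central circular "bone" discs excluded; PD varies smoothly
  (±5%) around an arbitrary base of 1000 units, T2 smoothly within
  [20, 60] ms (muscle band). Anatomy varies per subject via the seed.
* **Dynamics**: each subject draws a slope a ~ Normal(dle_mean, dle_sd),
  clipped at 0 from below (all default arm means are ≥10 SD above 0,
  so clipping is practically inert); the ROI amplitude at post-delivery
  time t is PD·(1 + a·t + b). The pre-delivery scan is unmodified
  baseline, so the true fractional change is exactly a·t + b — linear
  by construction, matching the model the pipeline fits. Saturating
  dynamics are deliberately out of scope.
* **Effect sizes** default to the published per-arm summaries: DLE
  means {0.0010, 0.0047, 0.0025}/min with SDs {0.0001, 0.0008, 0.0004},
  MAP reductions {2.65, 68.34, 90.67} mmHg with SDs {6.56, 15.19,
  11.58}. These are measured in-vivo values used as generator inputs;
  the absolute ULE scale of the original animals is *not* reproduced —
  with fractional ΔPD growing at ~0.001–0.005/min the 5-minute integral
  is necessarily O(10⁻²), so only relative ULE contrasts between arms
  are meaningful here.
* **Noise**: Rician by default (magnitude MRI; Gaussian and noise-free
  available), default σ = 17 ≈ first-echo muscle SNR 50 at the
  phantom's PD scale.
* **Pressure traces**: a baseline plateau at 165 mmHg (above the
  >150 mmHg hypertensive inclusion threshold) relaxing exponentially
  (τ = 3 min) to a plateau lowered by a draw from the arm's reduction
  distribution, sampled at 0.1-min steps from 5 min before to 60 min
  after delivery. The *measured* reduction is defined operationally as
  baseline-window mean minus final-15-minute plateau-window mean.
  Beat-to-beat fluctuation is off by default and can be enabled.

Determinism: a study is fully determined by (config, seed); per-subject
seeds are spawned from the study seed, and any subject can be
re-simulated bit-identically without materializing the cohort.

What the generator does **not** emulate: realistic anatomy, k-space /
acquisition physics (ghosting, B1, slice profile), motion, physiological
drift of the baseline, or nonlinear edema kinetics. Passing tests
therefore demonstrate correctness of the estimation chain under the
fitted model and noise assumptions, not robustness to real-scanner
artifacts.

## Validation problem sizes

The test suite and acceptance script run the full chain at reduced
sizes chosen to keep many-seed replication practical while preserving
every stage: 64×64 matrix, 3 ROI slices, 8 subjects per arm, Gaussian
noise at SNR 50 for recovery checks (50 seeded replicates for the
arm-ordering claim; the ensemble mean across replicates is compared to
the configured DLE truth because a single n=8 group mean carries ~6%
between-subject sampling error), and n=16 per arm for the omnibus-F
check. Relaxometry exactness is checked against a zooming dense
grid-search oracle and `scipy.optimize.curve_fit`; the statistical
layer against closed-form identities, brute-force formula evaluation,
and a 10,000-replicate null simulation of the Levene gate.

## Known limitations

* Single-compartment monoexponential T2 only; no multi-echo artifacts
  (stimulated echoes) are modeled or corrected.
* Rician bias is present (uncorrected) when fitting Rician-noise data
  at low SNR; at the default SNR ≈ 50 it is negligible relative to the
  effect sizes studied.
* ULE's absolute scale depends on the sampling grid only through the
  interpolant; with a single sample inside [0, 5] it is proportional
  to ΔPD(5).
* The Levene gate inherits the usual caveat that a variance pre-test
  conditions the post-hoc choice on the same data.
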