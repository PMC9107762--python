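# Methods

## The model family

`sca3prog` models the longitudinal course of a 0–100 ataxia severity score
(ICARS, higher = worse) in spinocerebellar ataxia type 3 on the
disease-duration timescale, `dt` = age at examination − age at onset of gait
ataxia (AOga). The working hypothesis is that progression is not uniform:
the annual rate differs between an early and a late disease stage.

For subject *i* at visit *j* the general linear mixed model is

    ICARS_ij = x_ij' β + z_ij' b_i + e_ij,
    b_i ~ N(0, Σ),   e_ij ~ N(0, σ²),

with three time bases:

* **linear** (`LM*`): x includes `1, dt`; random basis `(1, dt)`;
* **quadratic** (`QM1`): `1, dt, dt²`; random basis `(1, dt)` (no random
  quadratic term);
* **piece-wise** (`PM*`): `1, d1, d2` with a knot *I*, where
  `d1 = dt − I` if `dt ≤ I` else 0, and `d2 = dt − I` if `dt > I` else 0.
  The intercept is therefore the expected score **at** the knot, `d1` the
  early-stage slope and `d2` the late-stage slope, and the mean trajectory is
  continuous at the knot by construction. Random basis `(1, d1, d2)`.

Candidate modifiers — CAG repeat length (`CAGexp`), onset age (`AOga`), its
CAG-independent residual (`RAO`), and gender (female = 1, male = 0) — enter
uncentered, each with a main effect plus a time interaction. In piece-wise
models the interaction is either segment-wise (`d1*cov`, `d2*cov`) or, in
the `c` variants, on raw duration (`dt*cov`). The `c` convention and the
absence of centering are pinned down by exact reproduction of the published
worked-example predictions (14.836 and 13.121; see `tests/test_predict.py`).

Random-effects covariances are unstructured: 2×2 for linear/quadratic
models, 3×3 for piece-wise models. This convention is forced by the
parameter-count arithmetic of the published fit statistics: AIC = 2k − 2·logLik
reproduces every published column only with k = (#fixed) + q(q+1)/2 + 1
(e.g. k = 6 for LM1, 10 for PM1, 14 for PM4c).

Gender models (LM5/PM5) include both a main effect and time interactions;
because the published supplement with their estimates is unavailable, both
the segment-wise (`PM5`, default) and raw-duration (`PM5c`) interaction
variants are registered.

## Estimation

Estimation is full maximum likelihood (not REML): the downstream model
comparison rests on likelihood-ratio tests of fixed effects, and the
published information criteria are ML-based (see the AIC identity above).

Writing Σ = σ²G and W_i = Z_i G Z_i' + I, both β (generalized least squares)
and σ² are profiled out of the marginal Gaussian likelihood analytically,
leaving a q(q+1)/2-dimensional optimization over G alone. G is parameterized
by a log-diagonal Cholesky factor, which enforces positive semi-definiteness
without constraints. Per-subject matrix algebra is reduced with the Woodbury
identity to q×q operations on precomputed cross-products (Z'Z, Z'X, Z'y per
subject), batched over subjects with stacked `numpy` arrays — so one
likelihood evaluation costs O(m·q³) regardless of visit counts.

The optimizer is L-BFGS-B (finite-difference gradients, `ftol` 1e-12, `gtol`
1e-6, diagonal log-SD parameters bounded to ±10) restarted from three
dispersed points: unit G, near-zero G (log-SD −4), and a method-of-moments
guess built from per-subject OLS coefficients of pooled-OLS residuals. The
best optimum is kept. Non-convergence is reported via `converged=False`;
a singular (boundary) Σ̂ is flagged, never silently re-parameterized. With
data simulated at realistic sizes the fits agree with an independent
reference mixed-model implementation (statsmodels `MixedLM`, ML) to
|Δloglik| ≤ 1e-4 and relative fixed-effect error ≤ 1e-4.

Standard errors come from the inverse GLS information Σᵢ X_i'V_i⁻¹X_i with
normal-reference Wald p-values (the published table's p-value method is not
stated, so p-value comparisons in tests carry tolerance and never gate on a
boundary). Subject-level trajectories use empirical-Bayes BLUPs
b̂_i = Σ̂Z_i'V_i⁻¹(y_i − X_iβ̂).

Variance explained is reported as marginal/conditional R²: with
σ²_f = Var(Xβ̂) (population convention) and σ²_r = mean over rows of z'Σ̂z,
R²_marginal = σ²_f/(σ²_f+σ²_r+σ̂²) and R²_conditional adds σ²_r to the
numerator. The denominator's row-average random-slope term generalizes the
intercept-only formula.

Degenerate inputs: a rank-deficient fixed design raises an error naming the
collinear columns (greedy rank scan); a zero-residual (noiseless) dataset is
handled by flooring σ̂² at 1e-12, in which limit the GLS solution equals OLS
exactly.

## Knot selection and model comparison

The knot is selected by refitting the base piece-wise model over the
candidate grid {3, 5, 7, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 25,
30, 35} years and minimizing AIC (ties → smaller BIC → smaller knot).
Because all candidates share k, ranking by logLik, AIC or BIC is identical
for the base model; AIC is used for generality. Candidates outside the
observed duration range are inadmissible; a candidate with fewer than five
subjects contributing visits on one side is fitted but flagged thin.

The ladder comparison runs three ANOVA schemes: (a) each extension vs the
single-slope model LM1, (b) each extension vs the base piece-wise model PM1,
(c) each piece-wise model vs its linear counterpart. Nesting is verified
numerically (column-span containment of both design matrices on the actual
data), which correctly treats e.g. LM2 ⊂ PM2c (raw `dt` lies in the span of
`1, d1, d2`). The quadratic-vs-piece-wise pair is **not** nested; the
published table nevertheless prints a p-value for it. This package refuses
the chi-square test for non-nested pairs and reports the AIC difference with
a note instead.

Collinearity between `CAGexp` and `AOga` is quantified as
VIF = 1/(1 − R²) from the subject-level regression of AOga on CAGexp
(R² ≈ 0.49 → VIF ≈ 2, below the conventional threshold of 5), with the
`RAO`-based model variants (`*6*`) available as the orthogonalized check.

## The synthetic cohort generator

No patient-level data ship with the package; every analysis stage is
exercised on synthetic cohorts that emulate the published cohort's
descriptive statistics: 81 subjects; CAG 67.7 ± 3.65 in [60, 75]; onset age
42.1 ± 9.88 years with 49% of its variance explained by CAG (negative slope:
longer repeats → earlier onset, floored at 5 years); ~7.83 visits per
subject (1 + Poisson, clamped to [1, 16]) at gamma-distributed intervals of
1.21 ± 0.783 years; first visit at 7.11 ± 5.03 years of duration (floored at
0.5). Distribution families are the simplest positive-support laws matching
the printed moments; where a truncated normal is used (CAG, first-visit
duration), the location and scale are solved from the truncated-moment
equations so the *truncated* law itself hits the target mean/SD — setting
them naively would miss the targets by far more than Monte-Carlo error
(e.g. CAG SD 3.15 instead of 3.65). The CAG→onset slope is likewise solved
against the realized spread of the drawn (rounded, truncated) CAG values so
the explained-variance share calibrates exactly.

Trajectory truths default to the published fixed-effect columns. The
published table does not print Σ or σ, so defaults are residual SD 3 ICARS
points and a diagonal Σ with intercept SD 12 and slope SD 1 point/year per
segment (correlations 0) — chosen so conditional R² ≫ marginal R², as in
the published fits. Parameter recovery is always judged against whatever
truth is configured, so these defaults affect realism, not correctness.
ICARS clipping to [0, 100] is off by default (clipping biases linear-model
recovery) and available via `clip_icars=True` for realism demonstrations.

What the generator does **not** emulate: dropout/censoring mechanisms,
mortality, pre-onset subjects, scale floor/ceiling compression near the
extremes, or measurement-error heteroscedasticity. Passing recovery tests
therefore show that the estimation machinery is correct and calibrated under
the model's own assumptions — not that the model is correct for real
clinical data.

## Problem sizes

The Monte-Carlo experiment sizes are: 200 replicates of 81 subjects for
slope recovery (two-segment and single-slope truths), 50 replicates for the
18-candidate knot search, 20 instances for the oracle cross-check, and
scaled-down versions (25–40 replicates, or 25–40 subjects) for the unit-level
recovery, coverage, and null-calibration checks. Replicate *r* always uses
seed `base_seed + r`, so a single integer reproduces any experiment
bit-for-bit.

## Known limitations

* Single knot, two segments; no subject-specific (random) change points.
* Gaussian responses only; no autocorrelated residuals, no crossed random
  effects.
* Wald p-values use the normal reference; no small-sample (Satterthwaite)
  degrees-of-freedom correction.
* The published BIC values back-calculate to n ≈ 632 observations while the
  stated analysis size is 634; this package always computes BIC from its own
  n_obs and does not imitate the discrepancy.
* The published worked example attributes 13.121 to "the PM4 model", but the
  arithmetic reproduces exactly under the PM4c column (and not under PM4);
  the prediction API follows the arithmetic.
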