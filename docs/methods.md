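# Methods

## The problem being modelled

Tractography algorithms terminate streamline propagation when a voxel's FA
or FOD amplitude falls below a magnitude threshold. Because such metrics
decline smoothly toward the ends of a streamline rather than dropping
abruptly, the voxels near both ends contribute systematically low values to
any tract-averaged metric, and the *proportion* of such voxels shrinks as
streamlines get longer. Within one brain this produces a moderate positive
ordinal association between mean streamline length and tract-averaged FA
(and AFD; negative for diffusivities). The association is piecewise: it is
strong and approximately linear below a subject-specific inflection length
(≈ 100 mm in adult human motor-network data) and negligible beyond it,
because real tissue attains a subject-specific asymptote well below the
theoretical range ceiling.

## Candidate models and the median-regression fit

Per subject, with observations (lᵢ, yᵢ) — one per tract — three nested
candidate curves are fitted:

| model     | form                                   | free params | k for AICc |
|-----------|----------------------------------------|-------------|------------|
| linear    | a + b·l                                | a, b        | 3          |
| blackman  | a + b·min(l, c)                        | a, b, c     | 4          |
| piecewise | a + b·min(l, c) + d·max(l − c, 0)      | a, b, c, d  | 5          |

`k` counts the regression parameters plus one for the error scale. All
fits minimise the sum of absolute residuals (median / τ = 0.5 quantile
regression), which is robust to the heavy-tailed, non-Gaussian residual
distributions typical of FA data and makes the residual distribution
approximately symmetric about zero — the property the adjustment relies on.

Numerically, for a fixed breakpoint `c` each model is linear in its
regressors, so the coefficient fit is an exact least-absolute-deviations
linear program (HiGHS). The breakpoint is profiled: a coarse grid at 1 mm
spacing over the admissible window, then golden-section refinement of the
profiled objective to 0.01 mm, ties broken toward the smaller `c`. The
solver contract is the objective value: any method attaining the same
minimum is equivalent.

**Admissible breakpoint window.** `c` is restricted to the [10th, 90th]
percentile of the subject's observed lengths, clipped so that at least two
observations inform each segment: the lower edge never falls below the
2nd-smallest length; the upper edge may reach the largest length for the
blackman model (an empty plateau simply reproduces the line) but stops at
the 2nd-largest for the piecewise model, whose second slope needs a point
beyond the breakpoint. This prevents degenerate one-point segments while
keeping small-sample fits well defined.

**Minimum data.** Fits require n ≥ 3 (linear), 4 (blackman), 5 (piecewise)
tracts with at least two distinct lengths; subjects below the configured
minimum are reported and skipped, never imputed. "Streamline length" is
taken as the mean streamline length per tract; the ingest layer accepts any
precomputed length column, so a median-based summary can be supplied
instead.

## AICc, Akaike weights and averaging

The L1 objective is, up to constants, the negative profile log-likelihood
of a Laplace error model; at the scale MLE b̂ = SAR/n the log-likelihood is
−n(ln(2b̂) + 1), giving AIC = 2k − 2·loglik and the small-sample form
AICc = AIC + 2k(k+1)/(n − k − 1). Only AICc *differences* enter the
weights, so the likelihood convention matters only if users mix it with
externally computed criteria (documented for that reason). A zero-residual
fit is a perfect-fit sentinel (AICc = −∞, weight 1; ties among perfect fits
split the weight equally); a model with n − k − 1 < 1 is excluded with a
warning.

Weights are wᵢ = exp(−Δᵢ/2)/Σⱼ exp(−Δⱼ/2), Δᵢ = AICcᵢ − min AICc; they sum
to 1 by construction. Averaged predictions are pointwise convex
combinations and therefore never leave the candidates' envelope.

The inflection-point parameters exist only for the two breakpoint models,
so their pair of weights is rescaled to sum to 1 before averaging:
c̄ = w′_B·c_B + w′_P·c_P, and the reference value v̄ averages each model's
value **at its own inflection** (not the averaged curve at c̄ — the two
differ in general, and the worked single-subject example pins this
convention). Averaged slopes follow the same rescaled weighting, the
blackman second slope entering as 0. If the linear model carries
essentially all weight (w_B + w_P = 0 at float precision) there is no
defined inflection; the subject is flagged and excluded from adjustment
rather than given a fabricated reference.

**Adjustment.** residual_t = y_t − averaged_fit_t;
adjusted_t = v̄ + residual_t. Observed = fit + residual holds exactly, the
within-subject rank order of adjusted values equals that of the residuals,
and the adjusted values are expressed on the metric's natural scale at the
subject's plateau-level reference, permitting across-subject comparison.

**Grid prediction.** Curves can be evaluated on nominal length grids (1 mm
default) for cohort summaries; grid points outside a subject's observed
length range are computed but flagged as extrapolation, since common
nominal grids across subjects necessarily extrapolate for some of them.

## Theoretical profile model

The generative thought experiment behind the synthetic data: along a
streamline the metric ramps from the termination threshold t₀ (default
0.2) at each end at rate s (default 0.016 per length unit ≡ 1.6 per 100
units) up to the range ceiling (1), giving terminal sections of length
L = (1 − t₀)/s = 50 units. The streamline-averaged metric then has the
closed form

* l ≤ 2L: t₀ + s·l/4 (linear; both ramps, no central plateau)
* l > 2L: 1 − (1 − t₀)²/(s·l) (power-law approach to the ceiling)

continuous at l = 2L, and the proportion of the streamline occupied by
terminal sections is p̂ = min(2L, l)/l. A real specimen attains an
asymptote A < 1 (default 0.7), so its empirical mean curve is capped:
min(theoretical mean, A) — rising, then exactly flat. This "mean-cap" is
the default reading (slope exactly zero past the crossing length,
l* = 400/3 ≈ 133.3 units at the defaults); a "profile-cap" variant that
caps the per-position profile at A instead is exposed as an option and
yields a smooth asymptotic approach rather than a hard plateau. Lengths
are unitless in the profile model; the simulator maps units to mm 1:1.
This is a statistical, not a biophysical, model: no diffusion physics,
partial-volume effects or FOD behaviour are represented.

## Synthetic cohort generator

The generator emulates the study-cohort geometry the pipeline targets:

* 43 subjects; an atlas of 120 tracts of which 82 are resolved per subject
  (uniform random subset);
* atlas tract lengths evenly spaced over 74–134 mm with per-subject
  Gaussian jitter (sd 16.0 mm). The span and jitter were calibrated once,
  by simulation, so the cohort reproduces the two geometry statistics that
  motivate per-subject (rather than per-tract) modelling: mean
  within-subject length range ≈ 106.4 mm and mean per-tract across-subject
  range ≈ 64 mm, with cohort-wide lengths spanning roughly 50–170 mm;
* per-subject blackman curves: inflection ~ N(102, 8²) mm (clipped to
  60–150), slope ~ N(0.004, 0.0008²) (floored at 5·10⁻⁴), plateau
  ~ N(0.45, 0.03²); dispersions chosen to be consistent with the reported
  cohort confidence intervals for these parameters;
* symmetric noise, Gaussian by default with sd 0.03 (Laplace optional —
  the median fit does not pin the noise law); FA-type metrics clipped to
  [0, 1];
* reproducibility: subject i is generated from `default_rng([seed, i])`,
  so any subject can be regenerated independently of the rest.

Under these defaults the per-subject Kendall τ between length and FA
averages ≈ 0.45 — the right direction and order as real motor-network data
(≈ 0.35), somewhat stronger because the synthetic curves are exactly
linear-plateau with homogeneous noise. What the synthetic cohort does
*not* emulate: tract-specific length distributions and anatomy,
heteroscedastic noise, metric-specific floors, or any spatial correlation
between tracts; passing tests therefore demonstrate correctness of the
statistical machinery and recoverability under the stated conditions, not
performance on any particular real acquisition. A generator option with
zero length jitter illustrates the degenerate per-tract case (every tract
has one length across subjects, so per-tract fits are impossible).

## Robust statistics

* **Kendall τ-b** (tie-corrected; delegated to scipy). Tract data carry no
  structural ties, but integer-valued synthetic tests do, so the variant
  is fixed. An all-tied sample raises an undefined-correlation error.
* **BCa bootstrap**: bias correction z₀ from the fraction of bootstrap
  replicates below the estimate (half-weight on ties), acceleration from
  jackknife skewness, percentile endpoints adjusted accordingly;
  deterministic given the seed. With z₀ = 0 and a = 0 it reduces exactly
  to the percentile interval. A degenerate bootstrap distribution
  collapses the interval to the point estimate with a warning. Default
  1000 resamples.
* **Correlation CIs**: per-unit τ values (units = subjects or tracts,
  matching the analysis) are Fisher-z transformed; units are resampled;
  the per-resample mean z is weighted by each unit's observation count
  (weighting applied inside each resample, before the BCa adjustment —
  the unweighted variant is available for sensitivity checks); BCa runs on
  the z scale and endpoints are inverse-transformed. |τ| = 1 is clamped to
  1 − 10⁻¹² with a warning before the transform.
* **Trimmed mean**: mean after removing ⌊trim·n⌋ observations per tail
  (default 20%).
* **Yuen's paired t**: trimmed-mean difference over the winsorized
  standard error with the winsorized covariance accounting for pairing;
  df = h − 1, h = n − 2⌊trim·n⌋. At trim 0 it reduces exactly to the
  classical paired t-test. The effect size δt standardises the
  trimmed-mean of the paired differences by their winsorized SD, rescaled
  by the winsorized SD of the standard normal at the same trimming level
  (computed, not hard-coded; 0.642 at 20%) so that δt equals Cohen's d
  under normality; its CI is a bootstrap percentile interval.

## Problem sizes used in validation

The cohort-scale checks run one seeded 43-subject × 82-tract cohort under
the default generative conditions, fitted once and shared across the
recovery, adjustment-efficacy and nesting checks. Bootstrap coverage is
calibrated on 2000 seeded Gaussian replicates (n = 30) with 1000 resamples
each — enough replicates to hold the Monte-Carlo error of the coverage
estimate near 0.6%. Exact-L1 oracle agreement is checked on n ≤ 8
instances against exhaustive finite candidate searches.

## Known limitations

* Only τ = 0.5 (median) regression is supported; other quantile levels are
  out of scope.
* The breakpoint profiling assumes the profiled objective is locally
  unimodal around the best grid point; with a 1 mm grid this has been
  robust, but a pathological objective could in principle refine into a
  local dip (the grid optimum is always retained as a fallback).
* AICc values (not differences) depend on the Laplace-likelihood
  convention; compare criteria across packages only via Δ values.
* The adjustment transfers any misfit of the averaged curve into the
  residuals; subjects whose data genuinely contain no inflection in the
  observed length range are flagged, and their adjusted values should be
  interpreted cautiously.
* Byte-stable outputs assume identical library versions; floating-point
  differences across BLAS builds can alter low-order digits.
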