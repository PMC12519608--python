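# Methods

Statistical models, estimators, conventions and numerical choices used by
`crvalid`. Everything here is implemented in `src/crvalid/` and exercised by
the test suite; no empirical claim in this document goes beyond what the
tests and `scripts/acceptance.py` compute.

## 1. Setting and notation

Right-censored competing-risks data: per subject an observed time `T_i > 0`,
a status `D_i ∈ {0, 1, …, K}` (0 = censored, k = failure from cause k) and
covariates `x_i`. The cause-specific hazard `h_k(t|x)` is the failure rate
from cause k among subjects event-free from all causes. Derived quantities:

- cause-specific survival `S_k(t|x) = exp(−H_k(t|x))` with
  `H_k(t|x) = ∫₀ᵗ h_k`,
- all-cause survival `S(t|x) = Π_k S_k(t|x)`,
- cause-specific absolute risk (CIF)
  `F_k(t|x) = ∫₀ᵗ S(u|x) h_k(u|x) du`,
- all-cause risk `F = 1 − S = Σ_k F_k` (conservation).

`1 − S_k(t|x)` is also reported, purely as a per-model diagnostic of the
cause-k hazard model; it is not a real-world risk in the presence of
competing events.

## 2. Flexible parametric cause-specific models (`fpm`)

Royston–Parmar form on the log cumulative hazard scale:

```
ln H_k(t | x) = s_k(ln t; γ_k) + β_k' x
```

with `s_k` a restricted cubic spline (RCS). `df` is the number of spline
basis columns (the first is linear in log time), so `df = 1` is a Weibull
model and a `df`-column basis has `df − 1` interior knots. Default `df = 3`.
Knots sit on log cause-k event times: boundary knots at min/max, interior
knots at equally spaced percentiles.

**Likelihood.** With `d_ik = I(D_i = k)` and η_i = s_k(ln t_i) + β'x_i,

```
ℓ = Σ_i d_ik [ ln s_k'(ln t_i) − ln t_i + η_i ] − exp(η_i)
```

(other-cause events enter as censorings). Maximisation uses L-BFGS-B with
the analytic gradient followed by a damped Newton polish on a numerical
Hessian; convergence requires a scaled gradient max-norm below 1e−6 (relaxed
proportionally for very large n). A Weibull (`df = 1`) fit warm-starts
higher-df fits. Where an iterate makes the fitted spline derivative
`s'` non-positive at an event time, `ln s'` is replaced by a steep linear
extension below a positivity floor (1e−8), which penalises invalid iterates
smoothly instead of returning −∞; converged fits have `s' > 0` at all event
times.

**Predictions.** `S_k`, `1 − S_k` and `h_k = s_k'(ln t)/t · exp(η)` are
closed-form. The CIF integral is evaluated by Gauss–Legendre quadrature on
the **log-time** scale: `F_k = ∫ S(e^v) exp(η_k(v)) s_k'(v) dv` over
`[v_lo, ln t]`, plus the exact lower tail `H_k(e^{v_lo})`, with `v_lo`
chosen so the total cumulative hazard below it is < 1e−7. The node count
doubles from 30 until the result changes by < 1e−7 (cap 240). Log-scale
integration removes the `t^{α−1}` end-point singularity of Weibull-like
hazards; conservation `S + Σ_k F_k = 1` holds within 1e−6 (tested), and the
two-cause constant-hazard closed form
`F_1(t) = λ₁/(λ₁+λ₂)(1 − e^{−(λ₁+λ₂)t})` is matched within 1e−6.

**Serialization.** Models round-trip through JSON bit-faithfully (Python's
shortest-repr floats): knots, γ, β with names, categorical level sets, fit
metadata.

## 3. Nonparametric estimators (`nonparam`)

Step functions (right-continuous, with left limits) built from a shared
risk-set table. Tie convention: at tied times, events precede censorings in
risk-set accounting. Evaluation beyond the last observed time returns the
last value; landmark times beyond follow-up trigger a warning upstream.

- Kaplan–Meier, all-cause or cause-specific (other causes censored).
- Aalen–Johansen CIF: `F̂_k(t) = Σ_{t_j ≤ t} Ŝ(t_{j−1}) d_kj / n_j` with the
  all-cause KM left limit. Conservation with the all-cause KM is exact.
- Reverse KM for the censoring distribution `Ĝ` (censoring is the event).
- Mixture KM: `Σ_r p_r Ŝ_{r,k}^KM` over risk groups with proportion weights.

## 4. Pseudo-observations (`pseudo`)

Jackknife pseudo-values at landmark `t*`:
`θ̂_ik = n θ̂_k − (n−1) θ̂_k^(−i)` with `θ̂_k` the Aalen–Johansen CIF (for
absolute risks) or `1 − KM` (cause-specific or all-cause failure).

**Fast jackknife.** Leave-one-out estimators are computed in O(n log n) via
prefix sums over the risk-set table; each subject's removal changes the
factors `1 − d_j/n_j` only at its own time and through risk-set counts,
which reduces to three cases (event-free past t*, censored off the event
grid, at-grid). Log-scale segment sums guard products that hit exactly 0. A
brute-force leave-one-out oracle (refitting the estimator n times) agrees
within 1e−12 on tied data up to n = 500 (tested), and is itself available
via `brute_force_pseudo`.

**Stratification.** For `1 − S_k` the competing event is a dependent
censoring mechanism, so pseudo-values are computed within R = 10 (default)
equal-percentile groups of the cause-k model's linear predictor — the
grouping is monotone-equivalent to grouping on predicted `1 − S_k`. Each
group's jackknife uses only its own subjects (the mixture-KM construction).
On the shipped generator this reduces the bias of the mean pseudo-value
against the true mean `1 − S_2(10)` by an order of magnitude (seeded test).
A stratum with no cause-k events has KM ≡ 1 there and pseudo-values 0 (with
a warning).

**Identities and their limits.** With complete data (no censoring before
t*), pseudo-values equal the event indicators and their mean equals the
full-sample estimator — both exact and tested (the O(n log n) path is exact
to one ulp; the brute-force path bit-exact). Under censoring the mean
identity does **not** hold in general: KM/AJ are not linear in leave-one-out
contributions (verified by direct computation on a 3-subject example), so
the tests assert it only where it is a theorem.

## 5. Calibration (`calibration`)

Observed (pseudo-value) risk is regressed on logit predicted risk with a
logit link. Because pseudo-values can fall outside [0, 1], the fit solves
the quasi-likelihood estimating equations `Σ x_i (θ_i − expit(x_i'b)) = 0`
by damped iteratively reweighted least squares (hand-rolled; standard GLM
routines reject out-of-range responses).

- **Curve**: RCS basis of logit(pred) with 3 interior knots, boundary knots
  at the 5th/95th percentiles; the curve is reported between the boundary
  knots and is bounded in (0, 1) by the link.
- **Slope**: coefficient of logit(pred) in the linear logit-link regression
  (ideal 1).
- **CITL**: intercept of the same regression refitted with logit(pred) as a
  fixed offset (ideal 0). Adding c to all predictions on the logit scale
  shifts CITL by −c and leaves the slope unchanged (tested).
- **O/E**: mean(θ)/mean(pred) (ideal 1); **grouped points**: mean observed
  vs mean predicted in 15 equal-percentile groups (plot overlay).

Predictions at exactly 0 or 1 are clamped to [1e−10, 1−1e−10] with a
warning; constant predictions are an error.

## 6. IPCW Brier score and IPA (`performance`)

At landmark t*, with outcome indicator `Y_i = I(T_i ≤ t*, D_i = k)`:

```
B̂_k = (1/n) Σ_i [ I(event by t*) (Y_i − p_i)² / Ĝ(T_i⁻)
                + I(event-free at t*) p_i² / Ĝ(t*⁻) ]
```

"Event-free at t*" means `T_i > t*` or censored exactly at t* (relevant
because the shipped scenarios censor administratively at t* = 10). Weights
use left limits: `Ĝ(T_i⁻)` for event subjects, `Ĝ(t*⁻)` for at-risk ones.
`Ĝ` comes from the reverse KM (default) or a flexible parametric censoring
model. A printed variant of this score that sums indicators over all causes
inside the square is not used; the single-cause score above is the package's
definition.

For the `1 − S_k` target the weights are doubled, `1/(Ĝ Ĝ_k)`, where `Ĝ_k`
is the predicted survival of the **competing event** (any cause ≠ k) from a
flexible parametric model whose covariate effects vary with log time
(spline-by-covariate interactions, default `td_df = 2`; covariates are the
union of all analysis-model terms). Competing-event subjects count as
censored for cause k at their event time: they contribute to neither term
and their mass is redistributed by the weights. No weight truncation is
applied by default; weights below 0.01 trigger a warning.

Null models: Aalen–Johansen (CIF target), `1 − cause-specific KM`
(`1 − S_k` target, same dual weights), `1 − all-cause KM` (all-cause
target). `IPA = 1 − B̂/B̂_null`: 1 = perfect, 0 = no better than the null,
negative = worse than the null.

**A practical caveat**: for `1 − S_k` of a low-risk cause whose competing
event is common, `Ĝ_k` becomes very small for late events (observed down to
~1e−4 on the shipped generator), so the dual-weight score has heavy-tailed
per-subject contributions and high Monte-Carlo variance; slightly negative
IPA values for a well-specified model are possible at finite n. This is a
property of the estimator, not an implementation defect (confirmed by
recomputing with the true generator weights).

## 7. Simulator (`simulator`)

Cause-specific-hazards generation: draw covariates, invert the total
cumulative hazard at a uniform draw to get the latent all-cause event time
(vectorized bisection on [1e−12, 10·c_admin], 80 halvings), assign the cause
with probability proportional to the cause-specific hazards at that time,
then apply administrative censoring at `c_admin` (status 0 at `c_admin`).
Optional independent exponential censoring is available for exercising the
IPCW machinery.

Shipped configuration (two causes, `c_admin = 10`):

| | baseline rate | baseline shape | x1 | x1² | x2 | x3 | x4 (2,3,4) |
|---|---|---|---|---|---|---|---|
| cause 1 | 0.08 | 1.2 | 0.5 | 0.2 | 0.3 | −0.3 | 0.2, 0.4, 0.6 |
| cause 2 | 0.04 | 1.0 | 0.3 | 0.1 | −0.2 | 0.25 | 0.15, 0.3, 0.45 |

Covariates: x1–x3 standard normal, x4 uniform over 4 levels. The structure
(Weibull baselines, a nonlinear — quadratic — x1 effect, a 4-level
categorical) follows the published simulation design; the numeric values are
this package's own choices, since the publication's exact parameter tables
live in supplementary material that was not available. External-validation
scenarios multiply baseline rates: `cause1_shift` (cause-1 rate ×1.8),
`cause2_shift` (cause-2 rate ×2.5), `both_shift` (both), with covariate
effects shared. These shifts were fixed before any validation statistics
were computed and are study conditions, not tuning knobs.

`true_cif` evaluates the generator's exact CIF by 200-node Gauss–Legendre
quadrature (absolute error ≲ 1e−5 near risk 1) for oracle comparisons;
`crvalid simulate --true-cif-at T` appends these as columns.

## 8. Limitations and non-goals

- No discrimination measures (C-index), integrated calibration index,
  recalibration/model updating, Fine–Gray subdistribution modelling, or
  time-dependent effects in the *prediction* models.
- No variance/confidence bands for calibration curves or nonparametric
  estimators.
- The jackknife mean identity is exact only without censoring before t*
  (see §4); the dual-weight Brier score can be noisy for rare causes
  (see §6).
- No left truncation, time-varying covariates or interval censoring.
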