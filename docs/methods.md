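# Methods

## The demand model

Consumption is modelled on the log10 scale as
`log10 Q(C) = log10 Q0 + k (e^{-alpha Q0 C} - 1)`.
The model assumes multiplicative (log-normal) observation noise, which is
why all fitting minimizes squared error in `log10 Q`; points with zero
consumption carry no information on that scale and are excluded, with
`n_points_used` recording the exclusion. Parameters are strictly positive,
so the optimizer works on `(log Q0, log alpha, log k)`; bounds are thereby
unnecessary and the Levenberg–Marquardt path stays available.

**Derived indices.** `EV = 1/(100 alpha k^1.5)` by definition. Expenditure
`E(C) = C * Q(C)` has an interior stationary point where the standardized
price `u = alpha Q0 C` solves `u e^{-u} = 1/(k ln 10)`; the smaller root
(principal Lambert-W branch, `u = -W0(-1/(k ln 10))`) is the unit-elasticity
point, giving `Pmax = u/(alpha Q0)` and `Omax = Pmax * Q(Pmax)`. Both
`Omax/(Q0 Pmax)` and `Omax/EV` are functions of `k` alone — the basis of
the shared-`k` consistency checks. Two caveats are worth knowing:

* the root exists only for `k ln 10 > e` (k ≳ 1.18); below that demand
  never becomes elastic and `derive_pmax` raises;
* because consumption is bounded below by `Q0 10^{-k}`, expenditure rises
  again at very high prices; for `k ≳ 1.6` the interior maximum dominates
  on `(0, 10 Pmax]`, which is the regime the oracle tests cover. Pmax is
  always the interior (behaviorally meaningful) maximum.

`derive_pmax(..., method="hursh_approx")` provides the historical
closed-form approximation `u ≈ (0.084 k + 0.65)/k^1.5` used by legacy
demand-curve templates.

**Fitting.** Individual fits need ≥ 3 positive points (≥ 4 when `k` is
free). Multi-start nonlinear least squares (default 5 starts: one
heuristic — `Q0` from the lowest-price consumption, `k` from the observed
log10 span + 0.5, `alpha` from a decade grid — plus seeded log-space
jitter of SD 0.4), tolerances 1e-12, best-RSS solution wins. The shared-`k`
joint fit stacks per-curve residuals and estimates `2 n_curves + 1`
parameters; per-curve seeds come from fixed-`k` individual fits at the
pooled `k` rule. `omax_observed` takes the first (lowest-price) maximizer
on ties.

**Extra sum-of-squares F test.** Convention: collapse each group to its
mean-consumption curve at each price (averaging over the subjects observed
at that price), then compare the full model (shared `k`, per-group `Q0`
and `alpha`) to the reduced model (shared `k`, per-group `Q0`, one
`alpha`): `F = ((RSS_r - RSS_f)/(df_r - df_f)) / (RSS_f / df_f)` with
`df_num = 1` for two groups and `df_den = n_points - (2 n_curves + 1)`.
Numerical nesting violations (reduced RSS a hair below full) are clipped to
zero, so `F >= 0` always. A subject-level variant (`grouping="per-subject"`)
shares one `alpha` across all individual curves instead.

## Group inference

Demand indices (EV, Q0, Pmax, Omax) are compared with the classic
pooled-variance Student t test (df = n_a + n_b − 2); Welch is available
behind `equal_var=False`. Two-sided p throughout. No multiplicity
correction is applied across the four index tests — the family is small
and confirmatory, and each statistic is reported with its group means and
SDs so readers can apply their own. Under a shared `k`, Omax is a
`k`-only multiple of EV, so their t statistics are identical by
construction; this is asserted in the tests and visible in the bundled
reference cohort.

## Per-gene negative-binomial regression

Expression (FPKM-like, non-negative) is rounded half-up to counts — the
NB likelihood is a count likelihood — and each gene is fitted with a
log-link NB2 GLM, `E[y] = exp(b0 + b1 * EV)`, `Var[y] = mu + mu^2/theta`.
Estimation alternates IRLS for the coefficients with a bounded
(`theta ∈ [1e-3, 1e6]`) profile update of the dispersion, initialized at
the method-of-moments value. A continuous quasi-likelihood alternative
(`round_counts=False`) is available.

Two small-sample choices depart from the asymptotic textbook recipe, both
made for calibration at the ~11-sample designs this package targets and
both measured in the test suite:

* **Cox–Reid–adjusted dispersion (default).** Plain ML profiling of
  `theta` is biased toward under-dispersion because the fitted mean soaks
  up variance; the adjustment subtracts `0.5 logdet(X'WX)` from the profile
  likelihood (the same correction dispersion-aware DE tools use). Without
  it, null p-values for well-expressed genes run liberal (~7% below 0.05 at
  n = 11). `dispersion="ml"` restores the classic `glm.nb`-style
  alternation and is what the statsmodels cross-check test compares against.
* **t-referenced Wald tests (default).** `z = b1/se` is referred to a
  Student t with `n − p` degrees of freedom rather than the normal;
  `wald_reference="normal"` gives the asymptotic behavior. With both
  defaults the null distribution of raw p is uniform by KS at 2,000
  simulated null genes.

Batch behavior (`regress_all_genes`): genes with fewer than 3 nonzero
samples are reported as skipped, not tested; genes whose fit fails to
converge are reported but excluded from the BH pool so unstable Wald
statistics cannot contaminate the FDR calibration; per-gene exceptions
never abort the batch. Benjamini–Hochberg is applied once per run (one
region × one predictor). Note that step-up BH is monotone but not
idempotent — re-adjusting adjusted values can only push them up.

The two-group screen (`nb_group_contrast`) fits the same GLM with a 0/1
group indicator (`log2 FC = b1/ln 2`) and feeds the conventional threshold
rule, applied with strict inequalities: `log2 FC > 1` or `< −1`, and
`p < 0.05`; a fold change of exactly 2 (log2 FC = 1.0) is excluded.

## The synthetic generator

One seeded configuration drives both generators; behavior and expression
consume independent child streams of the seed, so changing `n_genes` never
perturbs the behavioral draws.

* **Demand curves.** Per subject, `Q0` and `alpha` are lognormal with
  group-specific hyperparameters (positivity and the right-skew seen in
  real cohorts); defaults reproduce the bundled reference cohort's
  per-group geometric means and log-SDs at `k = 2.4` (METH
  `ln Q0 = 1.93 ± 0.64`, `ln alpha = −6.35 ± 0.66`; saline
  `0.10 ± 0.56`, `−3.78 ± 0.39`). Consumption is in mg/kg at the 0.05
  mg/kg/infusion unit dose; observed `Q` is the model curve times
  `10^{N(0, 0.1)}` noise, matching the least-squares objective. The ladder
  truncates at the first price whose realized infusion count
  (`Q / unit_dose`) rounds to zero — the escalating-FR stopping rule — and
  that failure price is recorded with zero consumption. At the defaults
  this leaves saline subjects ~7–9 positive points and METH subjects the
  full ladder, so every curve stays fittable.
* **Expression.** Counts are NB with `log mu = b0_g + beta_g * EV_s +
  log L_s`: gene baselines `b0_g ~ N(3.0, 1.5)` (natural log, a wide
  FPKM-like spread), `beta_g = 0.5` for a randomly chosen 2.5% of genes
  and 0 otherwise, dispersion `theta = 10`, and a ±10% uniform library-size
  factor `L_s`. Setting `drop_meth_pfc_sample` removes the first METH
  subject's sample, reproducing the unbalanced 5 + 6 design.

What the generator does **not** emulate — and hence what passing tests do
not certify about real data: gene–gene correlation, mean–dispersion trends,
composition/normalization artifacts beyond a scalar library factor,
zero-inflation beyond NB sampling, region differences between PFC and
hippocampus, and within-session behavioral microstructure.

## The bundled reference cohort and printed precision

The packaged table carries the published per-subject indices (2 decimal
places) of a 12-rat cohort. Our own consistency analysis of that table:
the ratio `Omax/(Q0 Pmax)` is constant to CV 0.13% across all 12 subjects,
confirming a single shared `k` — but the `k` back-solved from that ratio
with the exact Lambert-W root (2.357) disagrees with the `k` back-solved
from `Omax/EV` (2.499), while both ratios agree simultaneously at
`k ≈ 2.50` under the closed-form approximation. The producing software
evidently used the approximation; `infer_shared_k_from_indices` therefore
solves for `(k, u)` jointly from the two printed ratio families without
assuming either formula. With that solution, the six METH subjects'
printed Pmax and Omax regenerate within 0.6%. The saline rows cannot do
better than their input precision: an EV printed as 0.07–0.19 carries
2.6–7% rounding error (and one subject's EV prints as 0.00, making
`alpha = 1/(100 EV k^1.5)` undefined), so their regeneration errors of
2.3–3.9% sit inside the rounding bound, and the `Omax/EV` ratio CV over
the printed values (1.8%) exceeds what the underlying constant would give.
The corresponding acceptance tests assert the sharp bounds anyway and are
expected to fail exactly on those low-precision rows — the parametrization
makes the precision boundary explicit rather than hiding it.

## Problem sizes and numerical conventions

The test suite and the acceptance script use: 100 random parameter sets
for the Pmax/Omax brute-force oracle (tolerance 1e-6 relative, `k` drawn
from the typical 1.8–4 range); 200 noisy-replicate fits for `alpha`
recovery (median |relative error| < 15% at log10 noise SD 0.1); 2,000
simulated null genes for KS calibration and 500 replicates per slope for
NB bias (bound ±0.05 at `theta = 10`, n = 11); one default-size
(2,000-gene) end-to-end screen for FDR/power reporting. All stochastic
routines take explicit seeds; there is no global random state. TSV with
LF endings and `.` decimals everywhere; `#` lines are comments on input.

## Known limitations

* The NB Wald test, even t-referenced, is approximate; likelihood-ratio
  or resampling inference may behave differently in pathological genes.
* The exponential demand fit can be poorly conditioned when truncation
  leaves few positive points near `Q0`; the convergence flag and
  `n_points_used` should be inspected before downstream use.
* `ExpressionMatrix` performs no normalization; FPKM-like inputs are taken
  as given (the library-size factor exists only in the generator).
* The shared-`k` fit assumes a common range constant; badly violated, the
  derived EVs inherit the misfit.
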