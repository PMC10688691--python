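# Methods

## Model

The inverse Pareto distribution (IPD) with shape α > 0 has cdf
F(x|α) = (x/(1+x))^α on (0, ∞).  Its sufficient statistic for a sample is
S = Σ ln(x_i/(1+x_i)) ≤ 0; the log-likelihood of any censored-data scheme
used here depends on the data only through S and the survivor terms
ln(1 − (x_i/(1+x_i))^α).  For independent X ~ IPD(α₁) (strength) and
Y ~ IPD(α₂) (stress), P(Y < X) = α₁/(α₁+α₂): the reliability is a smooth
function of the two shapes, so every estimation route below estimates the
shapes per sample and maps through this closed form (invariance).

All cdf powers are evaluated in log space, `exp(α·(log x − log1p(x)))`.
This matters in practice: strength data of the kind shipped with the package
fit shapes near α ≈ 19–25, where direct powering of x/(1+x) loses digits.

## Progressive first-failure censoring

A PFFC experiment with n groups of k items, m observed failures and removal
vector G = (G₁, …, G_m), n = m + ΣG, yields order statistics distributed as
a progressively type-II censored sample from the group-minimum law
F*(x) = 1 − (1 − F(x))^k.  Every likelihood-type objective therefore carries
the censoring coefficients c_i = k(G_i + 1) − 1 on the survivor terms.
Setting k = 1 recovers ordinary progressive type-II censoring; k = 1 with no
removals recovers the complete sample, where the MLE has the closed form
α̂ = m / (−S).

### Simulator

Samples are generated by the exact uniform-spacings construction: with
W_i ~ U(0,1) and V_i = W_i^{1/(i + G_m + … + G_{m−i+1})}, the quantities
U_(i) = 1 − V_m·V_{m−1}⋯V_{m−i+1} are the ordered progressive type-II
uniforms; these are pushed through the inverse of F* (p = 1 − (1−U)^{1/k},
then the IPD quantile u/(1−u) with u = p^{1/α}).  The construction is O(m),
seedable, and validated two independent ways in the test suite: against a
brute-force simulation of the literal censoring experiment (draw all n·k
items, observe group minima, withdraw random groups), and against the
analytic marginal of the first failure (minimum of all n·k items).

The generator *is* the study design: simulation defaults mirror the
published Monte Carlo protocol (schemes over (n, m) ∈ {(25,20), (35,30),
(50,40)}, k ∈ {2, 4}, truths (α₁, α₂) = (2, 0.5) and (1.2, 0.8), R = 1000
replications).  What it does not emulate: group heterogeneity, dependence
between stress and strength samples, measurement rounding — so passing
simulation checks demonstrate correctness of the machinery under the model,
not robustness to model violations.

## Estimation routes

**Maximum product spacing.**  Per sample, maximize
H(α) = Σ_{i=1}^{m+1} ln[F(x_i) − F(x_{i−1})] + Σ_{i=1}^m c_i ln[1 − F(x_i)]
with boundary conventions F(x₀) = 0, F(x_{m+1}) = 1 taken exactly.  The
survivor sum runs to m only (the m+1 term has no defined removal count; its
inclusion would in any case multiply by ln 0 at the upper boundary).  The
two-sample criterion is additive, so each shape is a 1-D problem.  We
maximize H directly by bounded scalar minimization in log α (initial bracket
α ∈ (10⁻³, 10³), expanded geometrically when the optimum pins an edge,
convergence ~1e-8 on α) rather than solving the stationarity equation —
direct maximization cannot converge to a minimum of a flat or one-sided
criterion at small m.  Tied observations (present in the insulation data:
0.07, 0.07; 0.14, 0.14) collapse a spacing to zero; the standard Cheng–Amin
remedy replaces such a spacing with the density f(x_i; α), keeping H finite.
Underflowed spacings between distinct points are floored at the smallest
positive log rather than propagated as −∞.

**Maximum likelihood.**  The score
m/α + S − Σ c_i u_i^α ln u_i / (1 − u_i^α) (u_i = x_i/(1+x_i)) is strictly
decreasing in α, so the MLE is found by bracketed root finding (brentq),
initialized at the complete-sample closed form m/(−S), which is exact when
all c_i = 0 and the right order of magnitude otherwise.  The two-sample
log-likelihood separates; the cross-partial is identically zero and the
observed Fisher information is diagonal with entries
m/α² + Σ c_i (ln u_i)² u_i^α/(1 − u_i^α)².  The delta method gives
Var(φ̂) = q′ I⁻¹ q with q = (α₂, −α₁)/(α₁+α₂)² and the usual normal interval
φ̂ ± z_{ξ/2}·SE at default level 0.95.  Endpoints are reported raw; a clamp
to [0, 1] is available but off by default (a symmetric interval is easier to
reason about, and the shipped analyses stay inside the unit interval anyway).

**Bayes.**  Independent Gamma(r_i, s_i) priors are conditionally conjugate
up to the survivor product: the conditional posterior kernel is
α^{m+r−1} e^{−α(s−S)} Π (1 − u_i^α)^{c_i}.  With c_i = 0 it is exactly
Gamma(m+r, s−S), which is used as a closed-form oracle validating the whole
sampler in the tests.  Sampling is component-wise random-walk
Metropolis–Hastings with normal proposals; non-positive proposals are
rejected outright (the chain stays), which preserves the positive support.
Defaults chosen where the procedure leaves them open: chains start at the
MLEs; proposal scales default to the delta-method standard errors
(fallback 0.1·α̂), which lands acceptance rates in a workable 0.2–0.7 band
without manual tuning; M = 10,000 draws with M₀ = 2,000 burn-in.  The
analysis prior when nothing is known is near-flat, r = s = 10⁻⁴.  The point
estimate is the post-burn-in mean of φ_t = α₁ₜ/(α₁ₜ+α₂ₜ) (squared-error
loss); intervals are Chen–Shao HPD: among all windows of ⌊level·M⌋
consecutive ordered draws the shortest is reported, ties broken at the
smallest start index.

**Goodness of fit.**  One-sample Kolmogorov–Smirnov distance against the
IPD cdf at a supplied shape (in practice the MLE), p-value from the
asymptotic Kolmogorov distribution without correcting for parameter
estimation.  The plug-in p-value is anti-conservative; it is reported for
descriptive use only.

## Monte Carlo harness

Each replicate draws an independent strength/stress pair of PFFC samples
under a common scheme and applies the requested estimators; the harness
reports AV (mean estimate), MSE (against true φ) and AL (mean length of the
ACI or HPD interval).  Replicates whose solver fails are dropped and
counted, never silently imputed.  When the Bayes arm requests an informative
prior the default sets the prior mean equal to the true parameter (rates 2
and 4 for the strength and stress shapes respectively), matching standard
practice for calibration studies.  Full-scale Bayes cells
(R = 1000 × M = 10⁴) are expensive; the harness accepts reduced (R, M)
presets and the test suite runs those, asserting the qualitative orderings
(informative-prior Bayes MSE ≤ ML MSE; HPD length < ACI length) rather than
re-tabulating every cell.  Test-suite problem sizes: R = 1000 for the
ML/MPS-only reproduction of the (25, 20, 2) design cell, R = 40 with
M = 2000 for the Bayes orderings, R = 150–400 for consistency trends.

## Embedded data and known inconsistencies

The jute dataset (fibre breaking strengths at 15 mm and 20 mm gauge,
divided by 10) and the insulation dataset (failure times of two insulation
types under rising voltage, multiplied by 10) ship with their published
first-failure lists and four PFFC sub-samples each, stored exactly as
printed.  The published jute sub-samples are internally inconsistent: the
scheme-1 x̃ sample contains values (12.781, 22.565, 57.486, 71.630) that do
not appear in the published first-failure list from which sub-samples are
nominally drawn.  We deliberately do not "correct" the data.  A consequence
the user should know: the scheme-level point estimates originally reported
alongside these data cannot be reproduced from the printed sub-samples — our
grid-search-verified estimates differ from the reported ones by up to ~0.05
in φ (e.g. jute scheme 1: ML φ̂ = 0.5246 here vs 0.5403 reported), while the
complete-sample fits, the KS statistics, the jute ACI lower endpoint and the
simulation-study averages all reproduce to printed precision.  The pattern
is consistent with the original scheme analyses having been run on different
randomly re-drawn sub-samples than the ones printed.

## Degenerate inputs and numerical edges

- m = 1 with an extreme observation: the MPS criterion pushes α to a
  boundary; the optimizer expands its bracket and flags a boundary hit
  rather than failing silently.
- Samples with F(x_m) numerically 1 at large α: survivor logs are floored,
  and estimation remains finite.
- `CensoringScheme` validates n = m + ΣG, non-negative removals and k ≥ 1 at
  construction; `PFFCSample` enforces positivity, ordering and length m.
  Ties are admitted (real rounded data), relying on the MPS substitution
  rule.
- All randomness (simulator, sampler, harness) flows through
  `numpy.random.Generator` seeds passed top-down.

## Limitations

Only the squared-error-loss Bayes point estimate and gamma priors are
implemented; no Gibbs/slice alternatives or formal convergence diagnostics
beyond acceptance rates and trace exports.  Removal schemes are fixed in
advance (no adaptive or time-censored hybrids).  The KS p-value ignores
parameter estimation.  Interval estimates for the MPS route are not provided
(intervals come from the ML and Bayes routes only).
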