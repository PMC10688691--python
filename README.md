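# ipdssr

Stress–strength reliability estimation for inverse Pareto lifetimes observed
under progressive first-failure censoring (PFFC).

## The problem

In a stress–strength system a unit survives as long as its strength *X*
exceeds the stress *Y* applied to it; the system reliability is
φ = P(Y < X).  This package estimates φ when both variables follow the
one-parameter inverse Pareto distribution (IPD),

    f(x | α) = α x^(α−1) / (1+x)^(α+1),    F(x | α) = (x/(1+x))^α,   x, α > 0,

a lifetime law with decreasing or upside-down-bathtub hazard, and when both
samples are collected under PFFC: *n* independent groups of *k* items are put
on test, at the *i*-th observed first failure G_i surviving groups are
withdrawn, and the experiment stops at the *m*-th failure
(n = m + ΣG_i).  First-failure times are then a progressively type-II
censored sample from the group-minimum law 1 − (1 − F)^k.

For two independent IPD samples, X ~ IPD(α₁) and Y ~ IPD(α₂),

    φ = P(Y < X) = α₁ / (α₁ + α₂),

so estimating φ reduces to estimating the two shape parameters.  The package
provides

- **MPS**: maximum product spacing estimation (cdf-spacing criterion with
  censoring survivor factors, Cheng–Amin density substitution for tied data),
- **ML**: maximum likelihood with the observed Fisher information and the
  delta-method asymptotic confidence interval for φ,
- **Bayes**: independent gamma priors, component-wise random-walk
  Metropolis–Hastings on the conditional posteriors, posterior-mean point
  estimate (squared-error loss) and Chen–Shao HPD credible intervals,
- a seedable **PFFC simulator** (uniform-spacings construction) and a
  replicated **Monte Carlo harness** reporting average value (AV), mean
  squared error (MSE) and average interval length (AL),
- Kolmogorov–Smirnov goodness of fit of the IPD, and two classical embedded
  strength/stress datasets (jute-fibre breaking strengths, electrical
  insulation failure times) with their published PFFC sub-samples.

## Worked example

Maximum likelihood analysis of the scheme-1 jute PFFC samples
(k=2, n=15, m=10, removals (5,0,…,0)):

```sh
$ ipdssr estimate --method ml --data jute --scheme 1
{
  "method": "ml",
  "alpha1": 25.209311819967656,
  "alpha2": 22.840727905973704,
  "phi": 0.5246470546903127,
  "ci_low": 0.36780857310478987,
  "ci_high": 0.6814855362758355,
  "level": 0.95
}
```

The fitted shapes α̂₁ ≈ 25.2 and α̂₂ ≈ 22.8 say both gauge lengths produce
strongly right-shifted strength distributions; their ratio gives
φ̂ ≈ 0.525 — a 15 mm fibre withstands the 20 mm-gauge "stress" in about 52%
of pairings — with 95% delta-method interval (0.368, 0.681).

Model fit for the insulation data at the complete-sample MLEs:

```sh
$ ipdssr gof --data insulation
[
  {"sample": "insulation:X", "alpha": 0.8598, "ks_statistic": 0.1948, "p_value": 0.205},
  {"sample": "insulation:Y", "alpha": 1.6871, "ks_statistic": 0.1565, "p_value": 0.4543}
]
```

Neither KS test rejects the IPD at the 5% level.  The same analyses are
available as library calls (`ipdssr.aci_ssr`, `ipdssr.mps_ssr`,
`ipdssr.bayes_ssr_with_hpd`, `ipdssr.ks_test`), and
`ipdssr reproduce-tables` writes the full scheme-by-scheme CSV summaries for
both embedded datasets.

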