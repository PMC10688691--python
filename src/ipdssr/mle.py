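"""Maximum likelihood estimation for PFFC samples from the IPD, the observed
Fisher information, and the delta-method confidence interval for phi.

For a PFFC sample with scheme (n, k, G) the log-likelihood of the shape
parameter is (up to a data-only constant)

    l(alpha) = m ln alpha + alpha * S + sum_i c_i ln[1 - (x_i/(1+x_i))**alpha],

where S = sum_i ln(x_i/(1+x_i)) and c_i = k(G_i+1) - 1.  The two-sample
log-likelihood separates in (alpha1, alpha2), the cross partial is
identically zero, and the observed Fisher information is diagonal.  With
k = 1 and no removals (complete sample) the censoring coefficients vanish
and the MLE has the closed form alpha_hat = m / (-S).

The delta method propagates the (diagonal) inverse information through the
gradient of phi = alpha1/(alpha1+alpha2),

    q = ( alpha2, -alpha1 ) / (alpha1+alpha2)**2,

giving Var(phi_hat) = q' I^{-1} q and the usual normal interval
phi_hat +/- z_{xi/2} * sqrt(Var).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .censoring import PFFCSample
from .distributions import log_odds_ratio, ssr
from .records import SSREstimate

__all__ = [
    "log_likelihood",
    "score",
    "ml_estimate",
    "fisher_information",
    "ml_ssr",
    "aci_ssr",
]


def _sample_loglik(alpha: float, sample: PFFCSample) -> float:
    lu = log_odds_ratio(sample.times)
    ua = np.exp(alpha * lu)
    return float(
        sample.m * np.log(alpha) + alpha * np.sum(lu)
        + np.sum(sample.censor_coefficients * np.log1p(-ua))
    )


def _log_constant(sample: PFFCSample) -> float:
    """The data-only additive constant: ln C + m ln k - sum ln[x(1+x)]."""
    G = np.asarray(sample.scheme.removals)
    n = sample.scheme.n_groups
    # C = n (n - G1 - 1)(n - G1 - G2 - 2) ... over the first m-1 removals
    remaining = n - np.concatenate([[0], np.cumsum(G[:-1])]) - np.arange(sample.m)
    x = sample.times
    return float(
        np.sum(np.log(remaining)) + sample.m * np.log(sample.k)
        - np.sum(np.log(x) + np.log1p(x))
    )


def log_likelihood(
    alpha1: float,
    alpha2: float,
    sample_x: PFFCSample,
    sample_y: PFFCSample,
    include_constant: bool = True,
) -> float:
    """Joint two-sample log-likelihood l(alpha1, alpha2).

    The additive constant D does not affect the maximizer; set
    ``include_constant=False`` to drop it.
    """
    if alpha1 <= 0 or alpha2 <= 0:
        raise ValueError("shape parameters must be positive")
    value = _sample_loglik(alpha1, sample_x) + _sample_loglik(alpha2, sample_y)
    if include_constant:
        value += _log_constant(sample_x) + _log_constant(sample_y)
    return value


def score(alpha: float, sample: PFFCSample) -> float:
    """d/d alpha of the single-sample log-likelihood."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    lu = log_odds_ratio(sample.times)
    ua = np.exp(alpha * lu)
    c = sample.censor_coefficients
    return float(sample.m / alpha + np.sum(lu) - np.sum(c * ua * lu / (1.0 - ua)))


def ml_estimate(sample: PFFCSample) -> float:
    """Solve the score equation for one PFFC sample.

    Initialization is the complete-sample closed form m / (-sum ln(x/(1+x)))
    (the exact answer when all censoring coefficients are zero); a sign-change
    bracket is then expanded geometrically around it and brentq finishes.
    """
    lu = log_odds_ratio(sample.times)
    closed_form = sample.m / (-np.sum(lu))
    if np.all(sample.censor_coefficients == 0):
        return float(closed_form)
    f = lambda a: score(a, sample)
    lo = hi = closed_form
    # score is decreasing in alpha: > 0 left of the root, < 0 right of it
    for _ in range(200):
        if f(lo) > 0:
            break
        lo /= 2.0
    else:
        raise RuntimeError("could not bracket the MLE from below")
    for _ in range(200):
        if f(hi) < 0:
            break
        hi *= 2.0
    else:
        raise RuntimeError("could not bracket the MLE from above")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


def fisher_information(
    alpha1: float, alpha2: float, sample_x: PFFCSample, sample_y: PFFCSample
) -> np.ndarray:
    """Observed Fisher information, a diagonal 2x2 matrix in (alpha1, alpha2).

    The diagonal entries are -d2l/d alpha^2 per sample; the cross partial of
    the separated log-likelihood is identically zero.
    """

    def diag_entry(alpha: float, sample: PFFCSample) -> float:
        lu = log_odds_ratio(sample.times)
        ua = np.exp(alpha * lu)
        c = sample.censor_coefficients
        return float(
            sample.m / alpha**2 + np.sum(c * lu**2 * ua / (1.0 - ua) ** 2)
        )

    return np.diag([diag_entry(alpha1, sample_x), diag_entry(alpha2, sample_y)])


def ml_ssr(sample_x: PFFCSample, sample_y: PFFCSample) -> SSREstimate:
    """Plug-in ML estimate of phi = P(Y < X)."""
    a1 = ml_estimate(sample_x)
    a2 = ml_estimate(sample_y)
    return SSREstimate(method="ml", alpha1=a1, alpha2=a2, phi=ssr(a1, a2))


def aci_ssr(
    sample_x: PFFCSample,
    sample_y: PFFCSample,
    level: float = 0.95,
    clamp: bool = False,
) -> SSREstimate:
    """Delta-method asymptotic confidence interval for phi at the given level.

    Endpoints are reported raw; ``clamp=True`` truncates them to [0, 1].
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    a1 = ml_estimate(sample_x)
    a2 = ml_estimate(sample_y)
    info = fisher_information(a1, a2, sample_x, sample_y)
    if np.any(np.diag(info) <= 0) or not np.all(np.isfinite(info)):
        raise RuntimeError("observed information is singular or non-finite")
    s = a1 + a2
    q = np.array([a2 / s**2, -a1 / s**2])
    var = float(q @ np.linalg.solve(info, q))
    phi = ssr(a1, a2)
    z = norm.ppf(0.5 + level / 2.0)
    lo, hi = phi - z * np.sqrt(var), phi + z * np.sqrt(var)
    if clamp:
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return SSREstimate(
        method="ml", alpha1=a1, alpha2=a2, phi=phi, ci_low=lo, ci_high=hi, level=level
    )
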