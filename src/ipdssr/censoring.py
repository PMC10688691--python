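"""Progressive first-failure censoring (PFFC): schemes, samples, simulation.

A PFFC life test places n independent groups of k items each on test.  At the
i-th observed first failure, G_i of the surviving groups are withdrawn (along
with the group that just failed); the test stops at the m-th failure.  The
removal vector G = (G_1, ..., G_m) satisfies n = m + sum(G).  The observed
first-failure times are distributed as a progressively type-II censored
sample from the distribution with cdf

    F*(x) = 1 - (1 - F(x))**k,

the law of the minimum of k i.i.d. F-variables.  Special cases: k=1 recovers
ordinary progressive type-II censoring; k=1 with all G_i = 0 recovers the
complete sample.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .distributions import IPDParams, ipd_quantile

__all__ = [
    "CensoringScheme",
    "PFFCSample",
    "parse_scheme",
    "generate_pffc",
    "first_failure_from_groups",
]


@dataclass(frozen=True)
class CensoringScheme:
    """A prefixed PFFC plan: n groups of k items, m failures, removals G.

    Invariant: ``n_groups == m_failures + sum(removals)``.
    """

    n_groups: int
    k_per_group: int
    m_failures: int
    removals: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "removals", tuple(int(g) for g in self.removals))
        n, k, m, G = self.n_groups, self.k_per_group, self.m_failures, self.removals
        if k < 1:
            raise ValueError("k_per_group must be >= 1")
        if not 1 <= m <= n:
            raise ValueError(f"need 1 <= m <= n, got m={m}, n={n}")
        if len(G) != m:
            raise ValueError(f"removal vector has length {len(G)}, expected m={m}")
        if any(g < 0 for g in G):
            raise ValueError("removals must be non-negative")
        if n != m + sum(G):
            raise ValueError(
                f"scheme inconsistent: n={n} but m + sum(G) = {m + sum(G)}"
            )

    @property
    def total_items(self) -> int:
        return self.n_groups * self.k_per_group

    @classmethod
    def from_string(cls, text: str, k: int) -> "CensoringScheme":
        return parse_scheme(text, k)


_TOKEN = re.compile(r"^(\d+)(?:\*(\d+))?$")


def parse_scheme(text: str, k: int) -> CensoringScheme:
    """Parse compact scheme notation like ``"(5 * 1, 0 * 19)"``.

    Tokens are either a bare count ``v`` or ``v * r`` meaning v repeated r
    times; whitespace and surrounding parentheses are ignored.  n is derived
    as m + sum(G).
    """
    body = text.strip()
    if body.startswith("(") and body.endswith(")"):
        body = body[1:-1]
    removals: list[int] = []
    for raw in body.split(","):
        tok = raw.replace(" ", "")
        if not tok:
            raise ValueError(f"empty token in scheme string {text!r}")
        m_ = _TOKEN.match(tok)
        if m_ is None:
            raise ValueError(f"malformed scheme token {raw!r} in {text!r}")
        value = int(m_.group(1))
        repeat = int(m_.group(2)) if m_.group(2) else 1
        removals.extend([value] * repeat)
    m = len(removals)
    return CensoringScheme(
        n_groups=m + sum(removals), k_per_group=int(k), m_failures=m,
        removals=tuple(removals),
    )


@dataclass(frozen=True)
class PFFCSample:
    """Ordered first-failure times bound to their censoring scheme.

    Times must be positive and non-decreasing (strictly increasing with
    probability one under a continuous model, but rounded real data may
    contain ties) and of length ``scheme.m_failures``.
    """

    times: np.ndarray
    scheme: CensoringScheme

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or len(t) != self.scheme.m_failures:
            raise ValueError(
                f"sample has {len(t)} values, scheme expects m={self.scheme.m_failures}"
            )
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("failure times must be positive and finite")
        if np.any(np.diff(t) < 0):
            raise ValueError("failure times must be non-decreasing")

    @property
    def m(self) -> int:
        return self.scheme.m_failures

    @property
    def k(self) -> int:
        return self.scheme.k_per_group

    @property
    def censor_coefficients(self) -> np.ndarray:
        """The survivor exponents k(G_i + 1) - 1 appearing in every objective."""
        G = np.asarray(self.scheme.removals)
        return self.k * (G + 1) - 1


def _ordered_uniforms(scheme: CensoringScheme, rng: np.random.Generator) -> np.ndarray:
    """Ordered progressive type-II uniform sample via the spacings construction.

    With removals G_1..G_m, draw W_i ~ U(0,1), set
    V_i = W_i**(1 / (i + G_m + ... + G_{m-i+1})); then
    U_(i) = 1 - V_m V_{m-1} ... V_{m-i+1} are the ordered uniforms.  Exact and
    O(m).
    """
    G = np.asarray(scheme.removals)
    m = scheme.m_failures
    W = rng.random(m)
    tail_removals = np.cumsum(G[::-1])  # G_m, G_m+G_{m-1}, ...
    V = W ** (1.0 / (np.arange(1, m + 1) + tail_removals))
    return 1.0 - np.cumprod(V[::-1])


def generate_pffc(
    params: "IPDParams | float", scheme: CensoringScheme, seed=None
) -> PFFCSample:
    """Simulate a PFFC sample from the IPD under the given scheme.

    The ordered uniforms from the spacings construction are pushed through
    the inverse of the group-minimum cdf F*(x) = 1 - (1 - F(x))**k:
    p = 1 - (1 - U)**(1/k), then x = F^{-1}(p).  Deterministic under a fixed
    seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    U = _ordered_uniforms(scheme, rng)
    # p = 1 - (1-U)^(1/k), computed via expm1/log1p to keep tail accuracy
    p = -np.expm1(np.log1p(-U) / scheme.k_per_group)
    times = ipd_quantile(p, params)
    return PFFCSample(times=np.sort(times), scheme=scheme)


def first_failure_from_groups(groups) -> np.ndarray:
    """Per-group minima, sorted ascending — the first-failure censored sample."""
    minima = []
    for i, g in enumerate(groups):
        arr = np.asarray(g, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {i} is empty")
        minima.append(arr.min())
    return np.sort(np.asarray(minima))
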