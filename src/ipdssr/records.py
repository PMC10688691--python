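"""Estimate records shared by the MPS, ML and Bayesian routes."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class SSREstimate:
    """A point estimate of phi = P(Y < X) with optional interval.

    method is one of "mps", "ml", "bayes-self"; the interval, when present,
    is (ci_low, ci_high) at the given level (ACI for "ml", HPD for
    "bayes-self").
    """

    method: str
    alpha1: float
    alpha2: float
    phi: float
    ci_low: float | None = None
    ci_high: float | None = None
    level: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)
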