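"""Trace and posterior-density diagnostics for MCMC output."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .bayes import PosteriorChain

__all__ = ["plot_chain_diagnostics"]


def plot_chain_diagnostics(chain: PosteriorChain, path: str, param: str = "phi") -> str:
    """Write a two-panel trace + posterior-density figure to `path`."""
    draws = getattr(chain, param)
    kept = draws[chain.burn_in:]
    fig, (ax_trace, ax_dens) = plt.subplots(1, 2, figsize=(10, 3.5))
    ax_trace.plot(draws, lw=0.4)
    ax_trace.axvline(chain.burn_in, color="red", ls="--", lw=0.8, label="burn-in")
    ax_trace.set_xlabel("iteration")
    ax_trace.set_ylabel(param)
    ax_trace.legend(frameon=False)
    ax_dens.hist(kept, bins=60, density=True, alpha=0.75)
    ax_dens.set_xlabel(param)
    ax_dens.set_ylabel("posterior density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
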