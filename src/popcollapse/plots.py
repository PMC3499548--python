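"""Line plots for posterior summaries and Bayes-factor profiles.

Thin matplotlib helpers mirroring the figures such analyses are usually
reported with: overlaid posterior densities per run (with the prior for
comparison) and log-BF profiles over time with the substantial-support line.
"""

from __future__ import annotations

import numpy as np

from .inference import TraceSet
from .posterior import BFResult


def plot_posterior_density(trace: TraceSet, param: str, ax=None, prior=None,
                           bins: int = 60):
    """Per-chain posterior densities of one parameter; optionally overlays an
    analytic prior (any object with a ``pdf``)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    lo = trace.df[param].min()
    hi = trace.df[param].max()
    grid = np.linspace(lo, hi, 400)
    for c in trace.chains:
        ax.hist(trace.chain(c)[param], bins=bins, density=True,
                histtype="step", label=f"chain {c}")
    if prior is not None:
        ax.plot(grid, prior.pdf(grid), "k--", lw=1, label="prior")
    ax.set_xlabel(param)
    ax.set_ylabel("density")
    ax.legend(fontsize="small")
    return ax


def plot_bf_profile(results: list[BFResult], ax=None, support_line: float = 3.0):
    """Natural-log BF per time window, with the substantial-support line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mid = [(r.hypothesis.lo + r.hypothesis.hi) / 2 for r in results]
    bf = [r.bf for r in results]
    with np.errstate(divide="ignore", invalid="ignore"):
        ax.plot(mid, np.log(bf), drawstyle="steps-mid")
    ax.axhline(np.log(support_line), ls="--", color="grey",
               label=f"BF = {support_line:g}")
    ax.set_xlabel("years before present")
    ax.set_ylabel("ln BF")
    ax.legend(fontsize="small")
    return ax
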