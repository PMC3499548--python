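"""Posterior post-processing: burn-in, convergence, pooling, intervals, and
Bayes-factor dating of the size-change onset.

The dating framework converts posterior samples of the onset time T from
generations to years (generation time g is always explicit — 8 y and 25 y are
both defensible for long-lived apes) and weighs interval hypotheses by
approximate Bayes factors: posterior odds of "T in the interval" divided by
prior odds.  Four canonical epochs cover the last 100,000 years —
H1 (0, 200] (commercial forest exploitation), H2 (200, 5000] (first farmers),
H3 (5000, 40000] (hunter-gatherers), H4 (40000, 100000] (Pleistocene
climate) — each tested against the other three pooled, plus a sliding
500-year BF profile over the last 50,000 years.  BF >= 10 counts as strong
support, 3 <= BF < 10 substantial, below 3 none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .inference import HierarchicalPriors, TraceSet

__all__ = [
    "EpochHypothesis",
    "BFResult",
    "CANONICAL_EPOCHS",
    "discard_burnin",
    "geweke_z",
    "geweke_table",
    "drop_stuck_chains",
    "pool_runs",
    "interval_summary",
    "generations_to_years",
    "t_prior_years",
    "bayes_factor_interval",
    "epoch_bf_profile",
    "epoch_hypothesis_test",
    "support_label",
]


# ---------------------------------------------------------------------------
# Trace handling
# ---------------------------------------------------------------------------

def discard_burnin(trace: TraceSet, fraction: float = 0.10) -> TraceSet:
    """Drop the first ceil(fraction * n) retained samples of every chain."""
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    if trace.df.empty:
        raise ValueError("empty trace")
    kept = []
    for c in trace.chains:
        block = trace.chain(c)
        drop = math.ceil(fraction * len(block))
        kept.append(block.iloc[drop:])
    return replace(trace, df=pd.concat(kept, ignore_index=True))


def _spectrum0(x: np.ndarray) -> float:
    """Spectral density at frequency zero via Bartlett-windowed autocovariance
    (bandwidth ~ sqrt(n)); returns the large-sample variance of the mean * n."""
    n = x.size
    x = x - x.mean()
    bw = max(1, int(math.sqrt(n)))
    acov = np.correlate(x, x, mode="full")[n - 1: n - 1 + bw + 1] / n
    weights = 1.0 - np.arange(1, bw + 1) / (bw + 1)
    return float(acov[0] + 2.0 * np.sum(weights * acov[1:]))


def geweke_z(samples, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score for one scalar chain.

    Compares the mean of the first ``first`` fraction against the last
    ``last`` fraction, with spectral-density (frequency-zero) variance
    estimates.  Raises for constant windows, where the score is undefined.
    """
    x = np.asarray(samples, dtype=float).ravel()
    n = x.size
    na, nb = int(first * n), int(last * n)
    if na < 10 or nb < 10:
        raise ValueError("need >= 10 samples in each window")
    a, b = x[:na], x[n - nb:]
    va, vb = _spectrum0(a), _spectrum0(b)
    if va <= 0 and vb <= 0:
        raise ValueError("zero variance in both windows: z undefined")
    return float((a.mean() - b.mean()) / math.sqrt(va / na + vb / nb))


def geweke_table(trace: TraceSet, first: float = 0.1,
                 last: float = 0.5) -> pd.DataFrame:
    """Geweke z per chain and parameter (NaN where undefined)."""
    rows = []
    for c in trace.chains:
        block = trace.chain(c)
        row: dict[str, float] = {"chain": c}
        for p in trace.param_names:
            try:
                row[p] = geweke_z(block[p].to_numpy(), first, last)
            except ValueError:
                row[p] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def drop_stuck_chains(trace: TraceSet, burnin: float = 0.1,
                      tol: float = 20.0) -> tuple[TraceSet, list[int]]:
    """Convergence control across independent chains via the likelihood trace.

    Latent-genealogy samplers of this kind have long-lived metastable states
    (e.g. the instantaneous-change corner of the prior box) whose
    log-likelihood sits far below the plateau that converged chains share.
    Chains whose post-burn-in mean log-likelihood trails the best chain by
    more than ``tol`` have demonstrably not reached that plateau and are
    excluded before pooling — the automated counterpart of inspecting
    independent runs and pooling only those that agree.  Returns the filtered
    trace and the list of dropped chain ids; at least one chain (the best)
    is always kept.
    """
    if "loglik" not in trace.df.columns:
        raise ValueError("trace has no likelihood column")
    means = {}
    for c in trace.chains:
        block = trace.chain(c)
        drop = math.ceil(burnin * len(block))
        means[c] = float(block["loglik"].iloc[drop:].mean())
    best = max(means.values())
    stuck = [c for c, m in means.items() if m < best - tol]
    if not stuck:
        return trace, []
    kept_df = trace.df[~trace.df["chain"].isin(stuck)].reset_index(drop=True)
    return replace(trace, df=kept_df), stuck


def pool_runs(traces: list[TraceSet]) -> TraceSet:
    """Concatenate independent runs (burn-in already removed) into one trace,
    relabelling chains to stay unique and recording provenance."""
    if not traces:
        raise ValueError("no traces to pool")
    names = traces[0].param_names
    for t in traces[1:]:
        if t.param_names != names:
            raise ValueError("traces have different parameterizations")
    frames = []
    provenance = []
    acc: dict[int, dict[str, float]] = {}
    next_chain = 0
    for run_idx, t in enumerate(traces):
        for c in t.chains:
            block = t.chain(c).copy()
            block["chain"] = next_chain
            frames.append(block)
            provenance.append({"chain": next_chain, "run": run_idx,
                               "run_seed": t.seed, "orig_chain": c})
            if c in t.acceptance:
                acc[next_chain] = t.acceptance[c]
            next_chain += 1
    return TraceSet(pd.concat(frames, ignore_index=True), list(names),
                    traces[0].seed, acc,
                    meta={"pooled_from": provenance})


def interval_summary(samples, mass: float) -> dict[str, tuple[float, float]]:
    """Central quantile interval and highest-posterior-density interval.

    The HPD is the shortest window of the sorted samples containing
    ``ceil(mass * n)`` of them — never wider than the central interval.
    """
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 2:
        raise ValueError("need >= 2 samples")
    alpha = (1.0 - mass) / 2.0
    central = (float(np.quantile(x, alpha)), float(np.quantile(x, 1.0 - alpha)))
    m = max(2, math.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return {"central": central, "hpd": (float(x[i]), float(x[i + m - 1]))}


def generations_to_years(T_samples, g: float):
    """Convert onset-time samples from generations to years (elementwise)."""
    if g <= 0:
        raise ValueError("generation time must be > 0")
    return np.asarray(T_samples, dtype=float) * g


def t_prior_years(priors: HierarchicalPriors, g: float):
    """The analytic prior of T in years implied by the lognormal prior on T in
    generations: a scipy lognormal frozen distribution."""
    if g <= 0:
        raise ValueError("generation time must be > 0")
    sigma = priors.sd_log10_T * math.log(10.0)
    scale = g * 10.0 ** priors.mean_log10_T
    return stats.lognorm(s=sigma, scale=scale)


# ---------------------------------------------------------------------------
# Bayes-factor epoch dating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpochHypothesis:
    """A half-open candidate interval (lo, hi] for the decline onset, in years
    before present."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi):
            raise ValueError("need 0 <= lo < hi")

    def contains(self, x: np.ndarray) -> np.ndarray:
        return (x > self.lo) & (x <= self.hi)


CANONICAL_EPOCHS: tuple[EpochHypothesis, ...] = (
    EpochHypothesis("H1", 0.0, 200.0),        # commercial forest exploitation
    EpochHypothesis("H2", 200.0, 5_000.0),    # first farmers
    EpochHypothesis("H3", 5_000.0, 40_000.0),  # hunter-gatherers
    EpochHypothesis("H4", 40_000.0, 100_000.0),  # Pleistocene climate
)

H2_SPLIT: tuple[EpochHypothesis, ...] = (
    EpochHypothesis("H2.1", 200.0, 2_000.0),
    EpochHypothesis("H2.2", 2_000.0, 5_000.0),
)


def support_label(bf: float) -> str:
    """Conventional evidence labels: strong (>= 10), substantial [3, 10),
    none (< 3)."""
    if bf >= 10.0:
        return "strong"
    if bf >= 3.0:
        return "substantial"
    return "none"


@dataclass
class BFResult:
    hypothesis: EpochHypothesis
    bf: float
    posterior_mass_in: float
    posterior_mass_out: float
    prior_mass_in: float
    prior_mass_out: float
    support: str = field(init=False)
    bounded_below: bool = False  # empty-bin guard bound: true BF may be larger
    flagged: bool = False  # e.g. no prior mass: BF not computable

    def __post_init__(self) -> None:
        self.support = support_label(self.bf) if np.isfinite(self.bf) else "none"


def _prior_masses(prior, lo: float, hi: float) -> tuple[float, float]:
    if hasattr(prior, "cdf"):
        p_in = float(prior.cdf(hi) - prior.cdf(lo))
        p_out = 1.0 - p_in
    else:
        x = np.asarray(prior, dtype=float)
        p_in = float(np.mean((x > lo) & (x <= hi)))
        p_out = 1.0 - p_in
    return p_in, p_out


def bayes_factor_interval(posterior_samples, prior,
                          interval: tuple[float, float] | EpochHypothesis
                          ) -> BFResult:
    """Approximate Bayes factor for "the onset lies in the interval".

    BF = [post(in)/post(out)] / [prior(in)/prior(out)].  Posterior masses are
    sample proportions floored at 1/(M+1) so a finite sample never yields an
    infinite BF; when the floor binds the result is a lower/upper bound and is
    marked ``bounded_below``.  ``prior`` is either a frozen scipy distribution
    (analytic masses) or an array of prior samples.
    """
    hyp = (interval if isinstance(interval, EpochHypothesis)
           else EpochHypothesis("custom", float(interval[0]), float(interval[1])))
    x = np.asarray(posterior_samples, dtype=float).ravel()
    M = x.size
    if M < 1:
        raise ValueError("no posterior samples")
    pr_in, pr_out = _prior_masses(prior, hyp.lo, hyp.hi)
    if pr_in <= 0.0 or pr_out <= 0.0:
        raise ValueError(
            f"prior mass vanishes inside or outside {hyp.name}: not testable")
    floor = 1.0 / (M + 1.0)
    raw_in = float(np.mean(hyp.contains(x)))
    bounded = raw_in <= floor or (1.0 - raw_in) <= floor
    po_in = min(max(raw_in, floor), 1.0 - floor)
    po_out = 1.0 - po_in
    bf = (po_in / po_out) / (pr_in / pr_out)
    return BFResult(hyp, float(bf), po_in, po_out, pr_in, pr_out,
                    bounded_below=bounded)


def epoch_bf_profile(posterior_samples, prior, window: float = 500.0,
                     horizon: float = 50_000.0) -> list[BFResult]:
    """BF for each successive window (0, w], (w, 2w], ... up to the horizon
    (100 windows at the defaults).  Windows the prior cannot reach are flagged
    rather than raising."""
    if window <= 0:
        raise ValueError("window must be > 0")
    n_win = round(horizon / window)
    if abs(n_win * window - horizon) > 1e-9 * horizon:
        raise ValueError("horizon must be a multiple of window")
    out = []
    for i in range(int(n_win)):
        hyp = EpochHypothesis(f"({i * window:g},{(i + 1) * window:g}]",
                              i * window, (i + 1) * window)
        try:
            out.append(bayes_factor_interval(posterior_samples, prior, hyp))
        except ValueError:
            res = BFResult(hyp, float("nan"), 0.0, 1.0, 0.0, 1.0)
            res.flagged = True
            out.append(res)
    return out


def epoch_hypothesis_test(posterior_samples, prior,
                          split_h2: bool = False) -> list[BFResult]:
    """Each canonical epoch against the other epochs pooled, ranked by BF.

    Masses are restricted to the canonical horizon (0, 100000]; with
    ``split_h2`` the farmer epoch is subdivided into (200, 2000] and
    (2000, 5000] and those sub-periods join the comparison set.
    """
    epochs = list(CANONICAL_EPOCHS)
    if split_h2:
        epochs = [CANONICAL_EPOCHS[0], *H2_SPLIT, *CANONICAL_EPOCHS[2:]]
    horizon_lo, horizon_hi = 0.0, 100_000.0
    x = np.asarray(posterior_samples, dtype=float).ravel()
    x = x[(x > horizon_lo) & (x <= horizon_hi)]
    if x.size == 0:
        raise ValueError("no posterior mass inside the canonical horizon")
    M = x.size
    floor = 1.0 / (M + 1.0)
    results = []
    for hyp in epochs:
        pr_in, _ = _prior_masses(prior, hyp.lo, hyp.hi)
        pr_tot, _ = _prior_masses(prior, horizon_lo, horizon_hi)
        pr_in_c = pr_in / pr_tot
        pr_out_c = 1.0 - pr_in_c
        if pr_in_c <= 0.0 or pr_out_c <= 0.0:
            raise ValueError(f"prior mass vanishes for {hyp.name}")
        raw_in = float(np.mean(hyp.contains(x)))
        bounded = raw_in <= floor or (1.0 - raw_in) <= floor
        po_in = min(max(raw_in, floor), 1.0 - floor)
        po_out = 1.0 - po_in
        bf = (po_in / po_out) / (pr_in_c / pr_out_c)
        results.append(BFResult(hyp, float(bf), po_in, po_out, pr_in_c,
                                pr_out_c, bounded_below=bounded))
    results.sort(key=lambda r: -r.bf)
    return results


def bf_table(results: list[BFResult]) -> pd.DataFrame:
    """Flatten BF results for reporting."""
    return pd.DataFrame(
        [{"hypothesis": r.hypothesis.name, "lo_years": r.hypothesis.lo,
          "hi_years": r.hypothesis.hi, "bf": r.bf, "support": r.support,
          "posterior_mass": r.posterior_mass_in, "prior_mass": r.prior_mass_in,
          "bounded_below": r.bounded_below, "flagged": r.flagged}
         for r in results])
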