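"""Bayesian MCMC engines for effective-population-size change from microsatellites.

Two Metropolis–Hastings samplers over model parameters and per-locus latent
genealogies:

* **simple engine** (:func:`run_mcmc_simple`) — estimates the magnitude of size
  change r = N0/N1, the scaled time tf = ta/N0 and the scaled mutation rate
  theta = 2*N0*mu under wide uniform priors on the log10 scale, with a linear
  or exponential size trajectory.  Genealogy times are kept in units of 2*N0
  generations, so the three ratios are the only identifiable quantities.
* **hierarchical engine** (:func:`run_mcmc_hierarchical`) — estimates N0, N1
  and the onset time T (generations) directly under lognormal priors, with an
  exponential trajectory, a lognormal prior on the mutation rate and per-locus
  lognormal rate deviations around the population mean (half-normal hyperprior
  on the among-locus scale).

The likelihood integrates internal allele states analytically: tip allele
sizes are placed on a bounded integer ladder (observed range padded by K
repeat units) and pruned with the stepwise-mutation transition kernel
P(net displacement d | expected mutations lam) = exp(-lam) * I_|d|(lam)
(modified Bessel form of a symmetric +-1 random walk with Poisson-many steps).
The root state carries unit weight on every ladder rung (summed out), so a
single tip — or two identical tips with a vanishing mutation rate — has
log-likelihood zero.

Moves: Gaussian random walks on log10 parameters (occasionally replaced by
independence draws from the prior, which keeps prior-predictive runs close to
iid), single node-time shifts, whole-tree time scalings with the Jacobian, and
symmetric subtree exchanges for topology.  Step scales adapt toward a 0.2-0.5
acceptance rate during burn-in only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import ive

from .genotypes import MISSING, GenotypeMatrix
from .simulate import DemographicModel, Genealogy, sample_genealogy

__all__ = [
    "SimplePriors",
    "HierarchicalPriors",
    "MCMCConfig",
    "TraceSet",
    "smm_branch_prob",
    "genealogy_loglik",
    "run_mcmc_simple",
    "run_mcmc_hierarchical",
    "tune_proposals",
]

LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Priors and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimplePriors:
    """Uniform log10 priors for the simple (ratio-parameterised) engine."""

    log10_r_bounds: tuple[float, float] = (-5.0, 5.0)
    log10_tf_bounds: tuple[float, float] = (-5.0, 5.0)
    log10_theta_bounds: tuple[float, float] = (-5.0, 5.0)
    trajectory: str = "exponential"  # or "linear"

    def __post_init__(self) -> None:
        for lo, hi in (self.log10_r_bounds, self.log10_tf_bounds,
                       self.log10_theta_bounds):
            if not lo < hi:
                raise ValueError("prior bounds need lower < upper")
        if self.trajectory not in ("linear", "exponential"):
            raise ValueError("trajectory must be 'linear' or 'exponential'")


@dataclass(frozen=True)
class HierarchicalPriors:
    """Lognormal priors (given as log10 location/scale) for the hierarchical
    engine: N0, N1, onset time T in generations, mutation rate mu, and a
    half-normal hyperprior on the among-locus spread of log10 mu."""

    mean_log10_N0: float = 4.0
    sd_log10_N0: float = 2.0
    mean_log10_N1: float = 4.0
    sd_log10_N1: float = 2.0
    mean_log10_T: float = 5.0
    sd_log10_T: float = 2.0
    mean_log10_mu: float = -3.5
    sd_log10_mu: float = 0.25
    locus_scale: float = 0.3  # half-normal scale of among-locus sd of log10 mu

    def __post_init__(self) -> None:
        for s in (self.sd_log10_N0, self.sd_log10_N1, self.sd_log10_T,
                  self.sd_log10_mu, self.locus_scale):
            if s <= 0:
                raise ValueError("prior scales must be > 0")


@dataclass(frozen=True)
class MCMCConfig:
    """Chain-length and proposal settings.

    Defaults are desk-scale (minutes on one core); ``n_iterations`` counts
    elementary proposals and ``floor(n_iterations / thinning)`` samples are
    retained per chain, burn-in included — discard it afterwards with
    :func:`popcollapse.posterior.discard_burnin`.
    """

    n_iterations: int = 2_000_000
    thinning: int = 200
    n_chains: int = 4
    burnin_fraction: float = 0.10
    seed: int = 0
    step_scales: dict[str, float] | None = None
    ladder_padding: int = 10

    def __post_init__(self) -> None:
        if not (self.n_iterations > self.thinning > 0):
            raise ValueError("need n_iterations > thinning > 0")
        if not (0.0 <= self.burnin_fraction < 1.0):
            raise ValueError("burnin_fraction must be in [0, 1)")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.ladder_padding < 1:
            raise ValueError("ladder_padding must be >= 1")


@dataclass
class TraceSet:
    """Retained MCMC samples with provenance.

    ``df`` has one row per retained sample with columns ``chain``,
    ``iteration`` and one column per parameter; ``acceptance`` maps chain ->
    move label -> acceptance rate.
    """

    df: pd.DataFrame
    param_names: list[str]
    seed: int
    acceptance: dict[int, dict[str, float]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def parameters(self) -> pd.DataFrame:
        return self.df[self.param_names]

    @property
    def chains(self) -> list[int]:
        return sorted(self.df["chain"].unique().tolist())

    def chain(self, c: int) -> pd.DataFrame:
        return self.df[self.df["chain"] == c].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SMM transition kernel and ladder-pruning likelihood
# ---------------------------------------------------------------------------

def smm_branch_prob(d, lam):
    """P(net displacement d) for a symmetric +-1 stepwise walk with
    Poisson(lam) steps: exp(-lam) * I_|d|(lam).  Vectorised in both args."""
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 0):
        raise ValueError("lam must be >= 0")
    out = ive(np.abs(d), lam_arr)
    return float(out) if np.isscalar(d) and np.isscalar(lam) else out


@njit(cache=True)
def _prune_ladder(postorder, children, tip_idx, kernel, S):  # pragma: no cover
    """Felsenstein pruning on the allele ladder.  ``kernel[i, d]`` is the SMM
    transition probability across the branch above node i at displacement d.
    Root states carry unit weight (summed, not averaged).  Returns
    (loglik, boundary_mass_fraction)."""
    total = children.shape[0]
    partial = np.zeros((total, S))
    logscale = 0.0
    for idx in range(postorder.shape[0]):
        v = postorder[idx]
        if children[v, 0] < 0:
            continue
        for s in range(S):
            partial[v, s] = 1.0
        for ci in range(2):
            c = children[v, ci]
            if children[c, 0] < 0:
                ts = tip_idx[c]
                for s in range(S):
                    dd = s - ts if s >= ts else ts - s
                    partial[v, s] *= kernel[c, dd]
            else:
                for s in range(S):
                    acc = 0.0
                    for s2 in range(S):
                        dd = s - s2 if s >= s2 else s2 - s
                        acc += kernel[c, dd] * partial[c, s2]
                    partial[v, s] *= acc
        m = 0.0
        for s in range(S):
            if partial[v, s] > m:
                m = partial[v, s]
        if m <= 0.0:
            return -np.inf, 0.0
        inv = 1.0 / m
        for s in range(S):
            partial[v, s] *= inv
        logscale += np.log(m)
    root = postorder[postorder.shape[0] - 1]
    tot = 0.0
    for s in range(S):
        tot += partial[root, s]
    if tot <= 0.0:
        return -np.inf, 0.0
    boundary = (partial[root, 0] + partial[root, S - 1]) / tot
    return np.log(tot) + logscale, boundary


@njit(cache=True)
def _kernel_rows_fast(lams, S):  # pragma: no cover
    """Scaled Bessel rows exp(-lam) * I_d(lam) for d = 0..S-1, one row per
    branch, via Miller's backward recurrence normalised with the identity
    exp(lam) = I_0(lam) + 2 * sum_{k>=1} I_k(lam)."""
    B = lams.shape[0]
    out = np.zeros((B, S))
    for b in range(B):
        lam = lams[b]
        if lam <= 0.0:
            out[b, 0] = 1.0
            continue
        if lam > 2e4:
            # uniform asymptotic regime: exp(-lam) I_d(lam) ~
            # exp(-d^2/(2 lam)) / sqrt(2 pi lam) with the 1/(8 lam) correction
            pref = (1.0 + 0.125 / lam) / np.sqrt(2.0 * np.pi * lam)
            for j in range(S):
                out[b, j] = pref * np.exp(-0.5 * j * j / lam)
            continue
        m = S + 18 + int(1.3 * lam + 3.0 * np.sqrt(lam))
        ikp1 = 0.0          # I_{k+1}, unnormalised
        ik = 1e-280         # I_k at k = m
        sum1 = ik           # sum_{k>=1} I_k (I_m term)
        for k in range(m, 0, -1):
            ikm1 = ikp1 + (2.0 * k / lam) * ik
            if k - 1 >= 1:
                sum1 += ikm1
            if k - 1 < S:
                out[b, k - 1] = ikm1
            ikp1 = ik
            ik = ikm1
            if ik > 1e250:
                ik *= 1e-250
                ikp1 *= 1e-250
                sum1 *= 1e-250
                for j in range(S):
                    out[b, j] *= 1e-250
        norm = ik + 2.0 * sum1  # ik now holds unnormalised I_0
        for j in range(S):
            out[b, j] /= norm
    return out


def _postorder_of(children: np.ndarray, root: int) -> np.ndarray:
    total = children.shape[0]
    order = np.empty(total, dtype=np.int64)
    stack = [root]
    pos = total - 1
    while stack:
        v = stack.pop()
        order[pos] = v
        pos -= 1
        if children[v, 0] >= 0:
            stack.append(children[v, 0])
            stack.append(children[v, 1])
    return order  # reverse-preorder == valid postorder (root last)


def _kernel_rows(lams: np.ndarray, S: int) -> np.ndarray:
    return _kernel_rows_fast(np.ascontiguousarray(lams, dtype=np.float64),
                             int(S))


def genealogy_loglik(gen: Genealogy, tip_alleles, mu: float,
                     ladder_padding: int = 10,
                     auto_widen: bool = True) -> float:
    """log P(tip allele sizes | genealogy, mu) by ladder pruning.

    The ladder spans the observed allele range padded by ``ladder_padding``
    repeat units on each side and, with ``auto_widen``, widens (and retries)
    while more than 1e-6 of the root mass sits on the boundary rungs.
    ``auto_widen=False`` pins the ladder, e.g. to compare against an
    exhaustive state summation on the same ladder.
    """
    tips = np.asarray(tip_alleles, dtype=np.int64)
    if tips.size != gen.n_tips:
        raise ValueError("tip_alleles length must equal the tip count")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if gen.n_tips == 1:
        return 0.0
    K = int(ladder_padding)
    total = 2 * gen.n_tips - 1
    post = _postorder_of(gen.children, gen.root)
    lams = mu * gen.branch_lengths()
    for _ in range(12):
        offset = int(tips.min()) - K
        S = int(tips.max()) - offset + K + 1
        tip_idx = np.full(total, -1, dtype=np.int64)
        tip_idx[: gen.n_tips] = tips - offset
        kernel = np.zeros((total, S))
        kernel[: total - 1] = _kernel_rows(lams, S)
        ll, boundary = _prune_ladder(post, gen.children, tip_idx, kernel, S)
        if not auto_widen or (np.isfinite(ll) and boundary <= 1e-6):
            return float(ll)
        if not np.isfinite(ll):
            return float(ll)
        K += 10
    raise RuntimeError("allele ladder failed to contain the root mass")


# ---------------------------------------------------------------------------
# Coalescent log-density of a genealogy under a size trajectory
# ---------------------------------------------------------------------------

def _lambda_vec(t: np.ndarray, kind: str, N0: float, N1: float,
                ta: float) -> np.ndarray:
    """Vectorised integrated intensity for constant/linear/exponential N(t)."""
    t = np.asarray(t, dtype=float)
    if kind == "constant" or abs(N1 - N0) < 1e-12 * max(N0, N1):
        return t / (2.0 * N0)
    head_t = np.minimum(t, ta)
    tail = np.maximum(t - ta, 0.0)
    if kind == "linear":
        head = (ta / (2.0 * (N1 - N0))) * np.log1p((N1 - N0) * head_t / (N0 * ta))
    else:  # exponential
        beta = math.log(N1 / N0) / ta
        head = -np.expm1(-beta * head_t) / (2.0 * N0 * beta)
    return head + tail / (2.0 * N1)


def _size_vec(t: np.ndarray, kind: str, N0: float, N1: float,
              ta: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if kind == "constant":
        return np.full_like(t, N0)
    if kind == "linear":
        return np.where(t < ta, N0 + (N1 - N0) * t / ta, N1)
    logN = np.where(t < ta, math.log(N0) + (math.log(N1 / N0) / ta) * t,
                    math.log(N1))
    return np.exp(logN)


_KIND_CODE = {"constant": 0, "linear": 1, "exponential": 2}


@njit(cache=True)
def _coal_logprior_core(ts, n_tips, kind, N0, N1, ta):  # pragma: no cover
    same = abs(N1 - N0) < 1e-12 * max(N0, N1)
    if kind == 2 and not same:
        beta = np.log(N1 / N0) / ta
        lam_a = -np.expm1(-beta * ta) / (2.0 * N0 * beta)
    elif kind == 1 and not same:
        beta = 0.0
        lam_a = 0.0  # unused sentinel for linear
    else:
        beta = 0.0
        lam_a = 0.0
    logp = 0.0
    prev = 0.0
    k = float(n_tips)
    for i in range(ts.shape[0]):
        t = ts[i]
        if kind == 0 or same:
            lam = t / (2.0 * N0)
            size = N0
        elif kind == 1:
            h = t if t < ta else ta
            lam = (ta / (2.0 * (N1 - N0))) * np.log1p((N1 - N0) * h / (N0 * ta))
            if t > ta:
                lam += (t - ta) / (2.0 * N1)
                size = N1
            else:
                size = N0 + (N1 - N0) * t / ta
        else:
            if t < ta:
                lam = -np.expm1(-beta * t) / (2.0 * N0 * beta)
                size = N0 * np.exp(beta * t)
            else:
                lam = lam_a + (t - ta) / (2.0 * N1)
                size = N1
        pairs = k * (k - 1.0) / 2.0
        logp += -pairs * (lam - prev) - np.log(2.0 * size)
        prev = lam
        k -= 1.0
    return logp


def coalescent_logprior(internal_times: np.ndarray, n_tips: int, kind: str,
                        N0: float, N1: float, ta: float) -> float:
    """Log-density of the coalescence times of a labelled genealogy under a
    single-population trajectory (combinatorial constants dropped)."""
    ts = np.sort(np.asarray(internal_times, dtype=float))
    return float(_coal_logprior_core(ts, n_tips, _KIND_CODE[kind],
                                     float(N0), float(N1), float(ta)))


# ---------------------------------------------------------------------------
# Proposal tuning
# ---------------------------------------------------------------------------

def tune_proposals(step_scales: dict[str, float],
                   acceptance: dict[str, float],
                   in_burnin: bool,
                   target: tuple[float, float] = (0.2, 0.5)) -> dict[str, float]:
    """Adapt random-walk step scales toward the target acceptance window.

    Scales shrink when acceptance is below ``target[0]`` and grow when above
    ``target[1]``.  After burn-in the scales are returned unchanged, keeping
    the kernel fixed (detailed balance)."""
    if not in_burnin:
        return dict(step_scales)
    lo, hi = target
    out = dict(step_scales)
    for name, acc in acceptance.items():
        if name not in out:
            continue
        if acc < lo:
            out[name] = out[name] * 0.7
        elif acc > hi:
            out[name] = out[name] * 1.5
    return out


# ---------------------------------------------------------------------------
# Per-locus latent-genealogy state
# ---------------------------------------------------------------------------

class _LocusState:
    """Mutable genealogy + cached ladder likelihood for one locus."""

    def __init__(self, alleles: np.ndarray, K: int):
        self.alleles = np.asarray(alleles, dtype=np.int64)  # one per gene copy
        self.n_tips = self.alleles.size
        self.K = K
        self.parent: np.ndarray | None = None
        self.children: np.ndarray | None = None
        self.time: np.ndarray | None = None
        self.post: np.ndarray | None = None
        self.kernel: np.ndarray | None = None
        self.S = 0
        self.tip_idx: np.ndarray | None = None
        self.loglik = -np.inf
        self.logprior = -np.inf
        self.rate = np.nan  # mutations per unit branch length

    def set_ladder(self) -> None:
        offset = int(self.alleles.min()) - self.K
        self.S = int(self.alleles.max()) - offset + self.K + 1
        total = 2 * self.n_tips - 1
        self.tip_idx = np.full(total, -1, dtype=np.int64)
        self.tip_idx[: self.n_tips] = self.alleles - offset

    def adopt_genealogy(self, gen: Genealogy) -> None:
        self.parent = gen.parent.copy()
        self.children = gen.children.copy()
        self.time = gen.time.copy()
        self.post = _postorder_of(self.children, 2 * self.n_tips - 2)

    @property
    def root(self) -> int:
        return int(self.post[-1])

    def branch_lams(self, time: np.ndarray | None = None) -> np.ndarray:
        t = self.time if time is None else time
        total = 2 * self.n_tips - 1
        return self.rate * (t[self.parent[: total - 1]] - t[: total - 1])

    def full_likelihood(self, rate: float) -> tuple[float, np.ndarray, float]:
        """Likelihood with all kernel rows rebuilt at ``rate``."""
        total = 2 * self.n_tips - 1
        old_rate = self.rate
        self.rate = rate
        lams = self.branch_lams()
        self.rate = old_rate
        kernel = np.zeros((total, self.S))
        kernel[: total - 1] = _kernel_rows(lams, self.S)
        ll, boundary = _prune_ladder(self.post, self.children, self.tip_idx,
                                     kernel, self.S)
        return ll, kernel, boundary

    def internal_times(self) -> np.ndarray:
        return self.time[self.n_tips:]


def _alleles_by_locus(data: GenotypeMatrix) -> list[np.ndarray]:
    out = []
    for j in range(data.n_loci):
        calls = data.calls[:, j, :]
        ok = calls[:, 0] != MISSING
        out.append(calls[ok].ravel().astype(np.int64))
    return [a for a in out if a.size >= 2]


def _moment_theta(alleles_by_locus: list[np.ndarray]) -> float:
    """Method-of-moments start for theta from SMM equilibrium homozygosity
    F = 1/sqrt(1+2*theta): theta_hat = ((1/F)^2 - 1)/2."""
    homo = []
    for a in alleles_by_locus:
        vals, counts = np.unique(a, return_counts=True)
        p = counts / a.size
        homo.append(float(np.sum(p * p)))
    F = float(np.clip(np.mean(homo), 1e-3, 0.999))
    return max(((1.0 / F) ** 2 - 1.0) / 2.0, 1e-3)


# ---------------------------------------------------------------------------
# Shared genealogy-move machinery
# ---------------------------------------------------------------------------

def _init_locus_states(
    alleles_by_locus: list[np.ndarray],
    K: int,
    init_model: DemographicModel,
    rates: list[float],
    rng: np.random.Generator,
    traj: tuple[str, float, float, float],
) -> list[_LocusState]:
    """Build per-locus states with genealogies drawn from the coalescent at
    the initial parameters, and ladders widened until the likelihood is
    finite with negligible boundary mass."""
    states = []
    kind, N0, N1, ta = traj
    for alleles, rate in zip(alleles_by_locus, rates):
        st = _LocusState(alleles, K)
        ok = False
        for attempt in range(24):
            st.set_ladder()
            gen = sample_genealogy(init_model, alleles.size, rng)
            if attempt < 12:
                # keep the coalescent-prior tree shape but hand similar
                # alleles to tree-adjacent tips: topology is the slowest
                # mixing component, so starting with identical alleles in
                # shared subtrees removes most of the burn-in cost
                order = [v for v in _postorder_of(gen.children, gen.root)
                         if gen.children[v, 0] < 0]
                ranked = np.sort(alleles)
                permuted = np.empty_like(ranked)
                permuted[np.asarray(order)] = ranked
                st.alleles = permuted
                st.set_ladder()
            st.adopt_genealogy(gen)
            ll, kernel, boundary = st.full_likelihood(rate)
            if np.isfinite(ll) and boundary <= 1e-6:
                st.rate = rate
                st.kernel = kernel
                st.loglik = ll
                st.logprior = coalescent_logprior(
                    st.internal_times(), st.n_tips, kind, N0, N1, ta)
                ok = True
                break
            if np.isfinite(ll):
                st.K += 10  # boundary mass too high: widen the ladder
        if not ok:
            raise RuntimeError(
                "could not initialise a finite-likelihood genealogy; "
                f"last loglik={ll}, boundary={boundary}, ladder S={st.S}"
            )
        states.append(st)
    return states


def _is_ancestor(parent: np.ndarray, a: int, b: int) -> bool:
    """True if a is an ancestor of b."""
    v = parent[b]
    while v != -1:
        if v == a:
            return True
        v = parent[v]
    return False


class _GenealogyMoves:
    """Applies node-time, tree-scale and subtree-exchange moves to a locus,
    with Metropolis acceptance against likelihood x coalescent prior."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng

    def node_time(self, st: _LocusState, traj, root_step: float) -> bool:
        rng = self.rng
        n = st.n_tips
        v = int(n + rng.integers(n - 1))
        c1, c2 = st.children[v]
        lo = max(st.time[c1], st.time[c2])
        log_hastings = 0.0
        if st.parent[v] == -1:  # root: multiplicative walk above lo
            u = rng.normal(0.0, root_step)
            t_new = lo + (st.time[v] - lo) * math.exp(u)
            log_hastings = u
        else:
            hi = st.time[st.parent[v]]
            t_new = rng.uniform(lo, hi)
        time2 = st.time.copy()
        time2[v] = t_new
        affected = [c1, c2] + ([v] if st.parent[v] != -1 else [])
        lams = st.rate * np.array(
            [time2[st.parent[i]] - time2[i] for i in affected])
        kernel2 = st.kernel.copy()
        kernel2[affected] = _kernel_rows(lams, st.S)
        ll, _ = _prune_ladder(st.post, st.children, st.tip_idx, kernel2, st.S)
        lp = coalescent_logprior(time2[n:], n, *traj)
        if math.log(rng.random()) < (ll - st.loglik) + (lp - st.logprior) + log_hastings:
            st.time = time2
            st.kernel = kernel2
            st.loglik = ll
            st.logprior = lp
            return True
        return False

    def tree_scale(self, st: _LocusState, traj, scale_step: float) -> bool:
        rng = self.rng
        n = st.n_tips
        u = rng.normal(0.0, scale_step)
        c = math.exp(u)
        time2 = st.time * c  # tips at 0 stay put
        old_rate = st.rate
        lams = st.branch_lams(time2)
        total = 2 * n - 1
        kernel2 = np.zeros((total, st.S))
        kernel2[: total - 1] = _kernel_rows(lams, st.S)
        ll, _ = _prune_ladder(st.post, st.children, st.tip_idx, kernel2, st.S)
        lp = coalescent_logprior(time2[n:], n, *traj)
        log_jac = (n - 1) * u
        if math.log(rng.random()) < (ll - st.loglik) + (lp - st.logprior) + log_jac:
            st.time = time2
            st.kernel = kernel2
            st.loglik = ll
            st.logprior = lp
            return True
        return False

    def recent_scale(self, st: _LocusState, traj, scale_step: float) -> bool:
        """Scale only the coalescence times younger than the change onset.

        A bottleneck squeezes exactly this part of the genealogy, so giving
        the sampler a collective move for it avoids creeping there one node
        at a time.  Proposals that break the time ordering are rejected."""
        rng = self.rng
        n = st.n_tips
        ta = traj[3]
        recent = np.flatnonzero(st.time[n:] < ta) + n
        if recent.size == 0 or recent.size == n - 1:
            return False  # nothing to squeeze, or plain tree_scale territory
        u = rng.normal(0.0, scale_step)
        c = math.exp(u)
        time2 = st.time.copy()
        time2[recent] *= c
        for i in range(2 * n - 2):
            if time2[st.parent[i]] <= time2[i]:
                return False
        total = 2 * n - 1
        lams = st.rate * (time2[st.parent[: total - 1]] - time2[: total - 1])
        kernel2 = np.zeros((total, st.S))
        kernel2[: total - 1] = _kernel_rows(lams, st.S)
        ll, _ = _prune_ladder(st.post, st.children, st.tip_idx, kernel2, st.S)
        lp = coalescent_logprior(time2[n:], n, *traj)
        log_jac = recent.size * u
        if math.log(rng.random()) < (ll - st.loglik) + (lp - st.logprior) + log_jac:
            st.time = time2
            st.kernel = kernel2
            st.loglik = ll
            st.logprior = lp
            return True
        return False

    def subtree_swap(self, st: _LocusState, traj) -> bool:
        rng = self.rng
        total = 2 * st.n_tips - 1
        a, b = rng.choice(total - 1, size=2, replace=False)  # root excluded
        a, b = int(a), int(b)
        pa, pb = int(st.parent[a]), int(st.parent[b])
        if pa == pb:
            return False
        if st.time[pa] <= st.time[b] or st.time[pb] <= st.time[a]:
            return False
        if _is_ancestor(st.parent, a, b) or _is_ancestor(st.parent, b, a):
            return False
        children2 = st.children.copy()
        parent2 = st.parent.copy()
        children2[pa, 0 if children2[pa, 0] == a else 1] = b
        children2[pb, 0 if children2[pb, 0] == b else 1] = a
        parent2[a], parent2[b] = pb, pa
        post2 = _postorder_of(children2, total - 1)
        lams = st.rate * np.array(
            [st.time[parent2[i]] - st.time[i] for i in (a, b)])
        kernel2 = st.kernel.copy()
        kernel2[[a, b]] = _kernel_rows(lams, st.S)
        ll, _ = _prune_ladder(post2, children2, st.tip_idx, kernel2, st.S)
        # times unchanged: the coalescent prior is untouched
        if math.log(rng.random()) < ll - st.loglik:
            st.children = children2
            st.parent = parent2
            st.post = post2
            st.kernel = kernel2
            st.loglik = ll
            return True
        return False


def _norm_logpdf(x: float, m: float, s: float) -> float:
    return -0.5 * ((x - m) / s) ** 2 - math.log(s) - 0.5 * LOG2PI


def _halfnorm_logpdf(x: float, s: float) -> float:
    if x <= 0:
        return -np.inf
    return math.log(2.0) - 0.5 * (x / s) ** 2 - math.log(s) - 0.5 * LOG2PI


class _Accounting:
    def __init__(self):
        self.prop: dict[str, int] = {}
        self.acc: dict[str, int] = {}
        self.win_prop: dict[str, int] = {}
        self.win_acc: dict[str, int] = {}

    def record(self, label: str, accepted: bool) -> None:
        self.prop[label] = self.prop.get(label, 0) + 1
        self.win_prop[label] = self.win_prop.get(label, 0) + 1
        if accepted:
            self.acc[label] = self.acc.get(label, 0) + 1
            self.win_acc[label] = self.win_acc.get(label, 0) + 1

    def window_rates(self) -> dict[str, float]:
        return {k: self.win_acc.get(k, 0) / v
                for k, v in self.win_prop.items() if v >= 20}

    def reset_window(self) -> None:
        self.win_prop.clear()
        self.win_acc.clear()

    def rates(self) -> dict[str, float]:
        return {k: self.acc.get(k, 0) / v for k, v in self.prop.items()}


# ---------------------------------------------------------------------------
# Simple engine (ratio parameterisation)
# ---------------------------------------------------------------------------

_SIMPLE_PARAMS = ["log10_r", "log10_tf", "log10_theta"]


def _simple_traj(lr: float, ltf: float, kind: str):
    """Scaled trajectory: time unit 2*N0 generations, so the 'population size'
    is nu/2 with nu(0)=1 and nu(inf)=1/r; change completes at tf/2."""
    r = 10.0 ** lr
    tf = 10.0 ** ltf
    return (kind, 0.5, 1.0 / (2.0 * r), tf / 2.0)


def _run_simple_chain(alleles_by_locus, priors: SimplePriors, cfg: MCMCConfig,
                      chain_id: int, seed_seq: np.random.SeedSequence,
                      likelihood: bool) -> tuple[pd.DataFrame, dict[str, float]]:
    rng = np.random.default_rng(seed_seq)
    bounds = {
        "log10_r": priors.log10_r_bounds,
        "log10_tf": priors.log10_tf_bounds,
        "log10_theta": priors.log10_theta_bounds,
    }
    steps = {"log10_r": 0.4, "log10_tf": 0.4, "log10_theta": 0.25,
             "theta_times": 0.4, "tf_times": 0.5, "r_ridge": 0.6,
             "root_time": 0.5, "tree_scale": 0.3, "recent_scale": 0.5}
    if cfg.step_scales:
        steps.update(cfg.step_scales)
    # start at a positive log10 r (expansion side) with a *large* tf: with the
    # change pushed far into the past the genealogy prior exerts no pressure
    # to bunch coalescences at the change epoch, which keeps early burn-in
    # away from the degenerate instantaneous-change corner of the prior box
    x = {
        "log10_r": min(1.0, bounds["log10_r"][1] - 1e-6),
        "log10_tf": float(np.clip(2.0, *bounds["log10_tf"])),
        "log10_theta": 0.0,
    }
    kind = priors.trajectory
    states: list[_LocusState] = []
    if likelihood:
        theta0 = float(np.clip(math.log10(_moment_theta(alleles_by_locus)),
                               *bounds["log10_theta"]))
        x["log10_theta"] = theta0
        traj = _simple_traj(x["log10_r"], x["log10_tf"], kind)
        init_model = DemographicModel("constant", N0=0.5)
        rate = 10.0 ** x["log10_theta"]
        states = _init_locus_states(alleles_by_locus, cfg.ladder_padding,
                                    init_model, [rate] * len(alleles_by_locus),
                                    rng, traj)
    else:
        for p in x:
            x[p] = rng.uniform(*bounds[p])
        traj = _simple_traj(x["log10_r"], x["log10_tf"], kind)

    moves = _GenealogyMoves(rng)
    acct = _Accounting()
    burnin_iters = int(cfg.burnin_fraction * cfg.n_iterations)
    n_retain = cfg.n_iterations // cfg.thinning
    rows = np.empty((n_retain, 4))
    kept = 0

    def total_logprior() -> float:
        return sum(s.logprior for s in states)

    for it in range(1, cfg.n_iterations + 1):
        if likelihood and rng.random() < 0.75:
            li = int(rng.integers(len(states)))
            st = states[li]
            mt = rng.random()
            if mt < 0.55:
                ok = moves.node_time(st, traj, steps["root_time"])
                acct.record("node_time", ok)
            elif mt < 0.7:
                ok = moves.tree_scale(st, traj, steps["tree_scale"])
                acct.record("tree_scale", ok)
            elif mt < 0.85:
                ok = moves.recent_scale(st, traj, steps["recent_scale"])
                acct.record("recent_scale", ok)
            else:
                ok = moves.subtree_swap(st, traj)
                acct.record("subtree_swap", ok)
        elif likelihood and rng.random() < 0.35:
            # coupled likelihood-invariant moves: rescale genealogy times and
            # counter-rescale theta so branch mutation intensities stay fixed
            # (kernels untouched).  Two flavours: theta alone, or tf together
            # with the times so the change epoch rides along with tree depth.
            u_c = rng.random()
            label = ("tf_times" if u_c < 0.4 else
                     "theta_times" if u_c < 0.7 else "r_ridge")
            delta = rng.normal(0.0, steps[label])
            cand = dict(x)
            if label == "r_ridge":
                # slide along the degenerate star ridge (r up, tf down, theta
                # up, times down keeps both the likelihood and the relative
                # position of coalescences w.r.t. the change epoch), which
                # connects the instantaneous-change corner to the main basin
                cand["log10_r"] = x["log10_r"] + delta
                cand["log10_tf"] = x["log10_tf"] - delta
                cand["log10_theta"] = x["log10_theta"] + delta
                delta = -delta  # times scale opposite to theta below
            else:
                cand["log10_theta"] = x["log10_theta"] - delta
                if label == "tf_times":
                    cand["log10_tf"] = x["log10_tf"] + delta
            xth = cand["log10_theta"]
            ok_bounds = all(bounds[p][0] <= cand[p] <= bounds[p][1]
                            for p in _SIMPLE_PARAMS)
            if not ok_bounds:
                acct.record(label, False)
            else:
                c = 10.0 ** delta
                traj2 = _simple_traj(cand["log10_r"], cand["log10_tf"], kind)
                new_lp = [coalescent_logprior(st.internal_times() * c,
                                              st.n_tips, *traj2)
                          for st in states]
                log_jac = math.log(c) * sum(st.n_tips - 1 for st in states)
                delta_post = sum(new_lp) - total_logprior() + log_jac
                if math.log(rng.random()) < delta_post:
                    for st, lp in zip(states, new_lp):
                        st.time = st.time * c
                        st.logprior = lp
                        st.rate = 10.0 ** xth
                    x = cand
                    traj = traj2
                    acct.record(label, True)
                else:
                    acct.record(label, False)
        elif likelihood and rng.random() < 0.2:
            # joint independence refresh of (r, tf) from the flat prior: only
            # the genealogy priors weigh in, so when the data cannot pin the
            # trajectory down the pair hops freely across its prior instead
            # of random-walking through the weakly identified region
            lr2 = rng.uniform(*bounds["log10_r"])
            ltf2 = rng.uniform(*bounds["log10_tf"])
            traj2 = _simple_traj(lr2, ltf2, kind)
            new_lp = [coalescent_logprior(st.internal_times(), st.n_tips,
                                          *traj2) for st in states]
            if math.log(rng.random()) < sum(new_lp) - total_logprior():
                for st, lp in zip(states, new_lp):
                    st.logprior = lp
                x["log10_r"], x["log10_tf"] = lr2, ltf2
                traj = traj2
                acct.record("rtf_prior", True)
            else:
                acct.record("rtf_prior", False)
        else:
            # theta random walks force a full kernel rebuild on every locus,
            # and the coupled theta/times move already covers that direction,
            # so they get a small share of the parameter updates
            u_p = rng.random()
            if likelihood:
                p = ("log10_theta" if u_p < 0.1
                     else "log10_r" if u_p < 0.55 else "log10_tf")
            else:
                p = _SIMPLE_PARAMS[int(u_p * 3)]
            independent = rng.random() < 0.3
            if independent:
                xp = rng.uniform(*bounds[p])
            else:
                xp = x[p] + rng.normal(0.0, steps[p])
            label = p + ("_prior" if independent else "")
            if not (bounds[p][0] <= xp <= bounds[p][1]):
                acct.record(label, False)
            elif not likelihood:
                x[p] = xp  # flat prior: always accept inside bounds
                acct.record(label, True)
            elif p == "log10_theta":
                rate = 10.0 ** xp
                delta = 0.0
                pend = []
                for st in states:
                    ll, kernel, _ = st.full_likelihood(rate)
                    delta += ll - st.loglik
                    pend.append((ll, kernel))
                if math.log(rng.random()) < delta:
                    for st, (ll, kernel) in zip(states, pend):
                        st.loglik = ll
                        st.kernel = kernel
                        st.rate = rate
                    x[p] = xp
                    acct.record(label, True)
                else:
                    acct.record(label, False)
            else:
                cand = dict(x)
                cand[p] = xp
                traj2 = _simple_traj(cand["log10_r"], cand["log10_tf"], kind)
                new_lp = [coalescent_logprior(st.internal_times(), st.n_tips,
                                              *traj2) for st in states]
                delta = sum(new_lp) - total_logprior()
                if math.log(rng.random()) < delta:
                    for st, lp in zip(states, new_lp):
                        st.logprior = lp
                    x[p] = xp
                    traj = traj2
                    acct.record(label, True)
                else:
                    acct.record(label, False)
        if it <= burnin_iters and it % 2000 == 0:
            steps = tune_proposals(steps, acct.window_rates(), True)
            acct.reset_window()
        if it % cfg.thinning == 0:
            rows[kept] = (x["log10_r"], x["log10_tf"], x["log10_theta"],
                          sum(s.loglik for s in states))
            kept += 1
    df = pd.DataFrame(rows[:kept], columns=_SIMPLE_PARAMS + ["loglik"])
    df.insert(0, "iteration", np.arange(1, kept + 1) * cfg.thinning)
    df.insert(0, "chain", chain_id)
    return df, acct.rates()


def run_mcmc_simple(data: GenotypeMatrix | None, priors: SimplePriors,
                    cfg: MCMCConfig, likelihood: bool = True) -> TraceSet:
    """Sample (log10 r, log10 tf, log10 theta) and per-locus genealogies.

    ``data`` should hold a single (possibly pooled) site; all individuals are
    used regardless of label.  With ``likelihood=False`` the sampler targets
    the prior alone (no latent genealogies), which is the prior-recovery
    diagnostic mode; ``data`` may then be None.
    """
    if likelihood:
        if data is None:
            raise ValueError("data required when the likelihood is on")
        alleles = _alleles_by_locus(data)
        if not alleles:
            raise ValueError("no locus with >= 2 gene copies")
        if all(np.unique(a).size < 2 for a in alleles):
            raise ValueError("all loci monomorphic: nothing to infer")
    else:
        alleles = []
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_chains)
    frames = []
    acc: dict[int, dict[str, float]] = {}
    for c, child in enumerate(children):
        df, rates = _run_simple_chain(alleles, priors, cfg, c, child, likelihood)
        frames.append(df)
        acc[c] = rates
    return TraceSet(pd.concat(frames, ignore_index=True), _SIMPLE_PARAMS,
                    cfg.seed, acc,
                    meta={"engine": "simple", "trajectory": priors.trajectory,
                          "likelihood": likelihood})


# ---------------------------------------------------------------------------
# Hierarchical engine (N0, N1, T, mu)
# ---------------------------------------------------------------------------

def _hier_params(n_loci: int) -> list[str]:
    base = ["log10_N0", "log10_N1", "log10_T", "log10_mu", "sigma_mu"]
    return base + [f"dev_{j}" for j in range(n_loci)]


def _run_hier_chain(alleles_by_locus, priors: HierarchicalPriors,
                    cfg: MCMCConfig, chain_id: int,
                    seed_seq: np.random.SeedSequence,
                    likelihood: bool) -> tuple[pd.DataFrame, dict[str, float]]:
    rng = np.random.default_rng(seed_seq)
    L = len(alleles_by_locus)
    pr = priors
    steps = {"log10_N0": 0.4, "log10_N1": 0.4, "log10_T": 0.4,
             "log10_mu": 0.1, "sigma_mu": 0.4, "dev": 0.1, "ridge": 0.3,
             "tscale": 0.4,
             "root_time": 0.5, "tree_scale": 0.3, "recent_scale": 0.5}
    if cfg.step_scales:
        steps.update(cfg.step_scales)

    def draw_prior():
        return {
            "log10_N0": rng.normal(pr.mean_log10_N0, pr.sd_log10_N0),
            "log10_N1": rng.normal(pr.mean_log10_N1, pr.sd_log10_N1),
            "log10_T": rng.normal(pr.mean_log10_T, pr.sd_log10_T),
            "log10_mu": rng.normal(pr.mean_log10_mu, pr.sd_log10_mu),
            "sigma_mu": abs(rng.normal(0.0, pr.locus_scale)),
        }

    if likelihood:
        x = {"log10_N0": pr.mean_log10_N0, "log10_N1": pr.mean_log10_N1,
             "log10_T": pr.mean_log10_T, "log10_mu": pr.mean_log10_mu,
             "sigma_mu": pr.locus_scale / 2.0}
    else:
        x = draw_prior()
    lmu = np.full(L, x["log10_mu"]) + rng.normal(0.0, x["sigma_mu"], size=L)

    def hyper_logprior(xd, lmu_arr) -> float:
        lp = (_norm_logpdf(xd["log10_N0"], pr.mean_log10_N0, pr.sd_log10_N0)
              + _norm_logpdf(xd["log10_N1"], pr.mean_log10_N1, pr.sd_log10_N1)
              + _norm_logpdf(xd["log10_T"], pr.mean_log10_T, pr.sd_log10_T)
              + _norm_logpdf(xd["log10_mu"], pr.mean_log10_mu, pr.sd_log10_mu)
              + _halfnorm_logpdf(xd["sigma_mu"], pr.locus_scale))
        for v in lmu_arr:
            lp += _norm_logpdf(v, xd["log10_mu"], xd["sigma_mu"])
        return lp

    def traj_of(xd):
        return ("exponential", 10.0 ** xd["log10_N0"], 10.0 ** xd["log10_N1"],
                10.0 ** xd["log10_T"])

    states: list[_LocusState] = []
    traj = traj_of(x)
    if likelihood:
        init_model = DemographicModel("constant", N0=10.0 ** x["log10_N0"])
        states = _init_locus_states(alleles_by_locus, cfg.ladder_padding,
                                    init_model, list(10.0 ** lmu), rng, traj)

    moves = _GenealogyMoves(rng)
    acct = _Accounting()
    burnin_iters = int(cfg.burnin_fraction * cfg.n_iterations)
    n_retain = cfg.n_iterations // cfg.thinning
    names = _hier_params(L)
    rows = np.empty((n_retain, len(names) + 1))
    kept = 0
    hyper_lp = hyper_logprior(x, lmu)
    size_params = ("log10_N0", "log10_N1", "log10_T")

    for it in range(1, cfg.n_iterations + 1):
        if likelihood and rng.random() < 0.7:
            li = int(rng.integers(L))
            st = states[li]
            mt = rng.random()
            if mt < 0.55:
                ok = moves.node_time(st, traj, steps["root_time"])
                acct.record("node_time", ok)
            elif mt < 0.7:
                ok = moves.tree_scale(st, traj, steps["tree_scale"])
                acct.record("tree_scale", ok)
            elif mt < 0.85:
                ok = moves.recent_scale(st, traj, steps["recent_scale"])
                acct.record("recent_scale", ok)
            else:
                ok = moves.subtree_swap(st, traj)
                acct.record("subtree_swap", ok)
        elif likelihood and rng.random() < 0.15:
            # onset-time move: scale T and the genealogy times by a common
            # factor and the mutation rates by its inverse.  Branch mutation
            # intensities stay fixed (likelihood and kernels untouched) while
            # the change epoch rides along with tree depth, so T can traverse
            # its prior without fighting the likelihood.
            delta = rng.normal(0.0, steps["tscale"])
            cand = dict(x)
            cand["log10_T"] = x["log10_T"] + delta
            cand["log10_mu"] = x["log10_mu"] - delta
            lmu2 = lmu - delta
            c = 10.0 ** delta
            new_hyper = hyper_logprior(cand, lmu2)
            traj2 = traj_of(cand)
            new_lp = [coalescent_logprior(st.internal_times() * c,
                                          st.n_tips, *traj2) for st in states]
            log_jac = math.log(c) * sum(st.n_tips - 1 for st in states)
            delta_post = (new_hyper - hyper_lp + log_jac
                          + sum(new_lp) - sum(s.logprior for s in states))
            if math.log(rng.random()) < delta_post:
                x = cand
                lmu = lmu2
                hyper_lp = new_hyper
                traj = traj2
                for st, lp, v in zip(states, new_lp, lmu2):
                    st.time = st.time * c
                    st.logprior = lp
                    st.rate = 10.0 ** v
                acct.record("tscale", True)
            else:
                acct.record("tscale", False)
        elif likelihood and rng.random() < 0.2:
            # ridge move: scale N0, N1, T and the genealogy times by a common
            # factor and the mutation rates by its inverse.  Branch mutation
            # intensities are unchanged (likelihood and kernels untouched);
            # the coalescent-prior change cancels against the time Jacobian,
            # so only the lognormal priors weigh in - this lets the chain
            # slide quickly along the N*mu ridge the data cannot resolve,
            # with the mutation-rate prior anchoring the scale.
            delta = rng.normal(0.0, steps["ridge"])
            cand = dict(x)
            for p in size_params:
                cand[p] = x[p] + delta
            cand["log10_mu"] = x["log10_mu"] - delta
            lmu2 = lmu - delta
            c = 10.0 ** delta
            new_hyper = hyper_logprior(cand, lmu2)
            traj2 = traj_of(cand)
            new_lp = [coalescent_logprior(st.internal_times() * c,
                                          st.n_tips, *traj2) for st in states]
            log_jac = math.log(c) * sum(st.n_tips - 1 for st in states)
            delta_post = (new_hyper - hyper_lp + log_jac
                          + sum(new_lp) - sum(s.logprior for s in states))
            if math.log(rng.random()) < delta_post:
                x = cand
                lmu = lmu2
                hyper_lp = new_hyper
                traj = traj2
                for st, lp, v in zip(states, new_lp, lmu2):
                    st.time = st.time * c
                    st.logprior = lp
                    st.rate = 10.0 ** v
                acct.record("ridge", True)
            else:
                acct.record("ridge", False)
        else:
            which = rng.random()
            if which < 0.55:
                p = size_params[int(rng.integers(3))]
                independent = rng.random() < 0.3
                if independent:
                    means = {"log10_N0": (pr.mean_log10_N0, pr.sd_log10_N0),
                             "log10_N1": (pr.mean_log10_N1, pr.sd_log10_N1),
                             "log10_T": (pr.mean_log10_T, pr.sd_log10_T)}
                    xp = rng.normal(*means[p])
                    # independence proposal from the prior: prior terms cancel
                else:
                    xp = x[p] + rng.normal(0.0, steps[p])
                label = p + ("_prior" if independent else "")
                cand = dict(x)
                cand[p] = xp
                new_hyper = hyper_logprior(cand, lmu)
                delta = new_hyper - hyper_lp
                if independent:
                    # q ratio = prior(old)/prior(new); cancels that prior term
                    delta += (_norm_logpdf(x[p], *_prior_ms(pr, p))
                              - _norm_logpdf(xp, *_prior_ms(pr, p)))
                if likelihood:
                    traj2 = traj_of(cand)
                    new_lp = [coalescent_logprior(st.internal_times(),
                                                  st.n_tips, *traj2)
                              for st in states]
                    delta += sum(new_lp) - sum(s.logprior for s in states)
                if math.log(rng.random()) < delta:
                    x = cand
                    hyper_lp = new_hyper
                    if likelihood:
                        for st, lp in zip(states, new_lp):
                            st.logprior = lp
                        traj = traj2
                    acct.record(label, True)
                else:
                    acct.record(label, False)
            elif which < 0.75:
                if rng.random() < 0.4:
                    # block independence redraw of the whole rate hierarchy
                    # from its prior: the hyperprior terms cancel against the
                    # proposal density, leaving only the likelihood ratio
                    cand = dict(x)
                    cand["log10_mu"] = rng.normal(pr.mean_log10_mu, pr.sd_log10_mu)
                    cand["sigma_mu"] = abs(rng.normal(0.0, pr.locus_scale))
                    lmu2 = cand["log10_mu"] + rng.normal(
                        0.0, cand["sigma_mu"], size=L)
                    delta = 0.0
                    pend2 = []
                    if likelihood:
                        for j2, st2 in enumerate(states):
                            ll2, kern2, _ = st2.full_likelihood(10.0 ** lmu2[j2])
                            delta += ll2 - st2.loglik
                            pend2.append((ll2, kern2))
                    if math.log(rng.random()) < delta:
                        x = cand
                        lmu = lmu2
                        hyper_lp = hyper_logprior(x, lmu)
                        for st2, (ll2, kern2) in zip(states, pend2):
                            st2.loglik, st2.kernel = ll2, kern2
                        for j2, st2 in enumerate(states):
                            st2.rate = 10.0 ** lmu2[j2]
                        acct.record("rate_block_prior", True)
                    else:
                        acct.record("rate_block_prior", False)
                else:
                    p = "log10_mu" if rng.random() < 0.5 else "sigma_mu"
                    cand = dict(x)
                    if p == "sigma_mu":
                        u = rng.normal(0.0, steps["sigma_mu"])
                        cand[p] = x[p] * math.exp(u)
                        log_h = u  # multiplicative walk Jacobian
                    else:
                        cand[p] = x[p] + rng.normal(0.0, steps[p])
                        log_h = 0.0
                    new_hyper = hyper_logprior(cand, lmu)
                    if math.log(rng.random()) < new_hyper - hyper_lp + log_h:
                        x = cand
                        hyper_lp = new_hyper
                        acct.record(p, True)
                    else:
                        acct.record(p, False)
            else:
                j = int(rng.integers(L))
                v = lmu[j] + rng.normal(0.0, steps["dev"])
                delta = (_norm_logpdf(v, x["log10_mu"], x["sigma_mu"])
                         - _norm_logpdf(lmu[j], x["log10_mu"], x["sigma_mu"]))
                pend = None
                if likelihood:
                    st = states[j]
                    ll, kernel, _ = st.full_likelihood(10.0 ** v)
                    delta += ll - st.loglik
                    pend = (ll, kernel)
                if math.log(rng.random()) < delta:
                    old = lmu[j]
                    lmu[j] = v
                    hyper_lp += (_norm_logpdf(v, x["log10_mu"], x["sigma_mu"])
                                 - _norm_logpdf(old, x["log10_mu"], x["sigma_mu"]))
                    if pend is not None:
                        st.loglik, st.kernel = pend
                        st.rate = 10.0 ** v
                    acct.record("dev", True)
                else:
                    acct.record("dev", False)
        if it <= burnin_iters and it % 2000 == 0:
            steps = tune_proposals(steps, acct.window_rates(), True)
            acct.reset_window()
        if it % cfg.thinning == 0:
            rows[kept, :5] = (x["log10_N0"], x["log10_N1"], x["log10_T"],
                              x["log10_mu"], x["sigma_mu"])
            rows[kept, 5:-1] = lmu - x["log10_mu"]
            rows[kept, -1] = sum(s.loglik for s in states)
            kept += 1
    df = pd.DataFrame(rows[:kept], columns=names + ["loglik"])
    df.insert(0, "iteration", np.arange(1, kept + 1) * cfg.thinning)
    df.insert(0, "chain", chain_id)
    return df, acct.rates()


def _prior_ms(pr: HierarchicalPriors, p: str) -> tuple[float, float]:
    return {"log10_N0": (pr.mean_log10_N0, pr.sd_log10_N0),
            "log10_N1": (pr.mean_log10_N1, pr.sd_log10_N1),
            "log10_T": (pr.mean_log10_T, pr.sd_log10_T)}[p]


def run_mcmc_hierarchical(data: GenotypeMatrix | None,
                          priors: HierarchicalPriors, cfg: MCMCConfig,
                          likelihood: bool = True,
                          n_loci_prior_mode: int = 4) -> TraceSet:
    """Sample (log10 N0, log10 N1, log10 T, log10 mu, sigma_mu, per-locus
    deviations) and per-locus genealogies under the exponential-change model.

    With ``likelihood=False`` the latent genealogies are dropped and the
    sampler targets the joint prior; per-locus deviation slots are still
    sampled (``n_loci_prior_mode`` of them) so their hierarchy is exercised.
    """
    if likelihood:
        if data is None:
            raise ValueError("data required when the likelihood is on")
        alleles = _alleles_by_locus(data)
        if not alleles:
            raise ValueError("no locus with >= 2 gene copies")
    else:
        alleles = [np.empty(0, dtype=np.int64)] * n_loci_prior_mode
    ss = np.random.SeedSequence(cfg.seed)
    frames = []
    acc: dict[int, dict[str, float]] = {}
    for c, child in enumerate(ss.spawn(cfg.n_chains)):
        df, rates = _run_hier_chain(alleles, priors, cfg, c, child, likelihood)
        frames.append(df)
        acc[c] = rates
    return TraceSet(pd.concat(frames, ignore_index=True),
                    _hier_params(len(alleles)), cfg.seed, acc,
                    meta={"engine": "hierarchical", "likelihood": likelihood})
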