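"""Diversity and differentiation statistics for microsatellite genotype tables.

Per-site diversity: mean number of alleles (MNA), observed heterozygosity (Ho)
and Nei's unbiased expected heterozygosity (He).  Differentiation and
heterozygote deficit use the Weir & Cockerham (1984) variance-components
estimators: theta (pairwise FST) and f (FIS), combined across loci and alleles
as ratio of sums.  Significance comes from permutation tests (alleles among
individuals within a site for FIS; individuals among sites for FST) with the
(1 + #exceedances)/(n_perm + 1) convention, plus Bonferroni adjustment.

Missing calls are dropped locus-wise, so per-locus sample sizes vary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "LocusFrequencies",
    "FStatResult",
    "MonomorphicError",
    "allele_frequencies",
    "mean_num_alleles",
    "observed_heterozygosity",
    "nei_unbiased_he",
    "wc_fis",
    "wc_pairwise_fst",
    "permutation_pvalue",
    "bonferroni",
    "diversity_table",
    "pairwise_fst_table",
]


class MonomorphicError(ValueError):
    """Statistic undefined because no locus is polymorphic in the sample."""


@dataclass
class LocusFrequencies:
    """Allele relative frequencies per site at one locus.

    ``freqs`` maps site -> {allele: relative frequency}; ``n_diploid`` maps
    site -> number of individuals with a non-missing call.
    """

    locus: str
    freqs: dict[str, dict[int, float]]
    n_diploid: dict[str, int]

    def __post_init__(self) -> None:
        for site, f in self.freqs.items():
            if f:
                total = sum(f.values())
                if abs(total - 1.0) > 1e-12:
                    raise ValueError(f"frequencies at {site} sum to {total}, not 1")
                if any(v < 0 for v in f.values()):
                    raise ValueError("negative allele frequency")


@dataclass
class FStatResult:
    statistic: str  # "FIS" or "FST"
    value: float
    p_value: float
    n_permutations: int
    adjusted_p: float = float("nan")

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def allele_frequencies(g: GenotypeMatrix, locus: str) -> LocusFrequencies:
    """Observed allele frequencies and diploid counts per site at one locus."""
    j = g.loci.index(locus)
    freqs: dict[str, dict[int, float]] = {}
    n_dip: dict[str, int] = {}
    for site in g.site_set:
        idx = g.site_indices(site)
        calls = g.calls[idx, j, :]
        ok = calls[:, 0] != MISSING
        alleles = calls[ok].ravel()
        n_dip[site] = int(ok.sum())
        if alleles.size:
            vals, counts = np.unique(alleles, return_counts=True)
            freqs[site] = {int(v): float(c) / alleles.size for v, c in zip(vals, counts)}
        else:
            freqs[site] = {}
    return LocusFrequencies(locus, freqs, n_dip)


def _site_calls(g: GenotypeMatrix, site: str) -> np.ndarray:
    """(n_site, L, 2) calls for one site."""
    return g.calls[g.site_indices(site)]


def _per_locus_valid(calls: np.ndarray) -> np.ndarray:
    return calls[:, :, 0] != MISSING  # (n, L) mask


def mean_num_alleles(g: GenotypeMatrix, site: str) -> float:
    """Arithmetic mean over loci of the number of distinct alleles at a site.

    Loci with no data at the site are excluded with a warning.
    """
    calls = _site_calls(g, site)
    ok = _per_locus_valid(calls)
    counts = []
    for j in range(calls.shape[1]):
        alleles = calls[ok[:, j], j, :].ravel()
        if alleles.size == 0:
            warnings.warn(f"locus {g.loci[j]} has no data at {site}; excluded")
            continue
        counts.append(np.unique(alleles).size)
    if not counts:
        raise MonomorphicError(f"no locus with data at {site}")
    return float(np.mean(counts))


def observed_heterozygosity(g: GenotypeMatrix, site: str) -> float:
    """Mean over loci of the fraction of non-missing individuals with two
    different alleles."""
    calls = _site_calls(g, site)
    ok = _per_locus_valid(calls)
    vals = []
    for j in range(calls.shape[1]):
        c = calls[ok[:, j], j, :]
        if c.shape[0] == 0:
            warnings.warn(f"locus {g.loci[j]} has no data at {site}; excluded")
            continue
        vals.append(float(np.mean(c[:, 0] != c[:, 1])))
    if not vals:
        raise MonomorphicError(f"no locus with data at {site}")
    return float(np.mean(vals))


def nei_unbiased_he(g: GenotypeMatrix, site: str) -> float:
    """Nei's unbiased expected heterozygosity, averaged over loci.

    Per locus: (2n / (2n - 1)) * (1 - sum p_hat^2) with n the diploid sample
    count; loci with n < 2 are excluded with a warning.
    """
    calls = _site_calls(g, site)
    ok = _per_locus_valid(calls)
    vals = []
    for j in range(calls.shape[1]):
        c = calls[ok[:, j], j, :]
        n = c.shape[0]
        if n < 2:
            warnings.warn(
                f"locus {g.loci[j]} has <2 individuals at {site}; excluded"
            )
            continue
        alleles = c.ravel()
        _, counts = np.unique(alleles, return_counts=True)
        p = counts / alleles.size
        vals.append((2 * n / (2 * n - 1)) * (1.0 - float(np.sum(p * p))))
    if not vals:
        raise MonomorphicError(f"no locus with enough data at {site}")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) variance components
# ---------------------------------------------------------------------------

def _wc_components_fst(calls_by_pop: list[np.ndarray]) -> tuple[float, float]:
    """Sum of the a component and of a+b+c over loci and alleles, for r >= 2
    populations.  Each element of ``calls_by_pop`` is (n_i, L, 2)."""
    r = len(calls_by_pop)
    L = calls_by_pop[0].shape[1]
    num = 0.0
    den = 0.0
    for j in range(L):
        pops = []
        for c in calls_by_pop:
            cj = c[:, j, :]
            cj = cj[cj[:, 0] != MISSING]
            if cj.shape[0] >= 1:
                pops.append(cj)
        if len(pops) < r:
            continue  # require data in every population at this locus
        n_i = np.array([p.shape[0] for p in pops], dtype=float)
        if (n_i < 2).any():
            continue
        alleles = np.unique(np.concatenate([p.ravel() for p in pops]))
        if alleles.size < 2:
            continue
        n_sum = n_i.sum()
        n_bar = n_sum / r
        n_c = (n_sum - np.sum(n_i**2) / n_sum) / (r - 1)
        for A in alleles:
            p_i = np.array([np.mean(p == A) for p in pops])
            h_i = np.array(
                [np.mean((p[:, 0] == A) ^ (p[:, 1] == A)) for p in pops]
            )
            p_bar = float(np.sum(n_i * p_i) / n_sum)
            s2 = float(np.sum(n_i * (p_i - p_bar) ** 2) / ((r - 1) * n_bar))
            h_bar = float(np.sum(n_i * h_i) / n_sum)
            a = (n_bar / n_c) * (
                s2
                - (1.0 / (n_bar - 1.0))
                * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
            )
            b = (n_bar / (n_bar - 1.0)) * (
                p_bar * (1 - p_bar)
                - s2 * (r - 1) / r
                - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c_comp = h_bar / 2.0
            num += a
            den += a + b + c_comp
    if den == 0.0:
        raise MonomorphicError("no shared polymorphic locus between the sites")
    return num, den


def _wc_components_fis(calls: np.ndarray) -> tuple[float, float]:
    """Within-one-population WC components: returns (sum b, sum b+c)."""
    L = calls.shape[1]
    sum_b = 0.0
    sum_bc = 0.0
    for j in range(L):
        cj = calls[:, j, :]
        cj = cj[cj[:, 0] != MISSING]
        n = cj.shape[0]
        if n < 2:
            continue
        alleles = np.unique(cj.ravel())
        if alleles.size < 2:
            continue
        for A in alleles:
            p_bar = float(np.mean(cj == A))
            h_bar = float(np.mean((cj[:, 0] == A) ^ (cj[:, 1] == A)))
            b = (n / (n - 1.0)) * (
                p_bar * (1 - p_bar) - (2 * n - 1) / (4 * n) * h_bar
            )
            c_comp = h_bar / 2.0
            sum_b += b
            sum_bc += b + c_comp
    if sum_bc == 0.0:
        raise MonomorphicError("all loci monomorphic: FIS undefined")
    return sum_b, sum_bc


def wc_fis(g: GenotypeMatrix, site: str) -> float:
    """Weir–Cockerham f (inbreeding coefficient) at one site, multi-locus
    ratio of sums over loci and alleles.

    +1 means only homozygotes where two alleles segregate; -1 means every
    individual heterozygous at a p = 0.5 biallelic locus; ~0 under HWE.
    """
    calls = _site_calls(g, site)
    sum_b, sum_bc = _wc_components_fis(calls)
    return 1.0 - (sum_bc - sum_b) / sum_bc  # = sum_b / sum_bc rearranged


def wc_pairwise_fst(g: GenotypeMatrix, siteA: str, siteB: str) -> float:
    """Weir–Cockerham theta for two sites, multi-locus ratio of sums."""
    a = _site_calls(g, siteA)
    b = _site_calls(g, siteB)
    num, den = _wc_components_fst([a, b])
    return num / den


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

def _permute_alleles_within(calls: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle alleles among individuals, per locus, keeping missingness."""
    out = calls.copy()
    for j in range(calls.shape[1]):
        ok = calls[:, j, 0] != MISSING
        pool = calls[ok, j, :].ravel().copy()
        rng.shuffle(pool)
        out[ok, j, :] = np.sort(pool.reshape(-1, 2), axis=1)
    return out


def permutation_pvalue(
    g: GenotypeMatrix,
    statistic: str,
    unit: str | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    site: str | None = None,
    site_pair: tuple[str, str] | None = None,
) -> FStatResult:
    """One-sided permutation p-value for FIS or FST.

    FIS permutes alleles among individuals within ``site`` (breaking the
    within-individual association, i.e. the HWE null); FST permutes individuals
    among the two sites of ``site_pair`` (the no-differentiation null).  The
    p-value is (1 + #{permuted >= observed}) / (n_perm + 1); deterministic for
    a given seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if statistic == "FIS":
        if site is None:
            raise ValueError("FIS needs site=")
        unit = unit or "alleles_within_site"
        if unit != "alleles_within_site":
            raise ValueError("FIS permutes alleles within the site")
        calls = _site_calls(g, site)
        sum_b, sum_bc = _wc_components_fis(calls)
        observed = 1.0 - (sum_bc - sum_b) / sum_bc
        exceed = 0
        for _ in range(n_perm):
            perm = _permute_alleles_within(calls, rng)
            try:
                pb, pbc = _wc_components_fis(perm)
                val = 1.0 - (pbc - pb) / pbc
            except MonomorphicError:
                val = observed  # invariant data: counts as an exceedance tie
            if val >= observed:
                exceed += 1
    elif statistic == "FST":
        if site_pair is None:
            raise ValueError("FST needs site_pair=")
        unit = unit or "individuals_between_sites"
        if unit != "individuals_between_sites":
            raise ValueError("FST permutes individuals among the two sites")
        a_idx = g.site_indices(site_pair[0])
        b_idx = g.site_indices(site_pair[1])
        nA = a_idx.size
        both = np.concatenate([a_idx, b_idx])
        calls_all = g.calls[both]
        num, den = _wc_components_fst([calls_all[:nA], calls_all[nA:]])
        observed = num / den
        exceed = 0
        order = np.arange(both.size)
        for _ in range(n_perm):
            rng.shuffle(order)
            pa = calls_all[order[:nA]]
            pb = calls_all[order[nA:]]
            try:
                n2, d2 = _wc_components_fst([pa, pb])
                val = n2 / d2
            except MonomorphicError:
                val = observed
            if val >= observed:
                exceed += 1
    else:
        raise ValueError("statistic must be 'FIS' or 'FST'")
    p = (1.0 + exceed) / (n_perm + 1.0)
    return FStatResult(statistic, float(observed), p, n_perm)


def bonferroni(pvalues, m: int | None = None) -> list[float]:
    """Bonferroni adjustment: p -> min(1, p * m), m defaulting to len(pvalues)."""
    pvalues = list(pvalues)
    if m is None:
        m = len(pvalues)
    if m < len(pvalues):
        raise ValueError("m must be >= number of p-values")
    out = []
    for p in pvalues:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, p * m))
    return out


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def diversity_table(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-site MNA, Ho and He summary."""
    rows = []
    for site in g.site_set:
        rows.append(
            {
                "site": site,
                "n": int(g.site_indices(site).size),
                "MNA": mean_num_alleles(g, site),
                "Ho": observed_heterozygosity(g, site),
                "He": nei_unbiased_he(g, site),
            }
        )
    return pd.DataFrame(rows)


def pairwise_fst_table(
    g: GenotypeMatrix, n_perm: int = 0, seed: int = 0
) -> pd.DataFrame:
    """All site pairs with WC theta and (optionally) permutation p-values,
    Bonferroni-adjusted over the number of pairs."""
    sites = g.site_set
    rows = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            pair = (sites[i], sites[j])
            if n_perm > 0:
                res = permutation_pvalue(
                    g, "FST", n_perm=n_perm, seed=seed + i * 1000 + j,
                    site_pair=pair,
                )
                rows.append(
                    {"siteA": pair[0], "siteB": pair[1], "fst": res.value,
                     "p": res.p_value}
                )
            else:
                rows.append(
                    {"siteA": pair[0], "siteB": pair[1],
                     "fst": wc_pairwise_fst(g, *pair), "p": np.nan}
                )
    frame = pd.DataFrame(rows)
    if n_perm > 0 and len(frame):
        frame["adjusted_p"] = bonferroni(frame["p"].tolist(), len(frame))
    return frame
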