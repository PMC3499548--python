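"""Diversity statistics and Weir-Cockerham F-statistics against independent
oracles, plus the permutation-test contracts."""

import numpy as np
import pytest

from popcollapse.genotypes import GenotypeMatrix
from popcollapse.popgen_stats import (MonomorphicError, allele_frequencies,
                                      bonferroni, mean_num_alleles,
                                      nei_unbiased_he,
                                      observed_heterozygosity,
                                      permutation_pvalue, wc_fis,
                                      wc_pairwise_fst)

from conftest import random_matrix


def one_site(calls) -> GenotypeMatrix:
    calls = np.asarray(calls)
    return GenotypeMatrix([f"i{k}" for k in range(calls.shape[0])],
                          ["A"] * calls.shape[0],
                          [f"L{j}" for j in range(calls.shape[1])], calls)


# ---------------------------------------------------------------------------
# Independent scalar-loop oracle for the 1984 variance components
# ---------------------------------------------------------------------------

def oracle_fst(g: GenotypeMatrix, siteA: str, siteB: str) -> float:
    """Per-allele scalar transcription of the two-population variance
    components a, b, c; ratio of sums over loci and alleles."""
    num = den = 0.0
    r = 2
    for locus in g.loci:
        lf = allele_frequencies(g, locus)
        pops = []
        for s in (siteA, siteB):
            idx = g.site_indices(s)
            j = g.loci.index(locus)
            c = g.calls[idx, j, :]
            pops.append(c[c[:, 0] != 0])
        n1, n2 = len(pops[0]), len(pops[1])
        if n1 < 2 or n2 < 2:
            continue
        alleles = sorted({int(a) for p in pops for a in p.ravel()})
        if len(alleles) < 2:
            continue
        n_bar = (n1 + n2) / 2
        n_c = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
        for A in alleles:
            p1 = np.mean(pops[0] == A)
            p2 = np.mean(pops[1] == A)
            h1 = np.mean((pops[0][:, 0] == A) != (pops[0][:, 1] == A))
            h2 = np.mean((pops[1][:, 0] == A) != (pops[1][:, 1] == A))
            p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
            s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
            h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)
            a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r
                                       - h_bar / 4) / (n_bar - 1))
            b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r
                                         - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
            c = h_bar / 2
            num += a
            den += a + b + c
    return num / den


def oracle_fis(g: GenotypeMatrix, site: str) -> float:
    """Single-population f from the same components, coded as scalars."""
    sum_b = sum_bc = 0.0
    idx = g.site_indices(site)
    for j, _ in enumerate(g.loci):
        c = g.calls[idx, j, :]
        c = c[c[:, 0] != 0]
        n = len(c)
        if n < 2:
            continue
        alleles = sorted({int(a) for a in c.ravel()})
        if len(alleles) < 2:
            continue
        for A in alleles:
            p = np.mean(c == A)
            h = np.mean((c[:, 0] == A) != (c[:, 1] == A))
            b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
            sum_b += b
            sum_bc += b + h / 2
    return sum_b / sum_bc


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

class TestDiversity:
    def test_mna_counts_distinct_alleles(self):
        g = one_site([[[100, 102]], [[104, 104]]])
        assert mean_num_alleles(g, "A") == 3.0

    def test_mna_monomorphic_is_one(self):
        g = one_site([[[100, 100], [90, 90]], [[100, 100], [90, 90]]])
        assert mean_num_alleles(g, "A") == 1.0

    def test_mna_matches_recount(self, rng):
        g = random_matrix(rng, n_ind=12, n_loci=5, n_sites=1)
        expected = np.mean([
            len(set(g.calls[~g.missing_mask()[:, j], j, :].ravel()))
            for j in range(5)])
        assert mean_num_alleles(g, "s0") == pytest.approx(expected)

    def test_ho_extremes_and_fraction(self):
        het = one_site([[[100, 102]], [[104, 106]]])
        hom = one_site([[[100, 100]], [[104, 104]]])
        assert observed_heterozygosity(het, "A") == 1.0
        assert observed_heterozygosity(hom, "A") == 0.0
        g = one_site([[[100, 102]], [[100, 104]], [[102, 104]], [[100, 100]]])
        assert observed_heterozygosity(g, "A") == 0.75

    def test_he_monomorphic_zero(self):
        g = one_site([[[100, 100]], [[100, 100]]])
        assert nei_unbiased_he(g, "A") == 0.0

    def test_he_hand_values(self):
        # n = 2, both 100/102: (2n/(2n-1)) (1 - sum p^2) = (4/3)(1 - 0.5)
        g = one_site([[[100, 102]], [[100, 102]]])
        assert nei_unbiased_he(g, "A") == pytest.approx(2 / 3, abs=1e-12)
        # n = 2, four distinct alleles: (4/3)(1 - 0.25) = 1
        g = one_site([[[100, 102]], [[104, 106]]])
        assert nei_unbiased_he(g, "A") == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# F-statistics
# ---------------------------------------------------------------------------

class TestWeirCockerham:
    def test_fis_all_homozygotes_is_one(self):
        g = one_site([[[100, 100]], [[102, 102]], [[100, 100]], [[102, 102]]])
        assert wc_fis(g, "A") == pytest.approx(1.0, abs=1e-12)

    def test_fis_all_heterozygotes_is_minus_one(self):
        g = one_site([[[100, 102]]] * 6)
        assert wc_fis(g, "A") == pytest.approx(-1.0, abs=1e-12)

    def test_fis_near_zero_under_random_mating(self):
        rng = np.random.default_rng(5)
        calls = rng.choice([100, 102, 104, 106], size=(2000, 10, 2))
        g = one_site(calls)
        assert abs(wc_fis(g, "A")) < 0.05

    def test_fis_monomorphic_undefined(self):
        g = one_site([[[100, 100]], [[100, 100]]])
        with pytest.raises(MonomorphicError):
            wc_fis(g, "A")

    @staticmethod
    def _two_sites(callsA, callsB):
        callsA, callsB = np.asarray(callsA), np.asarray(callsB)
        n = callsA.shape[0] + callsB.shape[0]
        return GenotypeMatrix(
            [f"i{k}" for k in range(n)],
            ["A"] * callsA.shape[0] + ["B"] * callsB.shape[0],
            [f"L{j}" for j in range(callsA.shape[1])],
            np.concatenate([callsA, callsB]))

    def test_fixed_difference_gives_one(self):
        g = self._two_sites([[[100, 100]]] * 5, [[[104, 104]]] * 5)
        assert wc_pairwise_fst(g, "A", "B") == pytest.approx(1.0, abs=1e-12)

    def test_identical_compositions_give_small_theta(self):
        # theta for two identical demes is slightly negative, shrinking ~1/n
        block = [[[100, 102]], [[100, 100]], [[102, 104]], [[104, 104]]] * 12
        g = self._two_sites(block, block)
        theta = wc_pairwise_fst(g, "A", "B")
        assert theta <= 0.01
        assert abs(theta) < 0.05

    def test_no_shared_polymorphism_undefined(self):
        g = self._two_sites([[[100, 100]]] * 3, [[[100, 100]]] * 3)
        with pytest.raises(MonomorphicError):
            wc_pairwise_fst(g, "A", "B")

    def test_oracle_equivalence_on_random_tables(self):
        """Vectorised ratio-of-sums equals the independently coded scalar
        variance-component oracle on 100 random tables (1e-12)."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            g = random_matrix(rng, n_ind=14, n_loci=3, n_sites=2,
                              missing_rate=0.15)
            try:
                ours = wc_pairwise_fst(g, "s0", "s1")
            except MonomorphicError:
                continue
            assert ours == pytest.approx(oracle_fst(g, "s0", "s1"), abs=1e-12)
            assert wc_fis(g, "s0") == pytest.approx(oracle_fis(g, "s0"),
                                                    abs=1e-12)

    def test_multilocus_reduces_to_single_polymorphic_locus(self, rng):
        poly = rng.choice([100, 102], size=(10, 1, 2))
        mono = np.full((10, 1, 2), 90)
        g = one_site(np.concatenate([poly, mono], axis=1))
        g_single = one_site(poly)
        assert wc_fis(g, "A") == pytest.approx(wc_fis(g_single, "A"), abs=1e-12)


# ---------------------------------------------------------------------------
# Permutation tests and Bonferroni
# ---------------------------------------------------------------------------

class TestPermutation:
    def test_fixed_difference_small_pvalue(self):
        g = TestWeirCockerham._two_sites([[[100, 100]]] * 6 + [[[100, 102]]],
                                         [[[104, 104]]] * 6 + [[[104, 102]]])
        res = permutation_pvalue(g, "FST", n_perm=999, seed=0,
                                 site_pair=("A", "B"))
        assert res.p_value <= 0.005

    def test_determinism_and_range(self, rng):
        g = random_matrix(rng, n_ind=12, n_loci=3, n_sites=2, missing_rate=0)
        a = permutation_pvalue(g, "FST", n_perm=200, seed=9,
                               site_pair=("s0", "s1"))
        b = permutation_pvalue(g, "FST", n_perm=200, seed=9,
                               site_pair=("s0", "s1"))
        assert a.p_value == b.p_value
        assert 0 < a.p_value <= 1

    def test_fis_permutation_detects_heterozygote_excess_tail(self):
        # all heterozygous: observed f = -1 is the permutation minimum, so the
        # one-sided (>= observed) p-value is 1 within the +1 correction
        g = one_site([[[100, 102]]] * 8)
        res = permutation_pvalue(g, "FIS", n_perm=99, seed=2, site="A")
        assert res.p_value == 1.0

    def test_bonferroni(self):
        assert bonferroni([0.01], 6) == [0.06]
        assert bonferroni([0.5], 10) == [1.0]
        assert bonferroni([0.2, 0.03]) == [0.4, 0.06]
        with pytest.raises(ValueError):
            bonferroni([1.5], 2)
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)
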