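"""Hardy-Weinberg exact test and genotypic LD permutation test."""
import itertools
import math

import numpy as np
import pytest
from scipy.special import gammaln

from strpopkit.exact_tests import (
    bonferroni_threshold,
    count_genotype_arrays,
    enumerate_genotype_arrays,
    format_two_sig,
    hwe_exact_test,
    ld_g_statistic,
    ld_permutation_test,
    ld_test_matrix,
    levene_probability,
    log_levene_probability,
)
from strpopkit.model import (
    AlleleFrequencySpectrum,
    AlleleLabel,
    Genotype,
    GenotypeCountTable,
    GenotypeTable,
)
from strpopkit.simulate import simulate_genotypes, simulate_linked_pair


def gct_of(pairs):
    counts = {}
    for a, b, c in pairs:
        counts[Genotype.of(a, b)] = c
    return GenotypeCountTable(locus="L", counts=counts)


class TestLeveneProbability:
    def test_two_heterozygotes(self):
        # n=2, both AB: P = 2! * 2^2 * (2! 2!) / (4! * 2!) = 2/3
        assert levene_probability(gct_of([("1", "2", 2)])) == \
            pytest.approx(2 / 3)

    def test_opposite_homozygotes(self):
        # n=2, one AA one BB: P = 1/3
        assert levene_probability(
            gct_of([("1", "1", 1), ("2", "2", 1)])) == pytest.approx(1 / 3)

    def test_monomorphic_certainty(self):
        assert levene_probability(gct_of([("1", "1", 7)])) == \
            pytest.approx(1.0)

    @pytest.mark.parametrize("allele_counts", [
        (4, 4), (6, 2), (5, 3, 2), (4, 3, 2, 1), (8, 6, 4, 2),
        (10, 10),
    ])
    def test_sums_to_one_over_enumeration(self, allele_counts):
        """Levene probabilities over the complete conditional space."""
        total = sum(math.exp(log_levene_probability(arr))
                    for arr in enumerate_genotype_arrays(allele_counts))
        assert total == pytest.approx(1.0, abs=1e-10)


class TestEnumerationTest:
    def test_hw_counts_biallelic(self, biallelic_table):
        gct = biallelic_table.genotype_counts("L1")
        res = hwe_exact_test(gct, method="enumerate")
        # independent biallelic oracle: enumerate heterozygote count
        # arrays directly (n11, n12, n22) with m1 = m2 = 100
        m1 = m2 = 100
        n = 100

        def prob(n12):
            n11 = (m1 - n12) // 2
            n22 = (m2 - n12) // 2
            return math.exp(
                gammaln(n + 1) - gammaln(n11 + 1) - gammaln(n12 + 1)
                - gammaln(n22 + 1) + n12 * math.log(2)
                + gammaln(m1 + 1) + gammaln(m2 + 1) - gammaln(2 * n + 1))

        probs = {h: prob(h) for h in range(m1 % 2, min(m1, m2) + 1, 2)}
        obs = probs[50]
        expected = sum(p for p in probs.values() if p <= obs + 1e-12)
        assert res.p_value == pytest.approx(expected, abs=1e-10)
        assert res.method == "enumeration"

    def test_tail_includes_ties(self):
        # arrays: {2 het} with P=2/3 (observed) and {AA,BB} with P=1/3;
        # both are <= the observed probability, so p = 1
        gct = gct_of([("1", "2", 2)])
        res = hwe_exact_test(gct, method="enumerate")
        assert res.p_value == pytest.approx(1.0)
        # observing the less probable array instead gives p = 1/3
        res2 = hwe_exact_test(gct_of([("1", "1", 1), ("2", "2", 1)]),
                              method="enumerate")
        assert res2.p_value == pytest.approx(1 / 3)

    def test_monomorphic_p_one(self):
        res = hwe_exact_test(gct_of([("1", "1", 9)]))
        assert res.p_value == 1.0

    def test_auto_switches_to_mcmc(self):
        rng = np.random.default_rng(5)
        labels = [AlleleLabel(10 + i) for i in range(8)]
        freqs = rng.dirichlet(np.ones(8))
        spec = AlleleFrequencySpectrum(
            locus="L", n=10,
            freqs={l: float(f) for l, f in zip(labels, freqs)})
        t = simulate_genotypes({"L": spec}, n=500, seed=11)
        res = hwe_exact_test(t.genotype_counts("L"), method="auto",
                             reps=2000, burnin=500, seed=3,
                             enumeration_limit=10_000)
        assert res.method == "monte_carlo"
        assert res.se is not None

    def test_count_limit(self):
        assert count_genotype_arrays((4, 4)) == 3
        assert count_genotype_arrays((200,) * 6, limit=100) is None


class TestMcmcAgainstEnumeration:
    """The Guo-Thompson chain reproduces exact enumeration p-values."""

    def test_agreement_within_mc_error(self, rng):
        misses = 0
        trials = 40
        for trial in range(trials):
            labels = [AlleleLabel(8 + i) for i in range(3)]
            freqs = rng.dirichlet(np.ones(3) * 2)
            spec = AlleleFrequencySpectrum(
                locus="L", n=30,
                freqs={l: float(f) for l, f in zip(labels, freqs)})
            t = simulate_genotypes({"L": spec}, n=30,
                                   f=float(rng.uniform(0, 0.4)),
                                   seed=int(rng.integers(2 ** 31)))
            gct = t.genotype_counts("L")
            exact = hwe_exact_test(gct, method="enumerate")
            mc = hwe_exact_test(gct, method="mc", reps=20_000,
                                seed=int(rng.integers(2 ** 31)))
            chain = hwe_exact_test(gct, method="mcmc", reps=20_000,
                                   burnin=2000,
                                   seed=int(rng.integers(2 ** 31)))
            if abs(mc.p_value - exact.p_value) > 3 * max(mc.se, 1e-4):
                misses += 1
            if abs(chain.p_value - exact.p_value) > \
                    4 * max(chain.se, 1e-3):
                misses += 1
        assert misses <= 2

    def test_mcmc_reproducible(self, biallelic_table):
        gct = biallelic_table.genotype_counts("L1")
        r1 = hwe_exact_test(gct, method="mcmc", reps=5000, seed=42)
        r2 = hwe_exact_test(gct, method="mcmc", reps=5000, seed=42)
        assert r1.p_value == r2.p_value


class TestHweCalibration:
    def test_type_one_error_under_hwe(self, rng):
        """At f=0 the exact test rejects at ~alpha."""
        rejections = 0
        n_loci = 400
        labels = [AlleleLabel(10), AlleleLabel(11)]
        for i in range(n_loci):
            p = float(rng.uniform(0.2, 0.8))
            spec = AlleleFrequencySpectrum(
                locus="L", n=100,
                freqs={labels[0]: p, labels[1]: 1 - p})
            t = simulate_genotypes({"L": spec}, n=100, f=0.0,
                                   seed=int(rng.integers(2 ** 31)))
            res = hwe_exact_test(t.genotype_counts("L"),
                                 method="enumerate")
            if res.p_value < 0.05:
                rejections += 1
        assert 0.02 * n_loci * 0.3 <= rejections <= 0.09 * n_loci

    def test_power_grows_with_inbreeding(self, rng):
        """At f=0.3, n=307 the test should reject most of the time."""
        rejections = 0
        trials = 40
        labels = [AlleleLabel(10), AlleleLabel(11), AlleleLabel(12)]
        for i in range(trials):
            freqs = rng.dirichlet(np.ones(3) * 3)
            spec = AlleleFrequencySpectrum(
                locus="L", n=307,
                freqs={l: float(f) for l, f in zip(labels, freqs)})
            t = simulate_genotypes({"L": spec}, n=307, f=0.3,
                                   seed=int(rng.integers(2 ** 31)))
            res = hwe_exact_test(t.genotype_counts("L"), method="mc",
                                 reps=2000,
                                 seed=int(rng.integers(2 ** 31)))
            if res.p_value < 0.05:
                rejections += 1
        assert rejections / trials > 0.5


class TestGStatistic:
    def test_uniform_independence_zero(self):
        assert ld_g_statistic(np.full((3, 4), 5)) == pytest.approx(0.0)

    def test_hand_worked_2x2(self):
        # (10,0;0,10): G = 2 * (10 ln 2 + 10 ln 2) = 40 ln 2 = 27.726
        g = ld_g_statistic(np.array([[10, 0], [0, 10]]))
        assert g == pytest.approx(40 * math.log(2), abs=1e-9)
        assert g == pytest.approx(27.7259, abs=1e-4)

    def test_transpose_invariant(self, rng):
        t = rng.integers(0, 20, size=(4, 6))
        assert ld_g_statistic(t) == pytest.approx(
            ld_g_statistic(t.T), abs=1e-9)

    def test_degenerate_single_row(self):
        assert ld_g_statistic(np.array([[3, 4, 5]])) == 0.0


class TestLdPermutation:
    def test_coupled_pair_minimum_p(self):
        spec = AlleleFrequencySpectrum(
            locus="A", n=50,
            freqs={AlleleLabel(10): 0.4, AlleleLabel(11): 0.35,
                   AlleleLabel(12): 0.25})
        spec_b = AlleleFrequencySpectrum(
            locus="B", n=50, freqs=dict(
                (AlleleLabel(20 + i), f)
                for i, f in enumerate([0.4, 0.35, 0.25])))
        t = simulate_linked_pair(spec, spec_b, r=1.0, n=100, seed=17)
        res = ld_permutation_test(t, "A", "B", reps=500, seed=1)
        assert res.p_value == pytest.approx(1 / 501, abs=2e-3)

    def test_seeded_reproducibility(self, two_locus_table):
        r1 = ld_permutation_test(two_locus_table, "LA", "LB", reps=300,
                                 seed=9)
        r2 = ld_permutation_test(two_locus_table, "LA", "LB", reps=300,
                                 seed=9)
        assert r1.p_value == r2.p_value
        assert r1.statistic == r2.statistic

    def test_type_one_error_independent_loci(self, rng):
        """p ~ uniform for independently simulated HWE loci."""
        rejections = 0
        pairs = 120
        for i in range(pairs):
            fa = rng.dirichlet(np.ones(3) * 2)
            fb = rng.dirichlet(np.ones(3) * 2)
            sa = AlleleFrequencySpectrum(
                locus="A", n=100, freqs={
                    AlleleLabel(10 + j): float(f)
                    for j, f in enumerate(fa)})
            sb = AlleleFrequencySpectrum(
                locus="B", n=100, freqs={
                    AlleleLabel(20 + j): float(f)
                    for j, f in enumerate(fb)})
            t = simulate_linked_pair(sa, sb, r=0.0, n=200,
                                     seed=int(rng.integers(2 ** 31)))
            res = ld_permutation_test(t, "A", "B", reps=200,
                                      seed=int(rng.integers(2 ** 31)))
            if res.p_value < 0.05:
                rejections += 1
        assert 0.005 * pairs <= rejections <= 0.09 * pairs

    def test_matrix_counts_and_threshold(self, rng):
        from strpopkit.simulate import (SimulationConfig,
                                        simulate_ancestral_spectra,
                                        simulate_genotypes)

        cfg = SimulationConfig(n_loci=5, alleles_min=3, alleles_max=4,
                               n_per_pop=60, n_pops=1, seed=23)
        spectra = simulate_ancestral_spectra(cfg)
        t = simulate_genotypes(spectra, n=60, seed=23)
        mat = ld_test_matrix(t, reps=100, seed=4)
        assert mat.n_pairs == 10
        assert mat.bonferroni_alpha == pytest.approx(0.005)
        # order independence of per-pair streams
        mat2 = ld_test_matrix(t, reps=100, seed=4)
        assert {k: v.p_value for k, v in mat.results.items()} == \
            {k: v.p_value for k, v in mat2.results.items()}


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 210, 0.05 / 210), (0.05, 1, 0.05), (0.01, 10, 0.001),
    ])
    def test_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_display_two_sig_figs(self):
        assert format_two_sig(0.05 / 210) == "0.00024"
        assert format_two_sig(0.001) == "0.001"

    def test_invalid(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
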