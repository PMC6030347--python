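"""Nei DA, Weir-Cockerham theta and frequency-level Fst estimators."""
import math

import numpy as np
import pytest

from strpopkit.distances import (
    distance_table,
    frequency_fst,
    fst_permutation_pvalue,
    nei_da,
    wc_components,
    wc_theta,
)
from strpopkit.model import (
    AlleleFrequencySpectrum,
    AlleleLabel,
    Genotype,
    GenotypeTable,
)
from strpopkit.simulate import (
    SimulationConfig,
    simulate_ancestral_spectra,
    simulate_genotypes,
    simulate_population_spectra,
)


def spec_of(locus, freqs, n=100, base=10):
    return AlleleFrequencySpectrum(
        locus=locus, n=n,
        freqs={AlleleLabel(base + i): f for i, f in enumerate(freqs)})


def table_from_lists(pop, rows, loci):
    ids = [f"{pop}{i}" for i in range(len(rows))]
    calls = {l: [] for l in loci}
    for row in rows:
        for l, g in zip(loci, row):
            calls[l].append(Genotype.of(*g))
    return GenotypeTable(pop, ids, loci, calls)


class TestNeiDa:
    def test_identical_zero(self):
        a = {"L1": spec_of("L1", [0.6, 0.4]), "L2": spec_of("L2", [0.5, 0.5])}
        assert nei_da(a, a) == pytest.approx(0.0, abs=1e-15)

    def test_disjoint_is_one(self):
        a = {"L1": spec_of("L1", [0.5, 0.5], base=10)}
        b = {"L1": spec_of("L1", [0.5, 0.5], base=20)}
        assert nei_da(a, b) == pytest.approx(1.0)

    def test_hand_worked_single_locus(self):
        # x=(1,0) vs y=(0.5,0.5): DA = 1 - sqrt(0.5)
        a = {"L1": spec_of("L1", [1.0])}
        b = {"L1": spec_of("L1", [0.5, 0.5])}
        assert nei_da(a, b) == pytest.approx(1 - math.sqrt(0.5))

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            fa = rng.dirichlet(np.ones(5))
            fb = rng.dirichlet(np.ones(5))
            a = {"L": spec_of("L", fa.tolist())}
            b = {"L": spec_of("L", fb.tolist())}
            d1, d2 = nei_da(a, b), nei_da(b, a)
            assert d1 == pytest.approx(d2, abs=1e-12)
            assert -1e-12 <= d1 <= 1.0

    def test_no_shared_loci_raises(self):
        a = {"L1": spec_of("L1", [1.0])}
        b = {"L2": spec_of("L2", [1.0])}
        with pytest.raises(ValueError):
            nei_da(a, b)


def _textbook_biallelic_theta(n1, n2, p1, p2, h1, h2):
    """Independent two-population biallelic Weir-Cockerham calculator,
    written directly from the published component formulas."""
    r = 2
    ns = np.array([n1, n2], dtype=float)
    ps = np.array([p1, p2], dtype=float)
    hs = np.array([h1, h2], dtype=float)
    nbar = ns.mean()
    nc = (r * nbar - (ns ** 2).sum() / (r * nbar)) / (r - 1)
    a_all = b_all = c_all = 0.0
    for p_vec, h_vec in (((ps, hs)), ((1 - ps, hs))):
        pbar = (ns * p_vec).sum() / (r * nbar)
        s2 = (ns * (p_vec - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * h_vec).sum() / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        a_all += a
        b_all += b
        c_all += c
    return a_all / (a_all + b_all + c_all)


class TestWcTheta:
    def test_matches_independent_biallelic_calculator(self):
        # fixed counts: pop1 20 AA / 30 AB / 10 BB; pop2 5 / 20 / 35
        rows1 = ([[("1", "1")]] * 20 + [[("1", "2")]] * 30
                 + [[("2", "2")]] * 10)
        rows2 = ([[("1", "1")]] * 5 + [[("1", "2")]] * 20
                 + [[("2", "2")]] * 35)
        t1 = table_from_lists("p1", rows1, ["L"])
        t2 = table_from_lists("p2", rows2, ["L"])
        res = wc_theta([t1, t2])
        p1 = (2 * 20 + 30) / 120
        p2 = (2 * 5 + 20) / 120
        expect = _textbook_biallelic_theta(60, 60, p1, p2, 30 / 60, 20 / 60)
        assert res.theta == pytest.approx(expect, abs=1e-10)

    def test_same_spectrum_theta_near_zero(self):
        spec = {"L%d" % i: spec_of("L%d" % i, [0.4, 0.3, 0.2, 0.1])
                for i in range(8)}
        t1 = simulate_genotypes(spec, n=500, seed=71, population_id="a")
        t2 = simulate_genotypes(spec, n=500, seed=72, population_id="b")
        res = wc_theta([t1, t2])
        assert abs(res.theta) < 0.005

    def test_pooled_split_components(self, rng):
        """Splitting one sample in half: a ~ 0, b and c positive."""
        spec = {"L": spec_of("L", [0.5, 0.3, 0.2])}
        t = simulate_genotypes(spec, n=800, seed=5)
        half = t.n // 2
        t1 = GenotypeTable("h1", t.individual_ids[:half], ["L"],
                           {"L": t.calls["L"][:half]})
        t2 = GenotypeTable("h2", t.individual_ids[half:], ["L"],
                           {"L": t.calls["L"][half:]})
        a, b, c = wc_components([t1, t2], "L")
        theta = a / (a + b + c)
        assert abs(theta) < 0.01          # no real differentiation
        assert c > 0                      # within-individual variance
        assert b > -0.05                  # b is positive in expectation only

    def test_monomorphic_degenerate(self):
        rows = [[("10", "10")]] * 10
        t1 = table_from_lists("p1", rows, ["L"])
        t2 = table_from_lists("p2", rows, ["L"])
        res = wc_theta([t1, t2])
        assert res.degenerate and res.theta == 0.0

    def test_balding_nichols_recovery_medians(self):
        """Median multilocus theta across replicates tracks true F."""
        for F in (0.05, 0.15):
            thetas = []
            for rep in range(25):
                cfg = SimulationConfig(n_loci=10, n_per_pop=150, n_pops=2,
                                       F=F, seed=1000 + rep)
                anc = simulate_ancestral_spectra(cfg)
                tabs = []
                for p in range(2):
                    sp = simulate_population_spectra(anc, F, cfg.seed,
                                                     pop_index=p)
                    tabs.append(simulate_genotypes(
                        sp, 150, seed=cfg.seed, population_id=f"p{p}"))
                thetas.append(wc_theta(tabs).theta)
            med = float(np.median(thetas))
            assert abs(med - F) / F < 0.35


class TestFstPermutation:
    def test_seeded_reproducibility(self):
        spec = {"L": spec_of("L", [0.5, 0.5])}
        t1 = simulate_genotypes(spec, n=60, seed=3, population_id="a")
        t2 = simulate_genotypes(spec, n=60, seed=4, population_id="b")
        r1 = fst_permutation_pvalue(t1, t2, reps=200, seed=11)
        r2 = fst_permutation_pvalue(t1, t2, reps=200, seed=11)
        assert r1.p_value == r2.p_value

    def test_differentiated_pair_significant(self):
        cfg = SimulationConfig(n_loci=8, n_per_pop=150, n_pops=2, F=0.08,
                               seed=42)
        anc = simulate_ancestral_spectra(cfg)
        tabs = []
        for p in range(2):
            sp = simulate_population_spectra(anc, cfg.F, cfg.seed,
                                             pop_index=p)
            tabs.append(simulate_genotypes(sp, 150, seed=cfg.seed,
                                           population_id=f"p{p}"))
        res = fst_permutation_pvalue(tabs[0], tabs[1], reps=200, seed=1)
        assert res.p_value <= 0.02

    def test_type_one_error_same_source(self, rng):
        rejections = 0
        pairs = 60
        for i in range(pairs):
            freqs = rng.dirichlet(np.ones(4) * 2)
            spec = {"L": spec_of("L", freqs.tolist())}
            seeds = rng.integers(2 ** 31, size=3)
            t1 = simulate_genotypes(spec, n=60, seed=int(seeds[0]),
                                    population_id="a")
            t2 = simulate_genotypes(spec, n=60, seed=int(seeds[1]),
                                    population_id="b")
            res = fst_permutation_pvalue(t1, t2, reps=99,
                                         seed=int(seeds[2]))
            if res.p_value <= 0.05:
                rejections += 1
        assert 0 <= rejections <= 0.12 * pairs


class TestFrequencyFst:
    def test_identical_zero(self):
        a = {"L": spec_of("L", [0.6, 0.4])}
        assert frequency_fst(a, a) == pytest.approx(0.0, abs=1e-15)
        assert frequency_fst(a, a, "reynolds") == pytest.approx(0.0,
                                                                abs=1e-15)

    def test_fixed_alternative_alleles(self):
        a = {"L": spec_of("L", [1.0], base=10)}
        b = {"L": spec_of("L", [1.0], base=11)}
        assert frequency_fst(a, b) == pytest.approx(1.0)

    def test_hand_worked_gst(self):
        # x=(0.7,0.3), y=(0.3,0.7): HS=0.42, HT=0.5 -> 0.16
        a = {"L": spec_of("L", [0.7, 0.3])}
        b = {"L": spec_of("L", [0.3, 0.7])}
        assert frequency_fst(a, b) == pytest.approx(0.16)

    def test_gst_tracks_theta_rank_order(self, rng):
        """Frequency-level G_st and genotype-level theta order pairs the
        same way."""
        from scipy.stats import spearmanr

        gsts, thetas = [], []
        for i in range(25):
            F = float(rng.uniform(0.005, 0.2))
            cfg = SimulationConfig(n_loci=6, n_per_pop=200, n_pops=2, F=F,
                                   seed=5000 + i)
            anc = simulate_ancestral_spectra(cfg)
            tabs, specs = [], []
            for p in range(2):
                sp = simulate_population_spectra(anc, F, cfg.seed,
                                                 pop_index=p)
                specs.append(sp)
                tabs.append(simulate_genotypes(sp, 200, seed=cfg.seed,
                                               population_id=f"p{p}"))
            gsts.append(frequency_fst(specs[0], specs[1]))
            thetas.append(wc_theta(tabs).theta)
        rho = spearmanr(gsts, thetas).statistic
        assert rho > 0.9


class TestDistanceTable:
    def test_identical_populations_zero_matrix(self):
        spec = {"L": spec_of("L", [0.5, 0.5])}
        pops = [("a", spec), ("b", spec)]
        dm = distance_table(pops, metric="da")
        assert np.allclose(dm.d, 0.0)

    def test_symmetry_and_zero_diagonal(self, rng):
        pops = []
        for i in range(4):
            freqs = rng.dirichlet(np.ones(4))
            pops.append((f"p{i}", {"L": spec_of("L", freqs.tolist())}))
        dm = distance_table(pops, metric="da")
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)

    def test_da_ordering_tracks_differentiation(self):
        """Populations at higher F from the ancestor are farther in DA."""
        cfg = SimulationConfig(n_loci=12, n_per_pop=300, n_pops=1,
                               seed=321)
        anc = simulate_ancestral_spectra(cfg)
        anc_set = {l: s for l, s in anc.items()}
        near = simulate_population_spectra(anc, 0.01, 11, pop_index=0)
        far = simulate_population_spectra(anc, 0.15, 11, pop_index=1)
        d_near = nei_da(anc_set, near)
        d_far = nei_da(anc_set, far)
        assert d_near < d_far

    def test_fst_metric_floors_negatives(self):
        spec = {"L": spec_of("L", [0.5, 0.3, 0.2])}
        t1 = simulate_genotypes(spec, n=300, seed=8, population_id="a")
        t2 = simulate_genotypes(spec, n=300, seed=9, population_id="b")
        dm = distance_table([("a", t1), ("b", t2)], metric="fst")
        assert dm.d.min() >= 0.0
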