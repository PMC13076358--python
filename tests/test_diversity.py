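"""Diversity statistics: frequencies, rarefaction, heterozygosity, F_IS,
F_ST, selfing, and plastid haplotype diversity."""

import numpy as np
import pytest

from kinflow.core import load_individuals
from kinflow.diversity import (
    allele_frequencies,
    allelic_richness,
    g2_identity_disequilibrium,
    heterozygosities,
    inbreeding_coefficient,
    pairwise_fst,
    plastid_diversity,
    selfing_from_fis,
    selfing_from_g2,
    _wc_fst,
)
from kinflow.simulate import Kernel, SimulationParams, mate_and_disperse, simulate_adults

from conftest import make_csv

HEADER = "id,site,x,y,dbh,hap,loc1_a,loc1_b"


def table_from_genotypes(genos, haps=None):
    rows = []
    for k, g in enumerate(genos):
        h = haps[k] if haps else "H1"
        rows.append(f"i{k},s,0,{k},40,{h}," + ",".join(g))
    return load_individuals(make_csv(rows, HEADER))


class TestFrequencies:
    def test_direct_counts(self):
        t = table_from_genotypes([("A", "A"), ("A", "B")])
        lf = allele_frequencies(t)[0]
        assert dict(zip(lf.alleles, lf.freqs)) == {"A": 0.75, "B": 0.25}
        assert lf.n_copies == 4

    def test_missing_decrements_copies(self):
        t = table_from_genotypes([("A", "A"), ("NA", "NA")])
        assert allele_frequencies(t)[0].n_copies == 2

    def test_monomorphic(self):
        t = table_from_genotypes([("A", "A"), ("A", "A")])
        lf = allele_frequencies(t)[0]
        assert list(lf.freqs) == [1.0]


class TestAllelicRichness:
    def test_sample_equals_standard(self):
        t = table_from_genotypes([("A", "A")] * 25)  # 50 copies of one allele
        per, mean = allelic_richness(allele_frequencies(t), k=50)
        assert mean == pytest.approx(1.0)

    def test_rare_allele_closed_form(self):
        # counts {A:99, B:1}, k=50 -> 2 - C(99,50)/C(100,50) = 1.5
        genos = [("A", "A")] * 49 + [("A", "B")]
        per, mean = allelic_richness(allele_frequencies(genos_table(genos)), k=50)
        assert mean == pytest.approx(1.5, abs=1e-12)

    def test_k_equal_n_recovers_observed_count(self):
        t = table_from_genotypes([("A", "B"), ("B", "C")])
        per, mean = allelic_richness(allele_frequencies(t), k=4)
        assert mean == pytest.approx(3.0, abs=1e-12)

    def test_monotone_in_k(self):
        t = table_from_genotypes([("A", "B"), ("B", "C"), ("C", "D"), ("A", "A")])
        means = [allelic_richness(allele_frequencies(t), k=k)[1] for k in (2, 4, 6, 8)]
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))

    def test_matches_bruteforce_subsampling(self):
        # 3-allele toy locus: closed form vs Monte-Carlo rarefaction
        genos = [("A", "A")] * 6 + [("A", "B")] * 3 + [("B", "C")] * 1
        t = table_from_genotypes(genos)
        _, closed = allelic_richness(allele_frequencies(t), k=6)
        copies = np.array([a for g in genos for a in g])
        rng = np.random.default_rng(0)
        draws = [
            len(set(rng.choice(copies, size=6, replace=False))) for _ in range(10_000)
        ]
        assert closed == pytest.approx(np.mean(draws), abs=3 * np.std(draws) / 100)

    def test_small_k_rejected(self):
        t = table_from_genotypes([("A", "B")])
        with pytest.raises(ValueError):
            allelic_richness(allele_frequencies(t), k=1)


def genos_table(genos):
    return table_from_genotypes(genos)


class TestHeterozygosity:
    def test_all_heterozygotes(self):
        t = table_from_genotypes([("A", "B")] * 5)
        ho, he = heterozygosities(t)
        assert ho == 1.0

    def test_unbiased_formula_by_hand(self):
        # AA, AB: H_O = 0.5; H_E = (4/3)(1 - 0.75^2 - 0.25^2) = 0.5
        t = table_from_genotypes([("A", "A"), ("A", "B")])
        ho, he = heterozygosities(t)
        assert ho == pytest.approx(0.5)
        assert he == pytest.approx(0.5)

    def test_large_n_limit(self):
        t = table_from_genotypes([("A", "A")] * 500 + [("B", "B")] * 500)
        _, he = heterozygosities(t)
        assert he == pytest.approx(0.5, abs=1e-3)


class TestInbreeding:
    def test_heterozygote_excess_negative(self):
        t = table_from_genotypes([("A", "B")] * 20)
        fis, p, tier = inbreeding_coefficient(t, n_perm=200, seed=0)
        assert fis < 0
        assert p < 0.05

    def test_monomorphic_errors(self):
        t = table_from_genotypes([("A", "A")] * 5)
        with pytest.raises(ValueError):
            inbreeding_coefficient(t, n_perm=10)


class TestFst:
    def test_split_halves_of_one_population_near_zero(self):
        rng = np.random.default_rng(3)
        genos = [tuple(rng.choice(["A", "B", "C"], 2)) for _ in range(60)]
        rows = []
        for k, g in enumerate(genos):
            s = "s1" if k < 30 else "s2"
            rows.append(f"i{k},{s},0,{k},40,H1,{g[0]},{g[1]}")
        t = load_individuals(make_csv(rows, HEADER))
        fst, p = pairwise_fst(t.by_site(), n_perm=99, seed=1)
        assert abs(fst.loc["s1", "s2"]) < 0.05
        assert p.loc["s1", "s2"] > 0.05

    def test_fixed_alternative_alleles_give_one(self):
        rows = [f"a{k},s1,0,{k},40,H1,A,A" for k in range(10)] + [
            f"b{k},s2,0,{k},40,H1,B,B" for k in range(10)
        ]
        t = load_individuals(make_csv(rows, HEADER))
        fst, _ = pairwise_fst(t.by_site(), n_perm=19, seed=1)
        assert fst.loc["s1", "s2"] == pytest.approx(1.0)

    def test_matches_parametric_divergence(self):
        # Balding-Nichols demes at F = 0.1: mean WC theta over many loci
        # should recover F within Monte-Carlo error.
        rng = np.random.default_rng(7)
        F, L, n = 0.1, 150, 80
        codes = np.zeros((2 * n, L, 2), dtype=np.int32)
        for l in range(L):
            p0 = rng.uniform(0.2, 0.8)
            a, b = p0 * (1 - F) / F, (1 - p0) * (1 - F) / F
            for d in range(2):
                p = rng.beta(a, b)
                g = (rng.random((n, 2)) < p).astype(np.int32)
                codes[d * n : (d + 1) * n, l, :] = g
        theta = _wc_fst(codes[:n], codes[n:])
        assert theta == pytest.approx(F, abs=0.025)


class TestSelfing:
    def test_fis_transform(self):
        assert selfing_from_fis(0.0) == 0.0
        assert selfing_from_fis(1 / 3) == pytest.approx(0.5)

    def test_g2_inverse_round_trip(self):
        from kinflow.diversity import g2_equilibrium

        for s in (0.05, 0.3, 0.7):
            assert selfing_from_g2(g2_equilibrium(s)) == pytest.approx(s, abs=1e-9)

    def test_g2_recovers_simulated_selfing(self):
        # mixed mating at s = 0.3, burn-in to identity-disequilibrium
        # equilibrium; mean over replicates within +/- 0.05
        params = SimulationParams(
            plot_width=400.0,
            plot_height=400.0,
            adult_density=20.0,
            n_loci=66,
            target_he=0.5,
            selfing_rate=0.3,
            n_generations_burnin=6,
            pollen_kernel=Kernel(scale=1e5),  # near-random mating among adults
            seed_kernel=Kernel(scale=1e3),
            site_name="g2",
        )
        ests = []
        for r in range(12):
            adults, _ = simulate_adults(params, seed=100 + r)
            g2 = g2_identity_disequilibrium(adults)
            ests.append(selfing_from_g2(g2))
        assert np.mean(ests) == pytest.approx(0.3, abs=0.05)


class TestPlastid:
    def test_single_haplotype(self):
        t = table_from_genotypes([("A", "B")] * 4, haps=["H1"] * 4)
        d = plastid_diversity(t)
        assert d["effective_number"] == pytest.approx(1.0)
        assert d["haplotype_he"] == 0.0

    def test_equifrequent(self):
        haps = ["H1", "H2", "H3", "H4"] * 100
        t = table_from_genotypes([("A", "B")] * 400, haps=haps)
        d = plastid_diversity(t)
        assert d["effective_number"] == pytest.approx(4.0)
        assert d["haplotype_he"] == pytest.approx(0.75, abs=0.01)

    def test_effective_number_formula(self):
        haps = ["H1"] * 50 + ["H2"] * 30 + ["H3"] * 20
        t = table_from_genotypes([("A", "B")] * 100, haps=haps)
        d = plastid_diversity(t)
        assert d["effective_number"] == pytest.approx(1 / 0.38, abs=1e-9)
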