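"""Spatial genetic structure: Loiselle kinship, correlogram, Sp."""

import numpy as np
import pytest

from kinflow.core import DistanceMatrix, load_individuals, pairwise_distances
from kinflow.diversity import allele_frequencies
from kinflow.sgs import (
    DistanceClassSpec,
    TooFewPairsError,
    autocorrelogram,
    loiselle_kinship,
    neighbourhood_size,
    slope_over_range,
    sp_statistic,
)
from kinflow.simulate import Kernel, SimulationParams, simulate_adults

from conftest import make_csv

HEADER = "id,site,x,y,dbh,hap,loc1_a,loc1_b"


def brute_force_loiselle(table, mode="diploid"):
    """Literal double-loop reimplementation of the Loiselle estimator,
    kept deliberately naive and separate from the library code path."""
    n = table.n
    if mode == "diploid":
        loci = range(table.n_loci)

        def profile(i, l):
            g = tuple(table.genotypes[i, l])
            return None if g[0] is None else g
    else:
        loci = [0]

        def profile(i, l):
            h = table.haplotypes[i]
            return None if h is None else (h, h)

    # per-locus reference frequencies over typed individuals
    stats = []
    for l in loci:
        typed = [i for i in range(n) if profile(i, l) is not None]
        if mode == "diploid":
            copies = [a for i in typed for a in table.genotypes[i, l]]
        else:
            copies = [table.haplotypes[i] for i in typed]
        alleles = sorted(set(copies))
        if len(typed) < 2 or len(alleles) < 2:
            stats.append(None)
            continue
        pbar = {a: copies.count(a) / len(copies) for a in alleles}
        stats.append((typed, alleles, pbar))

    F = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for l_idx, l in enumerate(loci):
                if stats[l_idx] is None:
                    continue
                typed, alleles, pbar = stats[l_idx]
                gi, gj = profile(i, l), profile(j, l)
                if gi is None or gj is None:
                    continue
                m_copies = 2 * len(typed) if mode == "diploid" else len(typed)
                for a in alleles:
                    if mode == "diploid":
                        pia = gi.count(a) / 2
                        pja = gj.count(a) / 2
                    else:
                        pia = 1.0 if gi[0] == a else 0.0
                        pja = 1.0 if gj[0] == a else 0.0
                    num += (pia - pbar[a]) * (pja - pbar[a])
                    num += pbar[a] * (1 - pbar[a]) / (m_copies - 1)
                    den += pbar[a] * (1 - pbar[a])
            F[i, j] = num / den if den > 0 else np.nan
    return F


@pytest.fixture(scope="module")
def random_small_table():
    rng = np.random.default_rng(5)
    rows = []
    header = "id,site,x,y,dbh,hap," + ",".join(
        f"L{l}_a,L{l}_b" for l in range(5)
    )
    for i in range(20):
        g = []
        for l in range(5):
            if rng.random() < 0.1:
                g += ["NA", "NA"]
            else:
                g += [str(rng.integers(1, 5)), str(rng.integers(1, 5))]
        rows.append(
            f"i{i},s,{rng.uniform(0, 100):.2f},{rng.uniform(0, 100):.2f},40,"
            f"H{rng.integers(1, 4)}," + ",".join(g)
        )
    return load_individuals(make_csv(rows, header))


class TestLoiselleKinship:
    def test_matches_bruteforce_diploid(self, random_small_table):
        t = random_small_table
        kin = loiselle_kinship(t, allele_frequencies(t), mode="diploid", min_loci=1)
        bf = brute_force_loiselle(t, "diploid")
        assert np.allclose(kin.values, bf, atol=1e-12, equal_nan=True)

    def test_matches_bruteforce_haploid(self, random_small_table):
        t = random_small_table
        kin = loiselle_kinship(t, mode="haploid")
        bf = brute_force_loiselle(t, "haploid")
        assert np.allclose(kin.values, bf, atol=1e-12, equal_nan=True)

    def test_large_n_limits_at_balanced_biallelic(self):
        # p = 0.5 and huge n: the finite-sample term vanishes, so
        # AA-AA pairs -> +1, AA-BB pairs -> -1, AB-AB pairs -> 0
        n_half = 1000
        rows = [f"a{k},s,0,{k},40,H1,A,A" for k in range(n_half)] + [
            f"b{k},s,1,{k},40,H1,B,B" for k in range(n_half)
        ] + ["h1,s,2,0,40,H1,A,B", "h2,s,2,1,40,H1,A,B"]
        t = load_individuals(make_csv(rows, HEADER))
        kin = loiselle_kinship(t, mode="diploid", min_loci=1).values
        assert kin[0, 1] == pytest.approx(1.0, abs=2e-3)  # AA vs AA
        assert kin[0, n_half] == pytest.approx(-1.0, abs=2e-3)  # AA vs BB
        i_h = 2 * n_half
        assert kin[i_h, i_h + 1] == pytest.approx(0.0, abs=2e-3)  # AB vs AB

    def test_centered_on_panmictic_sample(self):
        params = SimulationParams(
            plot_width=300, plot_height=300, adult_density=10, n_loci=20,
            n_generations_burnin=0, site_name="pan",
        )
        adults, _ = simulate_adults(params, seed=3)
        kin = loiselle_kinship(adults, mode="diploid", min_loci=1).values
        iu, ju = np.triu_indices(adults.n, 1)
        assert abs(np.nanmean(kin[iu, ju])) <= 0.005

    def test_monomorphic_panel_errors(self):
        rows = [f"i{k},s,0,{k},40,H1,A,A" for k in range(5)]
        t = load_individuals(make_csv(rows, HEADER))
        with pytest.raises(ValueError):
            loiselle_kinship(t, mode="diploid")


class TestSlope:
    def _toy(self, slope=-0.01, c=0.05, n=40):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 300, (n, 2))
        d = np.hypot(
            coords[:, 0][:, None] - coords[:, 0][None, :],
            coords[:, 1][:, None] - coords[:, 1][None, :],
        )
        np.fill_diagonal(d, 0)
        f = np.where(d > 0, c + slope * np.log(np.where(d > 0, d, 1)), 0.0)
        from kinflow.sgs import KinshipMatrix

        kin = KinshipMatrix(values=f, n_loci_pair=np.full((n, n), 30), mode="diploid")
        dist = DistanceMatrix(values=d, mode="planar")
        return kin, dist

    def test_exact_linear_data_recovers_slope_on_any_subrange(self):
        kin, dist = self._toy(slope=-0.013)
        assert slope_over_range(kin, dist, 1, 1000) == pytest.approx(-0.013)
        assert slope_over_range(kin, dist, 30, 120) == pytest.approx(-0.013)

    def test_full_range_matches_correlogram_slope(self):
        kin, dist = self._toy()
        res = autocorrelogram(kin, dist, spec=[30, 60, 120, 300, 600], n_perm=0, seed=0)
        full = slope_over_range(kin, dist, 0, np.inf)
        assert res.b_log == pytest.approx(full)

    def test_too_few_pairs_error_carries_count(self):
        kin, dist = self._toy(n=10)
        with pytest.raises(TooFewPairsError) as e:
            slope_over_range(kin, dist, 0.0, 1.0)
        assert e.value.count == 0


class TestAutocorrelogram:
    def test_sp_identity_and_tabulated_values(self):
        # definitional identity on printed first-class kinship and slope
        assert round(sp_statistic(0.0362, -0.0061), 4) == 0.0063
        assert sp_statistic(0.0, 0.0) == 0.0
        assert neighbourhood_size(0.0) == np.inf

    def test_sp_equals_external_recompute(self, sim_site):
        adults = sim_site["adults"]
        kin = loiselle_kinship(adults, mode="diploid", min_loci=10)
        dist = pairwise_distances(adults)
        res = autocorrelogram(kin, dist, spec=[30, 60, 90, 130, 170, 220, 300], n_perm=20, seed=2)
        assert res.sp == pytest.approx(-res.b_log / (1 - res.f1), abs=1e-15)
        assert res.ns * res.sp == pytest.approx(1.0)
        assert (res.classes["env_lo"] <= res.classes["env_hi"]).all()

    def test_empty_first_class_errors(self):
        kin, dist = TestSlope()._toy()
        with pytest.raises(ValueError, match="first"):
            autocorrelogram(kin, dist, spec=[0.001, 600], n_perm=0)

    def test_plastid_sgs_stronger_than_nuclear_under_short_kernels(self):
        params = SimulationParams(
            plot_width=300, plot_height=300, adult_density=25, n_loci=25,
            n_plastid_haplotypes=10, n_generations_burnin=8,
            seed_kernel=Kernel(scale=15.0), pollen_kernel=Kernel(scale=60.0),
            site_name="short",
        )
        spec = [20, 40, 60, 90, 130, 180, 260, 420]
        wins = 0
        for r in range(3):
            adults, _ = simulate_adults(params, seed=60 + r)
            dist = pairwise_distances(adults)
            nuc = autocorrelogram(
                loiselle_kinship(adults, mode="diploid", min_loci=10), dist, spec, n_perm=0
            )
            cp = autocorrelogram(
                loiselle_kinship(adults, mode="haploid"), dist, spec, n_perm=0
            )
            if cp.sp > nuc.sp > 0:
                wins += 1
        assert wins >= 2

    def test_envelope_calibration_under_null(self):
        # on spatially random data the observed F_1 should fall inside the
        # 95% envelope in roughly 95% of replicates
        params = SimulationParams(
            plot_width=300, plot_height=300, adult_density=10, n_loci=15,
            n_generations_burnin=0, cluster_sigma=1e5, cluster_density=5.0,
            site_name="null",
        )
        inside = 0
        R = 40
        for r in range(R):
            adults, _ = simulate_adults(params, seed=900 + r)
            kin = loiselle_kinship(adults, mode="diploid", min_loci=5)
            dist = pairwise_distances(adults)
            res = autocorrelogram(kin, dist, spec=[50, 100, 200, 450], n_perm=99, seed=r)
            row = res.classes.iloc[0]
            if row["env_lo"] <= row["mean_kinship"] <= row["env_hi"]:
                inside += 1
        assert inside / R >= 0.85
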