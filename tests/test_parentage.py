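"""Parentage assignment: LOD scores, calibration, exclusion, concordance,
and sibship clustering."""

import math

import numpy as np
import pytest

from kinflow.core import load_individuals
from kinflow.diversity import allele_frequencies
from kinflow.parentage import (
    GenotypingErrorModel,
    ParentageAssignment,
    assign_exclusion,
    assign_likelihood,
    assignments_to_frame,
    calibrate_thresholds,
    concordant,
    pair_lod,
    sibship_clusters,
)

from conftest import make_csv


def geno_table(rows_spec, loci=3):
    header = "id,site,x,y,dbh,hap," + ",".join(f"L{l}_a,L{l}_b" for l in range(loci))
    rows = []
    for rid, dbh, hap, genos in rows_spec:
        flat = ",".join(a for g in genos for a in g)
        rows.append(f"{rid},s,0,0,{dbh},{hap},{flat}")
    return load_individuals(make_csv(rows, header))


class TestPairLod:
    def test_hand_computed_trio(self):
        # 3 loci; population frequencies from the 4 adults below.
        adults = geno_table(
            [
                ("m", 40, "H1", [("1", "1"), ("1", "2"), ("1", "1")]),
                ("f", 40, "H2", [("2", "2"), ("1", "1"), ("1", "2")]),
                ("u1", 40, "H1", [("1", "2"), ("2", "2"), ("2", "2")]),
                ("u2", 40, "H2", [("1", "2"), ("1", "2"), ("1", "2")]),
            ]
        )
        off = geno_table([("o", 5, "H1", [("1", "2"), ("1", "1"), ("1", "1")])])
        freqs = allele_frequencies(adults)
        lod = pair_lod(off.genotypes[0], adults.genotypes[0], adults.genotypes[1], freqs)
        # hand oracle, locus by locus (epsilon = 0; every locus has
        # p(1) = p(2) = 0.5 over the 4 adults above):
        # L0: o = 1/2; m = 1/1 transmits 1 w.p. 1, f = 2/2 transmits 2 w.p. 1
        #     num = 1; den = 2 * 0.5 * 0.5          -> ln 2
        # L1: o = 1/1; m = 1/2 -> 0.5, f = 1/1 -> 1; den = 0.5^2 -> ln 2
        # L2: o = 1/1; m = 1/1 -> 1, f = 1/2 -> 0.5; den = 0.5^2 -> ln 2
        expected = 3 * math.log(2.0)
        assert lod == pytest.approx(expected, rel=1e-12)
        assert lod > 0

    def test_impossible_transmission_is_minus_inf(self):
        adults = geno_table(
            [
                ("m", 40, "H1", [("1", "1")]),
                ("f", 40, "H2", [("1", "1")]),
            ],
            loci=1,
        )
        # offspring carries allele 3 absent from both candidates; keep the
        # allele in the frequency reference via a third adult
        extra = geno_table(
            [
                ("m", 40, "H1", [("1", "1")]),
                ("f", 40, "H2", [("1", "1")]),
                ("z", 40, "H3", [("3", "3")]),
            ],
            loci=1,
        )
        off = geno_table([("o", 5, "H1", [("1", "3")])], loci=1)
        freqs = allele_frequencies(extra)
        lod = pair_lod(off.genotypes[0], adults.genotypes[0], adults.genotypes[1], freqs)
        assert lod == -np.inf

    def test_monomorphic_loci_are_uninformative(self):
        adults = geno_table(
            [("m", 40, "H1", [("1", "1")]), ("f", 40, "H2", [("1", "1")])], loci=1
        )
        off = geno_table([("o", 5, "H1", [("1", "1")])], loci=1)
        freqs = allele_frequencies(adults)
        lod = pair_lod(off.genotypes[0], adults.genotypes[0], adults.genotypes[1], freqs)
        assert lod == pytest.approx(0.0)


class TestCalibration:
    def test_easy_limit_accepts_true_parents(self, sim_site):
        adults = sim_site["adults"]
        freqs = allele_frequencies(adults)
        thr = calibrate_thresholds(
            freqs,
            n_sim_offspring=400,
            n_candidates=100,
            prop_sampled=1.0,
            error_model=GenotypingErrorModel(0.0),
            seed=3,
        )
        assigns = assign_likelihood(
            sim_site["offspring"], adults, freqs, thr, error_model=GenotypingErrorModel(0.0)
        )
        truth = sim_site["truth"]
        tmap = {
            r.offspring_id: tuple(sorted((r.mother_id, r.father_id)))
            for r in truth.itertuples()
        }
        good = sum(a.pair == tmap[a.offspring_id] for a in assigns if a.pair)
        assert good / len(assigns) >= 0.99

    def test_threshold_stability_across_seeds(self, sim_site):
        freqs = allele_frequencies(sim_site["adults"])
        thrs = [
            calibrate_thresholds(
                freqs, n_sim_offspring=2000, n_candidates=80, prop_sampled=0.5, seed=s
            )
            for s in (1, 2)
        ]
        for attr in ("strict", "relaxed"):
            a, b = getattr(thrs[0], attr), getattr(thrs[1], attr)
            assert abs(a - b) / max(abs(a), abs(b), 1e-9) < 0.25

    def test_no_sampling_is_degenerate(self, sim_site):
        freqs = allele_frequencies(sim_site["adults"])
        with pytest.raises(ValueError):
            calibrate_thresholds(freqs, prop_sampled=0.0)


class TestSingleParentFallback:
    def test_mother_alone_assigned_when_father_unsampled(self, sim_site):
        adults, offspring, truth = (
            sim_site["adults"],
            sim_site["offspring"],
            sim_site["truth"],
        )
        row = truth[~truth["selfed"]].iloc[0]
        off = offspring.subset(offspring.ids == row["offspring_id"])
        cand = adults.subset(adults.ids != row["father_id"])
        freqs = allele_frequencies(adults)
        out = assign_likelihood(off, cand, freqs, error_model=GenotypingErrorModel(0.0))
        assert out[0].pair == (row["mother_id"],)
        assert out[0].parent2_id is None


class TestExclusion:
    def test_clean_trio_unique_acceptance(self):
        adults = geno_table(
            [
                ("m", 40, "H1", [("1", "1"), ("3", "4"), ("5", "5")]),
                ("f", 40, "H2", [("2", "2"), ("5", "6"), ("6", "6")]),
                ("u", 40, "H3", [("7", "7"), ("7", "7"), ("7", "7")]),
            ]
        )
        off = geno_table([("o", 5, "H1", [("1", "2"), ("4", "6"), ("5", "6")])])
        out = assign_exclusion(off, adults, max_mismatch=0)
        assert out[0].pair == ("f", "m")

    def test_identical_candidates_tie_is_unassigned(self):
        g = [("1", "1"), ("3", "4"), ("5", "5")]
        adults = geno_table(
            [("m", 40, "H1", g), ("f1", 40, "H2", g), ("f2", 40, "H2", g)]
        )
        off = geno_table([("o", 5, "H1", [("1", "1"), ("3", "4"), ("5", "5")])])
        out = assign_exclusion(off, adults, max_mismatch=0)
        assert out[0].pair is None

    def test_single_scoring_error_tolerated(self):
        adults = geno_table(
            [
                ("m", 40, "H1", [("1", "1"), ("3", "4"), ("5", "5")]),
                ("f", 40, "H2", [("2", "2"), ("5", "6"), ("6", "6")]),
                ("u", 40, "H3", [("7", "7"), ("8", "8"), ("9", "9")]),
            ]
        )
        # locus 0 mis-scored: offspring reads 8/8 instead of 1/2
        off = geno_table([("o", 5, "H1", [("8", "8"), ("4", "6"), ("5", "6")])])
        assert assign_exclusion(off, adults, max_mismatch=1)[0].pair == ("f", "m")
        assert assign_exclusion(off, adults, max_mismatch=0)[0].pair is None


class TestConcordance:
    def _assign(self, oid, pair, method="likelihood", tier="relaxed"):
        p1, p2 = pair if pair else (None, None)
        return ParentageAssignment(oid, p1, p2, 0.0, 1.0, tier if pair else "none", method)

    def test_identity(self):
        a = [self._assign("o1", ("p1", "p2"))]
        assert concordant(a, a)[0].pair == ("p1", "p2")

    def test_disjoint_gives_empty(self):
        a = [self._assign("o1", ("p1", "p2"))]
        b = [self._assign("o1", ("p1", "p3"), method="exclusion")]
        assert concordant(a, b) == []

    def test_merged_at_least_as_accurate_as_either(self, sim_site):
        adults, offspring, truth = (
            sim_site["adults"],
            sim_site["offspring"],
            sim_site["truth"],
        )
        freqs = allele_frequencies(adults)
        a = assign_likelihood(offspring, adults, freqs, error_model=GenotypingErrorModel(0.0))
        b = assign_exclusion(offspring, adults, max_mismatch=0)
        merged = concordant(a, b)
        tmap = {
            r.offspring_id: tuple(sorted((r.mother_id, r.father_id)))
            for r in truth.itertuples()
        }

        def rate(assigns):
            pairs = [x for x in assigns if x.pair]
            return sum(x.pair == tmap[x.offspring_id] for x in pairs) / len(pairs)

        assert rate(merged) >= rate(a)
        assert rate(merged) >= rate(b)
        assert all(m.pair in {x.pair for x in a} for m in merged)

    def test_lod_minus_inf_iff_exclusion_mismatch(self, sim_site):
        # at epsilon = 0 the likelihood and exclusion routes agree exactly
        # on which trios are impossible
        adults = sim_site["adults"].subset(np.arange(12))
        offspring = sim_site["offspring"].subset(np.arange(25))
        freqs = allele_frequencies(sim_site["adults"])
        from kinflow.parentage import _Panel, _trio_mismatches

        panel = _Panel(freqs, offspring, adults)
        off_c, cand_c = panel.encode(offspring), panel.encode(adults)
        for i in range(offspring.n):
            for a in range(adults.n):
                for b in range(a, adults.n):
                    lod = pair_lod(
                        offspring.genotypes[i], adults.genotypes[a], adults.genotypes[b], freqs
                    )
                    mm = _trio_mismatches(off_c[i], cand_c[a], cand_c[b])
                    assert (lod == -np.inf) == (mm >= 1)


class TestSibships:
    def _assign(self, oid, pair):
        return ParentageAssignment(oid, pair[0], pair[1], 0.0, 1.0, "relaxed", "concordant")

    def test_full_sib_family(self):
        fc = sibship_clusters([self._assign("o1", ("p1", "p2")), self._assign("o2", ("p1", "p2"))])
        assert fc.sizes == [2]
        assert list(fc.clusters[0]["full_sib_families"].values()) == [["o1", "o2"]]

    def test_half_sib_chain_links_one_cluster(self):
        fc = sibship_clusters([self._assign("A", ("P1", "P2")), self._assign("B", ("P2", "P3"))])
        assert len(fc.clusters) == 1
        assert fc.clusters[0]["offspring"] == ["A", "B"]
        assert fc.clusters[0]["parents"] == ["P1", "P2", "P3"]

    def test_invariant_under_relabeling(self):
        assigns = [
            self._assign("o1", ("p1", "p2")),
            self._assign("o2", ("p2", "p3")),
            self._assign("o3", ("p9", "p9")),
        ]
        a = sibship_clusters(assigns)
        b = sibship_clusters(assigns[::-1])
        assert [c["offspring"] for c in a.clusters] == [c["offspring"] for c in b.clusters]

    def test_frame_round_trip(self):
        df = assignments_to_frame([self._assign("o1", ("p1", "p2"))])
        assert df.loc[0, "offspring_id"] == "o1"
        assert set(df.columns) >= {"parent1", "parent2", "lod", "delta", "tier", "method"}
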