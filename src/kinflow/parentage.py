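"""Parent-pair assignment for offspring among candidate adults.

Two independent routes are implemented and then merged:

1. A likelihood route: per-trio LOD scores (log-likelihood of the
   offspring genotype given the candidate parents under Mendelian
   transmission with a per-allele mis-scoring rate, against a random
   draw from the population allele frequencies), with confidence
   thresholds on the LOD gap Delta calibrated by Monte-Carlo simulation
   of offspring with known parents at a stated parent sampling rate.
2. An exclusion route: Mendelian-incompatibility counting per dyad and
   trio; a pair is accepted only when it is the unique pair within the
   allowed mismatch budget.

Only assignments on which both routes agree are treated as robust
downstream.  Offspring sharing an inferred parent are grouped into
half/full-sib family clusters by connected components.

The error model is deliberately simple: each recorded allele is, with
probability epsilon, replaced by a random allele from the locus
frequency distribution; the transmission probability folds this in on
the offspring side only, which is the standard first-order likelihood
formulation for low error rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import IndividualTable
from .diversity import AlleleFrequencies, allele_frequencies


@dataclass
class GenotypingErrorModel:
    """Per-allele mis-scoring rate epsilon in [0, 0.5)."""

    epsilon: float = 0.01

    def __post_init__(self):
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")


@dataclass
class ParentageAssignment:
    offspring_id: str
    parent1_id: str | None
    parent2_id: str | None
    lod: float
    delta: float
    tier: str  # "strict" | "relaxed" | "none"
    method: str  # "likelihood" | "exclusion" | "concordant"

    @property
    def pair(self):
        """Unordered parent pair; a 1-tuple for single-parent assignments,
        None if unassigned."""
        if self.parent1_id is None:
            return None
        if self.parent2_id is None:
            return (self.parent1_id,)
        return tuple(sorted([self.parent1_id, self.parent2_id]))


@dataclass
class ConfidenceThresholds:
    strict: float  # Delta threshold at 95% expected correctness
    relaxed: float  # at 80%
    seed: int
    n_sim: int
    params: dict = field(default_factory=dict)


@dataclass
class FamilyClusters:
    """Connected components of offspring sharing >= 1 inferred parent."""

    clusters: list[dict]  # {offspring: [...], parents: set, size: int}

    @property
    def sizes(self):
        return [c["size"] for c in self.clusters]


# ----------------------------------------------------------------------
# shared genotype encoding against a frequency reference


class _Panel:
    """Integer-coded genotypes for offspring and candidates over the allele
    space of a reference frequency set (alleles unseen in the reference get
    a small floor frequency so likelihoods stay finite)."""

    def __init__(self, freqs: AlleleFrequencies, *tables: IndividualTable):
        self.loci = [lf.locus for lf in freqs.loci]
        self.L = len(self.loci)
        self.alleles = []
        self.freq_vec = []
        floor = 1e-4
        for l, lf in enumerate(freqs.loci):
            labs = list(lf.alleles)
            extra = set()
            for t in tables:
                li = t.loci.index(lf.locus)
                for a in t.genotypes[:, li, :].ravel():
                    if a is not None and a not in labs:
                        extra.add(a)
            labs = labs + sorted(extra)
            p = np.concatenate([lf.freqs, np.full(len(extra), floor)])
            p = p / p.sum()
            self.alleles.append(labs)
            self.freq_vec.append(p)

    def encode(self, table: IndividualTable) -> np.ndarray:
        codes = np.full((table.n, self.L, 2), -1, dtype=np.int32)
        for l, locus in enumerate(self.loci):
            li = table.loci.index(locus)
            lut = {a: k for k, a in enumerate(self.alleles[l])}
            for i in range(table.n):
                a, b = table.genotypes[i, li]
                if a is not None:
                    codes[i, l, 0] = lut[a]
                    codes[i, l, 1] = lut[b]
        return codes


def _transmission_matrix(cand_codes: np.ndarray, p: np.ndarray, eps: float) -> np.ndarray:
    """(n_cand, n_alleles) matrix T[c, a] = P(candidate c transmits observed
    allele a) = (1-eps) * Mendel + eps * p_a; missing candidates get the
    population distribution (uninformative)."""
    n_cand = cand_codes.shape[0]
    k = len(p)
    M = np.zeros((n_cand, k))
    rows = np.arange(n_cand)
    typed = cand_codes[:, 0] >= 0
    M[rows[typed], cand_codes[typed, 0]] += 0.5
    M[rows[typed], cand_codes[typed, 1]] += 0.5
    T = (1 - eps) * M + eps * p[None, :]
    T[~typed] = p[None, :]
    return T


def pair_lod(
    off_geno,
    mother_geno,
    father_geno,
    freqs: AlleleFrequencies,
    error_model: GenotypingErrorModel | None = None,
) -> float:
    """LOD of one trio: sum over loci of
    ln P(offspring | parents, Mendel + error) - ln P(offspring | HWE draw).

    Genotypes are sequences of per-locus allele pairs (labels, None for
    missing); loci missing in any of the three are skipped.  Returns -inf
    when a locus is Mendelian-impossible at epsilon = 0.
    """
    eps = (error_model or GenotypingErrorModel(0.0)).epsilon
    lod = 0.0
    used = 0
    for l, lf in enumerate(freqs.loci):
        o = off_geno[l]
        m = mother_geno[l]
        f = father_geno[l]
        if o[0] is None or m[0] is None or f[0] is None:
            continue
        labs = {a: k for k, a in enumerate(lf.alleles)}
        p = lf.freqs

        def trans(parent, a):
            mendel = 0.5 * (parent[0] == a) + 0.5 * (parent[1] == a)
            pa = p[labs[a]] if a in labs else 0.0
            return (1 - eps) * mendel + eps * pa

        o1, o2 = o
        if o1 == o2:
            num = trans(m, o1) * trans(f, o1)
            den = (p[labs[o1]] if o1 in labs else 0.0) ** 2
        else:
            num = trans(m, o1) * trans(f, o2) + trans(m, o2) * trans(f, o1)
            p1 = p[labs[o1]] if o1 in labs else 0.0
            p2 = p[labs[o2]] if o2 in labs else 0.0
            den = 2 * p1 * p2
        if den == 0:
            continue
        used += 1
        if num == 0:
            return -np.inf
        lod += np.log(num / den)
    if used == 0:
        raise ValueError("no jointly typed informative loci for this trio")
    return float(lod)


# ----------------------------------------------------------------------
# vectorized scoring


def _score_offspring(off_codes, cand_codes, T_list, freq_vec, top_m: int):
    """For each offspring: best and second-best parent-pair LODs.

    Pairs are shortlisted to the ``top_m`` candidates by single-parent
    likelihood, then scored jointly (the joint LOD is symmetric in the
    pair, and the selfed diagonal is included); with informative
    multi-locus panels the true parents dominate the dyad ranking, so the
    shortlist is exact in practice.  Returns (best_i, best_j, best_lod,
    delta) with candidate indices.
    """
    n_off = off_codes.shape[0]
    excluded = [[] for _ in range(n_off)]
    return _score_offspring_excluding(off_codes, cand_codes, T_list, freq_vec, top_m, excluded)


def _build_scoring(freqs: AlleleFrequencies, offspring: IndividualTable, candidates: IndividualTable, eps: float):
    panel = _Panel(freqs, offspring, candidates)
    off_codes = panel.encode(offspring)
    cand_codes = panel.encode(candidates)
    T_list = [
        _transmission_matrix(cand_codes[:, l, :], panel.freq_vec[l], eps)
        for l in range(panel.L)
    ]
    return panel, off_codes, cand_codes, T_list


def assign_likelihood(
    offspring: IndividualTable,
    candidates: IndividualTable,
    freqs: AlleleFrequencies | None = None,
    thresholds: ConfidenceThresholds | None = None,
    error_model: GenotypingErrorModel | None = None,
    top_m: int = 20,
) -> list[ParentageAssignment]:
    """Best parent pair per offspring by joint LOD, tiered by Delta.

    Without calibrated ``thresholds`` every finite assignment is tiered
    ``relaxed`` when Delta > 0 (exact ties give ``none``).
    """
    if candidates.n == 0:
        return [
            ParentageAssignment(o, None, None, -np.inf, 0.0, "none", "likelihood")
            for o in offspring.ids
        ]
    eps = (error_model or GenotypingErrorModel()).epsilon
    if freqs is None:
        freqs = allele_frequencies(candidates)
    panel, off_codes, cand_codes, T_list = _build_scoring(freqs, offspring, candidates, eps)
    bi, bj, lod, delta, (dy_best, dy_lod, dy_delta) = _score_offspring(
        off_codes, cand_codes, T_list, panel.freq_vec, top_m
    )

    def tier_for(d):
        if d <= 0:
            return "none"
        if thresholds is None:
            return "relaxed"
        if d >= thresholds.strict:
            return "strict"
        if d >= thresholds.relaxed:
            return "relaxed"
        return "none"

    out = []
    for i, oid in enumerate(offspring.ids):
        tier = tier_for(delta[i]) if np.isfinite(lod[i]) else "none"
        if tier != "none":
            p1, p2 = str(candidates.ids[bi[i]]), str(candidates.ids[bj[i]])
            out.append(
                ParentageAssignment(str(oid), p1, p2, float(lod[i]), float(delta[i]), tier, "likelihood")
            )
            continue
        # fall back to a single parent when only one candidate passes
        s_tier = tier_for(dy_delta[i]) if np.isfinite(dy_lod[i]) and dy_lod[i] > 0 else "none"
        if s_tier != "none":
            out.append(
                ParentageAssignment(
                    str(oid), str(candidates.ids[dy_best[i]]), None,
                    float(dy_lod[i]), float(dy_delta[i]), s_tier, "likelihood",
                )
            )
        else:
            out.append(
                ParentageAssignment(str(oid), None, None, float(lod[i]), float(delta[i]), "none", "likelihood")
            )
    return out


# ----------------------------------------------------------------------
# calibration


def calibrate_thresholds(
    freqs: AlleleFrequencies,
    n_sim_offspring: int = 10_000,
    n_candidates: int = 500,
    prop_sampled: float = 0.25,
    error_model: GenotypingErrorModel | None = None,
    seed: int = 0,
    strict_rate: float = 0.95,
    relaxed_rate: float = 0.80,
    top_m: int = 20,
) -> ConfidenceThresholds:
    """Monte-Carlo calibration of the Delta confidence thresholds.

    Simulates offspring from parents drawn in HWE from ``freqs``; each true
    parent is independently present in the candidate set with probability
    ``prop_sampled``.  All candidates are scored for every offspring; the
    Delta of each best assignment is recorded together with whether it is
    the true pair.  The threshold for a confidence level c is the smallest
    Delta above which the fraction of correct best assignments is >= c.
    """
    if prop_sampled <= 0:
        raise ValueError("prop_sampled must be > 0: no correct assignment can exist")
    eps = (error_model or GenotypingErrorModel()).epsilon
    rng = np.random.default_rng(seed)
    L = len(freqs.loci)
    if all(len(lf.alleles) < 2 for lf in freqs.loci):
        raise ValueError("all loci monomorphic: calibration impossible")
    pvecs = [lf.freqs for lf in freqs.loci]
    ks = [len(p) for p in pvecs]

    def draw_genos(n):
        g = np.empty((n, L, 2), dtype=np.int32)
        for l in range(L):
            g[:, l, :] = rng.choice(ks[l], size=(n, 2), p=pvecs[l])
        return g

    cand = draw_genos(n_candidates)
    # choose true parents among the pool, then hide them per offspring
    mothers = rng.integers(0, n_candidates, n_sim_offspring)
    fathers = rng.integers(0, n_candidates, n_sim_offspring)
    off = np.empty((n_sim_offspring, L, 2), dtype=np.int32)
    for l in range(L):
        pm = rng.integers(0, 2, n_sim_offspring)
        pf = rng.integers(0, 2, n_sim_offspring)
        off[:, l, 0] = cand[mothers, l, :][np.arange(n_sim_offspring), pm]
        off[:, l, 1] = cand[fathers, l, :][np.arange(n_sim_offspring), pf]
        if eps > 0:
            for c in range(2):
                flip = rng.random(n_sim_offspring) < eps
                if flip.any():
                    off[flip, l, c] = rng.choice(ks[l], size=int(flip.sum()), p=pvecs[l])
    off.sort(axis=2)

    m_vis = rng.random(n_sim_offspring) < prop_sampled
    f_vis = rng.random(n_sim_offspring) < prop_sampled

    T_list = [_transmission_matrix(cand[:, l, :], pvecs[l], eps) for l in range(L)]
    # mask hidden true parents by scoring then excluding: cheaper to score all
    # and drop pairs containing a hidden parent per offspring, so score in
    # blocks with per-offspring exclusion applied to the dyad ranking.
    deltas = np.empty(n_sim_offspring)
    correct = np.zeros(n_sim_offspring, dtype=bool)
    block = 500
    for s in range(0, n_sim_offspring, block):
        e = min(s + block, n_sim_offspring)
        sl = slice(s, e)
        bi, bj, lod, dl, _dy = _score_offspring_excluding(
            off[sl], cand, T_list, pvecs, top_m,
            excluded=_hidden_lists(mothers[sl], fathers[sl], m_vis[sl], f_vis[sl]),
        )
        deltas[sl] = dl
        true_pair = [
            tuple(sorted((mothers[i], fathers[i]))) for i in range(s, e)
        ]
        got = [tuple(sorted((bi[i], bj[i]))) for i in range(e - s)]
        vis_pair = m_vis[sl] & f_vis[sl]
        correct[sl] = [
            vis_pair[i] and got[i] == true_pair[i] and np.isfinite(lod[i])
            for i in range(e - s)
        ]

    order = np.argsort(-deltas)
    d_sorted = deltas[order]
    c_sorted = correct[order]
    # running fraction correct among assignments accepted at threshold d
    frac = np.cumsum(c_sorted) / np.arange(1, len(c_sorted) + 1)

    def threshold_for(rate):
        ok = np.nonzero(frac >= rate)[0]
        if len(ok) == 0:
            return float(d_sorted[0]) + 1.0  # nothing acceptable
        k = ok.max()  # most inclusive prefix still meeting the rate
        return float(d_sorted[k])

    return ConfidenceThresholds(
        strict=threshold_for(strict_rate),
        relaxed=threshold_for(relaxed_rate),
        seed=seed,
        n_sim=n_sim_offspring,
        params={
            "n_candidates": n_candidates,
            "prop_sampled": prop_sampled,
            "epsilon": eps,
            "strict_rate": strict_rate,
            "relaxed_rate": relaxed_rate,
        },
    )


def _hidden_lists(mothers, fathers, m_vis, f_vis):
    out = []
    for i in range(len(mothers)):
        h = []
        if not m_vis[i]:
            h.append(int(mothers[i]))
        if not f_vis[i]:
            h.append(int(fathers[i]))
        out.append(h)
    return out


def _score_offspring_excluding(off_codes, cand_codes, T_list, freq_vec, top_m, excluded):
    """As _score_offspring but with per-offspring candidate exclusions
    (used by calibration to hide unsampled true parents)."""
    n_off = off_codes.shape[0]
    n_cand = cand_codes.shape[0]
    L = off_codes.shape[1]
    m = min(top_m, n_cand)
    with np.errstate(divide="ignore", invalid="ignore"):
        dyad = np.zeros((n_off, n_cand))
        for l in range(L):
            o = off_codes[:, l, :]
            typed_o = o[:, 0] >= 0
            T = T_list[l]
            p = freq_vec[l]
            o1 = np.maximum(o[:, 0], 0)
            o2 = np.maximum(o[:, 1], 0)
            het = o1 != o2
            t1 = T[:, o1].T
            t2 = T[:, o2].T
            num = np.where(het[:, None], t1 * p[o2][:, None] + t2 * p[o1][:, None], t1 * p[o1][:, None])
            den = np.where(het, 2 * p[o1] * p[o2], p[o1] ** 2)
            contrib = np.log(num) - np.log(den)[:, None]
            contrib[~typed_o] = 0.0
            dyad += contrib
        for i, h in enumerate(excluded):
            dyad[i, h] = -np.inf
        order = np.argsort(-dyad, axis=1)[:, :m]
        # single-parent (dyad) summary: best candidate, LOD, gap to runner-up
        dyad_best = order[:, 0]
        dyad_lod = dyad[np.arange(n_off), dyad_best]
        if n_cand > 1:
            dyad_second = dyad[np.arange(n_off), order[:, 1]]
            dyad_delta = np.minimum(dyad_lod - dyad_second, DELTA_CAP)
        else:
            dyad_delta = np.full(n_off, DELTA_CAP)
        dyad_delta[~np.isfinite(dyad_lod)] = 0.0
        # mask shortlisted slots that are excluded candidates (possible when
        # the shortlist spans the whole candidate set)
        excl_slot = np.zeros((n_off, m), dtype=bool)
        for i, h in enumerate(excluded):
            if h:
                excl_slot[i] = np.isin(order[i], h)
        pair_lods = np.zeros((n_off, m, m))
        for l in range(L):
            o = off_codes[:, l, :]
            typed_o = o[:, 0] >= 0
            T = T_list[l]
            p = freq_vec[l]
            o1 = np.maximum(o[:, 0], 0)
            o2 = np.maximum(o[:, 1], 0)
            het = o1 != o2
            t1 = T[order, o1[:, None]]
            t2 = T[order, o2[:, None]]
            num = np.where(
                het[:, None, None],
                t1[:, :, None] * t2[:, None, :] + t2[:, :, None] * t1[:, None, :],
                t1[:, :, None] * t1[:, None, :],
            )
            den = np.where(het, 2 * p[o1] * p[o2], p[o1] ** 2)
            contrib = np.log(num) - np.log(den)[:, None, None]
            contrib[~typed_o] = 0.0
            pair_lods += contrib
        pair_lods[excl_slot[:, :, None] | excl_slot[:, None, :]] = -np.inf
    best_i = np.empty(n_off, dtype=int)
    best_j = np.empty(n_off, dtype=int)
    best_lod = np.empty(n_off)
    delta = np.empty(n_off)
    iu, ju = np.triu_indices(m)
    for i in range(n_off):
        vals = pair_lods[i][iu, ju]
        k_best = int(np.argmax(vals))
        best_i[i] = order[i, iu[k_best]]
        best_j[i] = order[i, ju[k_best]]
        best_lod[i] = vals[k_best]
        rest = np.delete(vals, k_best)
        if not np.isfinite(best_lod[i]):
            delta[i] = 0.0
            continue
        second = rest.max() if len(rest) else -np.inf
        # a Mendelian-impossible runner-up makes the gap unbounded; cap it
        # so calibrated thresholds stay finite and comparable
        delta[i] = min(vals[k_best] - second, DELTA_CAP)
    return best_i, best_j, best_lod, delta, (dyad_best, dyad_lod, dyad_delta)


#: ceiling on the LOD gap Delta (log-likelihood units)
DELTA_CAP = 100.0


# ----------------------------------------------------------------------
# exclusion route


def assign_exclusion(
    offspring: IndividualTable,
    candidates: IndividualTable,
    max_mismatch: int = 1,
) -> list[ParentageAssignment]:
    """Mendelian-incompatibility pair assignment.

    A dyad mismatch is a locus where offspring and candidate share no
    allele; a trio mismatch is a locus where no joint transmission from
    the pair can produce the offspring genotype.  A pair is accepted only
    if it is the unique pair with trio mismatches <= max_mismatch and both
    dyad counts <= max_mismatch; ties leave the offspring unassigned.
    """
    if candidates.n == 0:
        return [
            ParentageAssignment(str(o), None, None, -np.inf, 0.0, "none", "exclusion")
            for o in offspring.ids
        ]
    # shared allele-code space
    from .diversity import allele_frequencies as _af

    panel = _Panel(_af(candidates), offspring, candidates)
    off = panel.encode(offspring)
    cand = panel.encode(candidates)
    n_off, L, _ = off.shape
    n_cand = cand.shape[0]

    # dyad mismatch counts, vectorized per locus
    dyad_mm = np.zeros((n_off, n_cand), dtype=np.int32)
    for l in range(L):
        o = off[:, l, :]
        c = cand[:, l, :]
        typed = (o[:, 0] >= 0)[:, None] & (c[:, 0] >= 0)[None, :]
        share = (
            (o[:, 0][:, None] == c[:, 0][None, :])
            | (o[:, 0][:, None] == c[:, 1][None, :])
            | (o[:, 1][:, None] == c[:, 0][None, :])
            | (o[:, 1][:, None] == c[:, 1][None, :])
        )
        dyad_mm += (typed & ~share).astype(np.int32)

    out = []
    for i in range(n_off):
        ok = np.nonzero(dyad_mm[i] <= max_mismatch)[0]
        accepted = None
        tie = False
        if len(ok) >= 1:
            pairs = []
            for ai in range(len(ok)):
                for bi in range(ai, len(ok)):
                    ca, cb = ok[ai], ok[bi]
                    mm = _trio_mismatches(off[i], cand[ca], cand[cb])
                    if mm <= max_mismatch:
                        pairs.append((ca, cb, mm))
            if len(pairs) == 1:
                accepted = pairs[0]
            elif len(pairs) > 1:
                tie = True
        if accepted is None:
            out.append(
                ParentageAssignment(str(offspring.ids[i]), None, None, np.nan, 0.0, "none", "exclusion")
            )
        else:
            ca, cb, mm = accepted
            out.append(
                ParentageAssignment(
                    str(offspring.ids[i]),
                    str(candidates.ids[ca]),
                    str(candidates.ids[cb]),
                    np.nan,
                    0.0,
                    "relaxed",
                    "exclusion",
                )
            )
    return out


def _trio_mismatches(off_g, m_g, f_g) -> int:
    """Loci where no transmission (o1 from one parent, o2 from the other)
    is possible."""
    mm = 0
    L = off_g.shape[0]
    for l in range(L):
        o1, o2 = off_g[l]
        if o1 < 0 or m_g[l, 0] < 0 or f_g[l, 0] < 0:
            continue
        m_has_1 = o1 in (m_g[l, 0], m_g[l, 1])
        m_has_2 = o2 in (m_g[l, 0], m_g[l, 1])
        f_has_1 = o1 in (f_g[l, 0], f_g[l, 1])
        f_has_2 = o2 in (f_g[l, 0], f_g[l, 1])
        if not ((m_has_1 and f_has_2) or (m_has_2 and f_has_1)):
            mm += 1
    return mm


# ----------------------------------------------------------------------
# concordance and sibships


def concordant(
    assign_a: list[ParentageAssignment], assign_b: list[ParentageAssignment]
) -> list[ParentageAssignment]:
    """Keep an offspring's pair iff both methods assigned the identical
    unordered pair (both parents present)."""
    by_off = {a.offspring_id: a for a in assign_b}
    out = []
    for a in assign_a:
        b = by_off.get(a.offspring_id)
        if b is None:
            continue
        if a.pair is not None and a.tier != "none" and b.pair == a.pair and b.tier != "none":
            out.append(
                ParentageAssignment(
                    a.offspring_id, a.parent1_id, a.parent2_id, a.lod, a.delta, a.tier, "concordant"
                )
            )
    return out


def assignment_rates(offspring_ids, assign_a, assign_b, merged) -> dict:
    """Per-site percentages assigned by each method and in common."""
    n = len(offspring_ids)

    def rate(assigns):
        good = sum(1 for a in assigns if a.pair is not None and a.tier != "none")
        return 100.0 * good / n if n else np.nan

    return {
        "pct_method_a": rate(assign_a),
        "pct_method_b": rate(assign_b),
        "pct_concordant": 100.0 * len(merged) / n if n else np.nan,
    }


def sibship_clusters(assignments: list[ParentageAssignment], flag_size: int = 5) -> FamilyClusters:
    """Half/full-sib family clusters: offspring sharing >= 1 inferred parent
    are connected; clusters are connected components.  Clusters larger than
    ``flag_size`` are flagged (map-display convention)."""
    g = nx.Graph()
    parent_map = {}
    for a in assignments:
        if a.pair is None:
            continue
        g.add_node(a.offspring_id)
        parent_map[a.offspring_id] = set(a.pair)
        for p in a.pair:
            g.add_edge(a.offspring_id, ("parent", p))
    clusters = []
    for comp in nx.connected_components(g):
        offs = sorted(x for x in comp if not isinstance(x, tuple))
        if not offs:
            continue
        parents = sorted(x[1] for x in comp if isinstance(x, tuple))
        full_sib = {}
        for o in offs:
            full_sib.setdefault(tuple(sorted(parent_map[o])), []).append(o)
        clusters.append(
            {
                "offspring": offs,
                "parents": parents,
                "size": len(offs),
                "full_sib_families": full_sib,
                "flagged": len(offs) > flag_size,
            }
        )
    clusters.sort(key=lambda c: (-c["size"], c["offspring"]))
    return FamilyClusters(clusters=clusters)


def assignments_to_frame(assignments: list[ParentageAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "offspring_id": a.offspring_id,
                "parent1": a.parent1_id,
                "parent2": a.parent2_id,
                "lod": a.lod,
                "delta": a.delta,
                "tier": a.tier,
                "method": a.method,
            }
            for a in assignments
        ]
    )
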