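"""Genetic diversity and inbreeding statistics for SSR panels.

Implements the per-group summary statistics used for diversity report
tables: allele frequencies, rarefied allelic richness (hypergeometric
standardization to k gene copies), observed and unbiased expected
heterozygosity, multilocus F_IS with a gene-copy permutation test,
Weir-Cockerham pairwise F_ST, selfing-rate estimators (equilibrium F_IS
transform and identity-disequilibrium g2 with jackknife significance),
and haplotype diversity for the maternally inherited plastid marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

from .core import IndividualTable, encode_genotypes


@dataclass
class LocusFrequencies:
    locus: str
    alleles: list
    counts: np.ndarray  # gene-copy counts per allele
    n_copies: int

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.n_copies if self.n_copies else self.counts * 0.0


@dataclass
class AlleleFrequencies:
    """Per-locus allele counts/frequencies over non-missing gene copies."""

    loci: list[LocusFrequencies]

    def __getitem__(self, i):
        return self.loci[i]

    def __len__(self):
        return len(self.loci)


def allele_frequencies(table: IndividualTable) -> AlleleFrequencies:
    codes, alleles = encode_genotypes(table)
    out = []
    for l, locus in enumerate(table.loci):
        flat = codes[:, l, :].ravel()
        flat = flat[flat >= 0]
        counts = np.bincount(flat, minlength=len(alleles[l])).astype(int)
        out.append(
            LocusFrequencies(
                locus=locus, alleles=alleles[l], counts=counts, n_copies=int(flat.size)
            )
        )
    return AlleleFrequencies(loci=out)


# ----------------------------------------------------------------------
# allelic richness


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def allelic_richness(freqs: AlleleFrequencies, k: int = 50):
    """Rarefied allelic richness standardized to ``k`` gene copies.

    Per locus: ``A_R = sum_a [1 - C(n_l - n_a, k) / C(n_l, k)]`` — the
    expected number of distinct alleles in a random draw of k gene copies
    without replacement.  Loci with fewer than k typed copies are skipped.
    Returns ``(per_locus: dict, mean: float)``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    per_locus = {}
    for lf in freqs.loci:
        if lf.n_copies < k:
            continue
        n = lf.n_copies
        terms = []
        for na in lf.counts:
            if na == 0:
                continue
            if n - na < k:
                terms.append(1.0)
            else:
                terms.append(1.0 - np.exp(_log_comb(n - na, k) - _log_comb(n, k)))
        per_locus[lf.locus] = float(np.sum(terms))
    mean = float(np.mean(list(per_locus.values()))) if per_locus else np.nan
    return per_locus, mean


# ----------------------------------------------------------------------
# heterozygosities


def heterozygosities(table: IndividualTable, freqs: AlleleFrequencies | None = None):
    """Observed and unbiased expected heterozygosity, averaged over loci.

    H_O is the simple fraction of typed individuals that are heterozygous.
    H_E applies the small-sample correction n/(n-1) * (1 - sum p^2) with n
    the number of typed gene copies.
    """
    if freqs is None:
        freqs = allele_frequencies(table)
    ho_l, he_l = [], []
    miss = table.missing_mask()
    for l, lf in enumerate(freqs.loci):
        typed = ~miss[:, l]
        if typed.sum() == 0:
            continue
        g = table.genotypes[typed, l]
        het = np.array([a != b for a, b in g])
        ho_l.append(het.mean())
        n = lf.n_copies
        if n > 1:
            he_l.append(n / (n - 1) * (1.0 - float(np.sum(lf.freqs**2))))
    return float(np.mean(ho_l)), float(np.mean(he_l))


def _multilocus_fis(codes: np.ndarray) -> float:
    """Multilocus F_IS = 1 - H_O/H_E with locus-weighted (summed) H terms."""
    n, L, _ = codes.shape
    ho_sum = he_sum = 0.0
    for l in range(L):
        g = codes[:, l, :]
        typed = g[:, 0] >= 0
        m = typed.sum()
        if m == 0:
            continue
        flat = g[typed].ravel()
        counts = np.bincount(flat)
        nc = flat.size
        p = counts / nc
        he = nc / (nc - 1) * (1.0 - np.sum(p**2)) if nc > 1 else 0.0
        ho = np.mean(g[typed, 0] != g[typed, 1])
        # ratio of sums across loci (loci implicitly weighted by diversity)
        ho_sum += ho
        he_sum += he
    if he_sum == 0:
        raise ValueError("all loci monomorphic: F_IS undefined")
    return 1.0 - ho_sum / he_sum


def inbreeding_coefficient(table: IndividualTable, n_perm: int = 10_000, seed: int = 0):
    """Multilocus F_IS with a two-sided permutation test.

    The null shuffles gene copies among individuals within each locus
    (random union of gametes), recomputing F_IS each time; p is two-sided
    with the add-one convention.  Returns ``(fis, p, tier)`` where tier is
    the significance annotation (***/**/*/ns).
    """
    codes, _ = encode_genotypes(table)
    obs = _multilocus_fis(codes)
    rng = np.random.default_rng(seed)
    # gene diversity is invariant under the gene-copy shuffle, so only the
    # per-locus observed heterozygosity needs recomputing per permutation
    ho_null = np.zeros(n_perm)
    he_sum = 0.0
    for l in range(codes.shape[1]):
        g = codes[:, l, :]
        typed = g[:, 0] >= 0
        flat = g[typed].ravel()
        nc = flat.size
        if nc == 0:
            continue
        p_l = np.bincount(flat) / nc
        if nc > 1:
            he_sum += nc / (nc - 1) * (1.0 - np.sum(p_l**2))
        perms = rng.permuted(np.broadcast_to(flat, (n_perm, nc)).copy(), axis=1)
        pairs = perms.reshape(n_perm, nc // 2, 2)
        ho_null += (pairs[:, :, 0] != pairs[:, :, 1]).mean(axis=1)
    if he_sum == 0:
        raise ValueError("all loci monomorphic: F_IS undefined")
    null = 1.0 - ho_null / he_sum
    p_hi = (1 + np.sum(null >= obs)) / (n_perm + 1)
    p_lo = (1 + np.sum(null <= obs)) / (n_perm + 1)
    p = min(1.0, 2 * min(p_hi, p_lo))
    return obs, p, significance_tier(p)


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ----------------------------------------------------------------------
# Weir-Cockerham F_ST


def _wc_components(codes_a, codes_b):
    """Per-locus Weir-Cockerham (1984) variance components a, b, c summed
    over alleles, for two populations."""
    comps = []
    L = codes_a.shape[1]
    for l in range(L):
        pops = []
        for codes in (codes_a, codes_b):
            g = codes[:, l, :]
            g = g[g[:, 0] >= 0]
            if len(g) == 0:
                pops = None
                break
            pops.append(g)
        if pops is None:
            continue
        r = 2
        n_i = np.array([len(g) for g in pops], dtype=float)
        n_bar = n_i.mean()
        if n_bar == 0:
            continue
        nc = (r * n_bar - np.sum(n_i**2) / (r * n_bar)) / (r - 1)
        all_alleles = np.unique(np.concatenate([g.ravel() for g in pops]))
        a_sum = b_sum = c_sum = 0.0
        for al in all_alleles:
            p_i = np.array([np.mean(g == al) for g in pops])
            h_i = np.array([np.mean((g[:, 0] == al) != (g[:, 1] == al)) for g in pops])
            p_bar = np.sum(n_i * p_i) / (r * n_bar)
            s2 = np.sum(n_i * (p_i - p_bar) ** 2) / ((r - 1) * n_bar)
            h_bar = np.sum(n_i * h_i) / (r * n_bar)
            a = (n_bar / nc) * (
                s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c = h_bar / 2
            a_sum += a
            b_sum += b
            c_sum += c
        comps.append((a_sum, b_sum, c_sum))
    return comps


def _wc_fst(codes_a, codes_b):
    comps = _wc_components(codes_a, codes_b)
    num = sum(a for a, _, _ in comps)
    den = sum(a + b + c for a, b, c in comps)
    return num / den if den != 0 else np.nan


def pairwise_fst(tables: dict[str, IndividualTable], n_perm: int = 999, seed: int = 0):
    """Pairwise multilocus Weir-Cockerham theta between sites.

    Significance permutes individuals between the two sites.  Returns
    ``(fst_df, p_df)`` as pandas DataFrames.
    """
    import pandas as pd

    names = [k for k, t in tables.items() if t.n >= 2]
    rng = np.random.default_rng(seed)
    fst = pd.DataFrame(np.nan, index=names, columns=names)
    pval = pd.DataFrame(np.nan, index=names, columns=names)
    enc = {k: encode_genotypes(tables[k])[0] for k in names}
    for i, ka in enumerate(names):
        for kb in names[i + 1 :]:
            # re-encode on the union table so allele codes are shared
            ga, gb = _union_encode(tables[ka], tables[kb])
            obs = _wc_fst(ga, gb)
            pooled = np.concatenate([ga, gb], axis=0)
            na = len(ga)
            cnt = 0
            for _ in range(n_perm):
                idx = rng.permutation(len(pooled))
                t = _wc_fst(pooled[idx[:na]], pooled[idx[na:]])
                if t >= obs:
                    cnt += 1
            p = (1 + cnt) / (n_perm + 1)
            fst.loc[ka, kb] = fst.loc[kb, ka] = obs
            pval.loc[ka, kb] = pval.loc[kb, ka] = p
    _ = enc
    return fst, pval


def _union_encode(ta: IndividualTable, tb: IndividualTable):
    if ta.loci != tb.loci:
        raise ValueError("tables must share the same locus panel")
    n_a = ta.n
    merged_gen = np.concatenate([ta.genotypes, tb.genotypes], axis=0)
    L = len(ta.loci)
    codes = np.full((len(merged_gen), L, 2), -1, dtype=np.int32)
    for l in range(L):
        labs = sorted({a for a in merged_gen[:, l, :].ravel() if a is not None})
        lut = {a: k for k, a in enumerate(labs)}
        for i in range(len(merged_gen)):
            a, b = merged_gen[i, l]
            if a is not None:
                codes[i, l, 0] = lut[a]
                codes[i, l, 1] = lut[b]
    return codes[:n_a], codes[n_a:]


# ----------------------------------------------------------------------
# selfing


def selfing_from_fis(fis: float) -> float:
    """Equilibrium transform s = 2 F_IS / (1 + F_IS), clipped to [0, 1]."""
    if fis <= -1:
        raise ValueError("F_IS <= -1: equilibrium selfing undefined")
    return float(np.clip(2 * fis / (1 + fis), 0.0, 1.0))


def g2_identity_disequilibrium(table: IndividualTable):
    """Multilocus identity disequilibrium g2 (David et al. 2007 estimator,
    complete-data form applied to the typed subsets).

    g2 compares the rate of double heterozygosity within individuals
    across locus pairs with the rate expected if heterozygosity were
    independent among individuals:

        g2 = (N-1) * sum_{k!=l} m_kl / sum_{k!=l} (H_k H_l - m_kl) - 1

    where h_ik is the heterozygosity indicator of individual i at locus k,
    m_kl = sum_i h_ik h_il and H_k = sum_i h_ik.  Positive g2 indicates
    correlated heterozygosity deficits across loci (partial selfing).
    """
    codes, _ = encode_genotypes(table)
    n, L, _ = codes.shape
    typed = codes[:, :, 0] >= 0
    het = (codes[:, :, 0] != codes[:, :, 1]) & typed
    h = het.astype(float)
    # pairs where both loci typed in the same individual
    M = h.T @ h  # m_kl over individuals
    H = h.sum(axis=0)
    num = np.sum(M) - np.trace(M)
    cross = np.outer(H, H) - M
    den = np.sum(cross) - np.trace(cross)
    if den == 0:
        return np.nan
    return float((n - 1) * num / den - 1.0)


def g2_equilibrium(s: float) -> float:
    """Expected g2 at mixed-mating equilibrium for selfing rate s.

    With the selfing-class distribution P(n consecutive selfed
    generations) = (1-s) s^n and per-class heterozygosity proportional to
    2^-n, the across-locus heterozygosity correlation is

        g2(s) = E[4^-n] / E[2^-n]^2 - 1 = (2-s)^2 / ((4-s)(1-s)) - 1,

    which behaves as s/4 for small s.
    """
    if not 0 <= s < 1:
        raise ValueError("s must be in [0, 1)")
    return (2 - s) ** 2 / ((4 - s) * (1 - s)) - 1


def selfing_from_g2(g2: float) -> float:
    """Invert the mixed-mating equilibrium relation g2(s) (see
    :func:`g2_equilibrium`): g2 s^2 - (1 + 5 g2) s + 4 g2 = 0, taking the
    root in [0, 1]."""
    if not np.isfinite(g2) or g2 <= 0:
        return 0.0
    b = 1.0 + 5.0 * g2
    disc = max(b * b - 16.0 * g2 * g2, 0.0)
    s = (b - np.sqrt(disc)) / (2.0 * g2)
    return float(np.clip(s, 0.0, 1.0))


def selfing_rate(table: IndividualTable):
    """Selfing-rate estimates: (a) the F_IS equilibrium transform and
    (b) the g2 identity-disequilibrium route with jackknife-over-loci
    significance.  Returns a dict with both labelled estimates."""
    codes, _ = encode_genotypes(table)
    fis = _multilocus_fis(codes)
    s_fis = selfing_from_fis(fis) if fis > -1 else np.nan
    out = {"s_fis": s_fis, "fis": fis}
    poly = 0
    for l in range(table.n_loci):
        flat = codes[:, l, :].ravel()
        flat = flat[flat >= 0]
        if len(np.unique(flat)) > 1:
            poly += 1
    if poly < 2:
        out.update({"s_g2": np.nan, "g2": np.nan, "p_g2": np.nan, "tier": "ns"})
        return out
    g2 = g2_identity_disequilibrium(table)
    s_g2 = selfing_from_g2(g2)
    # jackknife over loci for a z-test of g2 > 0
    L = table.n_loci
    jack = []
    for l in range(L):
        keep = [k for k in range(L) if k != l]
        sub = table.subset(np.arange(table.n))
        sub.loci = [table.loci[k] for k in keep]
        sub.genotypes = table.genotypes[:, keep, :]
        jack.append(g2_identity_disequilibrium(sub))
    jack = np.array(jack, dtype=float)
    jack = jack[np.isfinite(jack)]
    if len(jack) > 1 and np.isfinite(g2):
        se = np.sqrt((len(jack) - 1) / len(jack) * np.sum((jack - jack.mean()) ** 2))
        p = 1.0 - norm.cdf(g2 / se) if se > 0 else (0.0 if g2 > 0 else 1.0)
    else:
        p = np.nan
    out.update(
        {"s_g2": s_g2, "g2": g2, "p_g2": p, "tier": significance_tier(p) if np.isfinite(p) else "ns"}
    )
    return out


# ----------------------------------------------------------------------
# plastid haplotype diversity


def plastid_diversity(table: IndividualTable):
    """Haplotype count, effective number (1 / sum p^2), and unbiased
    haplotype diversity n/(n-1) (1 - sum p^2)."""
    haps = [h for h in table.haplotypes if h is not None]
    n = len(haps)
    if n == 0:
        raise ValueError("no typed haplotypes")
    _, counts = np.unique(np.asarray(haps, dtype=object), return_counts=True)
    p = counts / n
    sum_p2 = float(np.sum(p**2))
    n_eff = 1.0 / sum_p2
    he = n / (n - 1) * (1.0 - sum_p2) if n > 1 else 0.0
    return {"n_haplotypes": len(counts), "effective_number": n_eff, "haplotype_he": he}


# ----------------------------------------------------------------------
# report


def diversity_report(
    table: IndividualTable,
    area_ha: float | None = None,
    k: int = 50,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """One-group summary row: N, density, A_R, H_O, H_E, F_IS (+tier), selfing."""
    freqs = allele_frequencies(table)
    _, ar = allelic_richness(freqs, k=k)
    ho, he = heterozygosities(table, freqs)
    fis, p_fis, tier = inbreeding_coefficient(table, n_perm=n_perm, seed=seed)
    selfing = selfing_rate(table)
    row = {
        "N": table.n,
        "density_ha": table.n / area_ha if area_ha else np.nan,
        "A_R": ar,
        "H_E": he,
        "H_O": ho,
        "F_IS": fis,
        "F_IS_p": p_fis,
        "F_IS_tier": tier,
        "selfing_g2": selfing["s_g2"],
        "selfing_fis": selfing["s_fis"],
        "selfing_tier": selfing["tier"],
    }
    try:
        row.update(plastid_diversity(table))
    except ValueError:
        pass
    return row
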