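"""Fine-scale spatial genetic structure (SGS).

Pairwise Loiselle kinship coefficients, distance-class autocorrelograms
with permutation envelopes, the kinship-on-ln(distance) regression slope
b_log, and the derived Sp statistic (-b_log / (1 - F_1)) and Wright's
neighbourhood size NS = 1/Sp.

The Loiselle estimator measures the correlation of allele-frequency
deviations between two individuals relative to the analyzed group's own
allele frequencies, with a finite-sample bias correction added to the
numerator; loci are weighted by their polymorphism by summing numerators
and denominators across loci before dividing.  A haploid mode treats the
plastid haplotype as a single multi-allelic locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DistanceMatrix, IndividualTable, encode_genotypes
from .diversity import AlleleFrequencies, allele_frequencies, significance_tier

#: Distance-class upper bounds (m) used throughout the package by default.
DEFAULT_CLASS_BOUNDS = [30.0, 60.0, 90.0, 130.0, 170.0, 220.0, 300.0, 600.0]


@dataclass
class DistanceClassSpec:
    """Half-open distance classes (lower, upper] from strictly increasing
    positive upper bounds; the first class is (0, bounds[0]]."""

    bounds: list[float]

    def __post_init__(self):
        b = list(self.bounds)
        if not b or any(x <= 0 for x in b) or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("bounds must be strictly increasing and positive")
        self.bounds = b

    def assign(self, d: np.ndarray) -> np.ndarray:
        """Class index per distance; -1 for d <= 0 or beyond the last bound."""
        idx = np.searchsorted(self.bounds, d, side="left")
        idx[d <= 0] = -1
        idx[d > self.bounds[-1]] = -1
        return idx

    @property
    def n_classes(self) -> int:
        return len(self.bounds)


@dataclass
class KinshipMatrix:
    """Symmetric pairwise Loiselle kinship with per-pair typed-locus counts."""

    values: np.ndarray  # (n, n) float, NaN where below min_loci
    n_loci_pair: np.ndarray  # (n, n) int
    mode: str  # "diploid" | "haploid"
    ids: np.ndarray | None = None


@dataclass
class SGSResult:
    classes: pd.DataFrame  # upper_bound, mean_kinship, n_pairs, env_lo, env_hi
    f1: float
    b_log: float
    sp: float
    ns: float
    p_b: float
    tier: str
    n_perm: int
    mode: str
    n_zero_distance_excluded: int = 0


# ----------------------------------------------------------------------
# kinship


def loiselle_kinship(
    table: IndividualTable,
    freqs: AlleleFrequencies | None = None,
    mode: str = "diploid",
    min_loci: int | None = None,
) -> KinshipMatrix:
    """Multilocus Loiselle kinship matrix.

    Per locus l and allele a, individual i carries an allele frequency
    p_ila in {0, 1/2, 1} (diploid) or {0, 1} (haploid).  With p̄_la the
    group frequency over the n_l typed individuals:

        num_l(i,j) = sum_a (p_ila - p̄_la)(p_jla - p̄_la) + sum_a p̄_la(1-p̄_la)/(m_l - 1)
        den_l      = sum_a p̄_la (1 - p̄_la)

    where m_l is the number of typed gene copies (2 n_l diploid, n_l
    haploid); the added term removes the finite-sample bias so the
    estimator is centered on zero for unrelated pairs.

    and F_ij = sum_l num_l / sum_l den_l over loci typed in both i and j.
    Pairs sharing fewer than ``min_loci`` typed loci (default 20 diploid,
    1 haploid) are set to NaN.
    """
    if mode not in ("diploid", "haploid"):
        raise ValueError("mode must be diploid or haploid")
    if min_loci is None:
        min_loci = 20 if mode == "diploid" else 1
    n = table.n
    if mode == "diploid":
        codes, alleles = encode_genotypes(table)
        L = table.n_loci
        typed = codes[:, :, 0] >= 0

        def locus_profile(l):
            k = len(alleles[l])
            X = np.zeros((n, k))
            g = codes[:, l, :]
            t = typed[:, l]
            for c in range(2):
                X[np.arange(n)[t], g[t, c]] += 0.5
            return X, t
    else:
        hap_labels = sorted({h for h in table.haplotypes if h is not None})
        lut = {h: i for i, h in enumerate(hap_labels)}
        L = 1
        typed = np.array([[h is not None] for h in table.haplotypes])

        def locus_profile(l):
            X = np.zeros((n, len(hap_labels)))
            for i, h in enumerate(table.haplotypes):
                if h is not None:
                    X[i, lut[h]] = 1.0
            return X, typed[:, 0]

    NUM = np.zeros((n, n))
    DEN = np.zeros((n, n))
    CNT = np.zeros((n, n), dtype=int)
    any_poly = False
    for l in range(L):
        X, t = locus_profile(l)
        n_l = int(t.sum())
        if n_l < 2:
            continue
        pbar = X[t].sum(axis=0) / n_l
        den_l = float(np.sum(pbar * (1.0 - pbar)))
        if den_l <= 0:
            continue
        any_poly = True
        m_copies = 2 * n_l if mode == "diploid" else n_l
        corr = den_l / (m_copies - 1)
        Xc = np.where(t[:, None], X - pbar[None, :], 0.0)
        Nl = Xc @ Xc.T
        pair_t = np.outer(t, t)
        NUM += np.where(pair_t, Nl + corr, 0.0)
        DEN += np.where(pair_t, den_l, 0.0)
        CNT += pair_t.astype(int)
    if not any_poly:
        raise ValueError("all loci monomorphic: kinship undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        F = NUM / DEN
    F[CNT < min_loci] = np.nan
    F = (F + F.T) / 2
    return KinshipMatrix(values=F, n_loci_pair=CNT, mode=mode, ids=table.ids)


# ----------------------------------------------------------------------
# pair extraction and regression


def _pairs(kinship: KinshipMatrix, distances: DistanceMatrix):
    n = kinship.values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    f = kinship.values[iu, ju]
    d = distances.values[iu, ju]
    ok = np.isfinite(f)
    return iu[ok], ju[ok], f[ok], d[ok]


def _slope(f: np.ndarray, d: np.ndarray) -> float:
    """Least-squares slope of pairwise kinship on ln(distance)."""
    x = np.log(d)
    xm, fm = x.mean(), f.mean()
    vx = np.sum((x - xm) ** 2)
    if vx == 0:
        return np.nan
    return float(np.sum((x - xm) * (f - fm)) / vx)


def slope_over_range(
    kinship: KinshipMatrix,
    distances: DistanceMatrix,
    d_min: float,
    d_max: float,
    min_pairs: int = 10,
) -> float:
    """b_log restricted to pairs with d_min < d <= d_max."""
    if d_min >= d_max:
        raise ValueError("d_min must be < d_max")
    _, _, f, d = _pairs(kinship, distances)
    sel = (d > d_min) & (d <= d_max) & (d > 0)
    n_sel = int(sel.sum())
    if n_sel < min_pairs:
        raise TooFewPairsError(n_sel, f"only {n_sel} pairs in ({d_min}, {d_max}]")
    return _slope(f[sel], d[sel])


class TooFewPairsError(ValueError):
    def __init__(self, count, msg):
        super().__init__(msg)
        self.count = count


# ----------------------------------------------------------------------
# autocorrelogram


def autocorrelogram(
    kinship: KinshipMatrix,
    distances: DistanceMatrix,
    spec: DistanceClassSpec | list[float] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> SGSResult:
    """Distance-class correlogram with permutation envelopes and Sp.

    Per-class mean kinship over pairs whose distance falls in the class;
    F_1 is the first-class mean; b_log is the least-squares slope of the
    pairwise kinship on ln(distance) over all positive-distance pairs.
    The null permutes individual locations (index permutation of the
    distance matrix) keeping kinship fixed; envelopes are the 2.5/97.5
    percentiles of null class means and the Sp/b_log p-value is two-sided
    on the null slope distribution with the add-one convention.
    """
    if spec is None:
        spec = DistanceClassSpec(DEFAULT_CLASS_BOUNDS)
    elif not isinstance(spec, DistanceClassSpec):
        spec = DistanceClassSpec(list(spec))
    n = kinship.values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    fin = np.isfinite(kinship.values[iu, ju])
    iu, ju = iu[fin], ju[fin]
    f = kinship.values[iu, ju]
    K = spec.n_classes

    def class_stats(d):
        cls = spec.assign(d)
        ok = cls >= 0
        counts = np.bincount(cls[ok], minlength=K)[:K]
        sums = np.bincount(cls[ok], weights=f[ok], minlength=K)[:K]
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return means, counts

    d_obs = distances.values[iu, ju]
    means, counts = class_stats(d_obs)
    if counts[0] == 0:
        raise ValueError("empty first distance class: F_1 undefined")
    f1 = float(means[0])
    pos = d_obs > 0
    n_zero = int((~pos).sum())
    b_obs = _slope(f[pos], d_obs[pos])

    rng = np.random.default_rng(seed)
    null_means = np.empty((n_perm, K))
    null_b = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        d_p = distances.values[perm[iu], perm[ju]]
        m_p, _ = class_stats(d_p)
        null_means[b] = m_p
        posp = d_p > 0
        null_b[b] = _slope(f[posp], d_p[posp])
    if n_perm > 0:
        env_lo = np.nanpercentile(null_means, 2.5, axis=0)
        env_hi = np.nanpercentile(null_means, 97.5, axis=0)
        p_hi = (1 + np.sum(null_b >= b_obs)) / (n_perm + 1)
        p_lo = (1 + np.sum(null_b <= b_obs)) / (n_perm + 1)
        p_b = min(1.0, 2 * min(p_hi, p_lo))
    else:
        env_lo = np.full(K, np.nan)
        env_hi = np.full(K, np.nan)
        p_b = np.nan

    sp = -b_obs / (1.0 - f1) if f1 < 1 else np.nan
    ns = 1.0 / sp if np.isfinite(sp) and sp != 0 else np.inf
    classes = pd.DataFrame(
        {
            "upper_bound_m": spec.bounds,
            "mean_kinship": means,
            "n_pairs": counts,
            "env_lo": env_lo,
            "env_hi": env_hi,
        }
    )
    return SGSResult(
        classes=classes,
        f1=f1,
        b_log=b_obs,
        sp=float(sp),
        ns=float(ns),
        p_b=float(p_b) if np.isfinite(p_b) else np.nan,
        tier=significance_tier(p_b) if np.isfinite(p_b) else "ns",
        n_perm=n_perm,
        mode=kinship.mode,
        n_zero_distance_excluded=n_zero,
    )


def sp_statistic(f1: float, b_log: float) -> float:
    """Sp = -b_log / (1 - F_1): the strength of spatial genetic structure."""
    if f1 >= 1:
        raise ValueError("F_1 must be < 1")
    return -b_log / (1.0 - f1)


def neighbourhood_size(sp: float) -> float:
    """Wright's neighbourhood size NS = 1/Sp (infinite when Sp = 0)."""
    return np.inf if sp == 0 else 1.0 / sp


def plot_correlogram(result: SGSResult, path, title: str | None = None):
    """Write a correlogram figure: per-class mean kinship against distance
    with the permutation envelope shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cl = result.classes
    fig, ax = plt.subplots(figsize=(6, 4))
    x = cl["upper_bound_m"]
    ax.fill_between(x, cl["env_lo"], cl["env_hi"], color="0.85", label="95% null envelope")
    ax.plot(x, cl["mean_kinship"], "o-", color="C0", label="mean $F_{ij}$")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xscale("log")
    ax.set_xlabel("distance class upper bound (m)")
    ax.set_ylabel("kinship $F_{ij}$")
    ax.legend(frameon=False, fontsize=8)
    if title is None:
        title = f"{result.mode}: Sp = {result.sp:.4f} ({result.tier})"
    ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def sgs_analysis(
    table: IndividualTable,
    mode: str = "diploid",
    spec=None,
    n_perm: int = 10_000,
    seed: int = 0,
    min_loci: int | None = None,
) -> SGSResult:
    """Convenience wrapper: group frequencies -> kinship -> correlogram."""
    from .core import pairwise_distances

    freqs = allele_frequencies(table) if mode == "diploid" else None
    kin = loiselle_kinship(table, freqs, mode=mode, min_loci=min_loci)
    dist = pairwise_distances(table, mode="planar" if table.coord_mode == "planar" else None)
    return autocorrelogram(kin, dist, spec=spec, n_perm=n_perm, seed=seed)
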