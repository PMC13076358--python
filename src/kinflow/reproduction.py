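"""Reproductive success, size effects, and reproductive-skew inference.

Tallies offspring per adult (as mother, as father, and total over all
concordant assignments), regresses reproductive output on stem diameter,
compares maternal vs paternal output with a paired Wilcoxon signed-rank
test, and quantifies skew with the Gini index plus pairwise
permutation tests between sites (pooling and reassigning individual
outputs at the original sample sizes).

Conventions: all adults are potential parents, so zero-count adults are
included in the Gini by default (skew among potential breeders); a
selfed offspring adds one to its parent's mother-count and one to its
father-count, hence two to the total.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import IndividualTable
from .contemporary import RoleResolvedTrio
from .parentage import FamilyClusters, ParentageAssignment


def tally_success(
    adults: IndividualTable,
    assignments: list[ParentageAssignment],
    trios: list[RoleResolvedTrio] | None = None,
) -> pd.DataFrame:
    """Per-adult offspring counts.

    ``total`` counts each assigned offspring once per parental slot from
    the (merged) assignments; ``as_mother`` / ``as_father`` come from the
    role-resolved trios when given (zero otherwise).
    """
    ids = [str(i) for i in adults.ids]
    df = pd.DataFrame(
        {"individual_id": ids, "dbh": adults.dbh, "as_mother": 0, "as_father": 0, "total": 0}
    ).set_index("individual_id")
    for a in assignments:
        if a.pair is None:
            continue
        for p in (a.parent1_id, a.parent2_id):
            if p in df.index:
                df.loc[p, "total"] += 1
    if trios:
        for t in trios:
            if t.basis != "plastid-match":
                continue
            if t.mother_id in df.index:
                df.loc[t.mother_id, "as_mother"] += 1
            if t.father_id in df.index:
                df.loc[t.father_id, "as_father"] += 1
    return df.reset_index()


def dbh_fecundity_regression(success: pd.DataFrame):
    """OLS of total offspring count on DBH: (slope, r_squared, p_value)."""
    d = success.dropna(subset=["dbh"])
    if len(d) < 3:
        raise ValueError("need at least 3 adults with DBH")
    if d["dbh"].nunique() < 2:
        raise ValueError("zero DBH variance: regression undefined")
    res = stats.linregress(d["dbh"], d["total"])
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)


def role_balance_test(success: pd.DataFrame):
    """Paired Wilcoxon signed-rank of mother-count vs father-count over
    adults with >= 1 offspring in either role; zero-difference pairs are
    dropped per the standard procedure.  Returns (statistic, p, flag)."""
    d = success[(success["as_mother"] > 0) | (success["as_father"] > 0)]
    x = d["as_mother"].to_numpy(dtype=float)
    y = d["as_father"].to_numpy(dtype=float)
    if len(x) == 0 or np.all(x == y):
        return np.nan, 1.0, "all_differences_zero"
    res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
    return float(res.statistic), float(res.pvalue), ""


def gini(counts) -> float:
    """Sample Gini index G = sum_ij |x_i - x_j| / (2 n^2 mean), without
    small-sample correction.  Requires nonnegative, not-all-zero counts."""
    x = np.asarray(counts, dtype=float)
    if len(x) == 0 or np.any(x < 0):
        raise ValueError("counts must be nonnegative and nonempty")
    if np.all(x == 0):
        raise ValueError("all counts zero: Gini undefined")
    xs = np.sort(x)
    n = len(xs)
    # O(n log n) form of the mean absolute difference
    cum = np.cumsum(xs)
    g = (2.0 * np.sum(np.arange(1, n + 1) * xs) - (n + 1) * cum[-1]) / (n * cum[-1])
    return float(g)


def gini_permutation_test(
    site_counts: dict[str, np.ndarray],
    n_perm: int = 10_000,
    seed: int = 0,
    holm: bool = False,
) -> pd.DataFrame:
    """Pairwise permutation tests of Gini differences between sites.

    Observed statistic |G_a - G_b|; the null pools the two sites' counts
    and randomly reassigns them at the original sizes; p uses the add-one
    convention.  Sites with fewer than 2 adults are skipped.  No
    multiplicity correction by default; ``holm=True`` applies Holm
    step-down adjustment across the site pairs.
    """
    rng = np.random.default_rng(seed)
    names = [k for k, v in site_counts.items() if len(v) >= 2]
    p = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            xa = np.asarray(site_counts[a], dtype=float)
            xb = np.asarray(site_counts[b], dtype=float)
            obs = abs(gini(xa) - gini(xb))
            pool = np.concatenate([xa, xb])
            na = len(xa)
            cnt = 0
            for _ in range(n_perm):
                rng.shuffle(pool)
                pa, pb = pool[:na], pool[na:]
                if np.all(pa == 0) or np.all(pb == 0):
                    cnt += 1  # degenerate split counts as extreme
                    continue
                if abs(gini(pa) - gini(pb)) >= obs:
                    cnt += 1
            p.loc[a, b] = p.loc[b, a] = (1 + cnt) / (n_perm + 1)
    if holm and len(names) >= 2:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
        raw = np.array([p.loc[a, b] for a, b in pairs])
        order = np.argsort(raw)
        m = len(raw)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * raw[idx])
            adj[idx] = min(1.0, running)
        for (a, b), v in zip(pairs, adj):
            p.loc[a, b] = p.loc[b, a] = v
    return p


def cluster_summary(clusters: FamilyClusters) -> pd.DataFrame:
    """Per-cluster offspring totals plus the top-cluster share.

    The share of the largest cluster is stored in
    ``df.attrs['max_cluster_share']``.
    """
    rows = [
        {"cluster": k + 1, "n_offspring": c["size"], "n_parents": len(c["parents"])}
        for k, c in enumerate(clusters.clusters)
    ]
    df = pd.DataFrame(rows, columns=["cluster", "n_offspring", "n_parents"])
    total = df["n_offspring"].sum()
    df.attrs["max_cluster_share"] = (
        float(df["n_offspring"].max() / total) if total else np.nan
    )
    df.attrs["n_clusters"] = len(df)
    return df
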