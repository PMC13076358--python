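"""Contemporary dispersal from parentage: maternity resolution by plastid
haplotype, seed/pollen dispersal distances, and bootstrap CIs.

Maternity rule: within an assigned parent pair, the parent sharing the
offspring's maternally inherited plastid haplotype is the mother,
provided the other parent carries a *different* haplotype.  Pairs where
both parents match are unresolved (ambiguous maternity) and pairs where
neither matches are conflicts (genotyping error or wrong pair); both are
excluded from distance summaries but logged.

Seed distance is mother-to-offspring; pollen distance is
father-to-mother (the mating event).  The father-to-offspring distance is
also emitted as an auxiliary column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import IndividualTable
from .parentage import ParentageAssignment


@dataclass
class RoleResolvedTrio:
    offspring_id: str
    mother_id: str | None
    father_id: str | None
    basis: str  # "plastid-match" | "unresolved" | "conflict"
    seed_distance: float = np.nan
    pollen_distance: float = np.nan
    father_offspring_distance: float = np.nan


def resolve_roles(
    assignments: list[ParentageAssignment], table: IndividualTable
) -> list[RoleResolvedTrio]:
    """Apply the plastid maternity rule to each two-parent assignment."""
    hap = {str(i): h for i, h in zip(table.ids, table.haplotypes)}
    out = []
    for a in assignments:
        if a.pair is None:
            continue
        p1, p2 = a.parent1_id, a.parent2_id
        ho = hap.get(a.offspring_id)
        h1, h2 = hap.get(p1), hap.get(p2)
        if p1 == p2:
            # selfed pair: mother = father by construction
            if ho is not None and h1 is not None and ho == h1:
                out.append(RoleResolvedTrio(a.offspring_id, p1, p1, "plastid-match"))
            else:
                out.append(RoleResolvedTrio(a.offspring_id, None, None, "conflict" if None not in (ho, h1) else "unresolved"))
            continue
        if ho is None or h1 is None or h2 is None:
            out.append(RoleResolvedTrio(a.offspring_id, None, None, "unresolved"))
            continue
        m1, m2 = ho == h1, ho == h2
        if m1 and not m2:
            out.append(RoleResolvedTrio(a.offspring_id, p1, p2, "plastid-match"))
        elif m2 and not m1:
            out.append(RoleResolvedTrio(a.offspring_id, p2, p1, "plastid-match"))
        elif m1 and m2:
            out.append(RoleResolvedTrio(a.offspring_id, None, None, "unresolved"))
        else:
            out.append(RoleResolvedTrio(a.offspring_id, None, None, "conflict"))
    return out


def dispersal_distances(
    trios: list[RoleResolvedTrio], table: IndividualTable
) -> pd.DataFrame:
    """Per-event seed and pollen distances for resolved trios.

    Uses planar distances (lon/lat tables are projected first).  Events
    with missing coordinates are dropped with a count recorded in
    ``df.attrs['n_dropped']``.
    """
    t = table.to_planar()
    pos = {str(i): t.coords[k] for k, i in enumerate(t.ids)}
    rows, dropped = [], 0
    for tr in trios:
        if tr.basis != "plastid-match":
            continue
        try:
            po = pos[tr.offspring_id]
            pm = pos[tr.mother_id]
            pf = pos[tr.father_id]
        except KeyError:
            dropped += 1
            continue
        if np.isnan(po).any() or np.isnan(pm).any() or np.isnan(pf).any():
            dropped += 1
            continue
        rows.append(
            {
                "offspring_id": tr.offspring_id,
                "mother_id": tr.mother_id,
                "father_id": tr.father_id,
                "seed_dist_m": float(np.hypot(*(po - pm))),
                "pollen_dist_m": float(np.hypot(*(pf - pm))),
                "father_offspring_dist_m": float(np.hypot(*(pf - po))),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "offspring_id",
            "mother_id",
            "father_id",
            "seed_dist_m",
            "pollen_dist_m",
            "father_offspring_dist_m",
        ],
    )
    df.attrs["n_dropped"] = dropped
    return df


def bootstrap_mean_ci(values, n_boot: int = 10_000, seed: int = 0, level: float = 0.95):
    """Percentile bootstrap CI of the mean.

    Returns ``(mean, half_width, (lo, hi))``; half_width is reported the
    way dispersal tables quote "mean ± hw".  Requires n >= 2.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 2:
        raise ValueError("need at least 2 values for a bootstrap CI")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(v), size=(n_boot, len(v)))
    means = v[idx].mean(axis=1)
    a = (1.0 - level) / 2
    lo, hi = np.quantile(means, [a, 1 - a])
    mean = float(v.mean())
    return mean, float((hi - lo) / 2), (float(lo), float(hi))


def dispersal_summary(
    events: pd.DataFrame, n_boot: int = 10_000, seed: int = 0
) -> dict:
    """Site-level summary: mean/median seed and pollen distances with
    bootstrap CI half-widths for the means."""
    out = {"n_events": len(events), "n_boot": n_boot}
    for kind in ("seed", "pollen"):
        v = events[f"{kind}_dist_m"].to_numpy()
        out[f"mean_{kind}_m"] = float(np.mean(v)) if len(v) else np.nan
        out[f"median_{kind}_m"] = float(np.median(v)) if len(v) else np.nan
        if len(v) >= 2:
            _, hw, _ = bootstrap_mean_ci(v, n_boot=n_boot, seed=seed)
            out[f"ci_half_width_{kind}_m"] = hw
        else:
            out[f"ci_half_width_{kind}_m"] = np.nan
    return out


def distance_histogram(values, bin_width: float = 10.0) -> pd.DataFrame:
    """Event counts in fixed-width distance bins (10 m default), for
    dispersal barcharts."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return pd.DataFrame(columns=["bin_lo_m", "bin_hi_m", "count"])
    n_bins = int(np.floor(v.max() / bin_width)) + 1
    edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
    counts, _ = np.histogram(v, bins=edges)
    return pd.DataFrame(
        {"bin_lo_m": edges[:-1], "bin_hi_m": edges[1:], "count": counts}
    )
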