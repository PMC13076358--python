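"""End-to-end orchestration: one config in, report bundle out.

Stage order: diversity -> SGS (nuclear and plastid, per size class) ->
historical dispersal decomposition -> parentage (likelihood + exclusion,
concordance merge) -> contemporary dispersal (maternity resolution,
distances, bootstrap CIs) -> reproductive success and skew.  Outputs are
per-site CSV report tables (diversity, SGS, historical and contemporary
dispersal, reproduction),
correlogram data, dispersal histograms (10 m bins), family-cluster
summaries, and a YAML manifest recording every seed and parameter so a
run is fully reconstructible.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import IndividualTable, load_individuals, pairwise_distances, split_size_classes
from .diversity import allele_frequencies, diversity_report, pairwise_fst
from .sgs import DEFAULT_CLASS_BOUNDS, DistanceClassSpec, autocorrelogram, loiselle_kinship
from .history import dispersal_history
from .parentage import (
    GenotypingErrorModel,
    assign_exclusion,
    assign_likelihood,
    assignment_rates,
    assignments_to_frame,
    calibrate_thresholds,
    concordant,
    sibship_clusters,
)
from .contemporary import (
    dispersal_distances,
    dispersal_summary,
    distance_histogram,
    resolve_roles,
)
from .reproduction import (
    cluster_summary,
    dbh_fecundity_regression,
    gini,
    gini_permutation_test,
    role_balance_test,
    tally_success,
)


@dataclass
class PipelineConfig:
    """Everything one run needs; every stochastic stage has its own seed."""

    input_csvs: list[str] | None = None  # one per site; None -> simulate preset
    site_areas_ha: dict[str, float] = field(default_factory=dict)
    size_threshold_cm: float = 30.0
    distance_classes: list[float] = field(default_factory=lambda: list(DEFAULT_CLASS_BOUNDS))
    n_perm_diversity: int = 10_000
    n_perm_sgs: int = 10_000
    n_perm_gini: int = 10_000
    n_boot: int = 10_000
    de_fraction: float = 0.25
    error_rate: float = 0.01
    calib_n_sim: int = 10_000
    calib_n_candidates: int = 500
    calib_prop_sampled: float = 0.25
    calibrate: bool = True
    seed: int = 1
    out_dir: str = "kinflow_out"

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def run_pipeline(config: PipelineConfig, tables: dict[str, IndividualTable] | None = None):
    """Run the full analysis; returns a dict of output DataFrames and
    writes everything under ``config.out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(0, 2**31 - 1)) for k in
             ("diversity", "sgs", "calibration", "boot", "gini")}

    if min(config.n_perm_diversity, config.n_perm_sgs, config.n_perm_gini) < 100:
        warnings.warn("permutation counts < 100: significance tiers are unreliable")

    if tables is None:
        if not config.input_csvs:
            raise ValueError("either input_csvs or in-memory tables are required")
        tables = {}
        for path in config.input_csvs:
            t = load_individuals(path)
            for s, sub in t.by_site().items():
                tables[s] = sub

    spec = DistanceClassSpec(config.distance_classes)
    div_rows, sgs_rows, sgs_classes, hist_rows = [], [], [], []
    contemp_rows, repro_rows, cluster_rows, hist_bins = [], [], [], []
    site_counts = {}

    for stage, site in enumerate(sorted(tables)):
        table = tables[site].to_planar()
        area = config.site_areas_ha.get(site, np.nan)
        part = split_size_classes(table, config.size_threshold_cm)
        groups = {"SSS": part.sss, "ADL": part.adl}

        # --- diversity
        for gname, g in groups.items():
            if g.n < 2:
                continue
            row = diversity_report(
                g, area_ha=area, n_perm=config.n_perm_diversity, seed=seeds["diversity"] + stage
            )
            div_rows.append({"site": site, "size_class": gname, **row})

        # --- SGS per group and marker mode
        kin_cache = {}
        for gname, g in groups.items():
            if g.n < 10:
                continue
            dist = pairwise_distances(g, mode="planar")
            for mode_name, mode in (("nuclear", "diploid"), ("plastid", "haploid")):
                try:
                    kin = loiselle_kinship(g, mode=mode)
                    res = autocorrelogram(
                        kin, dist, spec=spec, n_perm=config.n_perm_sgs, seed=seeds["sgs"] + stage
                    )
                except ValueError as e:
                    # keep the row, flagged, so report tables never silently
                    # lose a site/group
                    sgs_rows.append(
                        {
                            "site": site, "size_class": gname, "marker": mode_name,
                            "F1": np.nan, "b_log": np.nan, "Sp": np.nan,
                            "NS": np.nan, "p": np.nan, "tier": "ns",
                            "flag": str(e),
                        }
                    )
                    continue
                kin_cache[(gname, mode_name)] = (kin, dist)
                sgs_rows.append(
                    {
                        "site": site,
                        "size_class": gname,
                        "marker": mode_name,
                        "F1": res.f1,
                        "b_log": res.b_log,
                        "Sp": res.sp,
                        "NS": res.ns,
                        "p": res.p_b,
                        "tier": res.tier,
                        "flag": "",
                    }
                )
                cl = res.classes.copy()
                cl.insert(0, "marker", mode_name)
                cl.insert(0, "size_class", gname)
                cl.insert(0, "site", site)
                sgs_classes.append(cl)

        # --- historical dispersal (adults)
        adl = part.adl
        if np.isfinite(area) and adl.n >= 10 and ("ADL", "nuclear") in kin_cache:
            kin_n, dist_a = kin_cache[("ADL", "nuclear")]
            if ("ADL", "plastid") in kin_cache:
                kin_p, _ = kin_cache[("ADL", "plastid")]
                est = dispersal_history(
                    kin_n, kin_p, dist_a, adl.n / area, de_fraction=config.de_fraction, spec=spec
                )
                hist_rows.append(
                    {
                        "site": site,
                        "De_per_m2": est.d_e,
                        "sigma_g_m": est.sigma_g.sigma,
                        "sigma_g_converged": est.sigma_g.converged,
                        "sigma_s_m": est.sigma_s.sigma,
                        "sigma_s_converged": est.sigma_s.converged,
                        "sigma_p_m": est.sigma_p,
                        "ratio_p_s": est.ratio_p_s,
                        "ratio_s_g": est.ratio_s_g,
                        "flag": est.sigma_p_flag or est.sigma_g.flag or est.sigma_s.flag,
                    }
                )

        # --- parentage
        if part.sss.n == 0 or adl.n < 2:
            continue
        freqs = allele_frequencies(table)
        err = GenotypingErrorModel(config.error_rate)
        thresholds = None
        if config.calibrate:
            thresholds = calibrate_thresholds(
                freqs,
                n_sim_offspring=config.calib_n_sim,
                n_candidates=config.calib_n_candidates,
                prop_sampled=config.calib_prop_sampled,
                error_model=err,
                seed=seeds["calibration"] + stage,
            )
        a_lik = assign_likelihood(part.sss, adl, freqs, thresholds, error_model=err)
        a_exc = assign_exclusion(part.sss, adl)
        merged = concordant(a_lik, a_exc)
        assignments_to_frame(merged).to_csv(
            os.path.join(config.out_dir, f"assignments_{site}.csv"), index=False
        )
        rates = assignment_rates(part.sss.ids, a_lik, a_exc, merged)

        # --- contemporary dispersal
        trios = resolve_roles(merged, table)
        events = dispersal_distances(trios, table)
        summ = dispersal_summary(events, n_boot=config.n_boot, seed=seeds["boot"] + stage)
        n_resolved = sum(1 for t in trios if t.basis == "plastid-match")
        contemp_rows.append(
            {
                "site": site,
                "density_adl_ha": adl.n / area if np.isfinite(area) else np.nan,
                "n_adl": adl.n,
                "n_sss": part.sss.n,
                "pct_likelihood": rates["pct_method_a"],
                "pct_exclusion": rates["pct_method_b"],
                "pct_concordant": rates["pct_concordant"],
                "pct_mother_identified": 100.0 * n_resolved / part.sss.n,
                **summ,
            }
        )
        for kind in ("seed", "pollen"):
            hb = distance_histogram(events[f"{kind}_dist_m"])
            hb.insert(0, "kind", kind)
            hb.insert(0, "site", site)
            hist_bins.append(hb)

        # --- reproduction
        success = tally_success(adl, merged, trios)
        site_counts[site] = success["total"].to_numpy()
        row = {"site": site}
        try:
            row["dbh_slope"], row["dbh_r2"], row["dbh_p"] = dbh_fecundity_regression(success)
        except ValueError as e:
            row["dbh_flag"] = str(e)
        row["wilcoxon_stat"], row["wilcoxon_p"], row["wilcoxon_flag"] = role_balance_test(success)
        try:
            row["gini"] = gini(success["total"])
        except ValueError:
            row["gini"] = np.nan
        repro_rows.append(row)
        clusters = sibship_clusters(merged)
        cs = cluster_summary(clusters)
        cs.insert(0, "site", site)
        cs["max_cluster_share"] = cs.attrs["max_cluster_share"]
        cluster_rows.append(cs)

    out = {}
    out["diversity"] = pd.DataFrame(div_rows)
    out["sgs"] = pd.DataFrame(sgs_rows)
    out["sgs_classes"] = pd.concat(sgs_classes, ignore_index=True) if sgs_classes else pd.DataFrame()
    out["dispersal_history"] = pd.DataFrame(hist_rows)
    out["contemporary"] = pd.DataFrame(contemp_rows)
    out["reproduction"] = pd.DataFrame(repro_rows)
    out["clusters"] = pd.concat(cluster_rows, ignore_index=True) if cluster_rows else pd.DataFrame()
    out["dispersal_histograms"] = pd.concat(hist_bins, ignore_index=True) if hist_bins else pd.DataFrame()
    if len(site_counts) >= 2:
        valid = {k: v for k, v in site_counts.items() if np.any(v > 0)}
        if len(valid) >= 2:
            out["gini_pairwise_p"] = gini_permutation_test(
                valid, n_perm=config.n_perm_gini, seed=seeds["gini"]
            )
    if len(tables) >= 2:
        fst, fst_p = pairwise_fst(
            {k: t.to_planar() for k, t in tables.items()},
            n_perm=min(config.n_perm_diversity, 999),
            seed=seeds["diversity"],
        )
        out["fst"] = fst
        out["fst_p"] = fst_p
        fst.to_csv(os.path.join(config.out_dir, "pairwise_fst.csv"))
        fst_p.to_csv(os.path.join(config.out_dir, "pairwise_fst_p.csv"))

    names = {
        "diversity": "diversity_report.csv",
        "sgs": "sgs_summary.csv",
        "sgs_classes": "correlograms.csv",
        "dispersal_history": "dispersal_history.csv",
        "contemporary": "contemporary_dispersal.csv",
        "reproduction": "reproduction.csv",
        "clusters": "clusters.csv",
        "dispersal_histograms": "dispersal_histograms.csv",
        "gini_pairwise_p": "gini_pairwise_p.csv",
    }
    for key, fname in names.items():
        if key in out:
            out[key].to_csv(os.path.join(config.out_dir, fname), index=False)

    manifest = {
        "kinflow_version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
        "conventions": {
            "dbh_at_threshold": "ADL",
            "slope_regression": "pairwise kinship on ln(distance)",
            "permutation_unit_sgs": "individual locations",
            "pollen_distance": "father to mother",
            "bootstrap": "percentile",
            "gini_includes_zero_count_adults": True,
            "distance_mode": "planar",
        },
    }
    with open(os.path.join(config.out_dir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    out["manifest"] = manifest
    return out
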