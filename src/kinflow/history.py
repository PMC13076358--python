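"""Historical dispersal distances from SGS under drift-dispersal equilibrium.

At isolation-by-distance equilibrium in two dimensions, the Sp statistic
approximates 1/(4*pi*D_e*sigma_g^2) for biparentally inherited nuclear
markers and 1/(2*pi*D_e*sigma_s^2) for maternally inherited plastid
markers, where D_e is the effective population density and sigma^2 is the
*axial* dispersal variance — half the mean squared parent-offspring
distance.  Inverting these relations yields historical gene (sigma_g) and
seed (sigma_s) dispersal distances; the pollen component follows from

    sigma_g^2 = sigma_s^2 + (1/2) sigma_p^2

because a seed carries two pollen-dispersed half-genomes per
seed-dispersed diploid genome.

Because the equilibrium slope applies over a restricted distance range
(roughly sigma to 20*sigma), sigma is estimated iteratively: start from
the full-range Sp, refit the kinship-ln(distance) slope over
(sigma, 20*sigma], recompute Sp and sigma, and repeat to convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DistanceMatrix
from .sgs import (
    DistanceClassSpec,
    KinshipMatrix,
    TooFewPairsError,
    _pairs,
    _slope,
    slope_over_range,
    sp_statistic,
)

HA = 10_000.0


def effective_density(census_adult_density_ha: float, fraction: float = 0.25) -> float:
    """Effective density D_e in individuals per m^2.

    ``fraction`` (default 0.25) scales the census adult density to account
    for variable age-related mortality and fertility: only a fraction of
    standing adults effectively reproduce in a given season.
    """
    if census_adult_density_ha <= 0:
        raise ValueError("census density must be positive")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return fraction * census_adult_density_ha / HA


def sigma_from_sp(sp: float, d_e: float, marker_mode: str) -> float:
    """Invert Sp ≈ 1/(c*pi*D_e*sigma^2), c = 4 (nuclear) or 2 (plastid)."""
    if sp <= 0:
        raise ValueError("Sp must be positive to invert")
    c = 4.0 if marker_mode == "nuclear" else 2.0
    return float(np.sqrt(1.0 / (c * np.pi * d_e * sp)))


@dataclass
class SigmaEstimate:
    sigma: float  # m; last iterate (censored value if not converged)
    converged: bool
    n_iter: int
    flag: str  # "", "negative_sp", "range_left_plot", "max_iter", "too_few_pairs"
    final_range: tuple[float, float] | None = None
    sp_final: float = np.nan


@dataclass
class SigmaEstimates:
    """Per-site bundle: D_e, sigma_g, sigma_s, sigma_p and dispersal ratios."""

    d_e: float  # individuals / m^2
    sigma_g: SigmaEstimate | None = None
    sigma_s: SigmaEstimate | None = None
    sigma_p: float = np.nan
    sigma_p_flag: str = ""
    ratio_p_s: float = np.nan
    ratio_s_g: float = np.nan


def estimate_sigma(
    kinship: KinshipMatrix,
    distances: DistanceMatrix,
    d_e: float,
    marker_mode: str,
    spec: DistanceClassSpec | None = None,
    max_iter: int = 20,
    tol: float = 0.01,
    range_mult: float = 20.0,
    min_pairs: int = 10,
) -> SigmaEstimate:
    """Iterative sigma estimate for one marker mode.

    Step 0 inverts the full-range Sp; step t refits b_log over
    (sigma_{t-1}, range_mult*sigma_{t-1}] (upper bound clipped to the
    largest pairwise distance) and re-inverts.  Convergence: relative
    change in sigma below ``tol``.  Non-convergence is flagged when Sp
    turns non-positive, the restricted range leaves the sampled plot
    (lower bound beyond the largest pairwise distance), too few pairs
    remain, or ``max_iter`` is hit; the last sigma is reported censored.
    """
    if marker_mode not in ("nuclear", "plastid"):
        raise ValueError("marker_mode must be nuclear or plastid")
    from .sgs import DEFAULT_CLASS_BOUNDS

    if spec is None:
        spec = DistanceClassSpec(DEFAULT_CLASS_BOUNDS)
    iu, ju, f, d = _pairs(kinship, distances)
    pos = d > 0
    f, d = f[pos], d[pos]
    if len(d) == 0:
        return SigmaEstimate(np.nan, False, 0, "too_few_pairs")
    d_max_plot = float(d.max())
    cls = spec.assign(d)
    first = cls == 0
    if not first.any():
        return SigmaEstimate(np.nan, False, 0, "too_few_pairs")
    f1 = float(f[first].mean())
    b0 = _slope(f, d)
    sp0 = sp_statistic(f1, b0)
    if sp0 <= 0:
        return SigmaEstimate(np.nan, False, 0, "negative_sp")
    sigma = sigma_from_sp(sp0, d_e, marker_mode)
    sp_t = sp0
    lo = hi = None
    for t in range(1, max_iter + 1):
        lo = sigma
        hi = min(range_mult * sigma, d_max_plot)
        if lo >= d_max_plot:
            return SigmaEstimate(sigma, False, t, "range_left_plot", (lo, hi), sp_t)
        try:
            b_t = slope_over_range(kinship, distances, lo, hi, min_pairs=min_pairs)
        except TooFewPairsError:
            return SigmaEstimate(sigma, False, t, "too_few_pairs", (lo, hi), sp_t)
        sp_t = sp_statistic(f1, b_t)
        if sp_t <= 0:
            return SigmaEstimate(sigma, False, t, "negative_sp", (lo, hi), sp_t)
        sigma_new = sigma_from_sp(sp_t, d_e, marker_mode)
        rel = abs(sigma_new - sigma) / sigma
        sigma = sigma_new
        if rel < tol:
            return SigmaEstimate(sigma, True, t, "", (lo, hi), sp_t)
    return SigmaEstimate(sigma, False, max_iter, "max_iter", (lo, hi), sp_t)


def decompose_pollen(sigma_g: float, sigma_s: float):
    """Pollen component from the gene/seed variance decomposition.

    sigma_p = sqrt(2 (sigma_g^2 - sigma_s^2)); undefined (NaN + flag) when
    sigma_s > sigma_g.  Also returns the sigma_p/sigma_s and
    sigma_s/sigma_g ratios.
    """
    if sigma_g < 0 or sigma_s < 0:
        raise ValueError("sigma values must be nonnegative")
    out = {"sigma_p": np.nan, "flag": "", "ratio_p_s": np.nan, "ratio_s_g": np.nan}
    if sigma_s > sigma_g:
        out["flag"] = "sigma_s_exceeds_sigma_g"
    else:
        out["sigma_p"] = float(np.sqrt(2.0 * (sigma_g**2 - sigma_s**2)))
        if sigma_s > 0:
            out["ratio_p_s"] = out["sigma_p"] / sigma_s
    if sigma_g > 0:
        out["ratio_s_g"] = sigma_s / sigma_g
    return out


def dispersal_history(
    kin_nuclear: KinshipMatrix,
    kin_plastid: KinshipMatrix,
    distances: DistanceMatrix,
    census_adult_density_ha: float,
    de_fraction: float = 0.25,
    **kwargs,
) -> SigmaEstimates:
    """Full per-site decomposition: sigma_g (nuclear), sigma_s (plastid),
    sigma_p (derived), and the dispersal ratios."""
    d_e = effective_density(census_adult_density_ha, de_fraction)
    est = SigmaEstimates(d_e=d_e)
    est.sigma_g = estimate_sigma(kin_nuclear, distances, d_e, "nuclear", **kwargs)
    est.sigma_s = estimate_sigma(kin_plastid, distances, d_e, "plastid", **kwargs)
    if np.isfinite(est.sigma_g.sigma) and np.isfinite(est.sigma_s.sigma):
        dec = decompose_pollen(est.sigma_g.sigma, est.sigma_s.sigma)
        est.sigma_p = dec["sigma_p"]
        est.sigma_p_flag = dec["flag"]
        est.ratio_p_s = dec["ratio_p_s"]
        est.ratio_s_g = dec["ratio_s_g"]
    return est
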