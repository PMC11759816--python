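"""Isotopic geo-location of juvenile origin.

The isoscape and the fractionation equation give, per grid cell and depth
stratum, a Monte-Carlo distribution of the otolith d18O a fish would have
precipitated there (water and temperature uncertainty plus fractionation
scatter, propagated by simple resampling).  Comparing a fish's observed
nuclear d18O to these distributions yields a per-cell probability of
occurrence; individual maps are averaged into synoptic maps, summed into
per-cell log-likelihoods, aggregated over sub-population polygons, and
thresholded into top-percentile origin regions per mixture cluster.

The occurrence metric is the two-sided Monte-Carlo tail probability
p = 2 min(F(x), 1 - F(x)): bounded on [0, 1] and equal to 1 when the observed
value sits at the centre of the expected distribution.  A normalized
Gaussian-likelihood alternative is available behind a flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isotopes import FractionationEquation, predict_oto
from .isoscape import Isoscape
from .types import AreaPolygon, EnvField, FishRecord, haversine_km

log = logging.getLogger("otogeo")

__all__ = [
    "ExpectedOtoDistribution", "OccurrenceMap", "BiasReport",
    "capture_site_expectation", "bias_test", "expected_distribution",
    "expected_distribution_grid", "occurrence_probability", "occurrence_map",
    "synoptic_map", "area_summary", "top_percentile_region",
]


@dataclass
class ExpectedOtoDistribution:
    cell: tuple[int, int]  # (lat index, lon index)
    stratum: int
    mc_samples: np.ndarray  # permil VPDB

    @property
    def mean(self) -> float:
        return float(np.mean(self.mc_samples))

    @property
    def sd(self) -> float:
        return float(np.std(self.mc_samples))


@dataclass
class OccurrenceMap:
    """Per-fish occurrence probabilities and their synoptic aggregates."""

    lon: np.ndarray
    lat: np.ndarray
    strata: list
    per_fish: dict[str, np.ndarray]  # fish_id -> (n_strata, n_lat, n_lon)
    mean_by_stratum: np.ndarray | None = None
    mean_across: np.ndarray | None = None  # (n_lat, n_lon)
    loglik: np.ndarray | None = None  # (n_lat, n_lon)
    eps: float = field(default=0.0)


@dataclass
class BiasReport:
    """Observed-minus-predicted edge d18O per fractionation equation."""

    rows: pd.DataFrame  # columns: equation, mean_bias, sd_bias, n

    def ranked(self) -> pd.DataFrame:
        return self.rows.reindex(self.rows["mean_bias"].abs().sort_values().index)


# ---------------------------------------------------------------------------
# capture-site averaging and bias testing
# ---------------------------------------------------------------------------

def capture_site_expectation(isoscape: Isoscape, temperature: EnvField,
                             lon: float, lat: float, depth: float,
                             radius_km: float = 100.0, layer_m: float = 100.0
                             ) -> tuple[float, float]:
    """Mean temperature and water d18O around a capture location.

    Unweighted mean over grid cells whose centre lies within ``radius_km``
    (great-circle) and strata overlapping the ``layer_m`` window centred on
    the capture depth.  Falls back to the nearest cell when the radius is
    smaller than the grid spacing.
    """
    LON, LAT = np.meshgrid(isoscape.lon, isoscape.lat)
    dist = haversine_km(lon, lat, LON, LAT)
    in_radius = dist <= radius_km
    if not np.any(in_radius):
        in_radius = dist <= float(dist.min()) + 1e-9  # nearest single cell
    lo, hi = depth - layer_m / 2.0, depth + layer_m / 2.0
    strata_idx = [k for k, s in enumerate(isoscape.strata) if s.overlaps(lo, hi)]
    if not strata_idx:
        raise ValueError(f"no depth strata overlap the layer around {depth} m")
    t_vals, w_vals = [], []
    for k in strata_idx:
        t_vals.append(temperature.values[k][in_radius])
        w_vals.append(isoscape.mean[k][in_radius])
    t = np.concatenate(t_vals)
    w = np.concatenate(w_vals)
    ok = np.isfinite(t) & np.isfinite(w)
    if not np.any(ok):
        raise ValueError("no finite cells within the capture-site window")
    return float(np.mean(t[ok])), float(np.mean(w[ok]))


def bias_test(equations: list[FractionationEquation], edge_obs: dict[str, float],
              fish: list[FishRecord], isoscape: Isoscape, temperature: EnvField,
              radius_km: float = 100.0, layer_m: float = 100.0,
              capture_depth: float = 100.0) -> BiasReport:
    """Compare observed edge d18O to each equation's capture-site prediction.

    bias_i = observed_i - predicted_i; equations are ranked by |mean bias|.
    Fish without a usable capture location are skipped with a log entry.
    """
    usable = []
    for f in fish:
        if f.fish_id not in edge_obs or edge_obs[f.fish_id] is None:
            continue
        try:
            t_bar, w_bar = capture_site_expectation(
                isoscape, temperature, f.capture_lon, f.capture_lat,
                capture_depth, radius_km, layer_m)
        except ValueError as err:
            log.info("bias_test: fish %s skipped (%s)", f.fish_id, err)
            continue
        usable.append((f.fish_id, t_bar, w_bar))
    if len(usable) < 5:
        raise ValueError(f"bias test needs >= 5 fish with capture data, got {len(usable)}")
    rows = []
    for eq in equations:
        biases = [edge_obs[fid] - predict_oto(eq, t, w) for fid, t, w in usable]
        rows.append({"equation": eq.name, "mean_bias": float(np.mean(biases)),
                     "sd_bias": float(np.std(biases, ddof=1)), "n": len(biases)})
    report = BiasReport(pd.DataFrame(rows))
    return report


# ---------------------------------------------------------------------------
# expected distributions and occurrence probabilities
# ---------------------------------------------------------------------------

def expected_distribution(isoscape: Isoscape, eq: FractionationEquation,
                          temperature: EnvField, cell: tuple[int, int], stratum: int,
                          n_mc: int = 5000, seed: int | None = None
                          ) -> ExpectedOtoDistribution:
    """Monte-Carlo distribution of expected otolith d18O at one cell/stratum.

    Each draw combines water ~ N(isoscape mean, sd), temperature ~ N(field
    mean, sd) and fractionation scatter ~ N(0, eq.residual_sd).
    """
    iy, ix = cell
    w_mu = isoscape.mean[stratum, iy, ix]
    w_sd = isoscape.sd[stratum, iy, ix]
    t_mu = temperature.values[stratum, iy, ix]
    t_var = temperature.variance[stratum, iy, ix] if temperature.variance is not None else 0.0
    if not (np.isfinite(w_mu) and np.isfinite(t_mu)):
        raise ValueError(f"cell {cell} stratum {stratum} has no isoscape/temperature value")
    for name, s in (("water sd", w_sd), ("temperature var", t_var)):
        if s < 0 or not np.isfinite(s):
            warnings.warn(f"{name} invalid at {cell}; treated as 0", stacklevel=2)
    w_sd = max(float(w_sd), 0.0) if np.isfinite(w_sd) else 0.0
    t_sd = float(np.sqrt(max(t_var, 0.0))) if np.isfinite(t_var) else 0.0
    rng = np.random.default_rng(seed)
    draws = predict_oto(eq, rng.normal(t_mu, t_sd, n_mc), rng.normal(w_mu, w_sd, n_mc))
    if eq.residual_sd > 0:
        draws = draws + rng.normal(0.0, eq.residual_sd, n_mc)
    return ExpectedOtoDistribution(cell=cell, stratum=stratum, mc_samples=np.asarray(draws))


def expected_distribution_grid(isoscape: Isoscape, eq: FractionationEquation,
                               temperature: EnvField, n_mc: int = 5000,
                               seed: int | None = None) -> np.ndarray:
    """Vectorized MC draws for every cell/stratum: (n_strata, n_lat, n_lon, n_mc)."""
    rng = np.random.default_rng(seed)
    w_mu = isoscape.mean[..., None]
    w_sd = np.maximum(np.nan_to_num(isoscape.sd[..., None], nan=0.0), 0.0)
    t_mu = temperature.values[..., None]
    t_var = temperature.variance if temperature.variance is not None else np.zeros_like(temperature.values)
    t_sd = np.sqrt(np.maximum(np.nan_to_num(t_var[..., None], nan=0.0), 0.0))
    shape = isoscape.mean.shape + (n_mc,)
    water = w_mu + w_sd * rng.standard_normal(shape)
    temp = t_mu + t_sd * rng.standard_normal(shape)
    draws = predict_oto(eq, temp, water)
    if eq.residual_sd > 0:
        draws = draws + eq.residual_sd * rng.standard_normal(shape)
    return draws


def occurrence_probability(observed_d18o: float, dist: ExpectedOtoDistribution | np.ndarray,
                           metric: str = "tail") -> float:
    """Probability of occurrence at one cell given the expected distribution.

    ``tail``: two-sided empirical tail probability 2 min(F(x), 1-F(x)) with a
    mid-rank empirical CDF (the MC median scores 1.0).  ``likelihood``:
    Gaussian density at x normalized by the density mode.
    """
    draws = dist.mc_samples if isinstance(dist, ExpectedOtoDistribution) else np.asarray(dist)
    if draws.size < 1000:
        warnings.warn("occurrence probability from < 1000 draws is noisy", stacklevel=2)
    if metric == "likelihood":
        mu, sd = float(np.mean(draws)), float(np.std(draws))
        if sd == 0:
            return 1.0 if observed_d18o == mu else 0.0
        return float(np.exp(-0.5 * ((observed_d18o - mu) / sd) ** 2))
    below = np.sum(draws < observed_d18o)
    equal = np.sum(draws == observed_d18o)
    f_hat = (below + 0.5 * equal) / draws.size
    return float(2.0 * min(f_hat, 1.0 - f_hat))


def occurrence_map(observed: dict[str, float], draws: np.ndarray, isoscape: Isoscape,
                   metric: str = "tail") -> dict[str, np.ndarray]:
    """Per-fish occurrence probability over every cell/stratum.

    ``draws`` comes from :func:`expected_distribution_grid`; the expected
    distributions are fish-independent, so the draw grid is shared and the
    empirical CDF is evaluated by sorting once per cell.
    """
    n_s, n_la, n_lo, n_mc = draws.shape
    flat = np.sort(draws.reshape(-1, n_mc), axis=1)
    out = {}
    for fid, x in observed.items():
        if x is None or not np.isfinite(x):
            continue
        if metric == "likelihood":
            mu = flat.mean(axis=1)
            sd = flat.std(axis=1)
            p = np.exp(-0.5 * ((x - mu) / np.where(sd > 0, sd, np.inf)) ** 2)
        else:
            lo = np.array([np.searchsorted(row, x, side="left") for row in flat])
            hi = np.array([np.searchsorted(row, x, side="right") for row in flat])
            f_hat = (lo + 0.5 * (hi - lo)) / n_mc
            p = 2.0 * np.minimum(f_hat, 1.0 - f_hat)
        out[fid] = p.reshape(n_s, n_la, n_lo)
    return out


def synoptic_map(per_fish: dict[str, np.ndarray], isoscape: Isoscape,
                 n_mc: int = 5000) -> OccurrenceMap:
    """Average individual maps and accumulate per-cell log-likelihoods.

    mean_by_stratum averages fish within each stratum; mean_across averages
    the stratum means (unweighted); loglik(cell) = sum_i ln p_i(cell) with
    the across-strata mean probability per fish, zero probabilities floored
    at eps = 1/(2 n_mc) (the MC resolution limit).
    """
    if not per_fish:
        raise ValueError("no per-fish maps supplied")
    stack = np.stack(list(per_fish.values()))  # (n_fish, n_s, n_lat, n_lon)
    eps = 1.0 / (2.0 * n_mc)
    mean_by_stratum = stack.mean(axis=0)
    mean_across = mean_by_stratum.mean(axis=0)
    per_fish_across = stack.mean(axis=1)  # fish x lat x lon
    floored = np.maximum(per_fish_across, eps)
    n_floored = int(np.sum(per_fish_across < eps))
    if n_floored:
        log.info("synoptic_map: floored %d zero probabilities at eps=%.2g", n_floored, eps)
    loglik = np.sum(np.log(floored), axis=0)
    return OccurrenceMap(lon=isoscape.lon, lat=isoscape.lat, strata=isoscape.strata,
                         per_fish=per_fish, mean_by_stratum=mean_by_stratum,
                         mean_across=mean_across, loglik=loglik, eps=eps)


def area_summary(omap: OccurrenceMap, polygons: list[AreaPolygon],
                 depth_range: tuple[float, float] = (0.0, 200.0)) -> pd.DataFrame:
    """Mean probability and log-likelihood per sub-population area.

    Cell probabilities are first averaged over the strata inside
    ``depth_range``; each polygon then averages the cells whose centre it
    covers.  The per-cell log-likelihood (sum over fish of ln p_i at that
    cell) is likewise averaged over the polygon's cells, so the reported
    value stays on the per-location scale.  Polygons covering no cell are
    flagged with NaN.
    """
    lo, hi = depth_range
    k_sel = [k for k, s in enumerate(omap.strata) if s.overlaps(lo, hi)]
    if not k_sel:
        raise ValueError("depth_range overlaps no strata")
    prob = omap.mean_by_stratum[k_sel].mean(axis=0)
    stack = np.stack(list(omap.per_fish.values()))[:, k_sel].mean(axis=1)
    loglik = np.sum(np.log(np.maximum(stack, omap.eps)), axis=0)

    from shapely.geometry import Point

    LON, LAT = np.meshgrid(omap.lon, omap.lat)
    rows = []
    for p in polygons:
        poly = p.to_shapely()
        mask = np.array([poly.covers(Point(x, y))
                         for x, y in zip(LON.ravel(), LAT.ravel())]).reshape(LON.shape)
        if not mask.any():
            warnings.warn(f"polygon {p.name} covers no grid cell", stacklevel=2)
            rows.append({"area": p.name, "mean_probability": np.nan,
                         "loglik": np.nan, "n_cells": 0})
            continue
        rows.append({"area": p.name,
                     "mean_probability": float(np.nanmean(prob[mask])),
                     "loglik": float(np.nanmean(loglik[mask])),
                     "n_cells": int(mask.sum())})
    return pd.DataFrame(rows)


def top_percentile_region(omap: OccurrenceMap, labels: dict[str, int] | None = None,
                          q: float = 0.95) -> dict[int, np.ndarray]:
    """Cells at or above the q-quantile of each cluster's synoptic map.

    ``labels`` maps fish_id to a cluster; with ``None`` all fish form one
    cluster 0.  Ties at the threshold are all included.  Returns a boolean
    mask (n_lat, n_lon) per cluster.
    """
    if labels is None:
        labels = {fid: 0 for fid in omap.per_fish}
    out = {}
    for cl in sorted(set(labels.values())):
        members = [omap.per_fish[fid] for fid, c in labels.items()
                   if c == cl and fid in omap.per_fish]
        if not members:
            continue
        syn = np.stack(members).mean(axis=0).mean(axis=0)  # across strata
        # "higher" keeps the top-(1-q) set tight for distinct values while
        # still including every tied cell at the threshold
        thr = np.nanquantile(syn, q, method="higher")
        out[cl] = syn >= thr
    return out
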