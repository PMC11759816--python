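"""Sample filtering, region extraction and length-based ageing.

Implements the study protocol applied before any modelling: inverse von
Bertalanffy ageing and cohort filtering (birth years 1989-2002), retention of
elements above detection limits in >= 95% of samples, removal of Al-spiked
ablations, and averaging of ablations 2-6 (nuclear, first-year-of-life) and
the last 3 ablations (marginal, recent adult life) into region signatures.
The first ablation is always excluded to minimize maternal effects.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .config import Config
from .types import FishRecord, OtolithTransect, RegionSignature

log = logging.getLogger("otogeo")


@dataclass
class GrowthModel:
    """von Bertalanffy growth with a linear otolith-radius/length map.

    length(t) = l_inf * (1 - exp(-k (t - t0)));  the inverse gives age from
    length on (0, l_inf).  Otolith radius (um) maps linearly to fish length
    (cm) so ablation distances can be dated.
    """

    l_inf: float  # cm
    k: float  # per year
    t0: float  # years
    radius_length_slope: float = 1.0 / 14.0  # cm per um
    radius_length_intercept: float = 0.0  # cm

    def __post_init__(self) -> None:
        if self.l_inf <= 0 or self.k <= 0:
            raise ValueError("l_inf and k must be positive")

    def length_at_age(self, age: float) -> float:
        return self.l_inf * (1.0 - math.exp(-self.k * (age - self.t0)))

    def length_from_radius(self, radius_um: float) -> float:
        return self.radius_length_intercept + self.radius_length_slope * radius_um

    def radius_from_length(self, length_cm: float) -> float:
        return (length_cm - self.radius_length_intercept) / self.radius_length_slope

    def age_at_radius(self, radius_um: float) -> float:
        return age_from_length(self.length_from_radius(radius_um), self)

    @classmethod
    def from_config(cls, cfg: Config) -> "GrowthModel":
        return cls(
            l_inf=cfg.growth_l_inf,
            k=cfg.growth_k,
            t0=cfg.growth_t0,
            radius_length_slope=cfg.radius_length_slope,
            radius_length_intercept=cfg.radius_length_intercept,
        )


def age_from_length(length: float, gm: GrowthModel) -> float:
    """Invert the growth curve: age = t0 - ln(1 - L/l_inf)/k.

    Undefined at or beyond the asymptotic length.
    """
    if not 0 < length < gm.l_inf:
        raise ValueError(
            f"length {length} cm outside (0, l_inf={gm.l_inf}); inverse undefined"
        )
    return gm.t0 - math.log(1.0 - length / gm.l_inf) / gm.k


def assign_ages(fish: list[FishRecord], gm: GrowthModel) -> list[FishRecord]:
    """Populate age_at_capture and birth_year from capture length."""
    for f in fish:
        f.age_at_capture = age_from_length(f.total_length, gm)
        f.derive_birth_year()
    return fish


def cohort_filter(fish: list[FishRecord], min_year: int = 1989, max_year: int = 2002) -> list[FishRecord]:
    """Retain fish with min_year <= birth_year <= max_year."""
    for f in fish:
        if f.birth_year is None:
            raise ValueError(f"birth_year not populated for fish {f.fish_id}")
    kept = [f for f in fish if min_year <= f.birth_year <= max_year]
    log.info("cohort_filter: %d in, %d retained (%d-%d)", len(fish), len(kept), min_year, max_year)
    if not kept:
        warnings.warn("cohort filter retained no fish", stacklevel=2)
    return kept


def select_elements(
    signatures: list[RegionSignature] | "np.ndarray",
    lod_table: dict[str, float],
    min_fraction: float = 0.95,
) -> list[str]:
    """Retain elements above their detection limit in >= min_fraction of samples.

    ``signatures`` may be RegionSignature objects or any iterable of
    element->value mappings.  The boundary is inclusive: exactly 95% passes.
    """
    values: dict[str, list[float]] = {}
    for s in signatures:
        elemental = s.elemental if isinstance(s, RegionSignature) else s
        for el, v in elemental.items():
            values.setdefault(el, []).append(v)
    retained = []
    for el, vals in values.items():
        if el not in lod_table:
            raise KeyError(f"element {el!r} missing from LOD table")
        arr = np.asarray(vals, dtype=float)
        # missing measurements count as below-LOD
        frac = float(np.sum(arr[~np.isnan(arr)] > lod_table[el])) / len(arr)
        if frac >= min_fraction:
            retained.append(el)
    log.info("select_elements: %d of %d elements retained", len(retained), len(values))
    return retained


def _robust_al_threshold(al: np.ndarray) -> float:
    med = float(np.median(al))
    mad = float(np.median(np.abs(al - med)))
    return med + 5.0 * mad


def exclude_contaminated(transect: OtolithTransect, al_threshold: float | None = None) -> OtolithTransect:
    """Drop ablations whose Al:Ca exceeds the contamination threshold.

    With no threshold given, a per-otolith robust default (median + 5*MAD of
    Al:Ca) is used.  Transects without Al data pass through with a warning.
    """
    al = np.array([p.al_ratio if p.al_ratio is not None else np.nan for p in transect.points])
    if np.all(np.isnan(al)):
        warnings.warn(f"fish {transect.fish_id}: no Al data, contamination filter skipped",
                      stacklevel=2)
        return transect
    thr = al_threshold if al_threshold is not None else _robust_al_threshold(al[~np.isnan(al)])
    keep = [p for p, a in zip(transect.points, al) if np.isnan(a) or a <= thr]
    removed = len(transect.points) - len(keep)
    if removed:
        log.info("fish %s: removed %d Al-contaminated ablations (threshold %.4g)",
                 transect.fish_id, removed, thr)
    return OtolithTransect(fish_id=transect.fish_id, points=keep)


def extract_regions(
    transect: OtolithTransect,
    nuclear_window: tuple[int, int] = (2, 6),
    marginal_n_last: int = 3,
    min_points: int = 9,
) -> tuple[RegionSignature, RegionSignature]:
    """Average ablations into nuclear and marginal region signatures.

    Nuclear = unweighted mean over ablation indices 2-6 (the first ablation is
    always excluded); marginal = mean over the last ``marginal_n_last``
    surviving ablations.  Elements missing at every contributing ablation
    propagate as missing for that region.
    """
    if len(transect.points) < min_points:
        raise ValueError(
            f"fish {transect.fish_id}: only {len(transect.points)} points "
            f"(< {min_points}); dropped"
        )
    lo, hi = nuclear_window
    nuclear_pts = [p for p in transect.points if lo <= p.index <= hi]
    marginal_pts = transect.points[-marginal_n_last:]
    if not nuclear_pts:
        raise ValueError(f"fish {transect.fish_id}: no ablations in nuclear window")

    def region_mean(points, region):
        elements = sorted({e for p in points for e in p.ratios})
        out = {}
        for el in elements:
            vals = np.array([p.ratios.get(el, np.nan) for p in points], dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[el] = float(np.nanmean(vals))
        return RegionSignature(fish_id=transect.fish_id, region=region, elemental=out)

    return region_mean(nuclear_pts, "nuclear"), region_mean(marginal_pts, "marginal")


def ablation_age_map(transect: OtolithTransect, gm: GrowthModel):
    """Return an age_map: 1-based ablation index -> estimated age (years).

    Age at an ablation is the inverse-growth age of the fish length implied by
    the ablation's distance from the core.  Distances whose implied length
    falls outside (0, l_inf) map to the boundary ages.
    """
    ages = {}
    for p in transect.points:
        length = gm.length_from_radius(p.distance_from_core)
        length = min(max(length, 1e-6), gm.l_inf * (1 - 1e-9))
        ages[p.index] = age_from_length(length, gm)

    def age_map(index: int) -> float:
        return ages[index]

    age_map.ages = ages  # type: ignore[attr-defined]
    return age_map
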