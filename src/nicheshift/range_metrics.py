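"""Range-change metrics on thresholded suitability maps.

Given current and projected suitability grids, these functions compute the
quantities a range-shift study reports per scenario: suprathreshold area
(true spherical km², strict > at the 0.5 cutoff), percent change versus
current, the area suprathreshold under both maps and the percent of the
current range retained, the suitability-weighted spherical centroid, its
great-circle displacement and 16-wind compass bearing, the displacement
rate in km per decade, and cross-scenario medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .projection_ensemble import ScenarioSpec, SuitabilityGrid
from .raster_stack import EARTH_RADIUS_KM, cell_area_grid

__all__ = [
    "RangeSummary",
    "threshold_area",
    "percent_change",
    "overlap_retained",
    "centroid",
    "great_circle_km",
    "initial_bearing",
    "compass_16",
    "rate_per_decade",
    "scenario_medians",
    "summarize_scenario",
    "summaries_to_frame",
]

COMPASS_POINTS = (
    "N", "NNE", "NE", "ENE", "E", "ESE", "SE", "SSE",
    "S", "SSW", "SW", "WSW", "W", "WNW", "NW", "NNW",
)


@dataclass
class RangeSummary:
    scenario: str
    area_km2: float
    pct_change: float
    common_km2: float
    pct_retained: float
    centroid_lon: float
    centroid_lat: float
    displacement_km: float
    bearing_deg: float
    bearing_compass: str
    rate_km_per_decade: int


def threshold_area(s: SuitabilityGrid, tau: float = 0.5) -> float:
    """Total spherical area (km²) of unmasked cells with suitability > tau."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    areas = cell_area_grid(s.grid)
    sel = (~s.mask) & (s.values > tau)
    return float(areas[sel].sum())


def percent_change(current_km2: float, future_km2: float) -> float:
    """(future − current) / current × 100; undefined for a zero current area."""
    if current_km2 <= 0:
        raise ValueError("percent change undefined: current area is zero")
    return (future_km2 - current_km2) / current_km2 * 100.0


def overlap_retained(
    current: SuitabilityGrid, future: SuitabilityGrid, tau: float = 0.5
) -> tuple[float, float]:
    """Area suprathreshold in both maps, and percent of the current range retained."""
    if not current.grid.approx_equal(future.grid):
        raise ValueError("current and future grids do not match")
    areas = cell_area_grid(current.grid)
    cur_sel = (~current.mask) & (current.values > tau)
    fut_sel = (~future.mask) & (future.values > tau)
    common = float(areas[cur_sel & fut_sel].sum())
    cur_area = float(areas[cur_sel].sum())
    if cur_area <= 0:
        raise ValueError("no current suprathreshold area; retention undefined")
    return common, common / cur_area * 100.0


def centroid(s: SuitabilityGrid) -> tuple[float, float]:
    """Suitability-weighted geometric center of the distribution.

    Weights are suitability × cell area over ALL unmasked cells (so a map
    whose suprathreshold range vanishes still has a centroid).  Cell-center
    unit vectors are averaged on the sphere and the resultant renormalized.
    """
    w = np.where(s.mask, 0.0, s.values) * cell_area_grid(s.grid)
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero suitability: centroid undefined")
    lat = np.radians(s.grid.lat_centers())[:, None]
    lon = np.radians(s.grid.lon_centers())[None, :]
    x = float((w * np.cos(lat) * np.cos(lon)).sum())
    y = float((w * np.cos(lat) * np.sin(lon)).sum())
    z = float((w * np.sin(lat) * np.ones_like(lon)).sum())
    norm = math.sqrt(x * x + y * y + z * z)
    if norm / total < 1e-9:
        raise ValueError("balanced antipodal mass: centroid undefined")
    return math.degrees(math.atan2(y, x)), math.degrees(math.asin(z / norm))


def great_circle_km(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Haversine great-circle distance (km), R = 6371 km; points are (lon, lat)."""
    lon1, lat1 = map(math.radians, p1)
    lon2, lat2 = map(math.radians, p2)
    dlat, dlon = lat2 - lat1, lon2 - lon1
    a = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def initial_bearing(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Initial great-circle bearing from p1 to p2, degrees clockwise from north."""
    lon1, lat1 = map(math.radians, p1)
    lon2, lat2 = map(math.radians, p2)
    dlon = lon2 - lon1
    y = math.sin(dlon) * math.cos(lat2)
    x = math.cos(lat1) * math.sin(lat2) - math.sin(lat1) * math.cos(lat2) * math.cos(dlon)
    return math.degrees(math.atan2(y, x)) % 360.0


def compass_16(bearing_degrees: float) -> str:
    """16-wind compass label; sector i spans [i·22.5 − 11.25, i·22.5 + 11.25)."""
    idx = int(math.floor(((bearing_degrees + 11.25) % 360.0) / 22.5))
    return COMPASS_POINTS[idx]


def rate_per_decade(
    displacement_km: float, horizon_year: int, baseline_year: int = 2010
) -> int:
    """Displacement rate in whole km per decade, rounded half away from zero."""
    if horizon_year <= baseline_year:
        raise ValueError("horizon year must follow the baseline year")
    decades = (horizon_year - baseline_year) / 10.0
    rate = displacement_km / decades
    return int(math.floor(rate + 0.5)) if rate >= 0 else int(math.ceil(rate - 0.5))


def summarize_scenario(
    current: SuitabilityGrid,
    future: SuitabilityGrid,
    tau: float = 0.5,
    baseline_year: int = 2010,
) -> RangeSummary:
    """All per-scenario range-change metrics for one ensemble map."""
    cur_area = threshold_area(current, tau)
    fut_area = threshold_area(future, tau)
    common, retained = overlap_retained(current, future, tau)
    c0 = centroid(current)
    c1 = centroid(future)
    dist = great_circle_km(c0, c1)
    brg = initial_bearing(c0, c1)
    if isinstance(future.scenario, ScenarioSpec):
        year = future.scenario.year
        label = future.scenario.label
    else:
        raise ValueError("future grid must carry a ScenarioSpec for rate computation")
    return RangeSummary(
        scenario=label,
        area_km2=fut_area,
        pct_change=percent_change(cur_area, fut_area),
        common_km2=common,
        pct_retained=retained,
        centroid_lon=c1[0],
        centroid_lat=c1[1],
        displacement_km=dist,
        bearing_deg=brg,
        bearing_compass=compass_16(brg),
        rate_km_per_decade=rate_per_decade(dist, year, baseline_year),
    )


def scenario_medians(summaries: list[RangeSummary]) -> dict[str, float]:
    """Sample medians of % change, % retained and the per-decade rate.

    The sample median averages the two middle order statistics for even
    counts, matching how cross-scenario summary figures are reported.
    """
    if not summaries:
        raise ValueError("need at least one summary")
    return {
        "median_pct_change": float(np.median([s.pct_change for s in summaries])),
        "median_pct_retained": float(np.median([s.pct_retained for s in summaries])),
        "median_rate_km_per_decade": float(
            np.median([s.rate_km_per_decade for s in summaries])
        ),
    }


def summaries_to_frame(summaries: list[RangeSummary]) -> pd.DataFrame:
    df = pd.DataFrame([s.__dict__ for s in summaries])
    for col in ("area_km2", "pct_change", "common_km2", "pct_retained"):
        df[col] = df[col].round(2)
    return df
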