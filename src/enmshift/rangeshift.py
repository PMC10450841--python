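"""Threshold selection, binary habitat maps, change classification, area
accounting on the sphere, and centroid shifts.

Continuous suitability maps become presence/absence maps at a threshold
chosen from the training data: the final threshold maximizes sensitivity
(over presence scores) plus specificity (over background scores); the
quasi-threshold mu - sigma (mean minus population standard deviation of
suitability at the occurrence points) is reported alongside. Binary maps
from two periods are classified per cell into absent (0->0), retention
(1->1), gain (0->1) and loss (1->0); areas use the spherical cell-area
closed form and centroids are area-weighted means on the unit sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geodata import GridHeader, Raster

__all__ = [
    "EARTH_RADIUS_KM",
    "ThresholdStats",
    "BinaryMap",
    "ChangeMap",
    "Centroid",
    "threshold_stats",
    "binarize",
    "change_map",
    "area_km2",
    "cell_areas_km2",
    "centroid",
    "centroid_shift",
]

EARTH_RADIUS_KM = 6371.0088

# change-map category codes
ABSENT, RETENTION, GAIN, LOSS = 0, 1, 2, 3


@dataclass
class ThresholdStats:
    mu: float
    sigma: float
    quasi_threshold: float
    maxss_threshold: float
    final_threshold: float


@dataclass
class BinaryMap:
    """Per-cell suitable (1) / unsuitable (0) with a validity mask."""

    header: GridHeader
    states: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.states.shape != (self.header.nrows, self.header.ncols):
            raise ValueError("states shape does not match header")
        if not np.isin(self.states[self.mask], (0, 1)).all():
            raise ValueError("states must be 0 or 1 on valid cells")

    @property
    def suitable(self) -> np.ndarray:
        return self.mask & (self.states == 1)

    def to_raster(self) -> Raster:
        vals = np.where(self.mask, self.states.astype(float), self.header.nodata)
        return Raster(self.header, vals, self.mask.copy())


@dataclass
class ChangeMap:
    """Categorical transition map between two periods plus area summary."""

    header: GridHeader
    categories: np.ndarray  # ABSENT/RETENTION/GAIN/LOSS on valid cells
    mask: np.ndarray
    areas_km2: dict

    def counts(self) -> dict:
        valid = self.categories[self.mask]
        return {
            "absent": int(np.sum(valid == ABSENT)),
            "retention": int(np.sum(valid == RETENTION)),
            "gain": int(np.sum(valid == GAIN)),
            "loss": int(np.sum(valid == LOSS)),
        }

    def to_raster(self) -> Raster:
        vals = np.where(self.mask, self.categories.astype(float), self.header.nodata)
        return Raster(self.header, vals, self.mask.copy())


@dataclass
class Centroid:
    lon: float
    lat: float
    area_km2: float
    defined: bool = True


def threshold_stats(
    suitability: Raster,
    occurrence_cells: list[tuple[int, int]],
    presence_scores,
    background_scores,
) -> ThresholdStats:
    """Occurrence-based quasi-threshold and the max sens+spec threshold.

    ``mu``/``sigma`` summarize suitability at the occurrence cells
    (population standard deviation). The final threshold is the presence
    score maximizing sensitivity + specificity, where sensitivity counts
    presence scores >= t and specificity counts background scores < t; ties
    prefer the lowest such threshold.
    """
    vals = []
    for r, c in occurrence_cells:
        if suitability.mask[r, c]:
            vals.append(suitability.values[r, c])
    if len(vals) < 2:
        raise ValueError("need >= 2 occurrences on valid cells")
    vals = np.asarray(vals)
    mu = float(vals.mean())
    sigma = float(vals.std())
    pres = np.asarray(presence_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    candidates = np.unique(pres)
    best_t, best_ss = candidates[0], -np.inf
    for t in candidates:
        ss = float(np.mean(pres >= t)) + float(np.mean(bg < t))
        if ss > best_ss:
            best_ss, best_t = ss, float(t)
    return ThresholdStats(
        mu=mu,
        sigma=sigma,
        quasi_threshold=mu - sigma,
        maxss_threshold=best_t,
        final_threshold=best_t,
    )


def binarize(suitability: Raster, threshold: float) -> BinaryMap:
    """Suitable iff suitability >= threshold (ties suitable); mask preserved."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    states = (suitability.values >= threshold).astype(np.int8)
    states[~suitability.mask] = 0
    return BinaryMap(suitability.header, states, suitability.mask.copy())


def change_map(current: BinaryMap, future: BinaryMap) -> ChangeMap:
    """Per-cell transition categories between two aligned binary maps."""
    if not current.header.aligned(future.header):
        raise ValueError("binary maps are not grid-aligned")
    mask = current.mask & future.mask
    cur, fut = current.states, future.states
    cats = np.full(cur.shape, ABSENT, dtype=np.int8)
    cats[(cur == 1) & (fut == 1)] = RETENTION
    cats[(cur == 0) & (fut == 1)] = GAIN
    cats[(cur == 1) & (fut == 0)] = LOSS
    cats[~mask] = ABSENT
    cell_a = cell_areas_km2(current.header)
    areas = {
        name: float(cell_a[mask & (cats == code)].sum())
        for name, code in (
            ("absent", ABSENT),
            ("retention", RETENTION),
            ("gain", GAIN),
            ("loss", LOSS),
        )
    }
    return ChangeMap(current.header, cats, mask, areas)


def cell_areas_km2(header: GridHeader) -> np.ndarray:
    """Spherical area of every cell, km^2 (constant along a row of latitude).

    A(row) = R^2 * dlambda * (sin phi_N - sin phi_S), with dlambda the cell
    width in radians and phi_N/phi_S the cell's north/south edge latitudes.
    """
    rows = np.arange(header.nrows)
    lat_n = np.radians(header.yll + (header.nrows - rows) * header.cellsize)
    lat_s = np.radians(header.yll + (header.nrows - rows - 1) * header.cellsize)
    dlam = math.radians(header.cellsize)
    row_area = EARTH_RADIUS_KM**2 * dlam * (np.sin(lat_n) - np.sin(lat_s))
    return np.repeat(row_area[:, None], header.ncols, axis=1)


def area_km2(target, header: GridHeader | None = None) -> float:
    """Total spherical area of suitable cells (BinaryMap) or a boolean grid."""
    if isinstance(target, BinaryMap):
        sel = target.suitable
        header = target.header
    else:
        if header is None:
            raise ValueError("header required for a bare cell selection")
        sel = np.asarray(target, dtype=bool)
    return float(cell_areas_km2(header)[sel].sum())


def centroid(bmap: BinaryMap, header: GridHeader | None = None) -> Centroid:
    """Area-weighted mean of suitable cell centers on the unit sphere."""
    hdr = bmap.header if header is None else header
    sel = bmap.suitable
    if not sel.any():
        return Centroid(lon=math.nan, lat=math.nan, area_km2=0.0, defined=False)
    lons, lats = hdr.cell_centers()
    w = cell_areas_km2(hdr)[sel]
    lam = np.radians(lons[sel])
    phi = np.radians(lats[sel])
    x = np.sum(w * np.cos(phi) * np.cos(lam))
    y = np.sum(w * np.cos(phi) * np.sin(lam))
    z = np.sum(w * np.sin(phi))
    norm = math.sqrt(x * x + y * y + z * z)
    if norm == 0:
        return Centroid(lon=math.nan, lat=math.nan, area_km2=float(w.sum()), defined=False)
    lat_c = math.degrees(math.asin(z / norm))
    lon_c = math.degrees(math.atan2(y, x))
    return Centroid(lon=lon_c, lat=lat_c, area_km2=float(w.sum()))


def centroid_shift(a: Centroid, b: Centroid) -> tuple[float, float]:
    """Great-circle distance (km) and initial bearing (degrees from north)."""
    if not (a.defined and b.defined):
        raise ValueError("cannot shift an undefined centroid")
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dphi = phi2 - phi1
    dlam = math.radians(b.lon - a.lon)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    dist = 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))
    y = math.sin(dlam) * math.cos(phi2)
    x = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlam)
    bearing = math.degrees(math.atan2(y, x)) % 360.0
    return dist, bearing
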