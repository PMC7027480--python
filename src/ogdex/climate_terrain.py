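"""Climate and topographic covariates for the development-rate model.

Six covariates drive the age-slope model:

* maximum snow depth (cm) — pass-through from gridded climate data,
* warmth index (degC month) — Kira's thermal sum over months above 5 degC,
* slope angle (degrees) from the DEM,
* positive openness (degrees) — mean over azimuths of the angle between
  the zenith and the terrain horizon; 90 deg on a plane, larger on
  convex terrain (ridges), smaller in valleys,
* catchment area (m^2) — D8 flow accumulation after depression filling,
  a surrogate for soil moisture and nutrient accumulation; log10-
  transformed before modeling because it is heavily right-skewed,
* relative annual potential solar radiation (dimensionless) — clear-sky
  direct insolation on each cell's slope/aspect normalized by the
  flat-surface value at the same latitude (1.0 on flat ground).

Slope/openness/catchment/radiation are derived here from a DEM raster;
snow depth and warmth index arrive as pre-computed rasters or columns
(1-km climate mesh sources, resampled nearest-neighbour).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np

from .raster import RasterGrid

COVARIATE_NAMES = (
    "snow_depth",
    "warmth_index",
    "slope_angle",
    "positive_openness",
    "log10_catchment",
    "solar_radiation",
)

# D8 neighbour offsets (drow, dcol) in the fixed tie-break order
# E, SE, S, SW, W, NW, N, NE (row 0 = north edge).
_D8 = (
    (0, 1), (1, 1), (1, 0), (1, -1),
    (0, -1), (-1, -1), (-1, 0), (-1, 1),
)


@dataclass(frozen=True)
class Covariates:
    """One plot's environmental covariates (raw units).

    ``log10_catchment`` is log10 of the catchment area in m^2 — the scale
    on which the covariate enters the model.
    """

    snow_depth: float
    warmth_index: float
    slope_angle: float
    positive_openness: float
    log10_catchment: float
    solar_radiation: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in COVARIATE_NAMES], dtype=float)


def warmth_index(monthly_means) -> float:
    """Kira's warmth index: sum of (T - 5) over months with mean T > 5 degC."""
    t = np.asarray(monthly_means, dtype=float)
    if t.shape != (12,):
        raise ValueError(f"need exactly 12 monthly means, got shape {t.shape}")
    if np.any(~np.isfinite(t)):
        raise ValueError("monthly means contain missing values")
    excess = t - 5.0
    return float(excess[excess > 0].sum())


def _horn_gradient(z: np.ndarray, cell: float) -> tuple[np.ndarray, np.ndarray]:
    """Horn 3x3 gradient (dz/dx eastward, dz/dy northward).

    Interior cells use Horn's weighted differences; edge cells fall back
    to one-sided/central differences via ``np.gradient``.  NaN anywhere
    in a 3x3 window propagates to its center.
    """
    # np.gradient axis 0 runs north->south; northward derivative is its negation
    gy_np, gx_np = np.gradient(z, cell)
    gx, gy = gx_np.copy(), -gy_np
    if z.shape[0] >= 3 and z.shape[1] >= 3:
        a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
        d = z[1:-1, :-2];                  f = z[1:-1, 2:]
        g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
        gx[1:-1, 1:-1] = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell)
        gy[1:-1, 1:-1] = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cell)
    return gx, gy


def slope_angle(dem: RasterGrid) -> RasterGrid:
    """Slope angle in degrees from Horn's 3x3 finite differences.

    Any nodata cell poisons its full 3x3 neighbourhood (Horn's stencil
    does not touch the center cell, so this must be enforced explicitly).
    """
    if min(dem.shape) < 3:
        raise ValueError("DEM must be at least 3x3")
    gx, gy = _horn_gradient(dem.values, dem.cell_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    from scipy.ndimage import maximum_filter

    bad = maximum_filter(~np.isfinite(dem.values), size=3)
    slope[bad] = np.nan
    return dem.like(slope)


def aspect_angle(dem: RasterGrid) -> RasterGrid:
    """Downslope aspect in degrees clockwise from north; NaN on flat cells."""
    gx, gy = _horn_gradient(dem.values, dem.cell_size)
    asp = (np.degrees(np.arctan2(-gx, -gy))) % 360.0
    asp = np.where(np.hypot(gx, gy) == 0, np.nan, asp)
    return dem.like(asp)


def positive_openness(
    dem: RasterGrid, radius: float = 200.0, n_azimuths: int = 8
) -> RasterGrid:
    """Positive topographic openness (degrees).

    For each cell and azimuth, find the maximum elevation angle to any
    cell within ``radius``; openness is the mean over azimuths of
    (90 deg - that angle).  A flat plane scores exactly 90 deg.  Azimuths
    are restricted to the 8 grid directions (``n_azimuths`` in {4, 8});
    off-grid lines of sight would require DEM resampling.
    """
    if radius < dem.cell_size:
        raise ValueError("radius must be at least one cell size")
    if n_azimuths not in (4, 8):
        raise ValueError("n_azimuths must be 4 or 8 (grid-aligned azimuths)")
    z = dem.values
    nrows, ncols = z.shape
    step = 2 if n_azimuths == 4 else 1  # cardinal-only when 4
    dirs = _D8[::step]
    acc = np.zeros_like(z)
    for drow, dcol in dirs:
        diag = math.sqrt(2.0) if drow and dcol else 1.0
        max_tan = np.full_like(z, -np.inf)
        kmax = int(radius // (dem.cell_size * diag))
        for k in range(1, max(kmax, 1) + 1):
            dist = k * dem.cell_size * diag
            if dist > radius:
                break
            shifted = _shift(z, k * drow, k * dcol)
            tan = (shifted - z) / dist
            max_tan = np.fmax(max_tan, tan)
        ang = np.degrees(np.arctan(np.where(np.isfinite(max_tan), max_tan, 0.0)))
        acc += 90.0 - ang
    out = acc / len(dirs)
    out[~np.isfinite(z)] = np.nan
    return dem.like(out)


def _shift(z: np.ndarray, drow: int, dcol: int) -> np.ndarray:
    """Shift with NaN fill (cells looking outside the grid see nothing)."""
    out = np.full_like(z, np.nan)
    nr, nc = z.shape
    rs = slice(max(drow, 0), nr + min(drow, 0))
    cs = slice(max(dcol, 0), nc + min(dcol, 0))
    rt = slice(max(-drow, 0), nr + min(-drow, 0))
    ct = slice(max(-dcol, 0), nc + min(-dcol, 0))
    out[rt, ct] = z[rs, cs]
    return out


def fill_depressions(dem: RasterGrid, epsilon: float = 1e-6) -> RasterGrid:
    """Priority-flood depression filling with an epsilon gradient.

    Raises every pit to its spill elevation plus a tiny increment so that
    every interior cell has a strictly descending path to the grid edge —
    D8 routing then never stalls on flats.
    """
    z = dem.values
    if not np.isfinite(z).any():
        raise ValueError("DEM is entirely nodata")
    nrows, ncols = z.shape
    filled = np.where(np.isfinite(z), z, np.nan)
    closed = ~np.isfinite(z)
    heap: list[tuple[float, int, int]] = []
    for r in range(nrows):
        for c in range(ncols):
            if closed[r, c]:
                continue
            if r in (0, nrows - 1) or c in (0, ncols - 1) or _touches_nodata(z, r, c):
                heapq.heappush(heap, (filled[r, c], r, c))
                closed[r, c] = True
    while heap:
        elev, r, c = heapq.heappop(heap)
        for drow, dcol in _D8:
            nr, nc = r + drow, c + dcol
            if 0 <= nr < nrows and 0 <= nc < ncols and not closed[nr, nc]:
                closed[nr, nc] = True
                filled[nr, nc] = max(filled[nr, nc], elev + epsilon)
                heapq.heappush(heap, (filled[nr, nc], nr, nc))
    return dem.like(filled)


def _touches_nodata(z: np.ndarray, r: int, c: int) -> bool:
    for drow, dcol in _D8:
        nr, nc = r + drow, c + dcol
        if 0 <= nr < z.shape[0] and 0 <= nc < z.shape[1] and not np.isfinite(z[nr, nc]):
            return True
    return False


def d8_receivers(dem: RasterGrid) -> np.ndarray:
    """Flat index of each cell's D8 receiver; -1 marks outlets.

    The DEM is depression-filled first.  Each cell drains to its steepest
    downslope neighbour (drop / distance), ties broken in the fixed order
    E, SE, S, SW, W, NW, N, NE; cells with no lower neighbour (grid edge
    or next to nodata after filling) are outlets.
    """
    filled = fill_depressions(dem)
    z = filled.values
    nrows, ncols = z.shape
    valid = np.isfinite(z)
    receiver = np.full((nrows, ncols), -1, dtype=np.int64)
    cell = dem.cell_size
    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                continue
            best_grad = 0.0
            best = -1
            for drow, dcol in _D8:
                nr, nc = r + drow, c + dcol
                if not (0 <= nr < nrows and 0 <= nc < ncols and valid[nr, nc]):
                    continue
                dist = cell * (math.sqrt(2.0) if drow and dcol else 1.0)
                grad = (z[r, c] - z[nr, nc]) / dist
                if grad > best_grad:  # strict: ties keep the earlier azimuth
                    best_grad = grad
                    best = nr * ncols + nc
            receiver[r, c] = best
    return receiver


def catchment_area(dem: RasterGrid) -> RasterGrid:
    """D8 single-direction flow accumulation, in m^2.

    Area counts the cell itself, so every valid cell carries at least
    one cell area; routing follows :func:`d8_receivers`.
    """
    receiver = d8_receivers(dem)
    z = fill_depressions(dem).values
    valid = np.isfinite(z)
    cell = dem.cell_size
    acc = np.where(valid, 1.0, np.nan)
    order = np.argsort(z, axis=None)[::-1]  # high to low: donors before receivers
    flat_acc = acc.ravel()
    flat_recv = receiver.ravel()
    flat_z = z.ravel()
    for idx in order:
        if not np.isfinite(flat_z[idx]):
            continue
        rec = flat_recv[idx]
        if rec >= 0:
            flat_acc[rec] += flat_acc[idx]
    return dem.like(acc * cell * cell)


def _sun_position(lat_rad: float, decl: float, hour_angle: float):
    """Solar elevation and azimuth (radians) from latitude/declination/hour angle."""
    sin_el = (
        math.sin(lat_rad) * math.sin(decl)
        + math.cos(lat_rad) * math.cos(decl) * math.cos(hour_angle)
    )
    el = math.asin(max(-1.0, min(1.0, sin_el)))
    cos_az = (math.sin(decl) - math.sin(lat_rad) * sin_el) / max(
        math.cos(lat_rad) * math.cos(el), 1e-12
    )
    az = math.acos(max(-1.0, min(1.0, cos_az)))
    if hour_angle > 0:  # afternoon: sun west of south
        az = 2 * math.pi - az
    return el, az


def potential_solar_radiation(
    dem: RasterGrid,
    latitude: float,
    *,
    day_step: int = 5,
    hour_step: float = 0.25,
) -> RasterGrid:
    """Relative annual potential direct insolation on each cell's slope/aspect.

    Clear-sky, no horizon shading: for every sampled time step the cosine
    of the solar incidence angle on the tilted cell is accumulated (when
    the sun is up and the surface lit), then divided by the same sum for
    a horizontal surface.  Flat cells are exactly 1.0 by construction.
    ``day_step``/``hour_step`` trade accuracy for speed; the annual
    integral is insensitive to them well below 1%.
    """
    if abs(latitude) > 66.5:
        raise ValueError("polar latitudes (beyond +/-66.5 deg) are not supported")
    gx, gy = _horn_gradient(dem.values, dem.cell_size)
    # unit surface normal in (east, north, up) coordinates
    norm = np.sqrt(gx**2 + gy**2 + 1.0)
    nx, ny, nz = -gx / norm, -gy / norm, 1.0 / norm
    lat = math.radians(latitude)
    tilted = np.zeros_like(dem.values)
    flat = 0.0
    for day in range(1, 366, day_step):
        decl = math.radians(23.44) * math.sin(2 * math.pi * (284 + day) / 365.0)
        hour = 0.0
        while hour < 24.0:
            ha = math.radians(15.0 * (hour - 12.0))
            el, az = _sun_position(lat, decl, ha)
            if el > 0:
                sx = math.sin(az) * math.cos(el)
                sy = math.cos(az) * math.cos(el)
                sz = math.sin(el)
                cos_inc = nx * sx + ny * sy + nz * sz
                tilted += np.maximum(cos_inc, 0.0)
                flat += sz
            hour += hour_step
    out = tilted / flat
    out[~np.isfinite(dem.values)] = np.nan
    return dem.like(out)
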