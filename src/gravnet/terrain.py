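"""DEM- and climate-derived predictor surfaces.

Implements the terrain and climate indices used as gravity-model
covariates:

* surface relief ratio (SRR) — moving-window ``(mean - min) / (max - min)``
  of elevation, a topographic-complexity index in [0, 1];
* compound topographic index (CTI) — ``ln(A_s / tan(slope))`` with the
  specific catchment area ``A_s`` from a D8 single-flow-direction
  accumulation, a steady-state wetness index;
* heat load index (HLI) — McCune & Keon's exponential function of latitude,
  slope and aspect folded about the southwest axis, a proxy for incident
  radiation;
* annual dryness index (ADI) — growing degree-days above 5 degC divided by
  mean annual precipitation;
* grid resampling (nearest / bilinear).

Slope and aspect use the Horn 3x3 finite-difference operator.  Aspect at
zero slope is set to the fold axis (225 deg), which makes the HLI there
equal its slope-zero closed form.  Nodata (NaN) cells are excluded from
window statistics and never become finite in any output.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .raster import RasterGrid

__all__ = [
    "surface_relief_ratio",
    "horn_slope_aspect",
    "compound_topographic_index",
    "heat_load_index",
    "annual_dryness_index",
    "resample",
]

#: days per month, non-leap calendar, used by the degree-day sum
DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

#: floor applied to tan(slope) in the CTI denominator
CTI_TAN_FLOOR = 1e-4

#: D8 neighbour order used for deterministic tie-breaking: E,SE,S,SW,W,NW,N,NE
_D8 = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def surface_relief_ratio(dem: RasterGrid, window: int = 3) -> RasterGrid:
    """Surface relief ratio (mean - min)/(max - min) over a centered window.

    ``window`` is an odd cell count (3 gives the fine-scale, 27 the
    broad-scale index on a 30 m DEM).  Nodata cells are excluded from the
    window statistics; a flat window (max == min) is defined as 0.5, the
    limit of a linear ramp.  Cells whose own value is nodata stay nodata.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    z = dem.values
    if z.ndim != 2:
        raise ValueError("DEM must be single-band")
    half = window // 2
    zp = np.pad(z, half, mode="constant", constant_values=np.nan)
    win = sliding_window_view(zp, (window, window)).reshape(z.shape + (window * window,))
    with np.errstate(invalid="ignore"):
        wmean = np.nanmean(win, axis=-1)
        wmin = np.nanmin(win, axis=-1)
        wmax = np.nanmax(win, axis=-1)
    rng = wmax - wmin
    flat = rng == 0
    srr = np.where(flat, 0.5, (wmean - wmin) / np.where(flat, 1.0, rng))
    srr = np.where(np.isnan(z), np.nan, srr)
    return dem.like(srr)


def horn_slope_aspect(dem: RasterGrid) -> tuple[np.ndarray, np.ndarray]:
    """Slope (radians) and downslope aspect (radians clockwise from north).

    Horn 3x3 operator; border cells use edge-replicated padding.  Aspect at
    zero slope is set to the SW fold axis (225 deg).
    """
    z = dem.values
    s = dem.cell_size
    zp = np.pad(z, 1, mode="edge")
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2];                   f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1];  i = zp[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * s)
    # +y is north (rows increase southward)
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * s)
    slope = np.arctan(np.hypot(dzdx, dzdy))
    # downslope direction: (-dzdx, -dzdy); azimuth clockwise from north
    aspect = np.arctan2(-dzdx, -dzdy) % (2 * np.pi)
    aspect = np.where(slope == 0, np.deg2rad(225.0), aspect)
    return slope, aspect


def compound_topographic_index(dem: RasterGrid) -> RasterGrid:
    """CTI = ln(specific catchment area / tan(slope)) from a D8 flow pass.

    Flow accumulation routes each cell's accumulated count (starting at 1)
    to its steepest-descent D8 neighbour, visiting cells from highest to
    lowest; ties in descent gradient are broken by a fixed
    E,SE,S,SW,W,NW,N,NE order.  Specific catchment area is accumulated
    cell count x cell_size (area divided by unit contour width).
    ``tan(slope)`` is floored at ``CTI_TAN_FLOOR`` so flats stay finite;
    higher CTI marks valleys, pits and flats.
    """
    z = dem.values
    if z.ndim != 2:
        raise ValueError("DEM must be single-band")
    valid = ~np.isnan(z)
    if not valid.any():
        raise ValueError("all-nodata DEM")
    nrow, ncol = z.shape
    s = dem.cell_size

    # receiver of each cell under D8 (steepest descent among valid neighbours)
    recv = np.full((nrow, ncol), -1, dtype=np.int64)
    flat_idx = np.arange(nrow * ncol).reshape(nrow, ncol)
    best_grad = np.zeros((nrow, ncol))
    for dr, dc in _D8:
        nz = np.full_like(z, np.nan)
        r0, r1 = max(0, -dr), min(nrow, nrow - dr)
        c0, c1 = max(0, -dc), min(ncol, ncol - dc)
        nz[r0:r1, c0:c1] = z[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        dist = s * np.hypot(dr, dc)
        with np.errstate(invalid="ignore"):
            grad = (z - nz) / dist
        nidx = np.full((nrow, ncol), -1, dtype=np.int64)
        nidx[r0:r1, c0:c1] = flat_idx[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        better = np.where(np.isnan(grad), False, grad > best_grad)
        recv = np.where(better, nidx, recv)
        best_grad = np.where(better, grad, best_grad)

    # accumulate from highest to lowest
    order = np.argsort(z, axis=None, kind="stable")[::-1]
    acc = np.where(valid, 1.0, np.nan).ravel()
    recv_flat = recv.ravel()
    zf = z.ravel()
    for idx in order:
        if np.isnan(zf[idx]):
            continue
        r = recv_flat[idx]
        if r >= 0 and not np.isnan(zf[r]):
            acc[r] += acc[idx]
    acc = acc.reshape(nrow, ncol)

    slope, _ = horn_slope_aspect(dem)
    tanb = np.maximum(np.tan(slope), CTI_TAN_FLOOR)
    with np.errstate(invalid="ignore"):
        cti = np.log((acc * s) / tanb)
    cti = np.where(valid, cti, np.nan)
    return dem.like(cti)


def heat_load_index(dem: RasterGrid, latitude_deg: float) -> RasterGrid:
    """McCune & Keon heat load index.

    With latitude L, slope S and aspect folded about the SW axis
    (A' = |180 - |aspect - 225||, all in radians):

        HLI = exp(-1.467 + 1.582 cos L cos S - 1.500 cos A' sin S sin L
                  - 0.262 sin L sin S + 0.607 sin A' sin S)

    Strictly positive; at slope zero it reduces to exp(-1.467 + 1.582 cos L)
    independent of aspect.
    """
    if not -90 <= latitude_deg <= 90:
        raise ValueError("latitude must be in [-90, 90]")
    slope, aspect = horn_slope_aspect(dem)
    folded = np.deg2rad(np.abs(180.0 - np.abs(np.rad2deg(aspect) - 225.0)))
    lat = np.deg2rad(latitude_deg)
    hli = np.exp(
        -1.467
        + 1.582 * np.cos(lat) * np.cos(slope)
        - 1.500 * np.cos(folded) * np.sin(slope) * np.sin(lat)
        - 0.262 * np.sin(lat) * np.sin(slope)
        + 0.607 * np.sin(folded) * np.sin(slope)
    )
    hli = np.where(np.isnan(dem.values), np.nan, hli)
    return dem.like(hli)


def degree_days_above_5(tmean_monthly: RasterGrid) -> np.ndarray:
    """dd5: sum over months of max(0, Tmean - 5 degC) x days in month."""
    t = tmean_monthly.values
    if t.ndim != 3 or t.shape[0] != 12:
        raise ValueError("tmean_monthly must have 12 bands")
    excess = np.clip(t - 5.0, 0.0, None)
    return np.tensordot(DAYS_IN_MONTH.astype(float), excess, axes=(0, 0))


def annual_dryness_index(tmean_monthly: RasterGrid, precip_annual: RasterGrid) -> RasterGrid:
    """ADI = dd5 / mean annual precipitation (degree-days per mm).

    Cells with non-positive precipitation become nodata.
    """
    dd5 = degree_days_above_5(tmean_monthly)
    p = precip_annual.values
    bad = ~(p > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        adi = np.where(bad, np.nan, dd5 / p)
    return precip_annual.like(adi)


def resample(grid: RasterGrid, target_cell: float, method: str = "bilinear") -> RasterGrid:
    """Resample onto the same extent at ``target_cell`` resolution.

    ``method`` is ``"nearest"`` or ``"bilinear"``; categorical grids must
    use nearest (bilinear would invent classes).
    """
    if target_cell <= 0:
        raise ValueError("target_cell must be > 0")
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown method {method!r}")
    if grid.categorical and method != "nearest":
        raise ValueError("categorical grids must use nearest resampling")
    nrow, ncol = grid.shape
    height = nrow * grid.cell_size
    width = ncol * grid.cell_size
    new_rows = max(1, int(round(height / target_cell)))
    new_cols = max(1, int(round(width / target_cell)))
    # fractional source indices of target cell centers
    rr = (np.arange(new_rows) + 0.5) * target_cell / grid.cell_size - 0.5
    cc = (np.arange(new_cols) + 0.5) * target_cell / grid.cell_size - 0.5
    rr = np.clip(rr, 0, nrow - 1)
    cc = np.clip(cc, 0, ncol - 1)
    R, C = np.meshgrid(rr, cc, indexing="ij")
    order = 0 if method == "nearest" else 1

    def _one(band: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(band, [R, C], order=order, mode="nearest")

    if grid.values.ndim == 2:
        out = _one(grid.values)
    else:
        out = np.stack([_one(b) for b in grid.values])
    res = grid.like(out)
    res.cell_size = float(target_cell)
    return res
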