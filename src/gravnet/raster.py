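"""Regular-grid raster container and GeoTIFF input/output.

All landscape variables travel through :class:`RasterGrid`: a single- or
multi-band regular grid on a projected coordinate system (meters), with a
``nodata`` value represented internally as NaN.  The grid convention is the
usual GIS one: ``origin`` is the outer corner of the top-left cell, rows
increase southward, columns increase eastward, and each cell covers the
half-open square ``[x0 + c*s, x0 + (c+1)*s) x (y0 - (r+1)*s, y0 - r*s]`` so
that a point lying exactly on a shared cell boundary belongs to the
higher-index cell.

GeoTIFF read/write uses :mod:`tifffile` with the standard GeoTIFF
georeferencing tags (ModelPixelScale, ModelTiepoint) plus the GDAL nodata
tag, so outputs open in ordinary GIS software.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = ["RasterGrid", "read_geotiff", "write_geotiff"]

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class RasterGrid:
    """A regular grid of cell values in a projected CRS.

    Parameters
    ----------
    values : ndarray
        ``(rows, cols)`` or ``(bands, rows, cols)`` float array; missing
        cells are NaN.
    cell_size : float
        Cell edge length in meters (> 0; square cells).
    origin : tuple of float
        ``(x0, y0)`` of the top-left corner of the grid, projected meters.
    crs_tag : str
        Opaque CRS label, carried through all operations.
    categorical : bool
        True for class grids (land cover, fire year); restricts resampling
        to nearest-neighbour.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str = "local-meters"
    categorical: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("values must be 2-D (rows, cols) or 3-D (bands, rows, cols)")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")

    # ---- shape helpers -------------------------------------------------
    @property
    def n_bands(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[-2:]

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is valid (not nodata)."""
        return ~np.isnan(self.values)

    def band(self, i: int) -> "RasterGrid":
        if self.values.ndim == 2:
            if i != 0:
                raise IndexError("single-band raster")
            return self
        return replace(self, values=self.values[i])

    # ---- coordinate arithmetic -----------------------------------------
    def rowcol(self, x, y):
        """Cell index containing point(s) (x, y) under the half-open convention."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((self.origin[1] - y) / self.cell_size).astype(int)
        # a point exactly on the top/left outer boundary still belongs to row/col 0
        nrow, ncol = self.shape
        row = np.where((y == self.origin[1]), 0, row)
        col = np.where((x == self.origin[0]), 0, col)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.rowcol(x, y)
        nrow, ncol = self.shape
        return (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)

    def value_at(self, x, y):
        """Value of the cell containing (x, y); raises if outside the extent."""
        row, col = self.rowcol(x, y)
        inside = self.contains(x, y)
        if not np.all(inside):
            raise ValueError("point outside raster extent")
        return self.values[..., row, col]

    def cell_center(self, row, col):
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin[1] - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        nrow, ncol = self.shape
        x0, y0 = self.origin
        return (x0, y0 - nrow * self.cell_size, x0 + ncol * self.cell_size, y0)

    def congruent_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
            and self.crs_tag == other.crs_tag
        )

    def like(self, values: np.ndarray, categorical: bool | None = None) -> "RasterGrid":
        """New raster sharing this grid spec."""
        out = replace(self, values=np.asarray(values, dtype=float))
        if categorical is not None:
            out.categorical = categorical
        return out


def write_geotiff(path, grid: RasterGrid, nodata: float = -9999.0) -> None:
    """Write a RasterGrid as a (multi-band) GeoTIFF with georeferencing tags."""
    vals = grid.values
    data = np.where(np.isnan(vals), nodata, vals).astype(np.float32)
    x0, y0 = grid.origin
    s = float(grid.cell_size)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (s, s, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    description = f"crs={grid.crs_tag};categorical={int(grid.categorical)}"
    tifffile.imwrite(
        path,
        data,
        extratags=extratags,
        description=description,
        photometric="minisblack",
        metadata=None,
    )


def read_geotiff(path) -> RasterGrid:
    """Read a GeoTIFF written by :func:`write_geotiff` (or any tagged single-grid TIFF)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = tif.asarray().astype(float)
        tags = page.tags
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value if _TAG_MODEL_PIXEL_SCALE in tags else (1.0, 1.0, 0.0)
        tie = tags[_TAG_MODEL_TIEPOINT].value if _TAG_MODEL_TIEPOINT in tags else (0, 0, 0, 0.0, 0.0, 0.0)
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        desc = page.description or ""
    crs_tag = "local-meters"
    categorical = False
    for part in desc.split(";"):
        if part.startswith("crs="):
            crs_tag = part[4:]
        elif part.startswith("categorical="):
            categorical = bool(int(part.split("=")[1]))
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    return RasterGrid(
        values=data,
        cell_size=float(scale[0]),
        origin=(float(tie[3]), float(tie[4])),
        crs_tag=crs_tag,
        categorical=categorical,
    )
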