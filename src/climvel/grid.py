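"""Single-band raster grids on a projected-metre coordinate system.

The :class:`Grid` is the carrier for every surface in the pipeline —
elevation, monthly climate normals, bioclimatic variables, class labels and
velocities.  The convention is fixed package-wide: upper-left origin,
row-major storage, cell-centre registration, 0-based indices.  The centre of
cell ``(r, c)`` sits at ``(origin_x + (c + 0.5) * cell_size,
origin_y - (r + 0.5) * cell_size)`` and all distances are measured between
cell centres.

GeoTIFF I/O is implemented directly on top of :mod:`tifffile`: single band,
float32, explicit nodata, with ModelPixelScale / ModelTiepoint /
GeoKeyDirectory / GDAL_NODATA tags, so the files round-trip through common
GIS tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "Grid",
    "read_grid",
    "write_grid",
    "aggregate_mean",
    "bilinear_resample",
]

DEFAULT_NODATA = -9999.0

# TIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113

# GeoTIFF keys
_GT_MODEL_TYPE = 1024
_GT_RASTER_TYPE = 1025
_PROJECTED_CS_TYPE = 3072
_MODEL_TYPE_PROJECTED = 1
_MODEL_TYPE_GEOGRAPHIC = 2
# ETRS89 / TM35FIN — a projected, metre-based CRS; any projected code works
# for the package, which never reprojects.
_DEFAULT_EPSG = 3067


@dataclass
class Grid:
    """A single-variable raster with nodata mask.

    Parameters
    ----------
    values
        2-D float array, row 0 at the top (north).
    cell_size
        Cell edge length in metres (> 0, square cells).
    origin
        ``(x, y)`` of the *upper-left corner* of the raster in projected
        metres.
    nodata_mask
        Boolean array, ``True`` where the cell holds no data.  Masked cells
        never participate in statistics or distance searches.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("values and nodata_mask must have identical shape")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def geometry(self) -> tuple[tuple[int, int], float, tuple[float, float]]:
        """``(shape, cell_size, origin)`` — enough to rebuild the frame."""
        return self.shape, self.cell_size, self.origin

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(x, y)`` coordinate arrays of all cell centres (2-D)."""
        rows, cols = self.shape
        x = self.origin[0] + (np.arange(cols) + 0.5) * self.cell_size
        y = self.origin[1] - (np.arange(rows) + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def same_geometry(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def masked_values(self) -> np.ndarray:
        """Values with masked cells set to NaN."""
        out = self.values.copy()
        out[self.nodata_mask] = np.nan
        return out

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Grid":
        """New Grid on this geometry with different values (and mask)."""
        return Grid(
            values=np.asarray(values, dtype=float),
            cell_size=self.cell_size,
            origin=self.origin,
            nodata_mask=self.nodata_mask.copy() if mask is None else mask,
        )


def _geokey_value(directory: tuple, key: int) -> int | None:
    """Look up a short GeoKey value in a GeoKeyDirectory tag tuple."""
    vals = tuple(directory)
    n = vals[3]
    for i in range(n):
        kid, loc, _count, value = vals[4 + 4 * i : 8 + 4 * i]
        if kid == key and loc == 0:
            return value
    return None


def read_grid(path) -> Grid:
    """Read a single-band georeferenced GeoTIFF into a :class:`Grid`.

    The raster must carry a projected (metre-based) CRS; a geographic
    (degree-based) CRS raises ``ValueError`` because every distance in the
    pipeline is Euclidean in metres.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = np.asarray(page.asarray(), dtype=float)
        if values.ndim == 3 and values.shape[2] == 1:
            values = values[:, :, 0]
        if values.ndim != 2:
            raise ValueError(f"{path}: expected a single-band raster")
        tags = page.tags
        scale_tag = tags.get(_MODEL_PIXEL_SCALE)
        tie_tag = tags.get(_MODEL_TIEPOINT)
        if scale_tag is None or tie_tag is None:
            raise ValueError(f"{path}: missing georeferencing tags")
        geo_tag = tags.get(_GEO_KEY_DIRECTORY)
        if geo_tag is not None:
            model = _geokey_value(geo_tag.value, _GT_MODEL_TYPE)
            if model == _MODEL_TYPE_GEOGRAPHIC:
                raise ValueError(
                    f"{path}: geographic (degree-based) CRS; a projected CRS "
                    "in metres is required"
                )
        sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
        if not np.isclose(sx, sy):
            raise ValueError(f"{path}: non-square cells ({sx} x {sy} m)")
        tie = tie_tag.value
        # tiepoint maps raster (i, j) to model (x, y); we require the
        # conventional corner registration at raster (0, 0)
        i, j = float(tie[0]), float(tie[1])
        ox = float(tie[3]) - i * sx
        oy = float(tie[4]) + j * sy
        nodata_tag = tags.get(_GDAL_NODATA)
        mask = np.isnan(values)
        if nodata_tag is not None:
            nodata = float(str(nodata_tag.value).strip())
            if np.isnan(nodata):
                pass
            else:
                mask |= values == nodata
    return Grid(values=values, cell_size=sx, origin=(ox, oy), nodata_mask=mask)


def write_grid(grid: Grid, path, nodata: float = DEFAULT_NODATA) -> None:
    """Write a :class:`Grid` as a single-band float32 GeoTIFF.

    Masked cells are stored as ``nodata``; the file re-reads into an equal
    Grid (values compared on unmasked cells).
    """
    data = np.asarray(grid.values, dtype=np.float32).copy()
    data[grid.nodata_mask] = np.float32(nodata)
    cs = float(grid.cell_size)
    ox, oy = grid.origin
    geokeys = (
        1, 1, 0, 3,
        _GT_MODEL_TYPE, 0, 1, _MODEL_TYPE_PROJECTED,
        _GT_RASTER_TYPE, 0, 1, 1,  # PixelIsArea
        _PROJECTED_CS_TYPE, 0, 1, _DEFAULT_EPSG,
    )
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0)),
        (_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def aggregate_mean(fine: Grid, factor: int) -> Grid:
    """Areal-mean aggregation of a fine grid onto a coarser grid.

    Each coarse cell is the mean of the unmasked fine cells it covers; it is
    masked iff *all* covered fine cells are masked.  Partial blocks at the
    right/bottom edge are averaged over the cells present, so dimensions
    need not be multiples of ``factor``.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return Grid(fine.values.copy(), fine.cell_size, fine.origin,
                    fine.nodata_mask.copy())
    rows, cols = fine.shape
    out_rows = -(-rows // factor)
    out_cols = -(-cols // factor)
    padded = np.full((out_rows * factor, out_cols * factor), np.nan)
    padded[:rows, :cols] = fine.masked_values()
    blocks = padded.reshape(out_rows, factor, out_cols, factor)
    with np.errstate(invalid="ignore"):
        counts = np.sum(~np.isnan(blocks), axis=(1, 3))
        sums = np.nansum(blocks, axis=(1, 3))
    mask = counts == 0
    values = np.where(mask, np.nan, sums / np.maximum(counts, 1))
    values = np.where(mask, 0.0, values)
    return Grid(
        values=values,
        cell_size=fine.cell_size * factor,
        origin=fine.origin,
        nodata_mask=mask,
    )


def bilinear_resample(
    coarse: Grid,
    target_cell_size: float,
    target_shape: tuple[int, int],
    target_origin: tuple[float, float] | None = None,
) -> Grid:
    """Resample a coarse grid onto a finer target geometry bilinearly.

    Interpolation is between coarse *cell centres*.  Outside the outermost
    centres the value is clamped to the nearest valid sample (constant
    extrapolation), so a coarse field whose extent covers the target still
    serves border cells.  Masked coarse cells are excluded by renormalising
    the four corner weights; the output is masked only where all four
    neighbours are masked.
    """
    if target_cell_size <= 0:
        raise ValueError("target_cell_size must be positive")
    t_rows, t_cols = int(target_shape[0]), int(target_shape[1])
    if t_rows < 1 or t_cols < 1:
        raise ValueError("empty target geometry")
    if target_origin is None:
        target_origin = coarse.origin
    ox, oy = float(target_origin[0]), float(target_origin[1])

    c_rows, c_cols = coarse.shape
    cs = coarse.cell_size

    # target cell centres expressed as fractional coarse indices
    tx = ox + (np.arange(t_cols) + 0.5) * target_cell_size
    ty = oy - (np.arange(t_rows) + 0.5) * target_cell_size
    fx = (tx - (coarse.origin[0] + 0.5 * cs)) / cs
    fy = ((coarse.origin[1] - 0.5 * cs) - ty) / cs
    fx = np.clip(fx, 0.0, c_cols - 1.0)
    fy = np.clip(fy, 0.0, c_rows - 1.0)

    c0 = np.floor(fx).astype(int)
    r0 = np.floor(fy).astype(int)
    c1 = np.minimum(c0 + 1, c_cols - 1)
    r1 = np.minimum(r0 + 1, c_rows - 1)
    wx = fx - c0
    wy = fy - r0

    WX, WY = np.meshgrid(wx, wy)
    C0, R0 = np.meshgrid(c0, r0)
    C1, R1 = np.meshgrid(c1, r1)

    vals = coarse.values
    valid = ~coarse.nodata_mask

    out = np.zeros((t_rows, t_cols))
    wsum = np.zeros((t_rows, t_cols))
    for R, C, W in (
        (R0, C0, (1 - WX) * (1 - WY)),
        (R0, C1, WX * (1 - WY)),
        (R1, C0, (1 - WX) * WY),
        (R1, C1, WX * WY),
    ):
        w = W * valid[R, C]
        out += w * vals[R, C]
        wsum += w
    mask = wsum <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(mask, 0.0, out / np.where(mask, 1.0, wsum))
    return Grid(values=values, cell_size=float(target_cell_size),
                origin=(ox, oy), nodata_mask=mask)
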