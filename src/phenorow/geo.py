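"""Georeferenced raster containers, GeoTIFF I/O and coordinate transforms.

The raster model is deliberately small: a band-major float/int array, an
affine geotransform mapping pixel (col, row) to projected world (x, y)
metres, a CRS identifier (``EPSG:xxxxx``), band labels with nominal centre
wavelengths, and a nodata value.  Pixels are 0-based ``(col, row)``;
rectangles are half-open ``[x0, x1) x [y0, y1)`` so that adjacent regions
partition exactly.

GeoTIFF files are written with the standard GeoTIFF tags
(ModelPixelScale, ModelTiepoint, GeoKeyDirectory and the GDAL nodata tag)
so round-trips preserve geometry bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "Affine",
    "MultibandRaster",
    "GroundControlPoint",
    "RasterFormatError",
    "GeometryError",
    "read_raster",
    "write_raster",
    "pixel_to_world",
    "world_to_pixel",
    "estimate_homography",
    "perspective_transform",
    "PerspectiveMapping",
]

# Nominal band centre wavelengths (nm) of a five-band multispectral camera.
BAND_WAVELENGTHS = {
    "blue": 475.0,
    "green": 560.0,
    "red": 668.0,
    "red_edge": 717.0,
    "nir": 840.0,
}
DEFAULT_NODATA = -9999.0

_TAG_PIXELSCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113


class RasterFormatError(ValueError):
    """Raster file is missing required georeferencing metadata."""


class GeometryError(ValueError):
    """Degenerate control-point geometry (collinear or concave corners)."""


@dataclass(frozen=True)
class Affine:
    """Affine geotransform: world = origin + pixel * scale.

    ``y_scale`` is normally negative (row index grows southwards).
    """

    x_origin: float
    y_origin: float
    x_scale: float
    y_scale: float

    def forward(self, col, row):
        """Pixel (col, row) -> world (x, y). Accepts arrays."""
        return (
            self.x_origin + np.asarray(col) * self.x_scale,
            self.y_origin + np.asarray(row) * self.y_scale,
        )

    def inverse(self, x, y):
        """World (x, y) -> fractional pixel (col, row)."""
        return (
            (np.asarray(x) - self.x_origin) / self.x_scale,
            (np.asarray(y) - self.y_origin) / self.y_scale,
        )


@dataclass(frozen=True)
class GroundControlPoint:
    """Marker with known world coordinates and its pixel location."""

    id: str
    world_x: float
    world_y: float
    pixel_col: float
    pixel_row: float


@dataclass
class MultibandRaster:
    """Band-major pixel grid with shared geotransform and CRS.

    ``data`` has shape (n_bands, height, width); ``band_labels`` names each
    band in order; ``wavelengths_nm`` are the nominal band centres.
    """

    data: np.ndarray
    transform: Affine
    crs: str
    band_labels: tuple = ()
    wavelengths_nm: tuple = ()
    nodata: float = DEFAULT_NODATA

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("raster data must be (bands, height, width)")
        if self.band_labels and len(self.band_labels) != self.data.shape[0]:
            raise ValueError("band_labels length must match band count")
        self.band_labels = tuple(self.band_labels)
        self.wavelengths_nm = tuple(self.wavelengths_nm)

    @property
    def n_bands(self):
        return self.data.shape[0]

    @property
    def shape(self):
        """(height, width) of every band."""
        return self.data.shape[1:]

    def band(self, label: str) -> np.ndarray:
        """Return the 2-D grid of the named band."""
        try:
            i = self.band_labels.index(label)
        except ValueError:
            raise KeyError(
                f"band {label!r} not present; have {list(self.band_labels)}"
            ) from None
        return self.data[i]

    def mask_valid(self, band_index: int = 0) -> np.ndarray:
        band = self.data[band_index]
        if self.nodata is None or np.isnan(self.nodata):
            return ~np.isnan(band)
        return band != self.nodata


def pixel_to_world(raster: MultibandRaster, col, row):
    """Map 0-based pixel indices to world coordinates (pixel corner)."""
    return raster.transform.forward(col, row)


def world_to_pixel(raster: MultibandRaster, x, y):
    """Inverse of :func:`pixel_to_world` (fractional pixel indices)."""
    return raster.transform.inverse(x, y)


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def write_raster(raster: MultibandRaster, path) -> None:
    """Write a multiband GeoTIFF with geotransform, CRS and band metadata."""
    t = raster.transform
    if not raster.crs:
        raise RasterFormatError("raster has no CRS; refusing to write")
    epsg = int(str(raster.crs).split(":")[-1])
    # GeoKeyDirectory: version, revision, minor, count, then 4-shorts per key.
    geokeys = (
        1, 1, 0, 3,
        1024, 0, 1, 1,      # GTModelType = projected
        1025, 0, 1, 1,      # GTRasterType = PixelIsArea
        3072, 0, 1, epsg,   # ProjectedCSType
    )
    extratags = [
        (_TAG_PIXELSCALE, "d", 3, (abs(t.x_scale), abs(t.y_scale), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x_origin, t.y_origin, 0.0)),
        (_TAG_GEOKEYS, "H", len(geokeys), geokeys),
        (
            _TAG_GDAL_NODATA, "s", 0,
            str(int(raster.nodata))
            if float(raster.nodata).is_integer()
            else str(raster.nodata),
        ),
    ]
    meta = {
        "band_labels": list(raster.band_labels),
        "wavelengths_nm": list(raster.wavelengths_nm),
        "y_scale_sign": -1 if t.y_scale < 0 else 1,
    }
    tifffile.imwrite(
        path,
        raster.data,
        photometric="minisblack",
        planarconfig="separate" if raster.n_bands > 1 else None,
        extratags=extratags,
        description=json.dumps(meta),
    )


def read_raster(path) -> MultibandRaster:
    """Read a GeoTIFF written by :func:`write_raster` (or compatible)."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = page.tags
        if _TAG_PIXELSCALE not in tags or _TAG_TIEPOINT not in tags:
            raise RasterFormatError(
                f"{path}: missing GeoTIFF geotransform tags "
                "(ModelPixelScale/ModelTiepoint)"
            )
        if _TAG_GEOKEYS not in tags:
            raise RasterFormatError(f"{path}: missing GeoKeyDirectory (no CRS)")
        scale = tags[_TAG_PIXELSCALE].value
        tie = tags[_TAG_TIEPOINT].value
        geokeys = tags[_TAG_GEOKEYS].value
        epsg = None
        for i in range(4, len(geokeys), 4):
            if geokeys[i] == 3072:
                epsg = geokeys[i + 3]
        if epsg is None:
            raise RasterFormatError(f"{path}: GeoKeyDirectory lacks a CRS code")
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
        meta = {}
        desc = page.description
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
        data = tif.asarray()
    y_sign = meta.get("y_scale_sign", -1)
    transform = Affine(
        x_origin=tie[3], y_origin=tie[4],
        x_scale=scale[0], y_scale=y_sign * scale[1],
    )
    return MultibandRaster(
        data=data,
        transform=transform,
        crs=f"EPSG:{epsg}",
        band_labels=tuple(meta.get("band_labels", ())),
        wavelengths_nm=tuple(meta.get("wavelengths_nm", ())),
        nodata=nodata,
    )


# ---------------------------------------------------------------------------
# Perspective rectification


def estimate_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """DLT homography from >= 4 point correspondences (rows of (x, y))."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape[0] < 4:
        raise GeometryError("need at least 4 correspondences")
    rows = []
    for (x, y), (u, v) in zip(src, dst):
        rows.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        rows.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    a = np.asarray(rows)
    _, s, vt = np.linalg.svd(a)
    if s[-2] < 1e-9 * s[0]:
        raise GeometryError("degenerate correspondences (collinear points?)")
    h = vt[-1].reshape(3, 3)
    return h / h[2, 2]


def _apply_homography(h: np.ndarray, pts: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    ones = np.ones((pts.shape[0], 1))
    p = np.hstack([pts, ones]) @ h.T
    return p[:, :2] / p[:, 2:3]


def _polygon_signed_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _check_convex_quad(pts: np.ndarray) -> None:
    if pts.shape != (4, 2):
        raise GeometryError("exactly 4 corner points required")
    crosses = []
    for i in range(4):
        a, b, c = pts[i], pts[(i + 1) % 4], pts[(i + 2) % 4]
        u, v = b - a, c - b
        crosses.append(u[0] * v[1] - u[1] * v[0])
    crosses = np.asarray(crosses, dtype=float)
    if np.any(np.abs(crosses) < 1e-12) or not (
        np.all(crosses > 0) or np.all(crosses < 0)
    ):
        raise GeometryError("corner GCPs are collinear or form a concave quad")


@dataclass
class PerspectiveMapping:
    """Forward/inverse pixel mapping of a perspective rectification.

    ``rectified_to_source`` maps rectified pixel coords back into the source
    raster; combined with the source geotransform it reports any rectified
    polygon in world coordinates.
    """

    homography: np.ndarray          # source px -> rectified px
    source_transform: Affine
    crs: str

    def source_to_rectified(self, pts):
        return _apply_homography(self.homography, pts)

    def rectified_to_source(self, pts):
        return _apply_homography(np.linalg.inv(self.homography), pts)

    def rectified_to_world(self, pts):
        src = self.rectified_to_source(pts)
        x, y = self.source_transform.forward(src[:, 0], src[:, 1])
        return np.column_stack([x, y])


def perspective_transform(
    raster: MultibandRaster,
    corner_gcps,
    order: str = "nearest",
):
    """Crop and rotate the quadrilateral spanned by 4 corner GCPs upright.

    The corners (any cyclic order) are mapped to an axis-aligned output
    rectangle whose side lengths preserve the mean source-edge lengths, so
    trial rows and blocks come out orthogonal to the image axes.  Returns
    ``(rectified MultibandRaster, PerspectiveMapping)``.

    Nearest-neighbour resampling is the default so vegetation-index extrema
    are preserved; pass ``order="bilinear"`` for smooth interpolation.
    """
    pts = np.asarray(
        [[g.pixel_col, g.pixel_row] for g in corner_gcps], dtype=float
    )
    # order corners clockwise in image coords starting top-left
    c = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0])
    pts = pts[np.argsort(ang)]
    top_left = np.argmin(pts.sum(axis=1))
    pts = np.roll(pts, -top_left, axis=0)
    _check_convex_quad(pts)

    tl, tr, br, bl = pts
    width = int(round((np.linalg.norm(tr - tl) + np.linalg.norm(br - bl)) / 2))
    height = int(round((np.linalg.norm(bl - tl) + np.linalg.norm(br - tr)) / 2))
    if width < 1 or height < 1:
        raise GeometryError("rectified output would be empty")
    dst = np.asarray(
        [[0, 0], [width, 0], [width, height], [0, height]], dtype=float
    )
    h = estimate_homography(pts, dst)
    hinv = np.linalg.inv(h)

    cols, rows_ = np.meshgrid(
        np.arange(width) + 0.5, np.arange(height) + 0.5
    )
    src = _apply_homography(hinv, np.column_stack([cols.ravel(), rows_.ravel()]))
    sc = src[:, 0].reshape(height, width) - 0.5
    sr = src[:, 1].reshape(height, width) - 0.5

    out = np.empty((raster.n_bands, height, width), dtype=raster.data.dtype)
    if order == "nearest":
        ic = np.clip(np.rint(sc).astype(np.intp), 0, raster.shape[1] - 1)
        ir = np.clip(np.rint(sr).astype(np.intp), 0, raster.shape[0] - 1)
        for b in range(raster.n_bands):
            out[b] = raster.data[b][ir, ic]
    elif order == "bilinear":
        from scipy.ndimage import map_coordinates

        for b in range(raster.n_bands):
            out[b] = map_coordinates(
                raster.data[b].astype(float), [sr, sc], order=1, mode="nearest"
            ).astype(raster.data.dtype)
    else:
        raise ValueError("order must be 'nearest' or 'bilinear'")

    rect = MultibandRaster(
        data=out,
        # rectified grid keeps a nominal transform at the source pixel scale
        transform=Affine(0.0, 0.0, 1.0, 1.0),
        crs=raster.crs,
        band_labels=raster.band_labels,
        wavelengths_nm=raster.wavelengths_nm,
        nodata=raster.nodata,
    )
    mapping = PerspectiveMapping(
        homography=h, source_transform=raster.transform, crs=raster.crs
    )
    return rect, mapping
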