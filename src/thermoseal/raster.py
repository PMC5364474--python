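"""Georeferenced thermal raster container and GeoTIFF I/O.

A thermal spatial index is a single-band raster of surface temperatures in
degrees Celsius on a projected, meter-unit grid (typically 8 cm ground
sampling distance from a UAS thermal survey). Rasters are stored north-up:
row 0 is the northernmost row, and the center of pixel (r, c) sits at
``(origin_x + (c + 0.5) * gsd, origin_y - (r + 0.5) * gsd)``.

GeoTIFF files are read and written with :mod:`tifffile`, carrying the
standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory) and
GDAL's nodata tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from shapely.geometry import shape as geojson_shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid
import shapely

__all__ = [
    "GridTransform",
    "ThermalRaster",
    "ExclusionMask",
    "read_thermal_index",
    "write_thermal_index",
    "read_exclusion_mask",
    "apply_exclusion_mask",
]

# GeoTIFF / GDAL TIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024        # 1 = projected, 2 = geographic
_KEY_RASTER_TYPE = 1025       # 1 = PixelIsArea
_KEY_PROJECTED_CS = 3072      # EPSG code of the projected CRS
_KEY_GEOGRAPHIC_CS = 2048     # EPSG code of a geographic CRS
_KEY_LINEAR_UNITS = 3076      # 9001 = metre

# Common geographic (degree-unit) EPSG codes we can recognise without a full
# CRS database; anything flagged geographic in the GeoKeys is also rejected.
_KNOWN_GEOGRAPHIC_EPSG = {4326, 4269, 4267, 4258, 4617, 4171, 4283, 4019}


@dataclass(frozen=True)
class GridTransform:
    """North-up affine grid-to-world mapping.

    Parameters
    ----------
    origin_x, origin_y
        World coordinates (meters) of the *outer corner* of pixel (0, 0),
        i.e. the north-west corner of the raster.
    gsd_m
        Pixel edge length in meters (square pixels).
    """

    origin_x: float
    origin_y: float
    gsd_m: float

    def __post_init__(self) -> None:
        if not (self.gsd_m > 0):
            raise ValueError(f"gsd_m must be positive, got {self.gsd_m}")

    def xy(self, row, col):
        """World coordinates of pixel-center(s) for grid indices."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.gsd_m
        y = self.origin_y - (np.asarray(row) + 0.5) * self.gsd_m
        return x, y

    def corner(self, row, col):
        """World coordinates of the north-west corner of pixel (row, col)."""
        x = self.origin_x + np.asarray(col) * self.gsd_m
        y = self.origin_y - np.asarray(row) * self.gsd_m
        return x, y

    def rowcol(self, x, y):
        """Fractional grid indices of world coordinates."""
        col = (np.asarray(x) - self.origin_x) / self.gsd_m
        row = (self.origin_y - np.asarray(y)) / self.gsd_m
        return row, col


def _parse_epsg(crs) -> int:
    if isinstance(crs, int):
        return crs
    s = str(crs).strip().upper()
    if s.startswith("EPSG:"):
        s = s.split(":", 1)[1]
    try:
        return int(s)
    except ValueError as exc:
        raise ValueError(
            f"CRS must be an EPSG code (int or 'EPSG:nnnn'), got {crs!r}"
        ) from exc


@dataclass
class ThermalRaster:
    """Single-band temperature grid (°C) with georeference.

    ``values`` is a 2-D float array; cells equal to ``nodata`` (or NaN) are
    outside the analysis area. ``crs`` is the EPSG code of a projected,
    meter-unit coordinate reference system.
    """

    values: np.ndarray
    transform: GridTransform
    crs: int
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty 2-D grid")
        self.crs = _parse_epsg(self.crs)
        if self.crs in _KNOWN_GEOGRAPHIC_EPSG:
            raise ValueError(
                f"EPSG:{self.crs} is a geographic (degree-unit) CRS; "
                "reproject the raster to a projected, meter-unit CRS first"
            )
        valid = self.valid_mask
        if not np.all(np.isfinite(self.values[valid])):
            raise ValueError("non-nodata values must be finite")

    @property
    def gsd_m(self) -> float:
        return self.transform.gsd_m

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean grid: True where a cell carries a real temperature."""
        with np.errstate(invalid="ignore"):
            return ~(np.isnan(self.values) | (self.values == self.nodata))

    def pixel_centers(self):
        """World coordinates of every pixel center (two 2-D arrays)."""
        rows, cols = np.indices(self.shape)
        return self.transform.xy(rows, cols)


@dataclass
class ExclusionMask:
    """World-coordinate polygons excluded from analysis.

    Used to remove landscape whose ambient temperature overlaps seal body
    temperature (e.g. sun-warmed rock along an island edge). Geometries are
    repaired with :func:`shapely.validation.make_valid` on construction.
    """

    polygons: list = field(default_factory=list)
    crs: int | None = None

    def __post_init__(self) -> None:
        repaired = []
        for geom in self.polygons:
            if not isinstance(geom, BaseGeometry):
                geom = geojson_shape(geom)
            if not geom.is_valid:
                geom = make_valid(geom)
            repaired.append(geom)
        self.polygons = repaired
        if self.crs is not None:
            self.crs = _parse_epsg(self.crs)


def _geokeys_projected(epsg: int) -> tuple[int, ...]:
    # GeoKeyDirectory: header (version, rev, minor, nkeys) then 4-tuples
    keys = [
        (_KEY_MODEL_TYPE, 0, 1, 1),       # projected
        (_KEY_RASTER_TYPE, 0, 1, 1),      # PixelIsArea
        (_KEY_PROJECTED_CS, 0, 1, epsg),
        (_KEY_LINEAR_UNITS, 0, 1, 9001),  # metre
    ]
    out = [1, 1, 0, len(keys)]
    for k in keys:
        out.extend(k)
    return tuple(out)


def write_thermal_index(raster: ThermalRaster, path) -> None:
    """Write a ThermalRaster as a single-band float GeoTIFF."""
    t = raster.transform
    geokeys = _geokeys_projected(raster.crs)
    nodata_ascii = str(raster.nodata)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.gsd_m, t.gsd_m, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.origin_x, t.origin_y, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_TAG_GDAL_NODATA, "s", len(nodata_ascii) + 1, nodata_ascii),
    ]
    tifffile.imwrite(
        str(path),
        raster.values.astype(np.float64),
        photometric="minisblack",
        extratags=extratags,
    )


def _geokey_dict(directory: Sequence[int]) -> dict[int, int]:
    d = np.asarray(directory).ravel()
    nkeys = int(d[3])
    out = {}
    for i in range(nkeys):
        key, tag_loc, count, value = d[4 + 4 * i : 8 + 4 * i]
        if tag_loc == 0 and count == 1:
            out[int(key)] = int(value)
    return out


def read_thermal_index(path) -> ThermalRaster:
    """Read a single-band georeferenced GeoTIFF of temperatures (°C).

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        For a multi-band raster, a missing georeference or CRS, or a
        geographic (degree-unit) CRS.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        spp = page.tags.get("SamplesPerPixel")
        n_bands = int(spp.value) if spp is not None else 1
        if len(tif.pages) > 1:
            n_bands = max(n_bands, len(tif.pages))
        if n_bands != 1:
            raise ValueError(
                f"expected single band thermal raster, got {n_bands} bands"
            )
        values = page.asarray().astype(np.float64)
        if values.ndim == 3:
            raise ValueError(
                f"expected single band thermal raster, got {values.shape[-1]} bands"
            )

        scale_tag = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
        tie_tag = page.tags.get(_TAG_MODEL_TIEPOINT)
        if scale_tag is None or tie_tag is None:
            raise ValueError("raster has no GeoTIFF georeference tags")
        sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
        if not np.isclose(sx, sy, rtol=1e-9):
            raise ValueError(f"non-square pixels ({sx} x {sy} m) not supported")
        tp = tie_tag.value
        # tiepoint maps raster (i, j) -> world (x, y); standard is (0,0)->NW corner
        origin_x = float(tp[3]) - float(tp[0]) * sx
        origin_y = float(tp[4]) + float(tp[1]) * sy

        geo_tag = page.tags.get(_TAG_GEO_KEY_DIRECTORY)
        if geo_tag is None:
            raise ValueError("raster has no CRS (GeoKeyDirectory missing)")
        keys = _geokey_dict(geo_tag.value)
        model_type = keys.get(_KEY_MODEL_TYPE)
        if model_type == 2 or (_KEY_PROJECTED_CS not in keys and _KEY_GEOGRAPHIC_CS in keys):
            raise ValueError(
                "raster CRS is geographic (degree units); reproject to a "
                "projected, meter-unit CRS before analysis"
            )
        epsg = keys.get(_KEY_PROJECTED_CS)
        if epsg is None:
            raise ValueError("raster has no projected CRS code in its GeoKeys")

        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        nodata = float(nodata_tag.value) if nodata_tag is not None else -9999.0

    return ThermalRaster(
        values=values,
        transform=GridTransform(origin_x, origin_y, sx),
        crs=int(epsg),
        nodata=nodata,
    )


def read_exclusion_mask(path, crs: int | None = None) -> ExclusionMask:
    """Read polygons from a GeoJSON file into an ExclusionMask."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [f["geometry"] for f in gj["features"]]
    elif gj.get("type") == "Feature":
        geoms = [gj["geometry"]]
    else:
        geoms = [gj]
    return ExclusionMask(polygons=[geojson_shape(g) for g in geoms], crs=crs)


def apply_exclusion_mask(raster: ThermalRaster, mask: ExclusionMask) -> ThermalRaster:
    """Set every pixel whose center lies inside a mask polygon to nodata.

    Pixel-center point-in-polygon semantics: a pixel is removed iff its
    center is covered by (inside or on the boundary of) any mask polygon.
    Returns a new raster; the input is untouched.
    """
    if mask.crs is not None and mask.crs != raster.crs:
        raise ValueError(
            f"mask CRS EPSG:{mask.crs} does not match raster CRS EPSG:{raster.crs}"
        )
    values = raster.values.copy()
    if not mask.polygons:
        return replace(raster, values=values)

    nrows, ncols = raster.shape
    t = raster.transform
    for poly in mask.polygons:
        if poly.is_empty:
            continue
        minx, miny, maxx, maxy = poly.bounds
        # candidate window of pixel centers overlapping the polygon bbox
        r0, c0 = t.rowcol(minx, maxy)
        r1, c1 = t.rowcol(maxx, miny)
        ri = np.arange(max(0, int(np.floor(r0 - 0.5))), min(nrows, int(np.ceil(r1 + 0.5))))
        ci = np.arange(max(0, int(np.floor(c0 - 0.5))), min(ncols, int(np.ceil(c1 + 0.5))))
        if ri.size == 0 or ci.size == 0:
            continue
        rr, cc = np.meshgrid(ri, ci, indexing="ij")
        xs, ys = t.xy(rr.ravel(), cc.ravel())
        inside = shapely.intersects_xy(poly, xs, ys)
        values[rr.ravel()[inside], cc.ravel()[inside]] = raster.nodata
    return replace(raster, values=values)
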