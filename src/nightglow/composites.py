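"""Georeferenced single-band composites and region masks.

The on-disk format is single-band GeoTIFF. Raw annual composites hold 6-bit
digital numbers (DN 0..63, stored as uint8 with 255 as the nodata sentinel);
calibrated composites hold real-valued DN on the base-year scale (float32 with
NaN as nodata). Georeferencing (GDAL-style geotransform and a CRS identifier)
plus year / satellite identity travel as a JSON document in the TIFF
ImageDescription tag, so no GDAL stack is required to round-trip the files.

Sea and shifted-out pixels are carried as an explicit ``nodata_mask`` and are
excluded from every downstream fit, correlation, mean and proportion: DN 0 is
a meaningful "dark land" value and must not be conflated with missing data.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

from .errors import AlignmentError, FormatError, ValidationError

DN_MIN = 0
DN_MAX = 63
#: uint8 sentinel used for nodata in raw composites (valid DN are 0..63).
RAW_NODATA = 255

#: default geotransform: 1 km pixels, origin at (0, 0), north-up
DEFAULT_GEOTRANSFORM = (0.0, 1000.0, 0.0, 0.0, 0.0, -1000.0)
DEFAULT_CRS = "EPSG:32630"

_FILENAME_RE = re.compile(r"(?P<sat>[A-Za-z0-9]+)_(?P<year>\d{4})")


def pixel_area_km2(geotransform: Sequence[float]) -> float:
    """Pixel footprint in km² from a GDAL-style geotransform (metre units)."""
    return abs(geotransform[1] * geotransform[5]) / 1e6


@dataclass
class AnnualComposite:
    """One year's nighttime-lights composite for one satellite.

    Parameters
    ----------
    year : int
        Calendar year of the annual composite.
    satellite_id : str
        Short satellite label, e.g. ``"F12"``.
    grid : ndarray
        2-D pixel values. Integer DN in [0, 63] for raw composites,
        real-valued DN in [0.0, 63.0] after calibration.
    geotransform : tuple of 6 floats
        GDAL-ordered affine transform (x0, dx, 0, y0, 0, -dy).
    crs_id : str
        Coordinate-reference identifier, e.g. ``"EPSG:32630"``.
    nodata_mask : ndarray of bool
        True where the pixel is sea / missing / shifted-out.
    calibrated : bool
        Whether ``grid`` is on the real-valued base-year scale.
    """

    year: int
    satellite_id: str
    grid: np.ndarray
    geotransform: tuple = DEFAULT_GEOTRANSFORM
    crs_id: str = DEFAULT_CRS
    nodata_mask: np.ndarray = None
    calibrated: bool = False

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValidationError(f"grid must be 2-D, got shape {self.grid.shape}")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.grid.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.grid.shape:
            raise ValidationError("nodata_mask shape differs from grid shape")
        self.geotransform = tuple(float(g) for g in self.geotransform)
        self._validate_range()

    def _validate_range(self):
        vals = self.grid[~self.nodata_mask]
        if vals.size == 0:
            return
        if not self.calibrated:
            if not np.issubdtype(self.grid.dtype, np.integer):
                raise ValidationError("raw composite grid must have integer dtype")
            bad = vals[(vals < DN_MIN) | (vals > DN_MAX)]
            if bad.size:
                raise ValidationError(
                    f"DN value {int(bad[0])} outside [{DN_MIN}, {DN_MAX}] "
                    f"in {self.satellite_id}_{self.year}"
                )
        else:
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < DN_MIN - 1e-9 or finite.max() > DN_MAX + 1e-9):
                raise ValidationError(
                    f"calibrated value outside [0, 63] in {self.satellite_id}_{self.year}"
                )

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    @property
    def pixel_area_km2(self) -> float:
        return pixel_area_km2(self.geotransform)

    @property
    def key(self) -> tuple:
        return (self.year, self.satellite_id)

    def with_grid(self, grid, nodata_mask=None, calibrated=None) -> "AnnualComposite":
        """Copy of this composite with a replaced grid (same georeferencing)."""
        return replace(
            self,
            grid=grid,
            nodata_mask=self.nodata_mask if nodata_mask is None else nodata_mask,
            calibrated=self.calibrated if calibrated is None else calibrated,
        )


@dataclass
class RegionMask:
    """A named boolean region on the series grid (True = inside region)."""

    region_id: str
    mask: np.ndarray
    pixel_area_km2: float = 1.0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("region mask must be 2-D")

    @property
    def land_area_km2(self) -> float:
        return float(self.mask.sum()) * self.pixel_area_km2

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def _parse_name(path: Path):
    m = _FILENAME_RE.search(path.stem)
    if m is None:
        return None, None
    return m.group("sat"), int(m.group("year"))


def read_composite(path) -> AnnualComposite:
    """Read a single-band composite GeoTIFF.

    Year and satellite come from the embedded JSON metadata when present,
    falling back to the ``<satellite>_<year>`` filename convention. Raw
    integer rasters are validated to DN 0..63; a value outside that range
    raises :class:`ValidationError` naming the offender.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise FormatError(f"{path.name}: expected a single band, got {len(tif.pages)} pages")
        page = tif.pages[0]
        grid = page.asarray()
        desc = page.description or ""
    if grid.ndim == 3:
        raise FormatError(f"{path.name}: multi-band raster not supported")

    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    sat, year = _parse_name(path)
    sat = meta.get("satellite_id", sat)
    year = meta.get("year", year)
    if sat is None or year is None:
        raise FormatError(
            f"{path.name}: no year/satellite metadata and filename does not match '<sat>_<year>'"
        )
    geotransform = tuple(meta.get("geotransform", DEFAULT_GEOTRANSFORM))
    crs_id = meta.get("crs_id", DEFAULT_CRS)
    calibrated = bool(meta.get("calibrated", np.issubdtype(grid.dtype, np.floating)))

    if calibrated:
        nodata = ~np.isfinite(grid)
        grid = grid.astype(np.float64)
        grid[nodata] = 0.0
    else:
        if not np.issubdtype(grid.dtype, np.integer):
            raise FormatError(f"{path.name}: raw composite must be an integer raster")
        nodata = grid == RAW_NODATA
        grid = grid.astype(np.int16)
        grid[nodata] = 0
    return AnnualComposite(
        year=int(year),
        satellite_id=str(sat),
        grid=grid,
        geotransform=geotransform,
        crs_id=crs_id,
        nodata_mask=nodata,
        calibrated=calibrated,
    )


def write_composite(composite: AnnualComposite, path) -> Path:
    """Write a composite as single-band GeoTIFF (uint8 raw / float32 calibrated)."""
    path = Path(path)
    meta = {
        "year": composite.year,
        "satellite_id": composite.satellite_id,
        "geotransform": list(composite.geotransform),
        "crs_id": composite.crs_id,
        "calibrated": composite.calibrated,
    }
    if composite.calibrated:
        out = composite.grid.astype(np.float32)
        out[composite.nodata_mask] = np.nan
    else:
        out = composite.grid.astype(np.uint8)
        out[composite.nodata_mask] = RAW_NODATA
    tifffile.imwrite(path, out, description=json.dumps(meta))
    return path


def write_region_mask(region: RegionMask, path, geotransform=DEFAULT_GEOTRANSFORM,
                      crs_id=DEFAULT_CRS) -> Path:
    path = Path(path)
    meta = {"region_id": region.region_id, "geotransform": list(geotransform),
            "crs_id": crs_id}
    tifffile.imwrite(path, region.mask.astype(np.uint8), description=json.dumps(meta))
    return path


def read_region_mask(path, geotransform=None, shape=None) -> RegionMask:
    """Read a region mask from a boolean GeoTIFF or a GeoJSON polygon.

    GeoJSON polygons are rasterized onto the series grid (pixel-centre
    containment test), which requires ``geotransform`` and ``shape``.
    """
    path = Path(path)
    if path.suffix.lower() in (".json", ".geojson"):
        if geotransform is None or shape is None:
            raise ValueError("rasterizing a polygon requires geotransform and shape")
        doc = json.loads(path.read_text())
        return rasterize_polygon(doc, geotransform, shape, region_id=path.stem)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        mask = page.asarray().astype(bool)
        desc = page.description or ""
    meta = json.loads(desc) if desc else {}
    gt = tuple(meta.get("geotransform", geotransform or DEFAULT_GEOTRANSFORM))
    return RegionMask(meta.get("region_id", path.stem), mask, pixel_area_km2(gt))


def rasterize_polygon(geojson: dict, geotransform, shape, region_id="region") -> RegionMask:
    """Rasterize a GeoJSON (multi)polygon onto the series grid."""
    import shapely
    from shapely.geometry import shape as geom_shape

    if geojson.get("type") == "Feature":
        geojson = geojson["geometry"]
    elif geojson.get("type") == "FeatureCollection":
        from shapely.ops import unary_union
        geom = unary_union([geom_shape(f["geometry"]) for f in geojson["features"]])
        return _rasterize_geom(geom, geotransform, shape, region_id)
    return _rasterize_geom(geom_shape(geojson), geotransform, shape, region_id)


def _rasterize_geom(geom, geotransform, shape, region_id):
    import shapely

    x0, dx, _, y0, _, dy = geotransform
    rows, cols = shape
    cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
    xs = x0 + (cc + 0.5) * dx
    ys = y0 + (rr + 0.5) * dy
    mask = shapely.contains_xy(geom, xs.ravel(), ys.ravel()).reshape(shape)
    return RegionMask(region_id, mask, pixel_area_km2(geotransform))


def align_check(series: Iterable[AnnualComposite]) -> list:
    """Validate that a series shares one grid; return it sorted by year.

    Raises :class:`AlignmentError` listing every composite whose dimensions,
    geotransform or CRS differ from the first.
    """
    series = list(series)
    if len(series) < 2:
        raise AlignmentError("align_check requires at least 2 composites")
    ref = series[0]
    offenders = [
        f"{c.satellite_id}_{c.year}"
        for c in series[1:]
        if c.shape != ref.shape or c.geotransform != ref.geotransform or c.crs_id != ref.crs_id
    ]
    if offenders:
        raise AlignmentError(
            "composites not on the common grid of "
            f"{ref.satellite_id}_{ref.year}: {', '.join(offenders)}"
        )
    return sorted(series, key=lambda c: (c.year, c.satellite_id))
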