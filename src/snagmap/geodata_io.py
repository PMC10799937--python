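"""Raster and vector I/O, grid conventions, tiling and run configuration.

All geometry lives in the projected CRS of the input (map units = metres).
Pixel indexing is row-major with the origin at the top-left corner and
half-open intervals, matching the GeoTIFF convention, so buffer distances
(6 m, 1 px) are unambiguous.

Rasters are GeoTIFFs written and parsed through :mod:`tifffile`; the
georeferencing tags handled are ModelPixelScale (33550), ModelTiepoint
(33922), the GeoKeyDirectory (34735, projected/geographic EPSG code) and
GDAL_NODATA (42113).  Vectors are GeoJSON feature collections with shapely
geometries.  CRS is carried as an identifier string ("EPSG:32610"); inputs
must agree — no reprojection is performed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import tifffile
from shapely.geometry import mapping as geom_mapping, shape as geom_shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

logger = logging.getLogger("snagmap")

# GeoTIFF tag codes
_TAG_PIXELSCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113
_GEOKEY_MODEL_TYPE = 1024
_GEOKEY_GEOGRAPHIC = 2048
_GEOKEY_PROJECTED = 3072


def configure_logging(level: str = "INFO") -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level.upper())


class Affine(NamedTuple):
    """Geotransform mapping pixel (col, row) to map (x, y).

    ``x = a*col + b*row + c``; ``y = d*col + e*row + f``.  For a north-up
    raster ``a`` is the pixel width and ``e`` the negative pixel height.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def __mul__(self, colrow):  # type: ignore[override]
        col, row = colrow
        return (self.a * col + self.b * row + self.c,
                self.d * col + self.e * row + self.f)

    @property
    def determinant(self) -> float:
        return self.a * self.e - self.b * self.d

    def invert(self, x: float, y: float) -> tuple[float, float]:
        """Map coordinates back to fractional (col, row)."""
        det = self.determinant
        if det == 0:
            raise ValueError("geotransform is singular")
        dx, dy = x - self.c, y - self.f
        col = (self.e * dx - self.b * dy) / det
        row = (-self.d * dx + self.a * dy) / det
        return col, row

    @classmethod
    def north_up(cls, x0: float, y0: float, pixel: float) -> "Affine":
        return cls(pixel, 0.0, x0, 0.0, -pixel, y0)


@dataclass
class RasterTile:
    """A georeferenced raster: 4-band uint8 imagery or any single-band array.

    ``pixels`` has shape (bands, rows, cols).
    """

    pixels: np.ndarray
    transform: Affine
    crs: str
    nodata: float | None = None

    def __post_init__(self) -> None:
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[None, :, :]
        if self.transform.determinant == 0:
            raise ValueError("geotransform must be invertible")
        if not self.crs:
            raise ValueError("CRS is required")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    @property
    def n_bands(self) -> int:
        return self.pixels.shape[0]

    @property
    def pixel_size(self) -> float:
        return math.hypot(self.transform.a, self.transform.d)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the pixel footprint."""
        h, w = self.shape
        xs, ys = zip(self.transform * (0, 0), self.transform * (w, 0),
                     self.transform * (0, h), self.transform * (w, h))
        return min(xs), min(ys), max(xs), max(ys)


@dataclass
class VectorLayer:
    """Geometry + attribute records in a shared projected CRS.

    Invalid geometries are repaired with :func:`shapely.validation.make_valid`
    on construction.
    """

    features: list[dict]
    crs: str

    def __post_init__(self) -> None:
        if not self.crs:
            raise ValueError("CRS is required")
        for feat in self.features:
            geom = feat["geometry"]
            if isinstance(geom, BaseGeometry) and not geom.is_valid:
                feat["geometry"] = make_valid(geom)

    def __len__(self) -> int:
        return len(self.features)

    def geometries(self) -> list[BaseGeometry]:
        return [f["geometry"] for f in self.features]


@dataclass(frozen=True)
class GridSpec:
    """An axis-aligned analysis grid anchored at ``origin`` (top-left).

    ``extent`` is (ncols, nrows); cells are half-open so a point on a shared
    edge belongs to exactly one cell.
    """

    origin: tuple[float, float]
    cell_size: float
    extent: tuple[int, int]

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if min(self.extent) < 1:
            raise ValueError("grid extent must be at least 1x1")

    @classmethod
    def from_raster(cls, tile: RasterTile, cell_size: float) -> "GridSpec":
        xmin, ymin, xmax, ymax = tile.bounds
        x0 = tile.transform.c
        y0 = tile.transform.f
        ncols = max(1, math.ceil((xmax - x0) / cell_size - 1e-9))
        nrows = max(1, math.ceil((y0 - ymin) / cell_size - 1e-9))
        return cls((x0, y0), cell_size, (ncols, nrows))

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        """(row, col) of the half-open cell containing the point, or None."""
        col = math.floor((x - self.origin[0]) / self.cell_size)
        row = math.floor((self.origin[1] - y) / self.cell_size)
        # top/left edges are inclusive: y == origin_y lands in row 0
        if y == self.origin[1]:
            row = 0
        if x == self.origin[0]:
            col = 0
        if 0 <= row < self.extent[1] and 0 <= col < self.extent[0]:
            return row, col
        return None

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        x0 = self.origin[0] + col * self.cell_size
        y1 = self.origin[1] - row * self.cell_size
        return x0, y1 - self.cell_size, x0 + self.cell_size, y1

    @property
    def transform(self) -> Affine:
        return Affine(self.cell_size, 0.0, self.origin[0],
                      0.0, -self.cell_size, self.origin[1])


@dataclass
class GridLayer:
    """A single-band raster of an aggregated metric at a stated cell size."""

    values: np.ndarray  # (nrows, ncols) float, NaN = nodata
    spec: GridSpec
    crs: str
    metric: str = ""
    bias_corrected: bool = False

    def __post_init__(self) -> None:
        nrows, ncols = self.values.shape
        if (ncols, nrows) != self.spec.extent:
            raise ValueError("values shape does not match grid extent")

    @property
    def nodata_mask(self) -> np.ndarray:
        return np.isnan(self.values)


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with one master seed.

    The config hash is embedded in artifact metadata so every output can be
    traced to the exact parameterisation that produced it.
    """

    # patching / tiling
    patch_size: int = 256
    patch_overlap: int = 32
    # energy encoding
    energy_levels: int = 5
    energy_threshold: float = 0.5
    energy_normalisation: str = "instance"  # or "absolute"
    # loss (Focal Tversky)
    loss_alpha: float = 0.4
    loss_beta: float = 0.6
    loss_gamma: float = 2.0
    # training
    width_preset: str = "small"
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 15
    augment_geometric: float = 0.35
    augment_spectral: float = 0.35
    background_fraction: float = 87 / 714
    # instance extraction
    min_pixels: int = 8
    # staging
    staging_constants: tuple[float, float, float, float] = (5.0, 5.0, 1e7, 1e4)
    literal_exponent: bool = False
    inner_buffer_px: int = 1
    # matching / comparison
    match_buffer_m: float = 6.0
    coverage_threshold: float = 0.5
    # grids
    grid_sizes: tuple[float, ...] = (30.0, 100.0, 240.0, 500.0)
    # eccentricity screening
    ecc_min_area_m2: float = 18.0
    ecc_min_pixels: int = 50
    ecc_flag_threshold: float = 0.8
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("patch_size", "energy_levels", "min_pixels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.energy_threshold < 1):
            raise ValueError("energy_threshold must lie in (0, 1)")
        if not all(math.isfinite(c) and c > 0 for c in self.staging_constants):
            raise ValueError("staging constants must be finite and positive")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        for key in ("staging_constants", "grid_sizes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# Raster I/O


def _epsg_code(crs: str) -> int | None:
    crs = crs.strip().upper()
    if crs.startswith("EPSG:"):
        try:
            return int(crs.split(":")[1])
        except ValueError:
            return None
    return None


def _geo_extratags(tile_transform: Affine, crs: str, nodata: float | None) -> list:
    t = tile_transform
    sx = math.hypot(t.a, t.d)
    sy = math.hypot(t.b, t.e)
    tags = [
        (_TAG_PIXELSCALE, "d", 3, (sx, sy, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.c, t.f, 0.0)),
    ]
    code = _epsg_code(crs)
    if code is not None:
        key = _GEOKEY_GEOGRAPHIC if code == 4326 else _GEOKEY_PROJECTED
        directory = (1, 1, 0, 2, _GEOKEY_MODEL_TYPE, 0, 1, 1 if key == _GEOKEY_PROJECTED else 2,
                     key, 0, 1, code)
        tags.append((_TAG_GEOKEYS, "H", len(directory), directory))
    if nodata is not None:
        nd = str(nodata)
        tags.append((_TAG_GDAL_NODATA, "s", len(nd) + 1, nd))
    return tags


def write_raster(path: str | Path, tile: RasterTile, description: str | None = None) -> None:
    """Write a RasterTile as a GeoTIFF (planar band layout)."""
    data = tile.pixels
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        planarconfig="separate" if data.shape[0] > 1 else None,
        description=description,
        metadata=None,
        extratags=_geo_extratags(tile.transform, tile.crs, tile.nodata),
    )


def read_raster(path: str | Path, require_bands: int = 3) -> RasterTile:
    """Read a GeoTIFF into a RasterTile.

    Three-band inputs get a synthesised all-zero NIR band (with a warning) so
    downstream code can rely on four bands.  A missing CRS is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            tags = tif.pages[0].tags
            description = tags.valueof(270)
            scale = tags.valueof(_TAG_PIXELSCALE)
            tiepoint = tags.valueof(_TAG_TIEPOINT)
            geokeys = tags.valueof(_TAG_GEOKEYS)
            nodata_tag = tags.valueof(_TAG_GDAL_NODATA)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise IOError(f"not a readable GeoTIFF: {path}") from exc
    if data.ndim == 2:
        data = data[None]
    elif data.ndim == 3 and data.shape[0] > data.shape[2]:
        # height,width,bands layout from interleaved writers
        data = np.moveaxis(data, -1, 0)
    if data.shape[0] < require_bands:
        raise IOError(f"expected >= {require_bands} bands, got {data.shape[0]}")
    if scale is None or tiepoint is None:
        raise IOError(f"missing georeferencing tags in {path}")
    sx, sy = float(scale[0]), float(scale[1])
    x0, y0 = float(tiepoint[3]), float(tiepoint[4])
    transform = Affine(sx, 0.0, x0, 0.0, -sy, y0)
    crs = None
    if geokeys is not None:
        vals = list(geokeys)
        for i in range(4, len(vals), 4):
            if vals[i] in (_GEOKEY_PROJECTED, _GEOKEY_GEOGRAPHIC):
                crs = f"EPSG:{vals[i + 3]}"
    if crs is None:
        raise ValueError(f"no CRS found in {path}")
    nodata = None
    if nodata_tag is not None:
        try:
            nodata = float(str(nodata_tag).strip("\x00 "))
        except ValueError:
            nodata = None
    if data.shape[0] == 3 and require_bands <= 3:
        logger.warning("%s has 3 bands; synthesising an all-zero NIR band", path)
        data = np.concatenate([data, np.zeros_like(data[:1])], axis=0)
    tile = RasterTile(data, transform, crs, nodata)
    tile.description = description  # type: ignore[attr-defined]
    return tile


def write_grid_layer(path: str | Path, layer: GridLayer) -> None:
    meta = json.dumps({"metric": layer.metric, "bias_corrected": layer.bias_corrected,
                       "cell_size": layer.spec.cell_size})
    tifffile.imwrite(
        path,
        layer.values.astype(np.float32),
        description=meta,
        metadata=None,
        extratags=_geo_extratags(layer.spec.transform, layer.crs, float("nan")),
    )


def read_grid_layer(path: str | Path) -> GridLayer:
    tile = read_raster(path, require_bands=1)
    values = tile.pixels[0].astype(float)
    spec = GridSpec((tile.transform.c, tile.transform.f), tile.transform.a,
                    (values.shape[1], values.shape[0]))
    meta = {}
    desc = getattr(tile, "description", None)
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    return GridLayer(values, spec, tile.crs, metric=meta.get("metric", ""),
                     bias_corrected=bool(meta.get("bias_corrected", False)))


# ---------------------------------------------------------------------------
# Vector I/O (GeoJSON)


def write_vector(path: str | Path, layer: VectorLayer) -> None:
    features = []
    for feat in layer.features:
        props = {k: v for k, v in feat.items() if k != "geometry"}
        props.update(feat.get("properties", {}))
        props.pop("properties", None)
        features.append({
            "type": "Feature",
            "geometry": geom_mapping(feat["geometry"]),
            "properties": props,
        })
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": layer.crs}},
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def read_vector(path: str | Path, crs: str | None = None) -> VectorLayer:
    doc = json.loads(Path(path).read_text())
    file_crs = doc.get("crs", {}).get("properties", {}).get("name")
    crs = file_crs or crs
    if not crs:
        raise ValueError(f"no CRS in {path} and none supplied")
    features = []
    for feat in doc.get("features", []):
        rec = dict(feat.get("properties") or {})
        rec["geometry"] = geom_shape(feat["geometry"])
        features.append(rec)
    return VectorLayer(features, crs)


def check_crs(*crs_list: str) -> str:
    """Assert CRS agreement across inputs; returns the shared CRS."""
    unique = {c for c in crs_list if c}
    if len(unique) != 1:
        raise ValueError(f"inputs must share one CRS, got {sorted(unique)}")
    return unique.pop()


# ---------------------------------------------------------------------------
# Tiling


def tile_raster(tile: RasterTile, patch_size: int, overlap: int = 0) -> Iterator[RasterTile]:
    """Split a raster into patches of ``patch_size`` sharing ``overlap`` pixels.

    Patches cover the input completely; the trailing patch is shifted inward
    (extra overlap) rather than padded, except when the raster is smaller than
    one patch, in which case a single zero-padded patch is emitted.
    """
    if not patch_size > overlap >= 0:
        raise ValueError("require patch_size > overlap >= 0")
    h, w = tile.shape
    if h < patch_size or w < patch_size:
        logger.warning("raster %dx%d smaller than patch %d; emitting one padded patch",
                       h, w, patch_size)
        padded = np.zeros((tile.n_bands, max(h, patch_size), max(w, patch_size)),
                          dtype=tile.pixels.dtype)
        padded[:, :h, :w] = tile.pixels
        yield RasterTile(padded, tile.transform, tile.crs, tile.nodata)
        return

    def starts(size: int) -> list[int]:
        step = patch_size - overlap
        out = list(range(0, size - patch_size + 1, step))
        if out[-1] + patch_size < size:
            out.append(size - patch_size)
        return out

    for r0 in starts(h):
        for c0 in starts(w):
            sub = tile.pixels[:, r0:r0 + patch_size, c0:c0 + patch_size]
            x0, y0 = tile.transform * (c0, r0)
            t = tile.transform
            yield RasterTile(sub, Affine(t.a, t.b, x0, t.d, t.e, y0), tile.crs, tile.nodata)


def rasterize_grid_metric(values: Mapping[tuple[int, int], float] | np.ndarray,
                          spec: GridSpec, crs: str, metric: str = "",
                          valid_range: tuple[float, float] | None = None) -> GridLayer:
    """Place per-cell values onto the grid; absent cells become nodata (NaN)."""
    ncols, nrows = spec.extent
    if isinstance(values, np.ndarray):
        grid = values.astype(float)
    else:
        grid = np.full((nrows, ncols), np.nan)
        for (row, col), v in values.items():
            if not (0 <= row < nrows and 0 <= col < ncols):
                raise IndexError(f"cell ({row}, {col}) outside grid extent")
            grid[row, col] = v
    if valid_range is not None:
        lo, hi = valid_range
        bad = np.nansum((grid < lo) | (grid > hi))
        if bad:
            logger.warning("%d cell values outside declared range [%g, %g] (kept)",
                           int(bad), lo, hi)
    return GridLayer(grid, spec, crs, metric=metric)
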