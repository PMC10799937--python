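"""From energy maps to individual crown records.

The watershed stage floods the decoded energy surface downhill from markers
placed on each basin's highest present energy level; ordinal nesting makes
those level cores natural seeds, and a change in the energy-gradient
direction between two touching crowns forms the valley where they split.
Connectivity is 8-neighbour throughout ("connectivity 2" in raster terms).

Each labelled instance then becomes a :class:`CrownRecord`: interior holes
are filled, the filled region is polygonised in map coordinates, and an
ellipse is fitted from second-order image moments to obtain semi-axes a, b,
focal distance c = sqrt(a^2 - b^2) and eccentricity e = c/a — the shape
proxy used to screen view-angle distortion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed

from .energy_encoding import EnergyMap
from .geodata_io import Affine, GridLayer, GridSpec, RasterTile

logger = logging.getLogger("snagmap")


@dataclass
class CrownRecord:
    """One detected dead tree crown with geometry and classification slots."""

    id: int
    polygon: object
    area_m2: float
    centroid: tuple[float, float]
    a: float  # semi-major axis, metres
    b: float  # semi-minor axis, metres
    c_focal: float
    eccentricity: float
    pixel_count: int
    stage: str = "unclassified"
    agents: list = dc_field(default_factory=list)
    source_tile: str = ""
    mask_window: tuple | None = None  # ((row slice, col slice), bool mask)

    def __post_init__(self) -> None:
        if self.area_m2 <= 0:
            raise ValueError("crown area must be positive")
        if not 0.0 <= self.eccentricity < 1.0:
            raise ValueError("eccentricity must lie in [0, 1)")


def watershed_instances(e: EnergyMap, min_pixels: int = 8) -> np.ndarray:
    """Separate instances by flooding the energy surface from level cores.

    Markers are the connected components of the top non-empty energy level
    within each basin (connected component of the level >= 1 mask); labels
    are dense from 1; components smaller than ``min_pixels`` are removed.
    """
    levels = e.levels
    mask = levels >= 1
    if not mask.any():
        return np.zeros(levels.shape, dtype=np.int32)
    basins = cc_label(mask, connectivity=2)
    n_basins = basins.max()
    basin_max = ndimage.maximum(levels, labels=basins, index=np.arange(1, n_basins + 1))
    top = mask & (levels == np.asarray(basin_max)[basins - 1])
    markers = cc_label(top, connectivity=2)
    labels = watershed(-levels.astype(np.int16), markers=markers, mask=mask,
                       connectivity=2)
    if min_pixels > 1:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_pixels)
        if small.size:
            labels[np.isin(labels, small)] = 0
    # dense relabel from 1, preserving raster order of first appearance
    uniq = np.unique(labels)
    uniq = uniq[uniq > 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[uniq] = np.arange(1, uniq.size + 1)
    return remap[labels]


def extract_crowns(labels: np.ndarray, image: RasterTile,
                   source_tile: str = "") -> list[CrownRecord]:
    """Fill holes, polygonise and measure every labelled instance."""
    t = image.transform
    px = image.pixel_size
    pixel_area = abs(t.determinant)
    records: list[CrownRecord] = []
    for sl, lab in zip(ndimage.find_objects(labels),
                       range(1, int(labels.max()) + 1)):
        if sl is None:
            continue
        mask = ndimage.binary_fill_holes(labels[sl] == lab)
        n_pix = int(mask.sum())
        props = regionprops(mask.astype(np.uint8))[0]
        r_c, c_c = props.centroid  # row/col within the window
        row0, col0 = sl[0].start, sl[1].start
        cx = t.a * (col0 + c_c + 0.5) + t.b * (row0 + r_c + 0.5) + t.c
        cy = t.d * (col0 + c_c + 0.5) + t.e * (row0 + r_c + 0.5) + t.f
        a_px = props.axis_major_length / 2.0
        b_px = props.axis_minor_length / 2.0
        if a_px == 0.0:
            logger.debug("instance %d is degenerate (%d px); half-pixel axes", lab, n_pix)
        # a pixel has physical extent: floor both semi-axes at half a pixel
        a_m = max(a_px * px, px / 2.0)
        b_m = max(b_px * px, px / 2.0)
        c_f = float(np.sqrt(max(a_m ** 2 - b_m ** 2, 0.0)))
        ecc = c_f / a_m
        rows, cols = np.nonzero(mask)
        polygon = unary_union([
            box(*_pixel_bounds(t, row0 + r, col0 + c)) for r, c in zip(rows, cols)
        ])
        records.append(CrownRecord(
            id=lab, polygon=polygon, area_m2=n_pix * pixel_area,
            centroid=(cx, cy), a=a_m, b=b_m, c_focal=c_f,
            eccentricity=min(ecc, 1.0 - 1e-9), pixel_count=n_pix,
            source_tile=source_tile,
            mask_window=((sl[0], sl[1]), labels[sl] == lab),
        ))
    return records


def _pixel_bounds(t: Affine, row: int, col: int) -> tuple[float, float, float, float]:
    xs = [t.a * c + t.b * r + t.c for c, r in ((col, row), (col + 1, row),
                                               (col, row + 1), (col + 1, row + 1))]
    ys = [t.d * c + t.e * r + t.f for c, r in ((col, row), (col + 1, row),
                                               (col, row + 1), (col + 1, row + 1))]
    return min(xs), min(ys), max(xs), max(ys)


def eccentricity_grid(crowns: list[CrownRecord], spec: GridSpec, crs: str,
                      min_pixels: int = 50,
                      flag_threshold: float = 0.8) -> tuple[GridLayer, GridLayer]:
    """Median crown eccentricity per (500 m) cell, plus a distortion flag.

    Only crowns larger than ``min_pixels`` (18 m^2 at 0.6 m GSD) enter the
    median — small rasterised crowns carry no reliable shape signal.  The
    companion layer flags cells whose median exceeds ``flag_threshold``
    (area-related metrics there should be used with caution).
    """
    ncols, nrows = spec.extent
    per_cell: dict[tuple[int, int], list[float]] = {}
    for crown in crowns:
        if crown.pixel_count <= min_pixels:
            continue
        cell = spec.cell_of(*crown.centroid)
        if cell is not None:
            per_cell.setdefault(cell, []).append(crown.eccentricity)
    med = np.full((nrows, ncols), np.nan)
    flag = np.full((nrows, ncols), np.nan)
    for (row, col), es in per_cell.items():
        med[row, col] = float(np.median(es))
        flag[row, col] = float(med[row, col] > flag_threshold)
    return (GridLayer(med, spec, crs, metric="median_eccentricity"),
            GridLayer(flag, spec, crs, metric="eccentricity_flag"))
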