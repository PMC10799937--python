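"""Gridded mortality products: counts, bias correction, canopy metrics,
brown-stage percentage, the 3-prong hotspot composite and the cluster-size
profile of 30 m cells.

Counting convention: a crown belongs to the (half-open) grid cell containing
its centroid, for every metric — crowns spanning a cell edge are not split.
Count maps at 30 m are always raw (per-tree analyses); coarser count maps
may be bias-corrected by adding the mean observed-minus-predicted error per
hectare (scaled to the cell area) so that patch-level systematic error does
not propagate into regional totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import CountComparison
from .geodata_io import GridLayer, GridSpec
from .instance_extraction import CrownRecord

logger = logging.getLogger("snagmap")


@dataclass
class BiasModel:
    """Mean count error per hectare, from a patch/plot comparison set."""

    me_per_ha: float
    F: float  # scale factor patch -> hectare
    source: str = ""

    def __post_init__(self) -> None:
        if not self.F > 0:
            raise ValueError("scale factor F must be positive")
        if not np.isfinite(self.me_per_ha):
            raise ValueError("ME must be finite")


def estimate_bias(comparisons: CountComparison, patch_area_ha: float,
                  source: str = "") -> BiasModel:
    """ME = F * mean(Y_obs - Y_pred), with F converting patch area to 1 ha."""
    if patch_area_ha <= 0:
        raise ValueError("patch_area_ha must be positive")
    F = 1.0 / patch_area_ha
    me = F * float(np.mean(comparisons.observed - comparisons.predicted))
    return BiasModel(me_per_ha=me, F=F, source=source)


def _cell_counts(crowns: list[CrownRecord], spec: GridSpec,
                 predicate=None) -> np.ndarray:
    ncols, nrows = spec.extent
    counts = np.zeros((nrows, ncols))
    for crown in crowns:
        if predicate is not None and not predicate(crown):
            continue
        cell = spec.cell_of(*crown.centroid)
        if cell is not None:
            counts[cell] += 1
    return counts


def count_grid(crowns: list[CrownRecord], spec: GridSpec, crs: str,
               bias: BiasModel | None = None) -> GridLayer:
    """Count crown centroids per cell, optionally bias-corrected.

    Bias correction adds ``ME_per_ha`` scaled to the cell area to every cell
    of the mapped extent.  It is rejected at 30 m: per-grid-cell analyses at
    that scale use raw segmentation-derived counts.
    """
    if bias is not None and spec.cell_size == 30:
        raise ValueError("30 m count grids must stay raw (no bias correction)")
    counts = _cell_counts(crowns, spec)
    corrected = bias is not None
    if corrected:
        cell_ha = spec.cell_size ** 2 / 10_000.0
        counts = counts + bias.me_per_ha * cell_ha
        counts = np.maximum(counts, 0.0)
    return GridLayer(counts, spec, crs, metric="dead_tree_count",
                     bias_corrected=corrected)


def percent_mortality(count: GridLayer, baseline: GridLayer) -> GridLayer:
    """100 * dead / baseline live-tree count, per (240 m) cell."""
    if count.spec != baseline.spec:
        raise ValueError("count and baseline grids are not aligned")
    dead = count.values.astype(float)
    base = baseline.values.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * dead / base
    pct[~np.isfinite(pct)] = np.nan
    pct[base == 0] = np.nan
    over = np.nansum(pct > 100.0)
    if over:
        logger.warning("%d cells exceed 100%% mortality vs baseline; clamped", int(over))
        pct = np.minimum(pct, 100.0)
    return GridLayer(pct, count.spec, count.crs, metric="percent_mortality",
                     bias_corrected=count.bias_corrected)


def canopy_metrics(crowns: list[CrownRecord], spec: GridSpec,
                   crs: str) -> tuple[GridLayer, GridLayer]:
    """Dead-canopy % and median crown size per (100 m) cell.

    Crown area is assigned to the cell holding the centroid; dead-canopy %
    is the summed crown area over the cell area.  Cells without crowns are
    nodata.
    """
    ncols, nrows = spec.extent
    areas: dict[tuple[int, int], list[float]] = {}
    for crown in crowns:
        cell = spec.cell_of(*crown.centroid)
        if cell is not None:
            areas.setdefault(cell, []).append(crown.area_m2)
    pct = np.full((nrows, ncols), np.nan)
    med = np.full((nrows, ncols), np.nan)
    cell_area = spec.cell_size ** 2
    for cell, vals in areas.items():
        pct[cell] = min(100.0 * sum(vals) / cell_area, 100.0)
        med[cell] = float(np.median(vals))
    return (GridLayer(pct, spec, crs, metric="dead_canopy_pct"),
            GridLayer(med, spec, crs, metric="median_crown_size_m2"))


def brown_pct_grid(crowns: list[CrownRecord], spec: GridSpec, crs: str,
                   drop_single_brown: bool = False) -> GridLayer:
    """Percentage of brown-stage trees among all dead trees per cell.

    Cells holding exactly one brown-stage tree are treated as staging noise:
    set to 0% by default, or dropped to nodata with ``drop_single_brown``.
    Cells with no dead trees are nodata.
    """
    total = _cell_counts(crowns, spec)
    brown = _cell_counts(crowns, spec, predicate=lambda c: c.stage == "brown")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * brown / total
    pct[total == 0] = np.nan
    single = brown == 1
    pct[single] = np.nan if drop_single_brown else 0.0
    pct[(total == 0)] = np.nan
    return GridLayer(pct, spec, crs, metric="brown_stage_pct")


def three_prong_map(count: GridLayer, brown_pct: GridLayer,
                    median_size: GridLayer) -> np.ndarray:
    """Compose the RGB hotspot map: R=count, G=brown %, B=median crown size.

    Each band is rescaled linearly between its own 2nd and 98th percentile
    over valid cells and clamped to [0, 1]; a constant band (p2 == p98) is
    set to 0.5.  Cells missing in any band are NaN in all three.
    """
    layers = (count, brown_pct, median_size)
    if len({layer.spec for layer in layers}) != 1:
        raise ValueError("the three layers must share one grid")
    out = np.empty((3,) + count.values.shape)
    for i, layer in enumerate(layers):
        vals = layer.values.astype(float)
        valid = ~np.isnan(vals)
        if not valid.any():
            out[i] = np.nan
            continue
        p2, p98 = np.percentile(vals[valid], [2, 98])
        if p98 == p2:
            logger.warning("band %d (%s) is constant; set to 0.5", i, layer.metric)
            band = np.where(valid, 0.5, np.nan)
        else:
            band = np.clip((vals - p2) / (p98 - p2), 0.0, 1.0)
        out[i] = band
    missing = np.isnan(out).any(axis=0)
    out[:, missing] = np.nan
    return out


def cluster_size_profile(count_30m: GridLayer) -> pd.DataFrame:
    """Histogram of 30 m cells by dead-tree count k, with cumulative shares.

    Columns: k, n_cells, n_trees, cum_pct_trees (share of all trees found in
    cells holding <= k trees).  Rows with no cells are omitted; the k=1 row
    is the isolated-tree count.
    """
    if count_30m.bias_corrected:
        raise ValueError("cluster-size profile requires raw (uncorrected) counts")
    vals = count_30m.values
    vals = vals[~np.isnan(vals)].astype(int)
    vals = vals[vals > 0]
    if vals.size == 0:
        return pd.DataFrame(columns=["k", "n_cells", "n_trees", "cum_pct_trees"])
    ks, n_cells = np.unique(vals, return_counts=True)
    n_trees = ks * n_cells
    total = n_trees.sum()
    cum = 100.0 * np.cumsum(n_trees) / total
    return pd.DataFrame({"k": ks, "n_cells": n_cells, "n_trees": n_trees,
                         "cum_pct_trees": cum})
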