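"""Ordinal energy-level encoding for deep-watershed instance segmentation.

An *energy map* stores, per pixel, a quantised distance-to-boundary level in
``0..K`` (0 = background).  Level K marks the innermost core of a crown and
level 1 its boundary ring, so the levels form nested rings: the set of pixels
at level >= j is spatially contained in the set at level >= j-1.  The network
predicts the K nested masks (ordinal classification: a higher level can only
be present where the lower one is), and the classic watershed transform
recovers individual instances from the decoded levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geodata_io import Affine, RasterTile, read_raster, write_raster

logger = logging.getLogger("snagmap")


@dataclass
class EnergyMap:
    """Integer energy levels in [0, K] with raster georeferencing."""

    levels: np.ndarray  # (H, W) int
    K: int
    transform: Affine
    crs: str

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.levels.min() < 0 or self.levels.max() > self.K:
            raise ValueError("levels must lie in [0, K]")


@dataclass
class OrdinalTarget:
    """K nested binary masks, ``masks[j-1] = (level >= j)``."""

    masks: np.ndarray  # (K, H, W) bool

    @property
    def K(self) -> int:
        return self.masks.shape[0]


def instances_to_energy(instances: np.ndarray, K: int,
                        transform: Affine | None = None, crs: str = "",
                        normalisation: str = "instance",
                        absolute_scale: float | None = None) -> EnergyMap:
    """Quantise per-instance distance-to-boundary into K ordinal levels.

    For each labelled instance the Euclidean distance of every pixel to the
    instance boundary is computed on the instance's own mask (so a shared
    interface between touching crowns counts as boundary for both).  Distances
    are normalised by the instance's maximum (``normalisation="instance"``) or
    by a fixed ``absolute_scale`` in pixels, then split into K equal bins:
    level K innermost, level 1 at the boundary ring.  Background stays 0.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if instances.min() < 0:
        raise ValueError("labels must be non-negative")
    transform = transform or Affine.north_up(0.0, 0.0, 1.0)
    levels = np.zeros(instances.shape, dtype=np.uint8)
    objects = ndimage.find_objects(instances)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        # pad by one pixel so the raster edge also counts as boundary context
        mask = np.pad(instances[sl] == idx, 1)
        if mask.sum() == 1:
            logger.debug("instance %d is a single pixel; assigned level K", idx)
        dist = ndimage.distance_transform_edt(mask)
        if normalisation == "instance":
            scale = dist.max()
        elif normalisation == "absolute":
            scale = absolute_scale if absolute_scale else float(K)
        else:
            raise ValueError(f"unknown normalisation {normalisation!r}")
        t = dist / scale
        lev = np.ceil(np.clip(t, 0.0, 1.0) * K).astype(np.uint8)
        inner = mask[1:-1, 1:-1]
        levels[sl][inner] = lev[1:-1, 1:-1][inner]
    return EnergyMap(levels, K, transform, crs or "EPSG:0")


def energy_to_ordinal(e: EnergyMap) -> OrdinalTarget:
    """Expand levels into K nested presence masks (level >= j)."""
    js = np.arange(1, e.K + 1).reshape(-1, 1, 1)
    return OrdinalTarget(e.levels[None, :, :] >= js)


def ordinal_to_energy(target: OrdinalTarget, transform: Affine | None = None,
                      crs: str = "") -> EnergyMap:
    """Inverse of :func:`energy_to_ordinal`: level = highest true mask index."""
    levels = target.masks.astype(np.uint8).sum(axis=0)
    return EnergyMap(levels, target.K, transform or Affine.north_up(0, 0, 1.0),
                     crs or "EPSG:0")


def monotone_enforce(probabilities: np.ndarray, threshold: float = 0.5,
                     transform: Affine | None = None, crs: str = "") -> EnergyMap:
    """Decode K per-level probability maps into a nested EnergyMap.

    Ordinal consistency is enforced by the cumulative product
    ``q_j = prod_{i<=j} p_i`` — a higher level cannot be present unless all
    lower levels are — and the decoded level is the largest j with
    ``q_j >= threshold`` (0 if none).  Because q is non-increasing in j the
    output satisfies the nesting invariant by construction.
    """
    if probabilities.ndim != 3:
        raise ValueError("expected (K, H, W) probability maps")
    q = np.cumprod(np.clip(probabilities, 0.0, 1.0), axis=0)
    levels = (q >= threshold).astype(np.uint8).sum(axis=0)
    return EnergyMap(levels, probabilities.shape[0],
                     transform or Affine.north_up(0, 0, 1.0), crs or "EPSG:0")


def check_nesting(e: EnergyMap) -> bool:
    """True iff pixels at level >= j nest inside level >= j-1 for all j.

    With a single integer level per pixel this holds automatically; the check
    exists to validate energy maps assembled from external sources.
    """
    masks = energy_to_ordinal(e).masks
    for j in range(1, e.K):
        if np.any(masks[j] & ~masks[j - 1]):
            return False
    return True


def write_energy(path, e: EnergyMap) -> None:
    tile = RasterTile(e.levels.astype(np.uint8)[None], e.transform, e.crs)
    write_raster(path, tile, description=f'{{"K": {e.K}}}')


def read_energy(path) -> EnergyMap:
    import json

    tile = read_raster(path, require_bands=1)
    desc = getattr(tile, "description", None)
    K = int(json.loads(desc)["K"]) if desc else int(tile.pixels.max())
    return EnergyMap(tile.pixels[0].astype(np.uint8), max(K, 2), tile.transform, tile.crs)
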