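"""HSV colour-space classification of mortality stage (brown vs grey).

A recently dead crown retains dried, discoloured foliage and appears
brownish-reddish in true colour; a long-dead crown has shed its foliage and
appears grey-white.  Each detected crown is classified from the mean RGB of
its pixels (after a one-pixel inner buffer against edge mixing) via four
competing scores:

    X_green  — peaked at hue 1/3 through H_g = 1 - |H - 1/3| / (1/6)
    X_brown  — peaked at warm hues through H_r = (1/2 - H) / (1/6) - 2
    X_grey   — decreasing in saturation
    X_background — decreasing in value (dark pixels)

Each hue/saturation/value term x in [0, 1] is mapped through the sharpening
curve (C^x - 1)/(C - 1) with class constants C = (5, 5, 1e7, 1e4); the class
with the maximal score wins.  Exact ties resolve conservatively in the order
grey > brown > green > background, so achromatic crowns are never promoted
to "recent mortality".  Red hues near H = 1 are wrapped (H - 1) before
computing H_r so warm colours on both ends of the hue circle score as brown.
"""

from __future__ import annotations

import colorsys
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import box

from .geodata_io import GridLayer, RasterTile, RunConfig, VectorLayer

logger = logging.getLogger("snagmap")

DEFAULT_CONSTANTS = (5.0, 5.0, 1e7, 1e4)  # C_g, C_r, C_y, C_b
_TIE_ORDER = ("grey", "brown", "green", "background")


@dataclass
class StageScore:
    """HSV terms and the four class scores for one crown's mean colour."""

    H: float
    S: float
    V: float
    H_g: float
    H_r: float
    X_green: float
    X_brown: float
    X_grey: float
    X_background: float

    def as_dict(self) -> dict[str, float]:
        return {"green": self.X_green, "brown": self.X_brown,
                "grey": self.X_grey, "background": self.X_background}


def _curve(C: float, x: float, literal: bool) -> float:
    """Score curve; ``literal`` selects the C^(x-1)/(C-1) reading."""
    if literal:
        return C ** (x - 1.0) / (C - 1.0)
    return (C ** x - 1.0) / (C - 1.0)


def stage_scores(rgb: tuple[float, float, float],
                 constants: tuple[float, float, float, float] = DEFAULT_CONSTANTS,
                 literal_exponent: bool = False) -> StageScore:
    """Compute the four stage scores from mean crown RGB (0..255)."""
    C_g, C_r, C_y, C_b = constants
    r, g, b = (float(c) / 255.0 for c in rgb)
    H, S, V = colorsys.rgb_to_hsv(r, g, b)

    H_g = 1.0 - abs(H - 1.0 / 3.0) / (1.0 / 6.0)
    H_wrapped = H - 1.0 if H > 5.0 / 6.0 else H
    H_r = (0.5 - H_wrapped) / (1.0 / 6.0) - 2.0

    if S == 0.0:
        # hue undefined on achromatic colours: hue-based scores are void
        X_green = X_brown = 0.0
    else:
        X_green = _curve(C_g, H_g, literal_exponent) if H_g >= 0 else 0.0
        X_brown = _curve(C_r, H_r, literal_exponent) if H_r >= 0 else 0.0
        X_brown = min(X_brown, 1.0)
        X_green = min(X_green, 1.0)
    # saturation is undefined for black (V = 0): the grey score is void
    # there, leaving the background score to dominate dark pixels
    X_grey = _curve(C_y, 1.0 - S, False) if V > 0.0 else 0.0
    X_background = _curve(C_b, 1.0 - V, False)
    return StageScore(H, S, V, H_g, H_r, X_green, X_brown, X_grey, X_background)


def classify_stage(score: StageScore) -> str:
    """Argmax of the four scores; ties resolve grey > brown > green > background."""
    scores = score.as_dict()
    best = max(scores.values())
    winners = [name for name in _TIE_ORDER if scores[name] == best]
    if len(winners) > 1:
        logger.debug("stage tie between %s resolved as %s", winners, winners[0])
    return winners[0]


def mean_crown_rgb(crown, image: RasterTile,
                   inner_buffer_px: int = 1) -> tuple[float, float, float]:
    """Mean R, G, B over the crown mask after a one-pixel inner buffer.

    If erosion would empty the mask (very small crowns), the un-eroded mask
    is used instead and a warning is logged.
    """
    window, mask = _crown_mask(crown, image)
    if not mask.any():
        raise ValueError(f"crown {getattr(crown, 'id', '?')} lies outside the image")
    if inner_buffer_px > 0:
        eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3)),
                                        iterations=inner_buffer_px)
        if eroded.any():
            mask = eroded
        else:
            logger.warning("crown %s erodes to empty; using un-eroded mask",
                           getattr(crown, "id", "?"))
    rs, cs = window
    pix = image.pixels[:3, rs, cs][:, mask].astype(float)
    return tuple(pix.mean(axis=1))  # type: ignore[return-value]


def _crown_mask(crown, image: RasterTile) -> tuple[tuple[slice, slice], np.ndarray]:
    """Pixel mask of a crown on the image grid (from extraction, or polygon)."""
    win = getattr(crown, "mask_window", None)
    if win is not None:
        return win
    # rasterise the polygon: pixel centre inside test
    poly = crown.polygon
    minx, miny, maxx, maxy = poly.bounds
    t = image.transform
    c0f, r0f = t.invert(minx, maxy)
    c1f, r1f = t.invert(maxx, miny)
    h, w = image.shape
    r0, c0 = max(0, int(r0f) - 1), max(0, int(c0f) - 1)
    r1, c1 = min(h, int(r1f) + 2), min(w, int(c1f) + 2)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("crown polygon does not overlap the image")
    from shapely import contains_xy

    cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
    xs = t.a * (cols + 0.5) + t.b * (rows + 0.5) + t.c
    ys = t.d * (cols + 0.5) + t.e * (rows + 0.5) + t.f
    mask = contains_xy(poly, xs.ravel(), ys.ravel()).reshape(rows.shape)
    return (slice(r0, r1), slice(c0, c1)), mask


def stage_crowns(crowns: list, image: RasterTile,
                 config: RunConfig | None = None) -> list:
    """Classify every crown in place; returns the same list.

    Crowns whose argmax is green or background keep ``stage="unclassified"``
    (flagged for QA via ``colour_class``) — they remain in the record set.
    """
    config = config or RunConfig()
    for crown in crowns:
        rgb = mean_crown_rgb(crown, image, config.inner_buffer_px)
        score = stage_scores(rgb, config.staging_constants, config.literal_exponent)
        cls = classify_stage(score)
        crown.colour_class = cls
        crown.stage = cls if cls in ("brown", "grey") else "unclassified"
        crown.stage_score = score
    return crowns


def validate_stage_by_polygons(brown_count_grid: GridLayer,
                               survey_polygons: VectorLayer,
                               min_area_ha: float = 1.0) -> dict:
    """Plot-level check of brown-stage counts against survey polygons.

    Sums gridded brown-stage counts under each survey polygon at least
    ``min_area_ha`` large; a polygon whose cells hold zero brown trees is a
    false negative (brown mortality seen by surveyors, missed by staging).
    """
    spec = brown_count_grid.spec
    min_area_m2 = min_area_ha * 10_000.0
    results = []
    for feat in survey_polygons.features:
        poly = feat["geometry"]
        if poly.area < min_area_m2:
            continue
        total = 0.0
        minx, miny, maxx, maxy = poly.bounds
        for row in range(spec.extent[1]):
            for col in range(spec.extent[0]):
                cb = spec.cell_bounds(row, col)
                if cb[2] < minx or cb[0] > maxx or cb[3] < miny or cb[1] > maxy:
                    continue
                if not box(*cb).intersects(poly):
                    continue
                val = brown_count_grid.values[row, col]
                if not np.isnan(val):
                    total += float(val)
        results.append({"year": feat.get("year"), "brown_total": total,
                        "false_negative": total == 0.0})
    n = len(results)
    n_fn = sum(r["false_negative"] for r in results)
    return {"n_polygons": n, "n_false_negative": n_fn,
            "false_negative_fraction": (n_fn / n) if n else float("nan"),
            "polygons": results}
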