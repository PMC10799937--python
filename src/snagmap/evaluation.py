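"""Count and segmentation accuracy metrics, and the field-comparison protocol.

Count metrics over paired per-unit (patch or plot) observations:

    MAE  = mean |Y_obs - Y_pred|              (trees per unit)
    rTE  = |sum(Y_obs - Y_pred)| / |sum Y_obs|
    bias = 100 * sum(Y_obs - Y_pred) / sum Y_obs   (positive = underestimation)

Pixel agreement uses per-class IoU = TP / (TP + FP + FN) and the mean over
classes (mIoU).  Field comparison follows the survey protocol: predicted
crowns are buffered by 6 m (the geo-referencing accuracy of the emulated
imagery) before matching; a ground point matches if any buffered crown
contains it, an observed crown polygon if buffered predictions cover more
than half of its area; plot counts use crown centroids inside the buffered
plot polygon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .instance_extraction import CrownRecord

logger = logging.getLogger("snagmap")


@dataclass
class CountComparison:
    """Paired observed/predicted counts per patch or plot."""

    observed: np.ndarray
    predicted: np.ndarray
    unit_area_ha: float = 1.0
    unit_ids: list | None = None
    years: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.observed.shape != self.predicted.shape:
            raise ValueError("observed and predicted must pair up")
        if self.observed.size < 1:
            raise ValueError("need at least one unit")
        if (self.observed < 0).any() or (self.predicted < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.observed.size

    @property
    def F(self) -> float:
        """Scale factor converting the unit area to one hectare."""
        return 1.0 / self.unit_area_ha

    def subset(self, mask: np.ndarray) -> "CountComparison":
        return CountComparison(
            self.observed[mask], self.predicted[mask], self.unit_area_ha,
            [u for u, m in zip(self.unit_ids, mask)] if self.unit_ids else None,
            self.years[mask] if self.years is not None else None)


def mae(c: CountComparison) -> float:
    """Mean absolute count error per unit."""
    return float(np.mean(np.abs(c.observed - c.predicted)))


def mean_error(c: CountComparison) -> float:
    """Signed mean error (observed - predicted) per unit."""
    return float(np.mean(c.observed - c.predicted))


def relative_total_error(c: CountComparison) -> float:
    """|sum of errors| / |sum observed|; NaN when nothing was observed."""
    total_obs = c.observed.sum()
    if total_obs == 0:
        return float("nan")
    return float(abs((c.observed - c.predicted).sum()) / abs(total_obs))


def count_bias(c: CountComparison) -> float:
    """Signed total-count bias in percent; positive = underestimation."""
    total_obs = c.observed.sum()
    if total_obs == 0:
        return float("nan")
    return float(100.0 * (c.observed - c.predicted).sum() / total_obs)


@dataclass
class SegmentationScores:
    """Per-class pixel confusion and IoU scores."""

    tp: dict[int, int]
    fp: dict[int, int]
    fn: dict[int, int]
    iou: dict[int, float]
    miou: float

    @property
    def k(self) -> int:
        return len(self.iou)


def iou_scores(pred_mask: np.ndarray, label_mask: np.ndarray,
               classes: list[int] | None = None,
               absent_class_iou: float | None = 1.0) -> SegmentationScores:
    """Per-class IoU = TP/(TP+FP+FN) and the mean over classes.

    A class absent from both rasters scores ``absent_class_iou`` (1 by
    convention, logged); pass ``None`` to exclude such classes from mIoU.
    """
    if pred_mask.shape != label_mask.shape:
        raise ValueError("masks must be aligned")
    if classes is None:
        classes = sorted(set(np.unique(pred_mask)) | set(np.unique(label_mask)))
    tp, fp, fn, iou = {}, {}, {}, {}
    for cls in classes:
        p = pred_mask == cls
        t = label_mask == cls
        tp[cls] = int(np.sum(p & t))
        fp[cls] = int(np.sum(p & ~t))
        fn[cls] = int(np.sum(~p & t))
        denom = tp[cls] + fp[cls] + fn[cls]
        if denom == 0:
            if absent_class_iou is None:
                continue
            logger.debug("class %s absent from both masks; IoU := %g",
                         cls, absent_class_iou)
            iou[cls] = absent_class_iou
        else:
            iou[cls] = tp[cls] / denom
    miou = float(np.mean(list(iou.values()))) if iou else float("nan")
    return SegmentationScores(tp, fp, fn, iou, miou)


@dataclass
class FieldObservation:
    """One ground record: a dead-tree point/polygon or a plot count."""

    geometry: BaseGeometry
    survey_year: int
    # opportunistic_tree: standalone dead-tree point/polygon
    # tree_in_plot:       census member point belonging to a plot_census plot
    # plot_census:        plot polygon whose count is aggregated from members
    # plot_count:         plot polygon carrying its own observed total
    kind: str = "opportunistic_tree"
    dbh_cm: float | None = None
    plot_geometry: BaseGeometry | None = None
    observed_count: float | None = None

    def __post_init__(self) -> None:
        if self.kind.startswith("plot") and self.plot_geometry is None:
            raise ValueError("plot-kind observations need a plot polygon")


def match_trees(crowns: list[CrownRecord], obs: list[FieldObservation],
                buffer_m: float = 6.0, coverage_threshold: float = 0.5,
                one_to_one: bool = False) -> pd.DataFrame:
    """Tree-level matching of ground observations against buffered crowns.

    Returns one row per observation with ``matched``; aggregate with
    :func:`match_summary`.  Matching is one-to-many by default (a predicted
    crown may account for several nearby field points); ``one_to_one``
    enforces a unique assignment for point observations via the Hungarian
    algorithm.
    """
    buffered = [c.polygon.buffer(buffer_m) for c in crowns]
    tree = STRtree(buffered) if buffered else None
    rows = []
    point_obs_idx: list[int] = []
    for i, ob in enumerate(obs):
        geom = ob.geometry
        matched = False
        if tree is not None:
            cand = tree.query(geom)
            if geom.geom_type == "Point":
                matched = any(buffered[j].covers(geom) for j in cand)
                point_obs_idx.append(i)
            else:
                cover = unary_union([buffered[j] for j in cand]) if len(cand) else None
                if cover is not None and geom.area > 0:
                    matched = cover.intersection(geom).area > coverage_threshold * geom.area
        rows.append({"obs_index": i, "year": ob.survey_year, "kind": ob.kind,
                     "matched": matched})
    df = pd.DataFrame(rows)
    if one_to_one and crowns and point_obs_idx:
        from scipy.optimize import linear_sum_assignment

        pts = [obs[i].geometry for i in point_obs_idx]
        cost = np.full((len(pts), len(buffered)), 1e9)
        for r, p in enumerate(pts):
            for c, poly in enumerate(buffered):
                if poly.covers(p):
                    cost[r, c] = p.distance(crowns[c].polygon)
        ri, ci = linear_sum_assignment(cost)
        assigned = {point_obs_idx[r] for r, c in zip(ri, ci) if cost[r, c] < 1e9}
        for i in point_obs_idx:
            df.loc[df.obs_index == i, "matched"] = i in assigned
    return df


def match_summary(matches: pd.DataFrame) -> pd.DataFrame:
    """Per-year matched % and its complement (the underestimation reading).

    The protocol's "bias" is reported both ways: ``matched_pct`` (share of
    ground observations intersected by predictions) and ``unmatched_pct``
    (100 - matched, the underestimation reading).
    """
    out = []
    for year, grp in matches.groupby("year"):
        pct = 100.0 * grp.matched.mean()
        out.append({"year": year, "n_obs": len(grp), "matched_pct": pct,
                    "unmatched_pct": 100.0 - pct})
    return pd.DataFrame(out)


def compare_plots(crowns: list[CrownRecord], plots: list[FieldObservation],
                  buffer_m: float = 6.0,
                  dbh_min_cm: float | None = 40.0) -> CountComparison:
    """Plot-level comparison: predicted = crown centroids in buffered plots.

    ``plot_count`` observations carry their own observed total;
    ``plot_census`` observations are aggregated here from their member
    points, applying the DBH threshold when DBH is recorded.
    """
    from shapely.geometry import Point

    plot_feats = [p for p in plots if p.kind.startswith("plot")]
    geoms = [p.plot_geometry for p in plot_feats]
    for i, gi in enumerate(geoms):
        for gj in geoms[i + 1:]:
            if gi.intersects(gj) and gi.intersection(gj).area > 0:
                logger.warning("overlapping plots evaluated independently; "
                               "dead trees in the overlap count twice")
                break
    observed, predicted, years, ids = [], [], [], []
    areas = []
    for idx, plot in enumerate(plot_feats):
        if plot.kind == "plot_count":
            y_obs = float(plot.observed_count or 0)
        else:
            members = [o for o in plots
                       if o.kind == "tree_in_plot" and plot.plot_geometry.covers(o.geometry)]
            if dbh_min_cm is not None:
                members = [o for o in members
                           if o.dbh_cm is None or o.dbh_cm >= dbh_min_cm]
            y_obs = float(len(members))
        buffered = plot.plot_geometry.buffer(buffer_m)
        y_pred = sum(buffered.covers(Point(*c.centroid)) for c in crowns)
        observed.append(y_obs)
        predicted.append(float(y_pred))
        years.append(plot.survey_year)
        ids.append(idx)
        areas.append(plot.plot_geometry.area / 10_000.0)
    return CountComparison(np.array(observed), np.array(predicted),
                           unit_area_ha=float(np.mean(areas)) if areas else 1.0,
                           unit_ids=ids, years=np.array(years))


def perfect_prediction_report(c: CountComparison) -> dict[str, float]:
    """All four count metrics in one dict (used by end-to-end reporting)."""
    return {"mae": mae(c), "me": mean_error(c),
            "rte": relative_total_error(c), "bias_pct": count_bias(c)}
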