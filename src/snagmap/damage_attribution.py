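"""Damage-agent attribution by temporal overlay of survey and fire polygons.

Aerial sketch-map surveys record up to three damage-agent codes per polygon
per survey year; fire perimeters carry only a year.  Where survey polygons
from different years overlap, the later record wins (mortality is reported
between consecutive surveys, so the newest attribution supersedes).  Where
survey regions overlap a fire perimeter, the fire is appended to the survey
agents if the fire is as recent as the survey — an older fire cannot explain
later-reported mortality.  Equal-year survey overlaps take the union of the
agent lists, truncated to three codes in sorted order.

The overlay is materialised as a planar partition (disjoint regions, each
with resolved agents); every crown is then attributed by the region holding
its centroid — a tree has one death and one location, so no area weighting.
Agent codes roll up through a configurable 4-level hierarchy.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .geodata_io import VectorLayer
from .instance_extraction import CrownRecord

logger = logging.getLogger("snagmap")

FIRE_CODE = "FIRE"
MAX_SURVEY_AGENTS = 3

# Demo hierarchy (level4 -> level3 -> level2 -> level1); the full survey
# taxonomy is user-supplied as CSV via AgentHierarchy.from_csv.
_DEMO_ROWS = [
    ("BB_WPB", "BARK_BEETLES", "INSECTS", "BIOTIC"),
    ("BB_MPB", "BARK_BEETLES", "INSECTS", "BIOTIC"),
    ("BB_FE", "BARK_BEETLES", "INSECTS", "BIOTIC"),
    ("WB_FLAT", "WOOD_BORERS", "INSECTS", "BIOTIC"),
    ("CANKER", "CANKERS", "DISEASES", "BIOTIC"),
    ("ROOT_DIS", "ROOT_DISEASES", "DISEASES", "BIOTIC"),
    ("ANIMAL", "ANIMAL_DAMAGE", "ANIMALS", "BIOTIC"),
    ("DROUGHT", "DROUGHT", "ABIOTIC_OTHER", "ABIOTIC"),
    ("FIRE", "FIRE", "FIRE", "ABIOTIC"),
    ("HERBICIDE", "HUMAN_ACTIVITY", "HUMAN", "HUMAN"),
]
DEMO_LEVEL4_CODES = [row[0] for row in _DEMO_ROWS]


@dataclass(frozen=True)
class AgentPolygon:
    """One survey or fire polygon with its year and agent codes."""

    geometry: BaseGeometry
    year: int
    agents: tuple[str, ...]
    kind: str = "survey"  # survey | fire

    def __post_init__(self) -> None:
        if self.kind == "fire":
            object.__setattr__(self, "agents", (FIRE_CODE,))
        elif not 1 <= len(self.agents) <= MAX_SURVEY_AGENTS:
            raise ValueError("survey polygons carry 1-3 agent codes")


class AgentHierarchy:
    """Level-4 code -> (level3, level2, level1) rollup table."""

    def __init__(self, rows: list[tuple[str, str, str, str]] | None = None):
        rows = rows if rows is not None else _DEMO_ROWS
        self._table = {l4: (l3, l2, l1) for l4, l3, l2, l1 in rows}

    @classmethod
    def from_csv(cls, path: str | Path) -> "AgentHierarchy":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            rows = [tuple(r[:4]) for r in reader if r and not r[0].startswith("#")]
        if rows and rows[0][0].lower() == "level4":
            rows = rows[1:]
        return cls(rows)  # type: ignore[arg-type]

    def rollup(self, code: str, level: int) -> str:
        """Map a level-4 code to the requested coarser level (4, 3, 2, 1)."""
        if level == 4:
            return code
        if code not in self._table:
            raise KeyError(f"unknown agent code {code!r}")
        return self._table[code][{3: 0, 2: 1, 1: 2}[level]]

    def codes(self) -> list[str]:
        return list(self._table)


def load_agent_layer(layer: VectorLayer) -> list[AgentPolygon]:
    """Parse a vector layer with ``year``, ``agents`` (semicolon-joined) and
    ``kind`` fields into AgentPolygons."""
    out = []
    for feat in layer.features:
        kind = feat.get("kind", "survey")
        agents = tuple(a for a in str(feat.get("agents", "")).split(";") if a)
        out.append(AgentPolygon(feat["geometry"], int(feat["year"]), agents, kind))
    return out


def buffer_drought_points(layer: VectorLayer, radius_m: float) -> list[AgentPolygon]:
    """Drought point records become survey polygons via a fixed buffer."""
    return [AgentPolygon(f["geometry"].buffer(radius_m), int(f["year"]),
                         ("DROUGHT",), "survey") for f in layer.features]


def _merge_agents(a: tuple[str, ...], b: tuple[str, ...],
                  limit: int = MAX_SURVEY_AGENTS) -> tuple[str, ...]:
    return tuple(sorted(set(a) | set(b))[:limit])


def resolve_survey_overlap(a1: AgentPolygon, a2: AgentPolygon) -> tuple[str, ...]:
    """Agents for the overlap of two survey polygons: the later year wins;
    equal years take the (sorted, truncated) union."""
    if a1.year > a2.year:
        return tuple(a1.agents)
    if a2.year > a1.year:
        return tuple(a2.agents)
    return _merge_agents(a1.agents, a2.agents)


def resolve_fire_overlap(survey_agents: tuple[str, ...], survey_year: int,
                         fire: AgentPolygon) -> tuple[str, ...]:
    """Fire is appended when it is at least as recent as the survey record.

    The union may carry four codes (three survey agents + fire); the survey
    truncation does not apply to the fire term.
    """
    if fire.year >= survey_year:
        if FIRE_CODE in survey_agents:
            return survey_agents
        return tuple(sorted(survey_agents)) + (FIRE_CODE,)
    return survey_agents


@dataclass
class AgentRegion:
    geometry: BaseGeometry
    agents: tuple[str, ...]
    year: int


def build_agent_partition(layers: list[AgentPolygon]) -> list[AgentRegion]:
    """Overlay all survey then fire polygons into disjoint resolved regions.

    Surveys are folded in ascending year order (the resolution rules make the
    result independent of input order); fires are applied afterwards.
    """
    surveys = sorted((p for p in layers if p.kind == "survey"),
                     key=lambda p: (p.year, p.agents))
    fires = sorted((p for p in layers if p.kind == "fire"),
                   key=lambda p: (p.year, p.agents))
    regions: list[AgentRegion] = []
    for poly in surveys:
        remaining = poly.geometry
        new_regions: list[AgentRegion] = []
        for region in regions:
            inter = region.geometry.intersection(poly.geometry)
            if inter.is_empty or inter.area == 0:
                new_regions.append(region)
                continue
            outside = region.geometry.difference(poly.geometry)
            if not outside.is_empty and outside.area > 0:
                new_regions.append(AgentRegion(outside, region.agents, region.year))
            proxy = AgentPolygon(inter, region.year, region.agents, "survey")
            agents = resolve_survey_overlap(proxy, poly)
            new_regions.append(AgentRegion(inter, agents, max(region.year, poly.year)))
            remaining = remaining.difference(region.geometry)
        if not remaining.is_empty and remaining.area > 0:
            new_regions.append(AgentRegion(remaining, tuple(sorted(poly.agents)),
                                           poly.year))
        regions = new_regions
    for fire in fires:
        remaining = fire.geometry
        new_regions = []
        for region in regions:
            inter = region.geometry.intersection(fire.geometry)
            if inter.is_empty or inter.area == 0:
                new_regions.append(region)
                continue
            outside = region.geometry.difference(fire.geometry)
            if not outside.is_empty and outside.area > 0:
                new_regions.append(AgentRegion(outside, region.agents, region.year))
            agents = resolve_fire_overlap(region.agents, region.year, fire)
            new_regions.append(AgentRegion(inter, agents, region.year))
            remaining = remaining.difference(region.geometry)
        if not remaining.is_empty and remaining.area > 0:
            new_regions.append(AgentRegion(remaining, (FIRE_CODE,), fire.year))
        regions = new_regions
    return regions


def attribute_crowns(crowns: list[CrownRecord], layers: list[AgentPolygon],
                     hierarchy: AgentHierarchy | None = None) -> list[CrownRecord]:
    """Assign each crown the agents of the resolved region at its centroid.

    Crowns outside every polygon stay unattributed (empty agent list).  A
    centroid on a shared boundary goes to the higher-year region (logged).
    """
    hierarchy = hierarchy or AgentHierarchy()
    regions = build_agent_partition(layers)
    for crown in crowns:
        pt = Point(*crown.centroid)
        hits = [r for r in regions if r.geometry.covers(pt)]
        if not hits:
            crown.agents = []
            crown.agent_rollup = {}
            continue
        if len(hits) > 1:
            hits.sort(key=lambda r: (r.year, r.agents), reverse=True)
            logger.debug("crown %s centroid on a region boundary; "
                         "assigned to the %d record", crown.id, hits[0].year)
        region = hits[0]
        crown.agents = list(region.agents)
        crown.agent_rollup = {
            level: sorted({hierarchy.rollup(a, level) for a in region.agents})
            for level in (3, 2, 1)
        }
    return crowns


def agent_summary(crowns: list[CrownRecord], hierarchy: AgentHierarchy | None = None,
                  level: int = 4) -> pd.DataFrame:
    """Counts and percentages of crowns per agent combination at a level.

    Each observed combination (e.g. bark beetles + fire) is its own row —
    crowns in a combination are not double-counted under the single agents.
    Percentages are reported against all crowns and against attributed ones.
    """
    hierarchy = hierarchy or AgentHierarchy()
    total = len(crowns)
    combos: dict[tuple[str, ...], int] = {}
    attributed = 0
    for crown in crowns:
        if not crown.agents:
            continue
        attributed += 1
        key = tuple(sorted({hierarchy.rollup(a, level) for a in crown.agents}))
        combos[key] = combos.get(key, 0) + 1
    rows = [{
        "agents": "+".join(key), "n_trees": n,
        "pct_of_total": 100.0 * n / total if total else float("nan"),
        "pct_of_attributed": 100.0 * n / attributed if attributed else float("nan"),
    } for key, n in sorted(combos.items())]
    df = pd.DataFrame(rows, columns=["agents", "n_trees", "pct_of_total",
                                     "pct_of_attributed"])
    df.attrs["n_total"] = total
    df.attrs["n_attributed"] = attributed
    df.attrs["attributed_pct"] = 100.0 * attributed / total if total else float("nan")
    return df
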