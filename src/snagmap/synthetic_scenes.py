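"""NAIP-like synthetic scenes with exhaustive ground truth.

The generator emulates the imagery the pipeline targets: 0.6 m GSD 4-band
(R, G, B, NIR) tiles of live conifer/oak canopy on which dead tree crowns
appear as brownish (recent, foliage retained) or grey-white (long-dead,
defoliated) ellipses, partly clustered into clumps, with a scene-wide affine
shear standing in for off-nadir view-angle distortion.  NIR is set low for
dead crowns relative to live canopy, mimicking chlorophyll loss.

Truth is exhaustive: every crown is emitted both as a polygon (with stage,
axes and centre) and as a label in an instance raster.  Overlapping crowns
keep both truth polygons — the later crown simply renders on top — because
separating such clumps is exactly what the watershed stage must do.
"""

from __future__ import annotations

import colorsys
import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon, box

from .geodata_io import Affine, RasterTile, VectorLayer, write_raster, write_vector

logger = logging.getLogger("snagmap")

# HSV (h, s, v in [0,1]) + NIR (digital number) palette ranges.  The dead
# palettes are chosen so that the HSV staging rules classify every sample of
# the brown palette as brown-stage and every grey sample as grey-stage:
# brown hue stays below 1/6 (X_brown active, X_green zero), grey hue sits in
# the cyan-blue range with low saturation (X_grey dominant, hue scores zero).
DEFAULT_PALETTES: dict[str, dict[str, tuple[float, float]]] = {
    "brown": {"h": (0.03, 0.10), "s": (0.45, 0.68), "v": (0.40, 0.68), "nir": (60, 95)},
    "grey": {"h": (0.55, 0.70), "s": (0.06, 0.12), "v": (0.55, 0.80), "nir": (80, 125)},
    "live": {"h": (0.26, 0.37), "s": (0.35, 0.60), "v": (0.25, 0.45), "nir": (145, 205)},
    "soil": {"h": (0.09, 0.13), "s": (0.25, 0.38), "v": (0.55, 0.75), "nir": (100, 140)},
}


@dataclass
class SceneParams:
    """Study conditions of a synthetic scene.

    Defaults follow the emulated survey setting: 0.6 m GSD, a 128 px
    (76.8 m) patch holding ~9 labelled dead crowns (the label density of the
    emulated training patches), crown radii lognormal around 2.2 m, 40% of
    crowns in clumps, one fifth of mortality in the brown stage.
    """

    extent_m: float = 76.8
    gsd: float = 0.6
    n_crowns: int = 9
    crown_radius_log_mu: float = math.log(2.2)
    crown_radius_log_sigma: float = 0.30
    axis_ratio_range: tuple[float, float] = (0.65, 1.0)
    clustering: float = 0.4
    clump_spread_m: float = 4.0
    mean_clump_size: float = 3.0
    stage_mix: float = 0.2
    palettes: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PALETTES.items()})
    shear_range: tuple[float, float] = (0.0, 0.20)
    scale_range: tuple[float, float] = (0.95, 1.08)
    noise_sd: float = 3.0
    n_soil_patches: int = 2
    soil_patch_radius_m: float = 3.0
    crs: str = "EPSG:32610"
    origin: tuple[float, float] = (500000.0, 4400000.0)
    placements: list | None = None  # explicit [{"x","y","a","b","theta","stage"}]

    def __post_init__(self) -> None:
        for frac in (self.clustering, self.stage_mix):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if math.exp(self.crown_radius_log_mu - 3 * self.crown_radius_log_sigma) <= 0:
            raise ValueError("crown radii must be positive")
        bh, gh = self.palettes["brown"]["h"], self.palettes["grey"]["h"]
        if not (bh[1] < gh[0] or gh[1] < bh[0]):
            raise ValueError("brown and grey palettes must not overlap in hue")

    @property
    def npix(self) -> int:
        return int(round(self.extent_m / self.gsd))

    @property
    def transform(self) -> Affine:
        return Affine.north_up(self.origin[0], self.origin[1], self.gsd)


@dataclass
class SceneBundle:
    """One generated scene: image + truth crowns + instance labels."""

    image: RasterTile
    truth_crowns: VectorLayer
    truth_instances: np.ndarray
    params: SceneParams
    seed: int

    @property
    def n_crowns(self) -> int:
        return len(self.truth_crowns)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_raster(directory / "image.tif", self.image)
        write_vector(directory / "truth_crowns.geojson", self.truth_crowns)
        write_raster(directory / "truth_instances.tif",
                     RasterTile(self.truth_instances.astype(np.int32)[None].astype(np.uint16)
                                if self.truth_instances.max() < 65535 else
                                self.truth_instances.astype(np.int32)[None],
                                self.image.transform, self.image.crs))
        params = dataclasses.asdict(self.params)
        params["seed"] = self.seed
        (directory / "params.json").write_text(json.dumps(params, default=str))


def _sample_range(rng: np.random.Generator, rng_pair) -> float:
    lo, hi = rng_pair
    return float(rng.uniform(lo, hi))


def _hsv_to_rgb255(h: float, s: float, v: float) -> tuple[int, int, int]:
    r, g, b = colorsys.hsv_to_rgb(h % 1.0, s, v)
    return int(round(r * 255)), int(round(g * 255)), int(round(b * 255))


def palette_rgb_samples(palette: dict, n: int = 27) -> np.ndarray:
    """Deterministic RGB (uint8) samples spanning a palette box."""
    steps = max(2, round(n ** (1 / 3)))
    hs = np.linspace(*palette["h"], steps)
    ss = np.linspace(*palette["s"], steps)
    vs = np.linspace(*palette["v"], steps)
    out = [np.array(_hsv_to_rgb255(h, s, v)) for h in hs for s in ss for v in vs]
    return np.array(out, dtype=np.uint8)


def validate_palettes(params: SceneParams) -> None:
    """Assert the dead-crown palettes agree with the HSV staging rules."""
    from .mortality_staging import classify_stage, stage_scores

    for name in ("brown", "grey"):
        for rgb in palette_rgb_samples(params.palettes[name]):
            got = classify_stage(stage_scores(tuple(int(c) for c in rgb)))
            if got != name:
                raise AssertionError(
                    f"{name} palette sample RGB{tuple(rgb)} classifies as {got}")


def _place_crowns(params: SceneParams, rng: np.random.Generator) -> list[dict]:
    """Sample crown centres, axes, orientations and stages in map coords."""
    x0, y0 = params.origin
    ext = params.extent_m
    if params.placements is not None:
        crowns = []
        for i, p in enumerate(params.placements, start=1):
            a = float(p["a"])
            b = float(p.get("b", a))
            crowns.append({"id": i, "x": float(p["x"]), "y": float(p["y"]), "a": a,
                           "b": b, "theta": float(p.get("theta", 0.0)),
                           "stage": p.get("stage", "grey")})
        return crowns

    n = params.n_crowns
    n_clustered = int(round(params.clustering * n))
    centres: list[tuple[float, float]] = []
    margin = math.exp(params.crown_radius_log_mu)
    lo_x, hi_x = x0 + margin, x0 + ext - margin
    lo_y, hi_y = y0 - ext + margin, y0 - margin
    # clumped placement: clump centres uniform, members Gaussian around them
    while len(centres) < n_clustered:
        cx, cy = rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y)
        size = max(2, int(rng.poisson(params.mean_clump_size)))
        for _ in range(min(size, n_clustered - len(centres))):
            px = float(np.clip(cx + rng.normal(0, params.clump_spread_m), lo_x, hi_x))
            py = float(np.clip(cy + rng.normal(0, params.clump_spread_m), lo_y, hi_y))
            centres.append((px, py))
    while len(centres) < n:
        centres.append((float(rng.uniform(lo_x, hi_x)), float(rng.uniform(lo_y, hi_y))))

    crowns = []
    for i, (cx, cy) in enumerate(centres, start=1):
        a = float(np.exp(rng.normal(params.crown_radius_log_mu,
                                    params.crown_radius_log_sigma)))
        a = max(a, 1.5 * params.gsd)
        ratio = _sample_range(rng, params.axis_ratio_range)
        stage = "brown" if rng.uniform() < params.stage_mix else "grey"
        crowns.append({"id": i, "x": cx, "y": cy, "a": a, "b": a * ratio,
                       "theta": float(rng.uniform(0, math.pi)), "stage": stage})
    return crowns


def _crown_matrix(crown: dict, distortion: np.ndarray) -> np.ndarray:
    """2x2 matrix mapping the unit disc to the rendered (distorted) ellipse."""
    ct, st = math.cos(crown["theta"]), math.sin(crown["theta"])
    rot = np.array([[ct, -st], [st, ct]])
    return distortion @ rot @ np.diag([crown["a"], crown["b"]])


def _rasterise_ellipse(M: np.ndarray, cx: float, cy: float,
                       params: SceneParams) -> tuple[slice, slice, np.ndarray] | None:
    """Boolean mask of the ellipse on the scene's pixel grid (windowed)."""
    npix = params.npix
    x0, y0 = params.origin
    gsd = params.gsd
    # bounding radius: largest singular value of M
    r = float(np.linalg.norm(M, 2))
    c0 = max(0, int((cx - r - x0) / gsd) - 1)
    c1 = min(npix, int((cx + r - x0) / gsd) + 2)
    r0 = max(0, int((y0 - cy - r) / gsd) - 1)
    r1 = min(npix, int((y0 - cy + r) / gsd) + 2)
    if c0 >= c1 or r0 >= r1:
        return None
    cols = x0 + (np.arange(c0, c1) + 0.5) * gsd - cx
    rows = y0 - (np.arange(r0, r1) + 0.5) * gsd - cy
    X, Y = np.meshgrid(cols, rows)
    Minv = np.linalg.inv(M)
    U = Minv[0, 0] * X + Minv[0, 1] * Y
    V = Minv[1, 0] * X + Minv[1, 1] * Y
    inside = U * U + V * V <= 1.0
    if not inside.any():
        return None
    return slice(r0, r1), slice(c0, c1), inside


def _ellipse_polygon(M: np.ndarray, cx: float, cy: float, n: int = 64) -> Polygon:
    phi = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    pts = M @ np.vstack([np.cos(phi), np.sin(phi)])
    return Polygon(np.column_stack([pts[0] + cx, pts[1] + cy]))


def generate_scene(params: SceneParams | None = None, seed: int = 0) -> SceneBundle:
    """Render one scene deterministically for a fixed (params, seed).

    Overlapping crowns are resolved by z-order (later id on top) in both the
    image and the instance raster, while every crown keeps its full truth
    polygon.  Raises if, after bounded retries, some crown would end up with
    no visible pixel (the extent cannot pack ``n_crowns``).
    """
    params = params or SceneParams()
    validate_palettes(params)
    rng = np.random.default_rng(seed)
    npix = params.npix

    # scene-wide off-nadir distortion
    shear = _sample_range(rng, params.shear_range)
    sx = _sample_range(rng, params.scale_range)
    distortion = np.array([[sx, shear], [0.0, 1.0]])

    # background: live canopy with spatially smooth brightness variation
    pal = params.palettes
    h = np.full((npix, npix), _sample_range(rng, pal["live"]["h"]))
    s = np.full((npix, npix), _sample_range(rng, pal["live"]["s"]))
    v_lo, v_hi = pal["live"]["v"]
    texture = ndimage.gaussian_filter(rng.normal(size=(npix, npix)), 3.0)
    tspan = texture.max() - texture.min()
    texture = (texture - texture.min()) / (tspan if tspan > 0 else 1.0)
    v = v_lo + texture * (v_hi - v_lo)
    nir = np.full((npix, npix), _sample_range(rng, pal["live"]["nir"]))

    for _ in range(params.n_soil_patches):
        cx = params.origin[0] + rng.uniform(0, params.extent_m)
        cy = params.origin[1] - rng.uniform(0, params.extent_m)
        rad = params.soil_patch_radius_m * rng.uniform(0.6, 1.4)
        win = _rasterise_ellipse(np.diag([rad, rad]), cx, cy, params)
        if win is None:
            continue
        rs, cs, mask = win
        h[rs, cs][mask] = _sample_range(rng, pal["soil"]["h"])
        s[rs, cs][mask] = _sample_range(rng, pal["soil"]["s"])
        v[rs, cs][mask] = _sample_range(rng, pal["soil"]["v"])
        nir[rs, cs][mask] = _sample_range(rng, pal["soil"]["nir"])

    for attempt in range(5):
        crowns = _place_crowns(params, rng)
        instances = np.zeros((npix, npix), dtype=np.int32)
        windows = []
        for crown in crowns:
            M = _crown_matrix(crown, distortion)
            win = _rasterise_ellipse(M, crown["x"], crown["y"], params)
            if win is None:
                windows = None
                break
            rs, cs, mask = win
            instances[rs, cs][mask] = crown["id"]
            windows.append((crown, M, win))
        if windows is None:
            continue
        visible = set(np.unique(instances)) - {0}
        if visible == {c["id"] for c in crowns}:
            break
    else:
        raise RuntimeError(
            f"could not pack {params.n_crowns} crowns into a "
            f"{params.extent_m:g} m extent with every crown visible")

    features = []
    for crown, M, (rs, cs, mask) in windows:
        stage_pal = pal[crown["stage"]]
        ch = _sample_range(rng, stage_pal["h"])
        cs_ = _sample_range(rng, stage_pal["s"])
        cv = _sample_range(rng, stage_pal["v"])
        cn = _sample_range(rng, stage_pal["nir"])
        top = instances[rs, cs][mask] == crown["id"]
        idx = np.where(mask)
        sel = (idx[0][top], idx[1][top])
        h[rs, cs][sel] = ch
        s[rs, cs][sel] = cs_
        v[rs, cs][sel] = cv
        nir[rs, cs][sel] = cn
        # post-distortion semi-axes from the SVD of the shape matrix
        svals = np.linalg.svd(M, compute_uv=False)
        features.append({
            "geometry": _ellipse_polygon(M, crown["x"], crown["y"]),
            "id": crown["id"], "stage": crown["stage"],
            "radius_a": float(svals[0]), "radius_b": float(svals[1]),
            "centre_x": crown["x"], "centre_y": crown["y"],
        })

    from skimage.color import hsv2rgb

    rgb = hsv2rgb(np.dstack([h % 1.0, np.clip(s, 0, 1), np.clip(v, 0, 1)])) * 255.0
    bands = np.concatenate([np.moveaxis(rgb, -1, 0), nir[None]], axis=0)
    bands = bands + rng.normal(0.0, params.noise_sd, bands.shape)
    image = RasterTile(np.clip(np.round(bands), 0, 255).astype(np.uint8),
                       params.transform, params.crs)
    return SceneBundle(image, VectorLayer(features, params.crs), instances, params, seed)


def generate_field_survey(bundle: SceneBundle, detectability: float = 1.0,
                          jitter_sd: float = 0.0, seed: int = 0,
                          survey_year: int = 2020) -> VectorLayer:
    """Emulate opportunistic ground points: one jittered point per sampled crown."""
    if not 0.0 <= detectability <= 1.0:
        raise ValueError("detectability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    features = []
    for feat in bundle.truth_crowns.features:
        if rng.uniform() > detectability:
            continue
        x = feat["centre_x"] + rng.normal(0.0, jitter_sd) if jitter_sd else feat["centre_x"]
        y = feat["centre_y"] + rng.normal(0.0, jitter_sd) if jitter_sd else feat["centre_y"]
        features.append({"geometry": Point(x, y), "survey_year": survey_year,
                         "truth_id": feat["id"]})
    return VectorLayer(features, bundle.truth_crowns.crs)


def generate_agent_polygons(bundle: SceneBundle, n_layers: int = 2,
                            years: list[int] | None = None, seed: int = 0,
                            include_fire: bool = False,
                            agent_codes: list[str] | None = None) -> VectorLayer:
    """Overlapping survey rectangles (plus an optional fire perimeter).

    Rectangles cover 40-80% of the extent per side so that multi-layer
    overlaps occur; each carries 1-3 agent codes and a survey year.
    """
    years = years or [2016 + 2 * i for i in range(n_layers)]
    if list(years) != sorted(years):
        raise ValueError("years must be sorted ascending")
    if agent_codes is None:
        from .damage_attribution import DEMO_LEVEL4_CODES

        agent_codes = [c for c in DEMO_LEVEL4_CODES if c != "FIRE"]
    rng = np.random.default_rng(seed)
    x0, y0 = bundle.params.origin
    ext = bundle.params.extent_m
    features = []
    total = n_layers + (1 if include_fire else 0)
    for i in range(total):
        w = rng.uniform(0.4, 0.8) * ext
        hgt = rng.uniform(0.4, 0.8) * ext
        bx = x0 + rng.uniform(0, ext - w)
        by = y0 - ext + rng.uniform(0, ext - hgt)
        is_fire = include_fire and i == total - 1
        if is_fire:
            agents, kind = ["FIRE"], "fire"
            year = int(years[-1])
        else:
            agents = sorted(rng.choice(agent_codes, size=rng.integers(1, 4),
                                       replace=False).tolist())
            kind, year = "survey", int(years[i % len(years)])
        features.append({"geometry": box(bx, by, bx + w, by + hgt),
                         "year": year, "agents": ";".join(agents), "kind": kind})
    return VectorLayer(features, bundle.params.crs)
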