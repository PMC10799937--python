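import numpy as np
import pytest
from shapely.geometry import Point

from snagmap.geodata_io import Affine, RasterTile
from snagmap.instance_extraction import CrownRecord
from snagmap.synthetic_scenes import SceneParams, generate_scene

CRS = "EPSG:32610"


@pytest.fixture(scope="session")
def default_scene():
    """One deterministic default-condition scene shared across tests."""
    return generate_scene(SceneParams(), seed=7)


@pytest.fixture()
def flat_tile():
    """A 64x64 uniform 4-band tile at 0.6 m GSD."""
    pixels = np.full((4, 64, 64), 100, dtype=np.uint8)
    return RasterTile(pixels, Affine.north_up(500000.0, 4400000.0, 0.6), CRS)


def make_crown(x: float, y: float, radius_m: float = 2.0, crown_id: int = 1,
               stage: str = "unclassified", pixel_count: int | None = None,
               eccentricity: float = 0.0) -> CrownRecord:
    """A synthetic circular crown record at map position (x, y)."""
    poly = Point(x, y).buffer(radius_m, quad_segs=32)
    if pixel_count is None:
        pixel_count = max(1, int(poly.area / 0.36))
    a = max(radius_m, 0.3)
    return CrownRecord(id=crown_id, polygon=poly, area_m2=poly.area,
                       centroid=(x, y), a=a, b=a * np.sqrt(1 - eccentricity ** 2),
                       c_focal=a * eccentricity, eccentricity=eccentricity,
                       pixel_count=pixel_count, stage=stage)
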