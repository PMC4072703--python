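import numpy as np
import pytest
from shapely.geometry import LineString

from fawnsurv.grid import Landscape
from fawnsurv.io import Raster
from fawnsurv.synthetic import PREDATOR_SPECIES, SimConfig, generate_landscape


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=11, extent=(1500.0, 1500.0), n_fawns=12, n_years=2)


@pytest.fixture(scope="session")
def small_landscape(small_config) -> Landscape:
    return generate_landscape(small_config)


def make_landscape(landcover_data, cellsize=30.0, n_classes=None, risk=None, ndvi_value=0.5):
    """Hand-built landscape for zonal tests: explicit rasters, one road."""
    landcover_data = np.asarray(landcover_data, dtype=float)
    lc = Raster(landcover_data, cellsize=cellsize)
    xmin, ymin, xmax, ymax = lc.bounds
    predators = {}
    for i, sp in enumerate(PREDATOR_SPECIES):
        if risk is not None and sp in risk:
            predators[sp] = risk[sp]
        else:
            predators[sp] = Raster(
                np.full_like(landcover_data, 0.1 * (i + 1)), cellsize=cellsize
            )
    ndvi = Raster(np.full_like(landcover_data, ndvi_value), cellsize=cellsize)
    roads = [LineString([(xmin, ymax / 2), (xmax, ymax / 2)])]
    return Landscape(
        landcover=lc,
        roads=roads,
        predators=predators,
        ndvi=ndvi,
        n_classes=n_classes or int(np.nanmax(landcover_data)),
    )
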