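import numpy as np
import pandas as pd
import pytest
from hypothesis import settings
from shapely.geometry import box

from neighscan.config import STRATA, CityConfig
from neighscan.grid import Grid, assemble_cells, zone_clip
from neighscan.synthetic import Building, CensusBlock, generate_city

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> CityConfig:
    return CityConfig(seed=1, width=3000.0, height=3000.0, n_blocks=9)


@pytest.fixture(scope="session")
def small_city(small_cfg):
    return generate_city(small_cfg)


@pytest.fixture(scope="session")
def small_grid(small_cfg) -> Grid:
    return Grid.from_extent(small_cfg.extent, small_cfg.cell_size)


@pytest.fixture(scope="session")
def small_weights(small_city, small_grid):
    blocks, buildings, _ = small_city
    return zone_clip(blocks, small_grid, buildings)


@pytest.fixture(scope="session")
def small_cells(small_city, small_grid, small_weights) -> pd.DataFrame:
    blocks, buildings, _ = small_city
    return assemble_cells(small_grid, blocks, buildings, small_weights)


def make_block(
    block_id: int = 0,
    bounds: tuple = (0, 0, 1000, 1000),
    population: int = 2000,
    strata: dict | None = None,
    socio: dict | None = None,
) -> CensusBlock:
    """Hand-built rectangular census block for toy layouts."""
    if strata is None:
        strata = {s: population // 8 for s in STRATA}
    if socio is None:
        socio = {"unemployment_rate": 10.0}
    return CensusBlock(block_id, box(*bounds), population, strata, socio)


def make_building(bid: int, bounds: tuple, height: float, block_id: int) -> Building:
    return Building(bid, box(*bounds), height, block_id)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
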