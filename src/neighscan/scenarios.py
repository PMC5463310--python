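"""Benchmark scenarios built from the synthetic generator.

Two study conditions recur in validation work and are packaged here so
scripts and tests construct them identically:

* a city whose cells carry five contextual profiles constant within
  census blocks (the cleanest setting for judging zone-design
  homogeneity: a perfect zoning recovers the blocks and IAC -> 1);
* a city with one planted circular relative-risk cluster covering
  roughly a tenth of the population, scanned at census-block level
  (the cleanest setting for judging cluster recovery and the Monte
  Carlo p-value floor).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import CityConfig, PlantedCluster
from .grid import Grid, assemble_cells, zone_clip
from .scan import block_scan_table
from .synthetic import block_profile_labels, generate_city, simulate_cases


def blockwise_profile_city(
    seed: int, n_blocks: int = 36, width: float = 6000.0, height: float = 6000.0
) -> tuple[pd.DataFrame, Grid]:
    """Inhabited-cell table with blockwise-constant NDI profiles.

    Each cell inherits the profile label of the block that contributes
    most of its population, so profiles are constant over blocks up to
    boundary cells. Returns (cells, grid); cells carry ``profile`` and
    the numeric ``ndi_score``.
    """
    cfg = CityConfig(seed=seed, width=width, height=height, n_blocks=n_blocks)
    blocks, buildings, _ = generate_city(cfg)
    grid = Grid.from_extent(cfg.extent, cfg.cell_size)
    weights = zone_clip(blocks, grid, buildings)
    cells = assemble_cells(grid, blocks, buildings, weights)

    labels = block_profile_labels(blocks, k=5)
    pop = {b.id: b.population for b in blocks}
    w = weights.dropna(subset=["habitable_fraction"]).copy()
    w["contrib"] = w["habitable_fraction"] * w["block_id"].map(pop)
    dominant = w.loc[w.groupby("cell_id")["contrib"].idxmax()].set_index("cell_id")["block_id"]

    inhabited = cells[cells["inhabited"]].copy()
    inhabited["profile"] = dominant.reindex(inhabited.index).map(labels)
    inhabited = inhabited.dropna(subset=["profile"])
    from .zones import ndi_numeric

    inhabited["ndi_score"] = ndi_numeric(inhabited["profile"])
    return inhabited, grid


def planted_cluster_city(
    seed: int,
    rr: float = 3.0,
    coverage: float = 0.10,
    n_blocks: int = 36,
    width: float = 6000.0,
    height: float = 6000.0,
) -> tuple[pd.DataFrame, PlantedCluster]:
    """Block-level scan table with one planted circular risk cluster.

    The disc is centred off-centre and sized to cover ``coverage`` of
    the extent area (~ the same share of population). Returns the scan
    table (zones = blocks) and the planted cluster geometry; zones whose
    centroid lies inside the disc are the ground-truth cluster members.
    """
    radius = math.sqrt(coverage * width * height / math.pi)
    planted = PlantedCluster(cx=0.3 * width, cy=0.65 * height, radius=radius, rr=rr)
    cfg = CityConfig(
        seed=seed, width=width, height=height, n_blocks=n_blocks,
        planted_clusters=[planted],
    )
    blocks, buildings, _ = generate_city(cfg)
    cases = simulate_cases(blocks, cfg, buildings, seed=cfg.seed + 1)
    table = block_scan_table(blocks, cases, years=cfg.years)
    return table, planted


def true_cluster_zones(table: pd.DataFrame, planted: PlantedCluster) -> set[int]:
    """Zone ids whose centroid falls inside the planted disc."""
    inside = (table["x"] - planted.cx) ** 2 + (table["y"] - planted.cy) ** 2 <= planted.radius**2
    return set(int(i) for i in table.index[inside])


def null_scan_table(seed: int, n_zones: int = 20, total_cases: int = 200) -> pd.DataFrame:
    """Flat-risk scan table: uniform-ish populations, cases multinomial
    with probabilities proportional to population (the scan's own null)."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, 5000, size=(n_zones, 2))
    pop = rng.uniform(1500, 2500, n_zones)
    probs = pop / pop.sum()
    cases = rng.multinomial(total_cases, probs).astype(float)
    df = pd.DataFrame(
        {"x": xy[:, 0], "y": xy[:, 1], "population": pop, "cases": cases}
    )
    df.index.name = "zone_id"
    return df
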