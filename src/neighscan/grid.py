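"""Regular analysis grid and dasymetric disaggregation.

The irregular census geography is replaced by a fixed square grid (cell
size chosen from the nearest-neighbour statistics of the point layers,
default 250 m). Block-level totals are reallocated to cells by zone
clipping: the share of a block's value a cell receives is the share of
the block's *habitable housing area* (building footprint x floors,
floors = height/3) that falls inside the cell. This is exact vector
intersection throughout -- no rasterization.

Cell ids are ``row * ncols + col`` with the origin at the extent's
lower-left corner and half-open cell intervals ``[x, x+size)`` so a
point on a boundary belongs to exactly one cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon, box
from shapely.strtree import STRtree

from .config import STRATA
from .synthetic import Building, CensusBlock


@dataclass(frozen=True)
class Grid:
    """Axis-aligned square grid tiling an extent."""

    x0: float
    y0: float
    cell_size: float
    nrows: int
    ncols: int

    @classmethod
    def from_extent(cls, extent: tuple[float, float, float, float], cell_size: float) -> "Grid":
        x0, y0, x1, y1 = extent
        ncols = int(math.ceil((x1 - x0) / cell_size))
        nrows = int(math.ceil((y1 - y0) / cell_size))
        return cls(x0, y0, cell_size, nrows, ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    def cell_id(self, row: int, col: int) -> int:
        return row * self.ncols + col

    def rowcol(self, cell_id: int) -> tuple[int, int]:
        return divmod(cell_id, self.ncols)

    def cell_polygon(self, row: int, col: int) -> Polygon:
        s = self.cell_size
        return box(self.x0 + col * s, self.y0 + row * s,
                   self.x0 + (col + 1) * s, self.y0 + (row + 1) * s)

    def cell_of_point(self, x: float, y: float) -> int:
        col = min(int((x - self.x0) // self.cell_size), self.ncols - 1)
        row = min(int((y - self.y0) // self.cell_size), self.nrows - 1)
        return self.cell_id(row, col)

    def all_polygons(self) -> list[Polygon]:
        return [self.cell_polygon(*self.rowcol(i)) for i in range(self.n_cells)]


# ---------------------------------------------------------------------------
# grid sizing


def mean_nearest_neighbour_distance(points: np.ndarray) -> float:
    """Mean Euclidean distance from each point to its nearest neighbour."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need at least 2 points")
    d, _ = cKDTree(pts).query(pts, k=2)
    return float(d[:, 1].mean())


def choose_cell_size(mean_nn: float, step: float = 50.0) -> float:
    """Round the mean nearest-neighbour distance to the nearest ``step``.

    Exact half-way ties round down (a finer grid loses less information
    than a coarser one); the result is never below one step.
    """
    if mean_nn <= 0:
        raise ValueError("mean nearest-neighbour distance must be > 0")
    q = mean_nn / step
    lower = math.floor(q)
    rounded = lower if (q - lower) <= 0.5 else lower + 1
    return max(step, rounded * step)


# ---------------------------------------------------------------------------
# habitable volume


def habitable_floors(height: float) -> int:
    """Number of habitable floors: floor(height / 3 m), at least one
    storey for any building of standing height."""
    if height < 3.0:
        raise ValueError(f"height {height} m < 3 m: no habitable floor")
    return max(1, int(height // 3.0))


def habitable_area(building: Building) -> float:
    """Habitable housing area: footprint area x floor count (m^2)."""
    return building.footprint.area * habitable_floors(building.height)


# ---------------------------------------------------------------------------
# zone clipping


def zone_clip(
    blocks: list[CensusBlock], grid: Grid, buildings: list[Building] | None = None
) -> pd.DataFrame:
    """Exact block/cell overlap weights.

    Returns a DataFrame with columns ``block_id, cell_id, area_fraction,
    habitable_fraction``. ``area_fraction`` is the share of the block's
    polygon area inside the cell; ``habitable_fraction`` the share of its
    habitable housing area (buildings straddling a cell boundary
    contribute to each side proportionally to footprint intersection).
    For a block without any building the habitable fraction is NaN (the
    dasymetric formula's denominator is zero); per block each defined
    fraction column sums to 1.
    """
    polys = grid.all_polygons()
    tree = STRtree(polys)

    area_w: dict[tuple[int, int], float] = {}
    for blk in blocks:
        if blk.polygon.is_empty:
            continue
        for idx in tree.query(blk.polygon):
            a = blk.polygon.intersection(polys[idx]).area
            if a > 0:
                area_w[(blk.id, int(idx))] = a

    if not area_w:
        raise ValueError("blocks and grid do not overlap")

    hab_w: dict[tuple[int, int], float] = {}
    if buildings:
        for b in buildings:
            ha_density = habitable_floors(b.height)  # per m^2 of footprint
            for idx in tree.query(b.footprint):
                a = b.footprint.intersection(polys[idx]).area
                if a > 0:
                    key = (b.block_id, int(idx))
                    hab_w[key] = hab_w.get(key, 0.0) + a * ha_density

    block_area = {b.id: b.polygon.area for b in blocks}
    block_hab: dict[int, float] = {}
    for (bid, _), v in hab_w.items():
        block_hab[bid] = block_hab.get(bid, 0.0) + v

    keys = sorted(set(area_w) | set(hab_w))
    rows = []
    for bid, cid in keys:
        af = area_w.get((bid, cid), 0.0) / block_area[bid]
        th = block_hab.get(bid, 0.0)
        hf = hab_w.get((bid, cid), 0.0) / th if th > 0 else np.nan
        rows.append((bid, cid, af, hf))
    return pd.DataFrame(rows, columns=["block_id", "cell_id", "area_fraction", "habitable_fraction"])


# ---------------------------------------------------------------------------
# disaggregation


def disaggregate_population(blocks: list[CensusBlock], weights: pd.DataFrame) -> pd.Series:
    """Cell populations: ``sum_b P_b x habitable_fraction(b, cell)``.

    Raises if a populated block has no habitable area (the dasymetric
    formula is undefined: its denominator, the block's total housing
    area, is zero). Cells without buildings receive 0.
    """
    pop = {b.id: b.population for b in blocks}
    bad = {
        int(bid)
        for bid in weights.loc[weights["habitable_fraction"].isna(), "block_id"].unique()
        if pop.get(int(bid), 0) > 0
    }
    if bad:
        raise ValueError(f"populated blocks without habitable area: {sorted(bad)}")
    w = weights.dropna(subset=["habitable_fraction"])
    vals = w["habitable_fraction"].to_numpy() * w["block_id"].map(pop).to_numpy()
    return pd.Series(vals).groupby(w["cell_id"].to_numpy()).sum().rename("population")


def disaggregate_variable(
    blocks: list[CensusBlock],
    weights: pd.DataFrame,
    variable: str,
    mode: str = "rate",
    cell_population: pd.Series | None = None,
) -> pd.Series:
    """Disaggregate one block variable to cells.

    ``mode="count"``: block values are counts, split by habitable
    fraction (mass conserving). ``mode="rate"``: block values are
    percentages (0-100 scale); they are converted to counts via block
    population, split, then re-expressed as a percentage of the cell
    population (NaN where the cell population is 0).
    """
    if mode not in ("count", "rate"):
        raise ValueError(f"unknown mode {mode!r}")
    vals = {b.id: b.socioeconomic[variable] for b in blocks}
    pop = {b.id: b.population for b in blocks}
    w = weights.dropna(subset=["habitable_fraction"])
    bid = w["block_id"].to_numpy()
    hf = w["habitable_fraction"].to_numpy()
    if mode == "count":
        counts = np.array([vals[b] for b in bid]) * hf
        return pd.Series(counts).groupby(w["cell_id"].to_numpy()).sum().rename(variable)
    counts = np.array([vals[b] / 100.0 * pop[b] for b in bid]) * hf
    cell_counts = pd.Series(counts).groupby(w["cell_id"].to_numpy()).sum()
    if cell_population is None:
        cell_population = disaggregate_population(blocks, weights)
    cp = cell_population.reindex(cell_counts.index)
    out = 100.0 * cell_counts / cp.where(cp > 0)
    return out.rename(variable)


def disaggregate_strata(blocks: list[CensusBlock], weights: pd.DataFrame) -> pd.DataFrame:
    """Sex x age-band stratum counts per cell (columns ``pop_<stratum>``)."""
    w = weights.dropna(subset=["habitable_fraction"])
    out = {}
    for s in STRATA:
        sv = {b.id: b.strata[s] for b in blocks}
        vals = w["habitable_fraction"].to_numpy() * w["block_id"].map(sv).to_numpy()
        out[f"pop_{s}"] = pd.Series(vals).groupby(w["cell_id"].to_numpy()).sum()
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# built centroids and cell assembly


def built_centroid(cell_polygon: Polygon, buildings: list[Building]) -> Point:
    """Habitable-area-weighted centroid of the built pieces inside a cell;
    falls back to the geometric cell centre when nothing is built."""
    wx = wy = wsum = 0.0
    for b in buildings:
        piece = b.footprint.intersection(cell_polygon)
        if piece.is_empty or piece.area == 0:
            continue
        wgt = piece.area * habitable_floors(b.height)
        c = piece.centroid
        wx += wgt * c.x
        wy += wgt * c.y
        wsum += wgt
    if wsum == 0:
        return cell_polygon.centroid
    return Point(wx / wsum, wy / wsum)


def assemble_cells(
    grid: Grid,
    blocks: list[CensusBlock],
    buildings: list[Building],
    weights: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the master per-cell table.

    One row per grid cell: geometry anchors (``x, y`` cell centre;
    ``bx, by`` built centroid), disaggregated ``population`` and stratum
    counts, every block socioeconomic variable re-expressed at cell level
    (percent scale, NaN for uninhabited cells), and an ``inhabited`` flag
    (population > 0). Uninhabited cells are excluded from profiling, zone
    design and scanning downstream.
    """
    if weights is None:
        weights = zone_clip(blocks, grid, buildings)

    idx = pd.RangeIndex(grid.n_cells, name="cell_id")
    rows, cols = np.divmod(np.arange(grid.n_cells), grid.ncols)
    s = grid.cell_size
    df = pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "x": grid.x0 + (cols + 0.5) * s,
            "y": grid.y0 + (rows + 0.5) * s,
        },
        index=idx,
    )

    pop = disaggregate_population(blocks, weights)
    df["population"] = pop.reindex(idx, fill_value=0.0)
    strata = disaggregate_strata(blocks, weights)
    for c in strata.columns:
        df[c] = strata[c].reindex(idx, fill_value=0.0)

    var_names = list(blocks[0].socioeconomic) if blocks else []
    for name in var_names:
        v = disaggregate_variable(blocks, weights, name, mode="rate", cell_population=pop)
        df[name] = v.reindex(idx)

    # built centroids (cell centre fallback)
    tree = STRtree([b.footprint for b in buildings]) if buildings else None
    bx = df["x"].to_numpy().copy()
    by = df["y"].to_numpy().copy()
    if tree is not None:
        for cid in range(grid.n_cells):
            cp = grid.cell_polygon(*grid.rowcol(cid))
            cand = [buildings[i] for i in tree.query(cp)]
            if cand:
                pt = built_centroid(cp, cand)
                bx[cid], by[cid] = pt.x, pt.y
    df["bx"] = bx
    df["by"] = by
    df["inhabited"] = df["population"] > 0
    return df
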