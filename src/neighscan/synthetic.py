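"""Synthetic metropolitan area generator.

Emulates the data substrate of a small-area contextual health study:
census blocks (~2000 inhabitants, socioeconomic attribute tables),
building footprints with heights, amenity layers, a lattice street
network, an age x sex stratified population, and geocoded myocardial
infarction events drawn from stratum baseline rates with optional
planted circular risk clusters.

Everything is driven by a single integer seed; identical configs give
byte-identical cities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Point, Polygon, box
from shapely.prepared import prep

from .config import (
    ASSOCIATION_TYPES,
    PROFILE_LABELS,
    RETAIL_CATEGORIES,
    STRATA,
    CityConfig,
)

# minimum area a census block needs to host housing (1 ha)
_MIN_BLOCK_AREA = 1e4

#: stratum shares of total block population (35-74 analysis population
#: is a subset of the full population; remainder is outside the age range)
_STRATUM_SHARES = {"f_35_54": 0.13, "f_55_74": 0.11, "m_35_54": 0.13, "m_55_74": 0.09}

#: socioeconomic variables: name -> (base %, slope per unit deprivation, noise sd)
#: slopes are monotone in the latent deprivation field by construction
SOCIO_VARIABLES: dict[str, tuple[float, float, float]] = {
    "unemployment_rate": (10.0, 7.0, 1.2),
    "pct_blue_collar": (20.0, 8.0, 1.5),
    "pct_precarious_jobs": (12.0, 5.0, 1.0),
    "pct_single_parent": (12.0, 5.0, 1.0),
    "pct_family_allowance": (50.0, 10.0, 1.5),
    "pct_safety_net": (5.0, 4.0, 0.8),
    "pct_no_car": (20.0, 10.0, 1.5),
    "pct_two_cars": (28.0, -12.0, 1.5),
    "pct_foreigners": (10.0, 6.0, 1.2),
    "pct_no_qualification": (18.0, 8.0, 1.5),
    "pct_high_school_grad": (9.0, -3.0, 0.8),
}


@dataclass
class CensusBlock:
    """Source areal unit: polygon + population + strata + socioeconomic table."""

    id: int
    polygon: Polygon
    population: int
    strata: dict[str, int]
    socioeconomic: dict[str, float]
    #: latent deprivation score the variables were generated from (kept for
    #: validation and for blockwise-constant profile scenarios)
    deprivation: float = 0.0


@dataclass
class Building:
    id: int
    footprint: Polygon
    height: float
    block_id: int


@dataclass
class AmenitySite:
    id: int
    layer: str
    geometry: Point | Polygon
    attributes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry helpers


def _bounded_voronoi(points: np.ndarray, extent: tuple[float, float, float, float]) -> list[Polygon]:
    """Voronoi cells of ``points`` clipped exactly to the extent rectangle.

    Mirroring the seeds across the four extent edges makes every original
    cell finite and aligned with the rectangle, so the cells partition it.
    """
    x0, y0, x1, y1 = extent
    mirrors = [
        np.column_stack([2 * x0 - points[:, 0], points[:, 1]]),
        np.column_stack([2 * x1 - points[:, 0], points[:, 1]]),
        np.column_stack([points[:, 0], 2 * y0 - points[:, 1]]),
        np.column_stack([points[:, 0], 2 * y1 - points[:, 1]]),
    ]
    vor = Voronoi(np.vstack([points, *mirrors]))
    bbox = box(x0, y0, x1, y1)
    polys = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(bbox)
        polys.append(poly)
    return polys


def deprivation_field(cfg: CityConfig, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Latent deprivation surface: radial centre-periphery gradient + tilt.

    Returns values in roughly ``[-strength, strength]``; the centre of the
    extent is the most deprived point (deprived urban core, advantaged
    periphery), matching the study-area pattern.
    """
    cx, cy = cfg.width / 2.0, cfg.height / 2.0
    r_ref = 0.5 * math.hypot(cfg.width, cfg.height)
    r = np.hypot(np.asarray(x) - cx, np.asarray(y) - cy) / r_ref
    tilt = cfg.gradient_ux * (np.asarray(x) / cfg.width - 0.5) + cfg.gradient_uy * (
        np.asarray(y) / cfg.height - 0.5
    )
    return cfg.gradient_strength * (1.0 - 2.0 * r + 0.5 * tilt)


def _field_unit(cfg: CityConfig, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Deprivation field rescaled to [0, 1] (0.5 everywhere when flat)."""
    s = abs(cfg.gradient_strength)
    if s == 0:
        return np.full(np.shape(x), 0.5)
    f = deprivation_field(cfg, x, y) / s
    return np.clip((f + 1.0) / 2.0, 0.0, 1.0)


def _sample_in_polygon(poly: Polygon, rng: np.random.Generator, n: int = 1) -> list[Point]:
    """Uniform points inside a polygon by bounding-box rejection."""
    x0, y0, x1, y1 = poly.bounds
    prepared = prep(poly)
    pts: list[Point] = []
    while len(pts) < n:
        p = Point(rng.uniform(x0, x1), rng.uniform(y0, y1))
        if prepared.contains(p):
            pts.append(p)
    return pts


# ---------------------------------------------------------------------------
# city generation


def _make_blocks(cfg: CityConfig, rng: np.random.Generator) -> list[CensusBlock]:
    if cfg.width * cfg.height < cfg.n_blocks * _MIN_BLOCK_AREA:
        raise ValueError(
            f"extent {cfg.width:g}x{cfg.height:g} m too small to host "
            f"{cfg.n_blocks} census blocks (need >= {_MIN_BLOCK_AREA:g} m^2 each)"
        )
    seeds = np.column_stack(
        [rng.uniform(0, cfg.width, cfg.n_blocks), rng.uniform(0, cfg.height, cfg.n_blocks)]
    )
    polys = _bounded_voronoi(seeds, cfg.extent)

    blocks = []
    for i, poly in enumerate(polys):
        c = poly.centroid
        dep = float(deprivation_field(cfg, c.x, c.y)) + rng.normal(0.0, 0.15)
        pop = int(round(max(200.0, rng.normal(cfg.target_block_pop, 0.15 * cfg.target_block_pop))))
        strata = {}
        for s in STRATA:
            share = _STRATUM_SHARES[s] * rng.uniform(0.9, 1.1)
            strata[s] = int(round(pop * share))
        socio = {}
        for name, (base, slope, sd) in SOCIO_VARIABLES.items():
            socio[name] = float(np.clip(base + slope * dep + rng.normal(0.0, sd), 0.0, 100.0))
        blocks.append(CensusBlock(i, poly, pop, strata, socio, dep))
    return blocks


def _make_buildings(blocks: list[CensusBlock], cfg: CityConfig, rng: np.random.Generator) -> list[Building]:
    buildings: list[Building] = []
    bid = 0
    for blk in blocks:
        n_b = max(3, int(round(blk.population / 60.0)))
        dhat = float(_field_unit(cfg, blk.polygon.centroid.x, blk.polygon.centroid.y))
        # denser, taller housing toward the deprived core
        max_floors = 2 + int(round(5 * dhat))
        centres = _sample_in_polygon(blk.polygon, rng, n_b)
        for c in centres:
            floors = int(rng.integers(1, max_floors + 1))
            height = 3.0 * floors + rng.uniform(0.0, 2.5)
            half = rng.uniform(5.0, 12.0)
            fp = box(c.x - half, c.y - half, c.x + half, c.y + half).intersection(blk.polygon)
            if fp.is_empty or fp.area < 25.0 or fp.geom_type != "Polygon":
                fp = box(c.x - 5.0, c.y - 5.0, c.x + 5.0, c.y + 5.0).intersection(blk.polygon)
                if fp.is_empty or fp.geom_type != "Polygon":
                    continue
            buildings.append(Building(bid, fp, float(height), blk.id))
            bid += 1
    return buildings


def _thinned_points(cfg: CityConfig, layer: str, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson sample for one amenity layer (thinning)."""
    lam = cfg.amenity_intensities.get(layer, 0.0)
    gamma = cfg.amenity_coupling.get(layer, 0.0)
    area_km2 = cfg.width * cfg.height / 1e6
    if lam <= 0 or area_km2 <= 0:
        return np.empty((0, 2))
    # normalize the acceptance weight so the expected count stays lam * area
    gx = np.linspace(0, cfg.width, 21)
    gy = np.linspace(0, cfg.height, 21)
    mx, my = np.meshgrid(gx, gy)
    w_grid = np.exp(gamma * (_field_unit(cfg, mx.ravel(), my.ravel()) - 0.5))
    w_max, w_mean = float(w_grid.max()), float(w_grid.mean())
    n_cand = rng.poisson(lam * area_km2 * w_max / w_mean)
    if n_cand == 0:
        return np.empty((0, 2))
    cand = np.column_stack(
        [rng.uniform(0, cfg.width, n_cand), rng.uniform(0, cfg.height, n_cand)]
    )
    w = np.exp(gamma * (_field_unit(cfg, cand[:, 0], cand[:, 1]) - 0.5))
    keep = rng.uniform(0, w_max, n_cand) < w
    return cand[keep]


def _make_amenities(cfg: CityConfig, rng: np.random.Generator) -> list[AmenitySite]:
    sites: list[AmenitySite] = []
    sid = 0
    bbox = box(*cfg.extent)
    for layer in sorted(cfg.amenity_intensities):
        pts = _thinned_points(cfg, layer, rng)
        for x, y in pts:
            attrs: dict = {}
            geom: Point | Polygon = Point(x, y)
            if layer == "park":
                cls = rng.choice(3, p=[0.6, 0.3, 0.1])
                if cls == 0:      # < 1 ha
                    area = rng.uniform(0.1, 0.99) * 1e4
                elif cls == 1:    # 1-10 ha
                    area = rng.uniform(1.0, 9.9) * 1e4
                else:             # > 10 ha
                    area = rng.uniform(10.5, 30.0) * 1e4
                r = math.sqrt(area / math.pi)
                geom = Point(x, y).buffer(r, quad_segs=12).intersection(bbox)
                attrs["area_m2"] = float(geom.area)
            elif layer == "bus_stop":
                attrs["lines"] = int(min(6, 1 + rng.geometric(0.5) - 1))
            elif layer == "tram_stop":
                attrs["lines"] = int(rng.integers(1, 3))
            elif layer == "retail":
                attrs["category"] = str(rng.choice(RETAIL_CATEGORIES, p=[0.1, 0.35, 0.35, 0.2]))
                attrs["floor_space"] = float(rng.lognormal(math.log(150.0), 0.8))
            elif layer == "school":
                attrs["level"] = "primary_middle" if rng.uniform() < 0.7 else "secondary"
                dhat = float(_field_unit(cfg, x, y))
                p_zep = 0.1 + 0.5 * dhat
                p_ar = 0.2
                p = np.array([p_zep, p_ar, max(1e-9, 1.0 - p_zep - p_ar)])
                attrs["grading"] = str(rng.choice(["ZEP", "AR", "other"], p=p / p.sum()))
            elif layer == "civic_association":
                attrs["type"] = str(rng.choice(ASSOCIATION_TYPES, p=[0.25, 0.15, 0.6]))
            sites.append(AmenitySite(sid, layer, geom, attrs))
            sid += 1
    return sites


def generate_city(cfg: CityConfig) -> tuple[list[CensusBlock], list[Building], list[AmenitySite]]:
    """Generate blocks, buildings and amenity layers for one seeded city.

    Blocks are a clipped Voronoi tessellation (an exact planar partition of
    the extent); socioeconomic variables are monotone in the latent
    deprivation field plus noise; buildings carry the habitable volume the
    dasymetric step weights by; amenity layers are inhomogeneous Poisson
    processes whose intensity covaries with deprivation.
    """
    rng = np.random.default_rng(cfg.seed)
    blocks = _make_blocks(cfg, rng)
    buildings = _make_buildings(blocks, cfg, rng)
    amenities = _make_amenities(cfg, rng)
    return blocks, buildings, amenities


def street_graph(cfg: CityConfig) -> nx.Graph:
    """Grid-lattice road network over the extent (edge weight = length m)."""
    dx = cfg.road_spacing
    nx_nodes = int(math.floor(cfg.width / dx)) + 1
    ny_nodes = int(math.floor(cfg.height / dx)) + 1
    g = nx.Graph()
    for i in range(nx_nodes):
        for j in range(ny_nodes):
            g.add_node((i, j), pos=(i * dx, j * dx))
    for i in range(nx_nodes):
        for j in range(ny_nodes):
            if i + 1 < nx_nodes:
                g.add_edge((i, j), (i + 1, j), weight=dx)
            if j + 1 < ny_nodes:
                g.add_edge((i, j), (i, j + 1), weight=dx)
    return g


# ---------------------------------------------------------------------------
# case simulation


def _cluster_multiplier(cfg: CityConfig, x: float, y: float) -> float:
    m = 1.0
    for cl in cfg.planted_clusters:
        if cl.contains(x, y):
            m *= cl.rr
    return m


def simulate_cases(
    blocks: list[CensusBlock],
    cfg: CityConfig,
    buildings: list[Building] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate geocoded MI events over the observation span.

    Per block and stratum the case count is Poisson with mean
    ``stratum population x years x rate/1e5 x planted-cluster multiplier``
    (multiplier applies when the block centroid falls inside a planted
    cluster). Locations are uniform over the block's building footprints,
    weighted by habitable area; blocks without buildings fall back to
    uniform-over-polygon. Years are uniform over the span.

    Returns a DataFrame with columns
    ``case_id, block_id, x, y, sex, age_band, year``.
    """
    if sum(b.population for b in blocks) <= 0:
        raise ValueError("zero population everywhere: cannot simulate cases")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)

    by_block: dict[int, list[Building]] = {}
    if buildings:
        for b in buildings:
            by_block.setdefault(b.block_id, []).append(b)

    rows = []
    cid = 0
    for blk in blocks:
        c = blk.polygon.centroid
        mult = _cluster_multiplier(cfg, c.x, c.y)
        blk_buildings = by_block.get(blk.id, [])
        if blk_buildings:
            w = np.array(
                [b.footprint.area * max(1, int(b.height // 3)) for b in blk_buildings]
            )
            w = w / w.sum()
        for s in STRATA:
            sex, band = s.split("_", 1)
            band = band.replace("_", "-")
            lam = blk.strata[s] * cfg.years * cfg.baseline_rates.get(s, 0.0) / 1e5 * mult
            n = int(rng.poisson(lam))
            for _ in range(n):
                if blk_buildings:
                    bld = blk_buildings[int(rng.choice(len(blk_buildings), p=w))]
                    pt = _sample_in_polygon(bld.footprint, rng)[0]
                else:
                    pt = _sample_in_polygon(blk.polygon, rng)[0]
                rows.append(
                    (cid, blk.id, pt.x, pt.y, sex, band, int(rng.integers(0, cfg.years)))
                )
                cid += 1
    return pd.DataFrame(
        rows, columns=["case_id", "block_id", "x", "y", "sex", "age_band", "year"]
    )


def block_profile_labels(blocks: list[CensusBlock], k: int = 5) -> dict[int, str]:
    """Quantile-bin block deprivation scores into k ordered profile labels.

    Convenience for blockwise-constant NDI scenarios (zone-design
    benchmarks): label A = least deprived quintile ... E = most deprived.
    """
    labels = PROFILE_LABELS[:k]
    dep = pd.Series({b.id: b.deprivation for b in blocks})
    cats = pd.qcut(dep.rank(method="first"), k, labels=False)
    return {int(i): labels[int(c)] for i, c in cats.items()}
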