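"""Amenity and psychosocial indicators per inhabited cell.

Each indicator follows a published GIS recipe: road-network distance to
the nearest healthcare and sports sites, a park attractiveness index with
size-dependent attraction radii (100 m below 1 ha, 500 m for 1-10 ha,
1000 m above), line-weighted transit catchments (300 m bus / 400 m tram),
a per-category retail score inside a 200 m radius, civic associations per
100 inhabitants by type, and a school density x socio-educational grading
index.

Boundary convention: all catchments and buffers are *strictly* inside
(a site exactly on the radius does not count).
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.strtree import STRtree

from .config import (
    ASSOCIATION_TYPES,
    RETAIL_CATEGORIES,
    AccessibilityParams,
)
from .grid import Grid
from .synthetic import AmenitySite


def _layer(sites: list[AmenitySite], name: str) -> list[AmenitySite]:
    return [s for s in sites if s.layer == name]


def _points_xy(sites: list[AmenitySite]) -> np.ndarray:
    return np.array([[s.geometry.x, s.geometry.y] for s in sites]).reshape(-1, 2)


# ---------------------------------------------------------------------------
# network distances


def network_distance_to_nearest(
    cells_xy: np.ndarray,
    sites_xy: np.ndarray,
    graph: nx.Graph,
    euclidean_fallback: bool = False,
) -> np.ndarray:
    """Road distance from each cell anchor point to its nearest site.

    Anchor and site are snapped to their nearest graph nodes; the
    travelled distance is straight-line connector + shortest path +
    connector, minimised over sites via a single multi-source Dijkstra
    (virtual source wired to every site's node with the site's connector
    as edge weight). Sites on disconnected components are ignored with a
    warning. With ``euclidean_fallback`` the straight-line distance is
    returned instead (and always when the graph is empty).

    Returns NaN for every cell when there are no sites.
    """
    cells_xy = np.asarray(cells_xy, float)
    if len(sites_xy) == 0:
        return np.full(len(cells_xy), np.nan)
    sites_xy = np.asarray(sites_xy, float)
    if euclidean_fallback or graph.number_of_nodes() == 0:
        d = np.hypot(
            cells_xy[:, None, 0] - sites_xy[None, :, 0],
            cells_xy[:, None, 1] - sites_xy[None, :, 1],
        )
        return d.min(axis=1)

    nodes = list(graph.nodes)
    pos = np.array([graph.nodes[n]["pos"] for n in nodes])
    tree = cKDTree(pos)

    sd, si = tree.query(sites_xy)
    g = graph.copy()
    src = "__virtual_source__"
    g.add_node(src)
    for conn, ni in zip(sd, si):
        node = nodes[ni]
        w = conn
        if g.has_edge(src, node):
            w = min(w, g.edges[src, node]["weight"])
        g.add_edge(src, node, weight=w)
    dist = nx.single_source_dijkstra_path_length(g, src, weight="weight")

    cd, ci = tree.query(cells_xy)
    out = np.empty(len(cells_xy))
    warned = False
    for k, (conn, ni) in enumerate(zip(cd, ci)):
        node = nodes[ni]
        if node in dist:
            out[k] = conn + dist[node]
        else:
            if not warned:
                warnings.warn("some cells/sites on disconnected road components; set NaN")
                warned = True
            out[k] = np.nan
    return out


# ---------------------------------------------------------------------------
# catchment indicators


def park_attraction_radius(area_m2: float, params: AccessibilityParams) -> float:
    """Size-class attraction radius: <1 ha, 1-10 ha, >10 ha."""
    if area_m2 < 1e4:
        return params.park_radius_small
    if area_m2 <= 1e5:
        return params.park_radius_medium
    return params.park_radius_large


def park_attractiveness(
    cells_xy: np.ndarray, parks: list[AmenitySite], params: AccessibilityParams | None = None
) -> np.ndarray:
    """Park attractiveness of each cell anchor.

    A park attracts a point when the point lies strictly within the park
    polygon buffered by its size-class radius. The default combination
    rule counts attracting parks; ``max`` scores 1 if any attracts;
    ``area_weighted`` sums attracting parks' areas in ha.
    """
    params = params or AccessibilityParams()
    cells_xy = np.asarray(cells_xy, float)
    score = np.zeros(len(cells_xy))
    for p in parks:
        area = p.attributes.get("area_m2", p.geometry.area)
        r = park_attraction_radius(area, params)
        d = np.array([p.geometry.distance(_pt(x, y)) for x, y in cells_xy])
        inside = d < r
        if params.park_rule == "area_weighted":
            score += inside * (area / 1e4)
        else:
            score += inside.astype(float)
    if params.park_rule == "max":
        return (score > 0).astype(float)
    return score


def _pt(x: float, y: float):
    from shapely.geometry import Point

    return Point(x, y)


def transit_availability(
    cells_xy: np.ndarray,
    stops: list[AmenitySite],
    params: AccessibilityParams | None = None,
) -> np.ndarray:
    """Line-weighted transit coverage: sum of line counts over stops whose
    catchment (300 m bus, 400 m tram, strict) contains the anchor."""
    params = params or AccessibilityParams()
    cells_xy = np.asarray(cells_xy, float)
    score = np.zeros(len(cells_xy))
    for s in stops:
        r = params.bus_catchment if s.layer == "bus_stop" else params.tram_catchment
        lines = int(s.attributes.get("lines", 1))
        d = np.hypot(cells_xy[:, 0] - s.geometry.x, cells_xy[:, 1] - s.geometry.y)
        score += (d < r) * lines
    return score


def retail_score(
    cells_xy: np.ndarray,
    outlets: list[AmenitySite],
    radius: float = 200.0,
) -> pd.DataFrame:
    """Per-category retail score within ``radius`` of each anchor.

    The quantity of retail stores in the radius is apportioned to each
    category by its share of the retail floor space there:
    ``score_c = (outlets in radius) x (category floor space / total
    floor space)``. All zero when no outlet is within the radius; with
    equal floor spaces the category scores sum to the plain outlet
    count.
    """
    cells_xy = np.asarray(cells_xy, float)
    cols = {f"retail_{c}": np.zeros(len(cells_xy)) for c in RETAIL_CATEGORIES}
    if outlets:
        xy = _points_xy(outlets)
        cats = np.array([o.attributes.get("category", "food") for o in outlets])
        space = np.array([float(o.attributes.get("floor_space", 1.0)) for o in outlets])
        tree = cKDTree(xy)
        for i, (x, y) in enumerate(cells_xy):
            idx = [j for j in tree.query_ball_point([x, y], radius) if
                   np.hypot(xy[j, 0] - x, xy[j, 1] - y) < radius]
            if not idx:
                continue
            tot = space[idx].sum()
            n = len(idx)
            for c in RETAIL_CATEGORIES:
                mask = cats[idx] == c
                if mask.any():
                    cols[f"retail_{c}"][i] = n * (space[idx][mask].sum() / tot)
    return pd.DataFrame(cols)


def calibrate_retail_radius(
    cells_xy: np.ndarray, outlets: list[AmenitySite], step: float = 10.0, max_radius: float = 2000.0
) -> float:
    """Smallest radius (grid search in ``step`` increments) at which at
    least half the cells have at least one outlet strictly within it."""
    if not outlets:
        raise ValueError("need at least one outlet")
    cells_xy = np.asarray(cells_xy, float)
    xy = _points_xy(outlets)
    d = np.hypot(
        cells_xy[:, None, 0] - xy[None, :, 0], cells_xy[:, None, 1] - xy[None, :, 1]
    ).min(axis=1)
    r = step
    while r <= max_radius:
        if (d < r).mean() >= 0.5:
            return r
        r += step
    return max_radius


def civic_ratio(
    cells: pd.DataFrame, grid: Grid, associations: list[AmenitySite]
) -> pd.DataFrame:
    """Associations per 100 inhabitants, by type, counted within the cell
    polygon. NaN for uninhabited cells (ratio undefined)."""
    counts = {t: np.zeros(len(cells)) for t in ASSOCIATION_TYPES}
    id_to_pos = {cid: k for k, cid in enumerate(cells.index)}
    for a in associations:
        cid = grid.cell_of_point(a.geometry.x, a.geometry.y)
        if cid in id_to_pos:
            t = a.attributes.get("type", "volunteer")
            counts[t][id_to_pos[cid]] += 1
    pop = cells["population"].to_numpy()
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for t in ASSOCIATION_TYPES:
            out[f"civic_{t}"] = np.where(pop > 0, 100.0 * counts[t] / pop, np.nan)
    return pd.DataFrame(out, index=cells.index)


def school_index(
    cells_xy: np.ndarray,
    schools: list[AmenitySite],
    params: AccessibilityParams | None = None,
) -> np.ndarray:
    """School density x socio-educational grading within the school radius.

    Default weights 1 (priority-zone ZEP), 2 (AR), 3 (other): higher =
    more favourable socio-educational context. The scheme is an explicit
    modelling choice (config-exposed); with equal weights the index
    degenerates to the school count.
    """
    params = params or AccessibilityParams()
    cells_xy = np.asarray(cells_xy, float)
    score = np.zeros(len(cells_xy))
    for s in schools:
        w = params.school_weights.get(s.attributes.get("grading", "other"), 1.0)
        d = np.hypot(cells_xy[:, 0] - s.geometry.x, cells_xy[:, 1] - s.geometry.y)
        score += (d < params.school_radius) * w
    return score


# ---------------------------------------------------------------------------
# assembly


def build_indicators(
    cells: pd.DataFrame,
    grid: Grid,
    amenities: list[AmenitySite],
    graph: nx.Graph,
    params: AccessibilityParams | None = None,
) -> pd.DataFrame:
    """All per-cell amenity/psychosocial indicators, keyed by cell id.

    Cell anchors are the built-area centroids (``bx, by``). Indicators
    are computed for every cell; downstream analyses restrict to
    inhabited ones.
    """
    params = params or AccessibilityParams()
    anchors = cells[["bx", "by"]].to_numpy()

    out = pd.DataFrame(index=cells.index)
    out["dist_healthcare"] = network_distance_to_nearest(
        anchors, _points_xy(_layer(amenities, "healthcare")), graph
    )
    out["dist_sports"] = network_distance_to_nearest(
        anchors, _points_xy(_layer(amenities, "sports")), graph
    )
    out["park_index"] = park_attractiveness(anchors, _layer(amenities, "park"), params)
    stops = _layer(amenities, "bus_stop") + _layer(amenities, "tram_stop")
    out["transit_index"] = transit_availability(anchors, stops, params)
    rs = retail_score(anchors, _layer(amenities, "retail"), params.retail_radius)
    rs.index = cells.index
    out = out.join(rs)
    out = out.join(civic_ratio(cells, grid, _layer(amenities, "civic_association")))
    out["school_index"] = school_index(anchors, _layer(amenities, "school"), params)
    return out
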