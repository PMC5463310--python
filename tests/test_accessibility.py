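"""Amenity indicators: network distances, catchment rules, retail scoring,
civic ratios and the school index."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from neighscan.accessibility import (
    calibrate_retail_radius,
    civic_ratio,
    network_distance_to_nearest,
    park_attraction_radius,
    park_attractiveness,
    retail_score,
    school_index,
    transit_availability,
)
from neighscan.config import AccessibilityParams
from neighscan.grid import Grid
from neighscan.synthetic import AmenitySite


def line_graph(length=1000.0, spacing=100.0) -> nx.Graph:
    g = nx.Graph()
    n = int(length / spacing) + 1
    for i in range(n):
        g.add_node(i, pos=(i * spacing, 0.0))
        if i:
            g.add_edge(i - 1, i, weight=spacing)
    return g


def site(layer, x, y, **attrs) -> AmenitySite:
    return AmenitySite(0, layer, Point(x, y), attrs)


def park(x, y, area_m2) -> AmenitySite:
    r = np.sqrt(area_m2 / np.pi)
    geom = Point(x, y).buffer(r, quad_segs=64)
    return AmenitySite(0, "park", geom, {"area_m2": area_m2})


# ---------------------------------------------------------------------------
# network distances


def test_network_distance_site_on_access_node():
    g = line_graph()
    # cell anchor 30 m off node 0, site exactly on node 0
    d = network_distance_to_nearest(np.array([[0.0, 30.0]]), np.array([[0.0, 0.0]]), g)
    assert d[0] == pytest.approx(30.0)


def test_network_distance_forced_path():
    g = line_graph()
    # site 400 m along the only road; anchor 10 m off node 0, site 5 m off node 4
    d = network_distance_to_nearest(np.array([[0.0, 10.0]]), np.array([[400.0, 5.0]]), g)
    assert d[0] == pytest.approx(10.0 + 400.0 + 5.0)


def _floyd_warshall(g: nx.Graph) -> dict:
    """Independent exhaustive all-pairs oracle."""
    nodes = list(g.nodes)
    dist = {a: {b: np.inf for b in nodes} for a in nodes}
    for a in nodes:
        dist[a][a] = 0.0
    for a, b, data in g.edges(data=True):
        dist[a][b] = dist[b][a] = min(dist[a][b], data["weight"])
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    return dist


def test_network_distance_matches_bruteforce(rng):
    """On a small random lattice the multi-source Dijkstra route equals an
    exhaustive Floyd-Warshall evaluation over all (cell, site) pairs."""
    g = nx.grid_2d_graph(5, 5)
    g = nx.relabel_nodes(g, {n: i for i, n in enumerate(sorted(g.nodes))})
    pos = {}
    for n in g.nodes:
        pos[n] = (200.0 * (n % 5), 200.0 * (n // 5))
        g.nodes[n]["pos"] = pos[n]
    for a, b in g.edges:
        g.edges[a, b]["weight"] = float(np.hypot(*(np.subtract(pos[a], pos[b]))))
    cells = rng.uniform(0, 800, size=(8, 2))
    sites = rng.uniform(0, 800, size=(3, 2))
    got = network_distance_to_nearest(cells, sites, g)

    apsp = _floyd_warshall(g)
    xy = np.array([pos[n] for n in g.nodes])

    def nearest(p):
        d = np.hypot(xy[:, 0] - p[0], xy[:, 1] - p[1])
        return int(d.argmin()), float(d.min())

    for i, c in enumerate(cells):
        cn, cd = nearest(c)
        best = min(
            cd + apsp[cn][nearest(s)[0]] + nearest(s)[1] for s in sites
        )
        assert got[i] == pytest.approx(best, rel=1e-9)


def test_network_distance_at_least_euclidean(rng):
    g = line_graph(2000, 100)
    cells = rng.uniform(0, 2000, size=(10, 2))
    sites = rng.uniform(0, 2000, size=(4, 2))
    net = network_distance_to_nearest(cells, sites, g)
    euc = network_distance_to_nearest(cells, sites, g, euclidean_fallback=True)
    assert (net >= euc - 1e-9).all()


def test_network_distance_no_sites():
    d = network_distance_to_nearest(np.array([[0.0, 0.0]]), np.empty((0, 2)), line_graph())
    assert np.isnan(d[0])


# ---------------------------------------------------------------------------
# parks


def test_park_radii_by_size_class():
    p = AccessibilityParams()
    assert park_attraction_radius(0.5e4, p) == 100.0
    assert park_attraction_radius(5e4, p) == 500.0
    assert park_attraction_radius(20e4, p) == 1000.0


def test_small_park_attracts_at_50m_not_150m():
    """A 0.5 ha park (100 m attraction radius) counts from its edge."""
    p = park(0, 0, 0.5e4)
    edge = np.sqrt(0.5e4 / np.pi)  # ~39.9 m park radius
    near = np.array([[edge + 50.0, 0.0]])
    far = np.array([[edge + 150.0, 0.0]])
    assert park_attractiveness(near, [p])[0] == 1.0
    assert park_attractiveness(far, [p])[0] == 0.0


def test_three_parks_three_classes():
    parks = [park(0, 0, 0.5e4), park(50, 0, 5e4), park(-50, 0, 20e4)]
    anchor = np.array([[0.0, np.sqrt(0.5e4 / np.pi) + 90.0]])  # within 100 m of all edges
    assert park_attractiveness(anchor, parks)[0] == 3.0


def test_park_rules():
    parks = [park(0, 0, 0.5e4), park(10, 0, 5e4)]
    anchor = np.array([[0.0, 80.0]])
    assert park_attractiveness(anchor, parks, AccessibilityParams(park_rule="max"))[0] == 1.0
    aw = park_attractiveness(anchor, parks, AccessibilityParams(park_rule="area_weighted"))[0]
    assert aw == pytest.approx(0.5 + 5.0)


# ---------------------------------------------------------------------------
# transit


def test_transit_none_in_catchment():
    stops = [site("bus_stop", 1000, 0, lines=3)]
    assert transit_availability(np.array([[0.0, 0.0]]), stops)[0] == 0.0


def test_transit_line_weighted_sum():
    stops = [site("bus_stop", 250, 0, lines=3), site("tram_stop", 0, 350, lines=2)]
    assert transit_availability(np.array([[0.0, 0.0]]), stops)[0] == 5.0


def test_transit_boundary_strict():
    stops = [site("bus_stop", 300.0, 0.0, lines=4)]
    assert transit_availability(np.array([[0.0, 0.0]]), stops)[0] == 0.0


# ---------------------------------------------------------------------------
# retail


def test_retail_single_outlet():
    outlets = [site("retail", 50, 0, category="food", floor_space=120.0)]
    rs = retail_score(np.array([[0.0, 0.0]]), outlets)
    assert rs.loc[0, "retail_food"] == pytest.approx(1.0)
    assert rs.loc[0, ["retail_itinerant", "retail_non_food", "retail_services"]].sum() == 0.0


def test_retail_no_outlets():
    rs = retail_score(np.array([[0.0, 0.0]]), [])
    assert (rs.to_numpy() == 0).all()


def test_retail_mixed_layout_hand_oracle():
    """Three outlets in radius, food holding 300 of 400 m^2: the outlet
    count splits 3 x 300/400 to food and 3 x 100/400 to services; an
    outlet at 250 m is outside the 200 m radius and ignored."""
    outlets = [
        site("retail", 10, 0, category="food", floor_space=100.0),
        site("retail", 0, 20, category="food", floor_space=200.0),
        site("retail", -30, 0, category="services", floor_space=100.0),
        site("retail", 250, 0, category="food", floor_space=999.0),
    ]
    rs = retail_score(np.array([[0.0, 0.0]]), outlets, radius=200.0)
    assert rs.loc[0, "retail_food"] == pytest.approx(3 * 300 / 400)
    assert rs.loc[0, "retail_services"] == pytest.approx(3 * 100 / 400)


def test_retail_equal_space_sums_to_count(rng):
    outlets = [
        site("retail", x, y, category=cat, floor_space=100.0)
        for (x, y), cat in zip(
            rng.uniform(-150, 150, size=(12, 2)),
            np.resize(["itinerant", "food", "non_food", "services"], 12),
        )
    ]
    rs = retail_score(np.array([[0.0, 0.0]]), outlets, radius=200.0)
    dists = [np.hypot(o.geometry.x, o.geometry.y) for o in outlets]
    n_in = sum(1 for d in dists if d < 200.0)
    assert rs.iloc[0].sum() == pytest.approx(n_in)


def test_calibrate_retail_radius_everywhere():
    cells = np.array([[0.0, 0.0], [5.0, 5.0]])
    outlets = [site("retail", 1, 1, category="food", floor_space=1.0)]
    assert calibrate_retail_radius(cells, outlets) == 10.0


def test_calibrate_retail_radius_matches_scan(rng):
    cells = rng.uniform(0, 2000, size=(40, 2))
    outlets = [site("retail", x, y) for x, y in rng.uniform(0, 2000, size=(5, 2))]
    got = calibrate_retail_radius(cells, outlets)
    xy = np.array([[o.geometry.x, o.geometry.y] for o in outlets])
    d = np.hypot(cells[:, None, 0] - xy[None, :, 0], cells[:, None, 1] - xy[None, :, 1]).min(axis=1)
    r = 10.0
    while (d < r).mean() < 0.5:
        r += 10.0
    assert got == r


def test_calibrate_needs_outlet():
    with pytest.raises(ValueError):
        calibrate_retail_radius(np.zeros((3, 2)), [])


# ---------------------------------------------------------------------------
# civic associations and schools


def _cells_df(grid: Grid, pops):
    idx = pd.RangeIndex(grid.n_cells, name="cell_id")
    return pd.DataFrame({"population": pops}, index=idx)


def test_civic_ratio_direct():
    grid = Grid(0, 0, 250, 1, 1)
    cells = _cells_df(grid, [400.0])
    assoc = [site("civic_association", 10, 10, type="religious"),
             site("civic_association", 20, 20, type="religious")]
    out = civic_ratio(cells, grid, assoc)
    assert out.loc[0, "civic_religious"] == pytest.approx(0.5)
    assert out.loc[0, "civic_political"] == 0.0


def test_civic_ratio_scaling_and_empty():
    grid = Grid(0, 0, 250, 1, 1)
    assoc = [site("civic_association", 10, 10, type="volunteer")]
    r1 = civic_ratio(_cells_df(grid, [400.0]), grid, assoc).loc[0, "civic_volunteer"]
    r2 = civic_ratio(_cells_df(grid, [800.0]), grid, assoc).loc[0, "civic_volunteer"]
    assert r1 == pytest.approx(2 * r2)
    r0 = civic_ratio(_cells_df(grid, [0.0]), grid, assoc)
    assert np.isnan(r0.loc[0, "civic_volunteer"])


def test_school_index_rules():
    anchor = np.array([[0.0, 0.0]])
    assert school_index(anchor, [])[0] == 0.0
    schools = [
        site("school", 100, 0, level="primary_middle", grading="ZEP"),
        site("school", 0, 200, level="secondary", grading="other"),
    ]
    assert school_index(anchor, schools)[0] == pytest.approx(1.0 + 3.0)
    flat = AccessibilityParams(school_weights={"ZEP": 1.0, "AR": 1.0, "other": 1.0})
    assert school_index(anchor, schools, flat)[0] == 2.0


def test_indicators_translation_invariant(rng):
    """Shifting the whole configuration leaves every indicator unchanged."""
    shift = np.array([1000.0, -500.0])
    anchors = rng.uniform(0, 500, size=(5, 2))
    stops = [site("bus_stop", x, y, lines=2) for x, y in rng.uniform(0, 500, size=(4, 2))]
    parks = [park(x, y, 3e4) for x, y in rng.uniform(0, 500, size=(2, 2))]
    outlets = [site("retail", x, y, category="food", floor_space=50.0)
               for x, y in rng.uniform(0, 500, size=(3, 2))]

    def shifted(sites):
        out = []
        for s in sites:
            g = type(s.geometry)
            from shapely.affinity import translate

            out.append(AmenitySite(s.id, s.layer, translate(s.geometry, *shift), s.attributes))
        return out

    assert np.allclose(
        transit_availability(anchors, stops),
        transit_availability(anchors + shift, shifted(stops)),
    )
    assert np.allclose(
        park_attractiveness(anchors, parks),
        park_attractiveness(anchors + shift, shifted(parks)),
    )
    assert np.allclose(
        retail_score(anchors, outlets).to_numpy(),
        retail_score(anchors + shift, shifted(outlets)).to_numpy(),
    )
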