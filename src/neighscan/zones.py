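"""Automated zone design: aggregate contiguous inhabited cells into
synthetic neighbourhoods of ~2000 inhabitants by simulated annealing.

The optimiser re-implements the classical automated-zoning procedure:
an initial seeded region-growing partition is improved by boundary-cell
moves, accepted by the Metropolis rule under geometric cooling, against
a weighted objective combining

* population targeting   ``sum_z ((pop_z - target)/target)^2``
* within-zone homogeneity ``1 - IAC`` (ANOVA intraclass correlation of
  the numeric NDI score grouped by zone; > 0.5 is the conventional bar
  for a very reasonable degree of homogeneity)
* shape compactness      ``mean P2A`` (isoperimetric quotient
  ``perimeter^2 / (4 pi area)``; 1 for a disc, larger = less compact)

Contiguity is 4-adjacency (diagonal neighbours are not contiguous),
which avoids string-of-pearls zones; every accepted move preserves the
partition invariants.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

from .config import PROFILE_LABELS, ZoneDesignParams
from .grid import Grid

logger = logging.getLogger(__name__)

#: numeric coding of the NDI labels for homogeneity computations
NDI_NUMERIC = {lab: i + 1 for i, lab in enumerate(PROFILE_LABELS)}


@dataclass
class Zone:
    id: int
    cell_ids: list[int]
    population: float
    profile_counts: dict[str, int]
    centroid: Point
    perimeter: float
    area: float
    polygon: Polygon | None = None


@dataclass
class ZoneQuality:
    iac: float
    mean_p2a: float
    pop_rms: float  # RMS relative deviation of zone populations from target


def ndi_numeric(labels: pd.Series) -> pd.Series:
    """Map profile labels A..E onto the ordinal scores 1..5."""
    return labels.map(NDI_NUMERIC).astype(float)


# ---------------------------------------------------------------------------
# quality measures


def iac(zone_labels: np.ndarray, scores: np.ndarray, method: str = "icc") -> float:
    """Intra-area correlation of ``scores`` grouped by zone.

    ``method="icc"`` is the one-way random-effects ANOVA intraclass
    correlation ``(MSB - MSW) / (MSB + (nbar - 1) MSW)`` with ``nbar``
    the mean zone size; ``method="eta2"`` the between/total variance
    share. Identical scores everywhere give 0 (0/0 case) with a warning.
    """
    zone_labels = np.asarray(zone_labels)
    scores = np.asarray(scores, float)
    zones = np.unique(zone_labels)
    n, k = len(scores), len(zones)
    if k < 2 or n < 2:
        raise ValueError("need >= 2 zones and >= 2 cells")
    if np.ptp(scores) == 0:
        warnings.warn("all scores identical: IAC defined as 0")
        return 0.0
    grand = scores.mean()
    ssb = ssw = 0.0
    for z in zones:
        s = scores[zone_labels == z]
        ssb += len(s) * (s.mean() - grand) ** 2
        ssw += ((s - s.mean()) ** 2).sum()
    msb = ssb / (k - 1)
    msw = ssw / (n - k) if n > k else 0.0
    if method == "eta2":
        return float(ssb / (ssb + ssw))
    nbar = n / k
    denom = msb + (nbar - 1) * msw
    return float((msb - msw) / denom) if denom > 0 else 0.0


def p2a(polygon: Polygon) -> float:
    """Isoperimetric compactness score of a polygon (disc = 1)."""
    if polygon.area <= 0:
        raise ValueError("zone has zero area")
    return polygon.length**2 / (4.0 * math.pi * polygon.area)


def p2a_cells(n_cells: int, boundary_edges: int, cell_size: float) -> float:
    """P2A of a union of grid cells from its cell and boundary-edge counts."""
    if n_cells <= 0:
        raise ValueError("zone has zero area")
    perim = boundary_edges * cell_size
    area = n_cells * cell_size**2
    return perim**2 / (4.0 * math.pi * area)


# ---------------------------------------------------------------------------
# lattice bookkeeping


class _Lattice:
    """Adjacency and per-zone running statistics for the annealer."""

    def __init__(self, cells: pd.DataFrame, cell_size: float):
        self.idx = cells.index.to_numpy()
        self.rc = list(zip(cells["row"].astype(int), cells["col"].astype(int)))
        self.pop = cells["population"].to_numpy(float)
        self.score = cells["ndi_score"].to_numpy(float)
        self.cell_size = cell_size
        pos = {rc: i for i, rc in enumerate(self.rc)}
        self.neigh: list[list[int]] = []
        for r, c in self.rc:
            self.neigh.append(
                [pos[rc] for rc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)) if rc in pos]
            )

    def components(self) -> list[list[int]]:
        seen = np.zeros(len(self.rc), bool)
        comps = []
        for start in range(len(self.rc)):
            if seen[start]:
                continue
            comp, queue = [], deque([start])
            seen[start] = True
            while queue:
                i = queue.popleft()
                comp.append(i)
                for j in self.neigh[i]:
                    if not seen[j]:
                        seen[j] = True
                        queue.append(j)
            comps.append(comp)
        return comps


def _zone_boundary_edges(lat: _Lattice, labels: np.ndarray, zone: int) -> int:
    """Number of unit boundary edges of one zone (grid-exterior edges count)."""
    edges = 0
    for i in np.flatnonzero(labels == zone):
        same = sum(1 for j in lat.neigh[i] if labels[j] == zone)
        # off-lattice sides (uninhabited or outside) are boundary too
        edges += 4 - same
    return edges


# ---------------------------------------------------------------------------
# initial partition


def initial_partition(
    cells: pd.DataFrame, target_pop: float, seed: int = 0, cell_size: float = 250.0
) -> np.ndarray:
    """Seeded region growing over the inhabited-cell lattice.

    Random seed cells grow by attaching adjacent unassigned cells until
    the population target is reached; undersized leftovers are merged
    into an adjacent zone. Returns an integer zone label per cell (in
    ``cells`` row order). Deterministic for a fixed seed.
    """
    lat = _Lattice(_with_score(cells), cell_size)
    rng = np.random.default_rng(seed)
    n = len(lat.pop)
    labels = np.full(n, -1)
    if lat.pop.sum() < target_pop:
        warnings.warn("total population below target: producing a single zone")
    zid = 0
    for comp in lat.components():
        unassigned = set(comp)
        while unassigned:
            seed_cell = int(rng.choice(sorted(unassigned)))
            members = [seed_cell]
            labels[seed_cell] = zid
            unassigned.discard(seed_cell)
            pop = lat.pop[seed_cell]
            while pop < target_pop:
                frontier = sorted(
                    {j for i in members for j in lat.neigh[i] if j in unassigned}
                )
                if not frontier:
                    break
                nxt = int(rng.choice(frontier))
                members.append(nxt)
                labels[nxt] = zid
                unassigned.discard(nxt)
                pop += lat.pop[nxt]
            zid += 1

    # merge undersized zones into an adjacent zone (smallest-population one)
    changed = True
    while changed:
        changed = False
        pops = pd.Series(lat.pop).groupby(labels).sum()
        for z in pops.index[pops < 0.5 * target_pop]:
            nbrs = {
                int(labels[j])
                for i in np.flatnonzero(labels == z)
                for j in lat.neigh[i]
                if labels[j] != z
            }
            if not nbrs:
                continue
            tgt = min(nbrs, key=lambda q: (pops.get(q, np.inf), q))
            labels[labels == z] = tgt
            changed = True
            break
    # compact zone ids
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def _with_score(cells: pd.DataFrame) -> pd.DataFrame:
    if "ndi_score" in cells.columns:
        return cells
    out = cells.copy()
    if "profile" in cells.columns:
        out["ndi_score"] = ndi_numeric(cells["profile"])
    else:
        out["ndi_score"] = 0.0
    return out


# ---------------------------------------------------------------------------
# simulated annealing


def _energy(
    lat: _Lattice, labels: np.ndarray, params: ZoneDesignParams
) -> tuple[float, ZoneQuality]:
    zones = np.unique(labels)
    pops = np.array([lat.pop[labels == z].sum() for z in zones])
    pop_term = float((((pops - params.target_pop) / params.target_pop) ** 2).sum())
    if len(zones) >= 2 and np.ptp(lat.score) > 0:
        h = iac(labels, lat.score)
    else:
        h = 0.0
    p2as = [
        p2a_cells(int((labels == z).sum()), _zone_boundary_edges(lat, labels, z), lat.cell_size)
        for z in zones
    ]
    mean_p2a = float(np.mean(p2as))
    e = params.w_pop * pop_term + params.w_homog * (1.0 - h) + params.w_shape * mean_p2a
    pop_rms = float(np.sqrt((((pops - params.target_pop) / params.target_pop) ** 2).mean()))
    return e, ZoneQuality(h, mean_p2a, pop_rms)


def _donor_stays_connected(lat: _Lattice, labels: np.ndarray, cell: int, zone: int) -> bool:
    members = [i for i in np.flatnonzero(labels == zone) if i != cell]
    if not members:
        return False
    member_set = set(members)
    queue = deque([members[0]])
    seen = {members[0]}
    while queue:
        i = queue.popleft()
        for j in lat.neigh[i]:
            if j in member_set and j not in seen:
                seen.add(j)
                queue.append(j)
    return len(seen) == len(members)


def anneal(
    cells: pd.DataFrame,
    labels: np.ndarray,
    params: ZoneDesignParams,
    cell_size: float = 250.0,
    trace_every: int = 200,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Improve a zone partition by simulated annealing.

    Moves reassign a boundary cell to an adjacent zone when both zones
    stay contiguous and non-empty; acceptance follows the Metropolis
    rule ``exp(-dE/T)`` under geometric cooling from ``params.t0``.
    Returns the best-ever labelling and a quality trace (iteration,
    energy, IAC, mean P2A, population RMS deviation).
    """
    lat = _Lattice(_with_score(cells), cell_size)
    labels = np.asarray(labels).copy()
    rng = np.random.default_rng(params.seed)
    n = len(labels)
    zone_ids = np.unique(labels)
    k = len(zone_ids)
    zmax = int(labels.max()) + 1

    # per-zone running aggregates (indexed by zone id)
    pop_z = np.zeros(zmax)
    n_z = np.zeros(zmax, int)
    sum_z = np.zeros(zmax)
    ssq_z = np.zeros(zmax)
    edges_z = np.zeros(zmax, int)
    for z in zone_ids:
        m = labels == z
        pop_z[z] = lat.pop[m].sum()
        n_z[z] = int(m.sum())
        sum_z[z] = lat.score[m].sum()
        ssq_z[z] = (lat.score[m] ** 2).sum()
        edges_z[z] = _zone_boundary_edges(lat, labels, z)

    grand = lat.score.sum()
    score_varies = bool(np.ptp(lat.score) > 0) and k >= 2 and n > k
    target = params.target_pop

    def _p2a_z(z: int) -> float:
        return p2a_cells(int(n_z[z]), int(edges_z[z]), lat.cell_size)

    # scalar accumulators (only the two touched zones change per move)
    pop_pen = float((((pop_z[zone_ids] - target) / target) ** 2).sum())
    ssb_acc = float((sum_z[zone_ids] ** 2 / n_z[zone_ids]).sum())
    ssw_acc = float((ssq_z[zone_ids] - sum_z[zone_ids] ** 2 / n_z[zone_ids]).sum())
    p2a_acc = float(sum(_p2a_z(z) for z in zone_ids))

    def _iac_now() -> float:
        if not score_varies:
            return 0.0
        ssb = ssb_acc - grand**2 / n
        msb = ssb / (k - 1)
        msw = ssw_acc / (n - k)
        denom = msb + (n / k - 1) * msw
        return (msb - msw) / denom if denom > 0 else 0.0

    def _energy_now() -> float:
        return (
            params.w_pop * pop_pen
            + params.w_homog * (1.0 - _iac_now())
            + params.w_shape * (p2a_acc / k)
        )

    def _pop_rms_now() -> float:
        return float(np.sqrt((((pop_z[zone_ids] - target) / target) ** 2).mean()))

    cur_e = _energy_now()
    best_e, best_labels = cur_e, labels.copy()
    trace = [(0, cur_e, _iac_now(), p2a_acc / k, _pop_rms_now())]

    t = params.t0
    stale_pool = 0
    for it in range(1, params.iterations + 1):
        # sample a boundary cell with a neighbouring foreign zone
        cell = int(rng.integers(n))
        foreign = [j for j in lat.neigh[cell] if labels[j] != labels[cell]]
        if not foreign:
            stale_pool += 1
            if stale_pool > 50 * n:
                logger.info("move pool empty; terminating annealing at iteration %d", it)
                break
            t *= params.decay
            continue
        stale_pool = 0
        b = int(labels[int(rng.choice(foreign))])
        a = int(labels[cell])
        if n_z[a] <= 1 or not _donor_stays_connected(lat, labels, cell, a):
            t *= params.decay
            continue

        nb_a = sum(1 for j in lat.neigh[cell] if labels[j] == a)
        nb_b = sum(1 for j in lat.neigh[cell] if labels[j] == b)
        p, y = lat.pop[cell], lat.score[cell]

        # stash the touched entries for cheap revert
        old = (pop_z[a], n_z[a], sum_z[a], ssq_z[a], edges_z[a],
               pop_z[b], n_z[b], sum_z[b], ssq_z[b], edges_z[b],
               pop_pen, ssb_acc, ssw_acc, p2a_acc)

        pop_pen -= ((pop_z[a] - target) / target) ** 2 + ((pop_z[b] - target) / target) ** 2
        ssb_acc -= sum_z[a] ** 2 / n_z[a] + sum_z[b] ** 2 / n_z[b]
        ssw_acc -= (ssq_z[a] - sum_z[a] ** 2 / n_z[a]) + (ssq_z[b] - sum_z[b] ** 2 / n_z[b])
        p2a_acc -= _p2a_z(a) + _p2a_z(b)

        pop_z[a] -= p; n_z[a] -= 1; sum_z[a] -= y; ssq_z[a] -= y * y
        edges_z[a] += 2 * nb_a - 4
        pop_z[b] += p; n_z[b] += 1; sum_z[b] += y; ssq_z[b] += y * y
        edges_z[b] += 4 - 2 * nb_b

        pop_pen += ((pop_z[a] - target) / target) ** 2 + ((pop_z[b] - target) / target) ** 2
        ssb_acc += sum_z[a] ** 2 / n_z[a] + sum_z[b] ** 2 / n_z[b]
        ssw_acc += (ssq_z[a] - sum_z[a] ** 2 / n_z[a]) + (ssq_z[b] - sum_z[b] ** 2 / n_z[b])
        p2a_acc += _p2a_z(a) + _p2a_z(b)

        new_e = _energy_now()
        de = new_e - cur_e
        if de < 0 or (t > 0 and rng.uniform() < math.exp(-de / t)):
            labels[cell] = b
            cur_e = new_e
            if cur_e < best_e:
                best_e, best_labels = cur_e, labels.copy()
        else:
            (pop_z[a], n_z[a], sum_z[a], ssq_z[a], edges_z[a],
             pop_z[b], n_z[b], sum_z[b], ssq_z[b], edges_z[b],
             pop_pen, ssb_acc, ssw_acc, p2a_acc) = old
        t *= params.decay
        if it % trace_every == 0:
            trace.append((it, cur_e, _iac_now(), p2a_acc / k, _pop_rms_now()))

    trace_df = pd.DataFrame(trace, columns=["iteration", "energy", "iac", "mean_p2a", "pop_rms"])
    return best_labels, trace_df


# ---------------------------------------------------------------------------
# zone objects


def build_zones(
    cells: pd.DataFrame, labels: np.ndarray, grid: Grid | None = None
) -> list[Zone]:
    """Materialise Zone records (with union polygons when a grid is given)."""
    cells = _with_score(cells)
    size = grid.cell_size if grid else 250.0
    lat = _Lattice(cells, size)
    out = []
    for z in np.unique(labels):
        mask = labels == z
        sub = cells[mask]
        pop = float(sub["population"].sum())
        w = sub["population"].to_numpy()
        w = w / w.sum() if w.sum() > 0 else np.full(len(sub), 1.0 / len(sub))
        cx = float((sub["bx"] if "bx" in sub else sub["x"]).to_numpy() @ w)
        cy = float((sub["by"] if "by" in sub else sub["y"]).to_numpy() @ w)
        counts = (
            sub["profile"].value_counts().to_dict() if "profile" in sub.columns else {}
        )
        poly = None
        if grid is not None:
            poly = unary_union(
                [grid.cell_polygon(int(r), int(c)) for r, c in zip(sub["row"], sub["col"])]
            )
        edges = _zone_boundary_edges(lat, labels, z)
        out.append(
            Zone(
                int(z), [int(i) for i in sub.index], pop, counts, Point(cx, cy),
                edges * size, int(mask.sum()) * size**2, poly,
            )
        )
    return out


def quality(cells: pd.DataFrame, labels: np.ndarray, params: ZoneDesignParams,
            cell_size: float = 250.0) -> ZoneQuality:
    """Quality summary (IAC, mean P2A, population RMS) of a partition."""
    lat = _Lattice(_with_score(cells), cell_size)
    _, q = _energy(lat, labels, params)
    return q
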