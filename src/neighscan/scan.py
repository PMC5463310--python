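"""Kulldorff circular spatial scan statistic, Poisson model.

Circular windows of growing radius are centred on every zone centroid;
a window absorbs zones in order of centroid distance until it would
exceed half the population at risk. Each window's observed count c is
compared with its expectation E under the null (crude: population
share; adjusted: indirect age/sex standardization) through the Poisson
log-likelihood ratio

    LLR = c ln(c/E) + (C - c) ln((C - c)/(C - E))

counted only when the window deviates in the scanned direction (c > E
for high-risk scans, c < E for low-risk). Inference conditions on the
total count C: replicate case sets are multinomial over zones with
probabilities E/C, each re-scanned identically, and

    p = (1 + #{replicate max LLR >= observed LLR}) / (n_reps + 1)

so with 999 replications the smallest attainable p is 0.001. Secondary
clusters are reported in decreasing LLR among windows sharing no zone
with a better-ranked reported cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import STRATA


@dataclass
class ScanCluster:
    centre_zone: int
    radius: float
    zone_ids: list[int]
    population: float
    expected: float
    observed: float
    rr: float
    llr: float
    p_value: float | None
    direction: str
    rank: int


@dataclass
class ScanComparison:
    crude: list["ScanCluster"]
    adjusted: list["ScanCluster"]
    overlap_jaccard: float = 0.0
    crude_llr: float = float("nan")
    adjusted_llr: float = float("nan")


# ---------------------------------------------------------------------------
# expected counts


def expected_counts(zones: pd.DataFrame, adjust: str = "none") -> np.ndarray:
    """Per-zone expected case counts under the null.

    ``adjust="none"``: E_i = N_i C / N (population share of the total
    count). ``adjust="age_sex"``: indirect standardization
    E_i = sum_s N_is (C_s / N_s) over the sex x age-band strata.
    Both modes conserve sum(E) = C exactly.
    """
    if adjust == "none":
        pop = zones["population"].to_numpy(float)
        c_tot = float(zones["cases"].sum())
        n_tot = pop.sum()
        if n_tot <= 0:
            raise ValueError("zero total population")
        return pop * c_tot / n_tot
    if adjust != "age_sex":
        raise ValueError(f"unknown adjustment {adjust!r}")
    e = np.zeros(len(zones))
    for s in STRATA:
        pop_s = zones[f"pop_{s}"].to_numpy(float)
        cases_s = zones[f"cases_{s}"].to_numpy(float)
        n_s = pop_s.sum()
        c_s = cases_s.sum()
        if n_s <= 0:
            if c_s > 0:
                raise ValueError(f"stratum {s} has cases but no population")
            continue
        e += pop_s * c_s / n_s
    return e


# ---------------------------------------------------------------------------
# likelihood ratio


def poisson_llr(
    c: float, e: float, c_total: float, direction: str = "high"
) -> float:
    """Poisson scan log-likelihood ratio for one window.

    Zero unless the window deviates in the scanned direction; the
    0 ln 0 = 0 convention applies at c = 0 and c = C.
    """
    if not 0 < e < c_total:
        raise ValueError("require 0 < E < C")
    if not 0 <= c <= c_total:
        raise ValueError("require 0 <= c <= C")
    if direction == "high" and c <= e:
        return 0.0
    if direction == "low" and c >= e:
        return 0.0
    inside = c * math.log(c / e) if c > 0 else 0.0
    rest = c_total - c
    outside = rest * math.log(rest / (c_total - e)) if rest > 0 else 0.0
    return inside + outside


def _llr_array(c: np.ndarray, e: np.ndarray, c_total: float, direction: str) -> np.ndarray:
    """Vectorized in-direction LLR (the workhorse of the Monte Carlo loop)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inside = np.where(c > 0, c * np.log(c / e), 0.0)
        rest = c_total - c
        outside = np.where(rest > 0, rest * np.log(rest / (c_total - e)), 0.0)
    llr = inside + outside
    mask = (c > e) if direction == "high" else (c < e)
    return np.where(mask, llr, 0.0)


def relative_risk(c: float, e: float, c_total: float) -> float:
    """Window relative risk: (c/E) / ((C-c)/(C-E))."""
    if c >= c_total:
        return math.inf
    return (c / e) / ((c_total - c) / (c_total - e))


# ---------------------------------------------------------------------------
# window geometry


def enumerate_windows(
    zones: pd.DataFrame, max_pop_frac: float = 0.5
) -> list[tuple[int, tuple[int, ...]]]:
    """All distinct circular windows: for each centre zone, the nested
    prefixes (by centroid distance, ties by zone id) whose cumulative
    population stays within ``max_pop_frac`` of the total. Duplicate
    member sets are removed (keeping the first encountered)."""
    if len(zones) < 2:
        raise ValueError("need at least 2 zones")
    order, n_win = _window_structure(zones, max_pop_frac)
    ids = zones.index.to_numpy()
    seen: set[frozenset] = set()
    out = []
    for row, kmax in enumerate(n_win):
        for size in range(1, kmax + 1):
            members = tuple(int(ids[j]) for j in order[row, :size])
            key = frozenset(members)
            if key not in seen:
                seen.add(key)
                out.append((int(ids[row]), members))
    return out


def _window_structure(
    zones: pd.DataFrame, max_pop_frac: float
) -> tuple[np.ndarray, np.ndarray]:
    """Distance-sorted zone order per centre and max window size per centre.

    ``order[i]`` lists zone positions by distance from centre i (ties by
    zone id); ``n_win[i]`` is the largest prefix whose cumulative
    population <= max_pop_frac * N.
    """
    xy = zones[["x", "y"]].to_numpy(float)
    pop = zones["population"].to_numpy(float)
    n = len(zones)
    d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
    # lexsort: primary key distance, secondary zone position (deterministic ties)
    order = np.empty((n, n), int)
    for i in range(n):
        order[i] = np.lexsort((np.arange(n), d[i]))
    cum = np.cumsum(pop[order], axis=1)
    cap = max_pop_frac * pop.sum()
    n_win = (cum <= cap).sum(axis=1)
    # a window always contains at least its centre zone
    np.maximum(n_win, 1, out=n_win)
    return order, n_win


# ---------------------------------------------------------------------------
# the scan


def _observed_windows(
    cases: np.ndarray,
    e: np.ndarray,
    order: np.ndarray,
    n_win: np.ndarray,
    direction: str,
) -> np.ndarray:
    """LLR of every (centre, size) window; invalid sizes are -inf."""
    c_total = float(cases.sum())
    cum_c = np.cumsum(cases[order], axis=1)
    cum_e = np.cumsum(e[order], axis=1)
    llr = _llr_array(cum_c, cum_e, c_total, direction)
    n = order.shape[0]
    invalid = np.arange(n)[None, :] >= n_win[:, None]
    llr[invalid] = -np.inf
    return llr


def scan(
    zones: pd.DataFrame,
    direction: str = "high",
    n_reps: int = 999,
    adjust: str = "none",
    max_pop_frac: float = 0.5,
    seed: int = 0,
    max_reported: int = 5,
) -> list[ScanCluster]:
    """Run the circular Poisson scan over a zone table.

    ``zones`` needs columns ``x, y, population, cases`` (indexed by zone
    id) and, for ``adjust="age_sex"``, the per-stratum ``pop_<s>`` /
    ``cases_<s>`` columns. ``n_reps=0`` skips Monte Carlo inference
    (p-values are None). Replicates are drawn conditional on the total
    count as multinomial with probabilities E/C, under the same
    adjustment as the observed analysis.
    """
    if direction not in ("high", "low"):
        raise ValueError("direction must be 'high' or 'low'")
    cases = zones["cases"].to_numpy(float)
    c_total = float(cases.sum())
    if c_total <= 0:
        raise ValueError("no cases to scan")
    e = expected_counts(zones, adjust)
    order, n_win = _window_structure(zones, max_pop_frac)

    llr = _observed_windows(cases, e, order, n_win, direction)

    # greedy non-overlapping cluster reporting in decreasing LLR
    flat = np.argsort(llr, axis=None)[::-1]
    n = len(zones)
    ids = zones.index.to_numpy()
    xy = zones[["x", "y"]].to_numpy(float)
    pop = zones["population"].to_numpy(float)
    used: set[int] = set()
    picked: list[tuple[int, int, float]] = []
    for f in flat:
        i, size_ix = divmod(int(f), n)
        val = llr[i, size_ix]
        if not np.isfinite(val) or val <= 0:
            break
        members = order[i, : size_ix + 1]
        if used.intersection(members):
            continue
        used.update(int(m) for m in members)
        picked.append((i, size_ix, float(val)))
        if len(picked) >= max_reported:
            break

    # Monte Carlo null distribution of the max LLR
    rep_max = None
    if n_reps > 0:
        rng = np.random.default_rng(seed)
        probs = e / e.sum()
        rep_max = np.empty(n_reps)
        for r in range(n_reps):
            sim = rng.multinomial(int(round(c_total)), probs).astype(float)
            sim_llr = _observed_windows(sim, e, order, n_win, direction)
            rep_max[r] = sim_llr.max()

    clusters = []
    for rank, (i, size_ix, val) in enumerate(picked, start=1):
        members = order[i, : size_ix + 1]
        c_in = float(cases[members].sum())
        e_in = float(e[members].sum())
        radius = float(
            np.hypot(xy[members, 0] - xy[i, 0], xy[members, 1] - xy[i, 1]).max()
        )
        p = None
        if rep_max is not None:
            p = float((1 + int((rep_max >= val).sum())) / (n_reps + 1))
        clusters.append(
            ScanCluster(
                centre_zone=int(ids[i]),
                radius=radius,
                zone_ids=[int(ids[m]) for m in members],
                population=float(pop[members].sum()),
                expected=e_in,
                observed=c_in,
                rr=relative_risk(c_in, e_in, c_total),
                llr=val,
                p_value=p,
                direction=direction,
                rank=rank,
            )
        )
    return clusters


def compare_crude_adjusted(
    zones: pd.DataFrame,
    direction: str = "high",
    n_reps: int = 999,
    max_pop_frac: float = 0.5,
    seed: int = 0,
) -> ScanComparison:
    """Two-stage analysis: crude scan, then age/sex-adjusted scan.

    Reports both most-likely clusters, their LLRs and the Jaccard
    overlap of their zone sets. With homogeneous stratum rates the two
    expected-count vectors coincide and so do the clusters.
    """
    crude = scan(zones, direction, n_reps, "none", max_pop_frac, seed)
    adjusted = scan(zones, direction, n_reps, "age_sex", max_pop_frac, seed)
    jac = 0.0
    c_llr = a_llr = float("nan")
    if crude and adjusted:
        a, b = set(crude[0].zone_ids), set(adjusted[0].zone_ids)
        jac = len(a & b) / len(a | b)
        c_llr, a_llr = crude[0].llr, adjusted[0].llr
    return ScanComparison(crude, adjusted, jac, c_llr, a_llr)


# ---------------------------------------------------------------------------
# zone-table assembly


def block_scan_table(blocks, cases: pd.DataFrame, years: int = 1) -> pd.DataFrame:
    """Scan table with one zone per census block (~2000 inhabitants each).

    Census blocks already sit at the areal scale the scan expects, so
    they can serve directly as scan zones when the zone-design stage is
    not part of the analysis. Cases are attributed by their ``block_id``.
    ``years`` is kept on ``attrs`` for rate work; the scan itself only
    uses counts and populations.
    """
    rows = {}
    for b in blocks:
        c = b.polygon.centroid
        row = {"x": c.x, "y": c.y, "population": float(b.population), "cases": 0.0}
        for s in STRATA:
            row[f"pop_{s}"] = float(b.strata.get(s, 0))
            row[f"cases_{s}"] = 0.0
        rows[b.id] = row
    for _, case in cases.iterrows():
        bid = int(case["block_id"])
        if bid not in rows:
            continue
        rows[bid]["cases"] += 1
        s = f"{case['sex']}_{str(case['age_band']).replace('-', '_')}"
        key = f"cases_{s}"
        if key in rows[bid]:
            rows[bid][key] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "zone_id"
    df.attrs["years"] = years
    return df


def scan_input_from_zones(
    zone_list,
    cells: pd.DataFrame,
    cases: pd.DataFrame,
    grid,
) -> pd.DataFrame:
    """Aggregate cell populations and geocoded cases into a scan table.

    Each case is assigned to the zone owning the grid cell containing
    its location; zone centroids are the population-weighted built
    centroids. Returns the ``x, y, population, cases`` (+ per-stratum)
    table :func:`scan` expects, indexed by zone id.
    """
    cell_to_zone: dict[int, int] = {}
    for z in zone_list:
        for cid in z.cell_ids:
            cell_to_zone[cid] = z.id

    rows = {}
    for z in zone_list:
        sub = cells.loc[[c for c in z.cell_ids if c in cells.index]]
        row = {
            "x": z.centroid.x,
            "y": z.centroid.y,
            "population": float(sub["population"].sum()),
            "cases": 0.0,
        }
        for s in STRATA:
            row[f"pop_{s}"] = float(sub[f"pop_{s}"].sum()) if f"pop_{s}" in sub else 0.0
            row[f"cases_{s}"] = 0.0
        rows[z.id] = row

    dropped = 0
    for _, case in cases.iterrows():
        cid = grid.cell_of_point(case["x"], case["y"])
        zid = cell_to_zone.get(cid)
        if zid is None:
            dropped += 1
            continue
        s = f"{case['sex']}_{str(case['age_band']).replace('-', '_')}"
        rows[zid]["cases"] += 1
        key = f"cases_{s}"
        if key in rows[zid]:
            rows[zid][key] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "zone_id"
    df.attrs["dropped_cases"] = dropped
    return df
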