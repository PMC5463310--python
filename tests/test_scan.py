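"""Poisson scan statistic: expected counts, LLR, window enumeration,
exhaustive-oracle equivalence and the crude/adjusted comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from neighscan.config import STRATA
from neighscan.scan import (
    compare_crude_adjusted,
    enumerate_windows,
    expected_counts,
    poisson_llr,
    relative_risk,
    scan,
)


def zone_table(xy, pop, cases):
    df = pd.DataFrame(
        {"x": np.asarray(xy)[:, 0], "y": np.asarray(xy)[:, 1],
         "population": pop, "cases": cases}
    )
    df.index.name = "zone_id"
    return df


def stratified_table(xy, pop_strata, cases_strata):
    """pop_strata/cases_strata: dict stratum -> array over zones."""
    n = len(xy)
    df = zone_table(
        xy,
        np.sum([pop_strata[s] for s in STRATA], axis=0),
        np.sum([cases_strata[s] for s in STRATA], axis=0),
    )
    for s in STRATA:
        df[f"pop_{s}"] = np.asarray(pop_strata[s], float)
        df[f"cases_{s}"] = np.asarray(cases_strata[s], float)
    return df


# ---------------------------------------------------------------------------
# expected counts


def test_expected_counts_one_stratum_collapse():
    pop = {s: np.zeros(3) for s in STRATA}
    cas = {s: np.zeros(3) for s in STRATA}
    pop["m_55_74"] = np.array([1000.0, 2000.0, 3000.0])
    cas["m_55_74"] = np.array([5.0, 10.0, 9.0])
    df = stratified_table([[0, 0], [1, 0], [2, 0]], pop, cas)
    crude = expected_counts(df, "none")
    adj = expected_counts(df, "age_sex")
    assert np.allclose(crude, adj)


def test_expected_counts_standardization_oracle():
    """Two zones, two active strata, counts chosen so crude and adjusted
    expectations differ; adjusted values follow the 2x2 indirect
    standardization computed by hand."""
    pop = {s: np.zeros(2) for s in STRATA}
    cas = {s: np.zeros(2) for s in STRATA}
    pop["m_35_54"] = np.array([900.0, 100.0])   # zone 1 young-heavy
    pop["m_55_74"] = np.array([100.0, 900.0])   # zone 2 old-heavy
    cas["m_35_54"] = np.array([9.0, 1.0])       # young rate 10/1000
    cas["m_55_74"] = np.array([4.0, 36.0])      # old rate 40/1000
    df = stratified_table([[0, 0], [1, 0]], pop, cas)

    crude = expected_counts(df, "none")
    adj = expected_counts(df, "age_sex")
    # hand: E1 = 900*(10/1000) + 100*(40/1000) = 13 ; E2 = 1 + 36 = 37
    assert adj == pytest.approx([13.0, 37.0])
    assert crude == pytest.approx([25.0, 25.0])
    assert adj.sum() == pytest.approx(df["cases"].sum(), abs=1e-9)
    assert crude.sum() == pytest.approx(df["cases"].sum(), abs=1e-9)


def test_expected_counts_empty_stratum_with_cases_errors():
    pop = {s: np.zeros(2) for s in STRATA}
    cas = {s: np.zeros(2) for s in STRATA}
    pop["m_55_74"] = np.array([100.0, 100.0])
    cas["f_35_54"] = np.array([1.0, 0.0])  # cases in an unpopulated stratum
    df = stratified_table([[0, 0], [1, 0]], pop, cas)
    with pytest.raises(ValueError, match="stratum"):
        expected_counts(df, "age_sex")


# ---------------------------------------------------------------------------
# LLR and RR (printed worked examples from the study's cluster table)


def solved_total(c=205.0, e=125.68, rr=1.70) -> float:
    """Total case count implied by the printed RR of the high-risk row."""
    return brentq(lambda C: (c / e) / ((C - c) / (C - e)) - rr, 300.0, 1e7)


def test_llr_zero_at_null():
    assert poisson_llr(50.0, 50.0, 500.0, "high") == 0.0
    assert poisson_llr(50.0, 50.0, 500.0, "low") == 0.0


def test_llr_high_risk_worked_example():
    """c=205 observed vs E=125.68 expected at the implied total reproduces
    the published log-likelihood ratio 22.56."""
    C = solved_total()
    assert C == pytest.approx(2083, abs=2)
    llr = poisson_llr(205.0, 125.68, C, "high")
    assert llr == pytest.approx(22.56, abs=0.15)


def test_llr_low_risk_worked_example():
    """c=2 vs E=54.91 at the same total reproduces the published 46.95."""
    C = solved_total()
    llr = poisson_llr(2.0, 54.91, C, "low")
    assert llr == pytest.approx(46.95, abs=0.15)


def test_llr_direction_gating():
    C = 1000.0
    assert poisson_llr(80.0, 50.0, C, "low") == 0.0
    assert poisson_llr(20.0, 50.0, C, "high") == 0.0
    assert poisson_llr(80.0, 50.0, C, "high") > 0.0
    assert poisson_llr(20.0, 50.0, C, "low") > 0.0


def test_llr_extremes_zero_convention():
    assert np.isfinite(poisson_llr(0.0, 10.0, 100.0, "low"))
    assert np.isfinite(poisson_llr(100.0, 10.0, 100.0, "high"))


def test_llr_invalid_inputs():
    with pytest.raises(ValueError):
        poisson_llr(5.0, 0.0, 100.0)
    with pytest.raises(ValueError):
        poisson_llr(5.0, 100.0, 100.0)
    with pytest.raises(ValueError):
        poisson_llr(101.0, 10.0, 100.0)


@given(st.integers(min_value=51, max_value=499))
def test_llr_monotone_in_c_above_e(c):
    """Holding E and C fixed, the high-direction LLR increases with c."""
    e, C = 50.0, 500.0
    assert poisson_llr(c + 1, e, C, "high") > poisson_llr(c, e, C, "high")


def test_relative_risk_values():
    C = solved_total()
    assert relative_risk(205.0, 125.68, C) == pytest.approx(1.70, abs=0.005)
    assert relative_risk(50.0, 50.0, 500.0) == pytest.approx(1.0)
    assert relative_risk(0.0, 10.0, 100.0) == 0.0
    assert relative_risk(100.0, 10.0, 100.0) == math.inf


# ---------------------------------------------------------------------------
# window enumeration


def test_two_equal_zones_only_singletons():
    df = zone_table([[0, 0], [1000, 0]], [2000.0, 2000.0], [3.0, 4.0])
    wins = enumerate_windows(df, max_pop_frac=0.5)
    assert sorted(w[1] for w in wins) == [(0,), (1,)]


def test_full_fraction_covers_all():
    df = zone_table([[0, 0], [500, 0], [1200, 0]], [1000.0] * 3, [1.0] * 3)
    wins = enumerate_windows(df, max_pop_frac=1.0)
    assert max(len(w[1]) for w in wins) == 3


def test_windows_match_bruteforce(rng):
    """On <= 10 zones the enumeration equals the exhaustive set of distinct
    centroid-circles under the population cap."""
    n = 10
    xy = rng.uniform(0, 3000, size=(n, 2))
    pop = rng.uniform(500, 1500, n)
    df = zone_table(xy, pop, np.ones(n))
    cap = 0.5 * pop.sum()

    expected = set()
    for i in range(n):
        d = np.hypot(xy[:, 0] - xy[i, 0], xy[:, 1] - xy[i, 1])
        order = np.lexsort((np.arange(n), d))
        cum = 0.0
        members = []
        for j in order:
            cum += pop[j]
            if cum > cap and members:
                break
            if cum > cap:
                members.append(int(j))  # centre always included
                break
            members.append(int(j))
            expected.add(frozenset(members))
    got = {frozenset(w[1]) for w in enumerate_windows(df, 0.5)}
    assert got == expected


# ---------------------------------------------------------------------------
# the scan itself


def test_scan_max_llr_matches_exhaustive_oracle(rng):
    """Observed max LLR equals a from-scratch evaluation of the scalar LLR
    over every enumerated window (30 zones)."""
    n = 30
    xy = rng.uniform(0, 5000, size=(n, 2))
    pop = rng.uniform(1000, 3000, n)
    cases = rng.poisson(8, n).astype(float)
    cases[0] += 30  # make a hotspot
    df = zone_table(xy, pop, cases)

    for direction in ("high", "low"):
        res = scan(df, direction, n_reps=0)
        e = expected_counts(df, "none")
        C = cases.sum()
        best = 0.0
        for _, members in enumerate_windows(df, 0.5):
            m = list(members)
            best = max(best, poisson_llr(cases[m].sum(), e[m].sum(), C, direction))
        assert res[0].llr == pytest.approx(best, rel=1e-12)


def test_scan_reported_clusters_disjoint(rng):
    n = 25
    df = zone_table(rng.uniform(0, 5000, size=(n, 2)),
                    rng.uniform(1000, 3000, n), rng.poisson(10, n).astype(float))
    res = scan(df, "high", n_reps=0)
    seen = set()
    for c in res:
        assert not seen.intersection(c.zone_ids)
        seen.update(c.zone_ids)
        assert c.population <= 0.5 * df["population"].sum() + 1e-9
        assert c.llr >= 0


def test_scan_pvalue_grid(rng):
    """With 99 replicates the p-values live on the grid {1/100 .. 1}."""
    n = 15
    df = zone_table(rng.uniform(0, 4000, size=(n, 2)),
                    rng.uniform(1000, 2000, n), rng.poisson(6, n).astype(float))
    res = scan(df, "high", n_reps=99, seed=5)
    for c in res:
        assert 0 < c.p_value <= 1
        assert round(c.p_value * 100, 9) == int(round(c.p_value * 100))


def test_scan_deterministic(rng):
    n = 12
    df = zone_table(rng.uniform(0, 4000, size=(n, 2)),
                    rng.uniform(1000, 2000, n), rng.poisson(6, n).astype(float))
    a = scan(df, "high", n_reps=99, seed=3)
    b = scan(df, "high", n_reps=99, seed=3)
    assert [(c.llr, c.p_value, tuple(c.zone_ids)) for c in a] == \
           [(c.llr, c.p_value, tuple(c.zone_ids)) for c in b]


def test_scan_no_cases_errors():
    df = zone_table([[0, 0], [1, 1]], [100.0, 100.0], [0.0, 0.0])
    with pytest.raises(ValueError):
        scan(df, "high")


# ---------------------------------------------------------------------------
# crude vs adjusted


def test_compare_identical_stratum_rates():
    """When every stratum has the same rate pattern across zones, crude and
    adjusted scans coincide exactly."""
    n = 6
    xy = [[i * 500.0, 0.0] for i in range(n)]
    base_pop = np.array([1000.0, 1200, 900, 1100, 1000, 950])
    base_cases = np.array([4.0, 5, 30, 4, 5, 4])
    pop = {s: base_pop / 4 for s in STRATA}
    cas = {s: base_cases / 4 for s in STRATA}
    df = stratified_table(xy, pop, cas)
    cmp = compare_crude_adjusted(df, "high", n_reps=0)
    assert cmp.overlap_jaccard == 1.0
    assert cmp.crude_llr == pytest.approx(cmp.adjusted_llr, rel=1e-12)


def test_confounded_city_adjustment_shrinks_llr():
    """If the apparent hotspot is an area enriched in a high-rate stratum,
    age/sex adjustment absorbs part of the excess: adjusted LLR < crude."""
    n = 8
    xy = [[i * 500.0, 0.0] for i in range(n)]
    pop = {s: np.full(n, 250.0) for s in STRATA}
    # zone 0 is strongly old-male-heavy; rates differ by stratum only
    pop["m_55_74"] = np.array([1600.0] + [250.0] * (n - 1))
    pop["f_35_54"] = np.array([100.0] + [250.0] * (n - 1))
    rate = {"f_35_54": 0.002, "f_55_74": 0.01, "m_35_54": 0.01, "m_55_74": 0.03}
    cas = {s: np.round(pop[s] * rate[s]) for s in STRATA}
    df = stratified_table(xy, pop, cas)
    cmp = compare_crude_adjusted(df, "high", n_reps=0)
    assert cmp.adjusted_llr < cmp.crude_llr
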