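"""Age/sex-standardized event rates by contextual profile, profile
comparisons, and cluster-vs-profile cross-tabulation.

Rates are annual events per 100,000 inhabitants. Standardization is
direct: stratum-specific rates weighted by a reference population's
stratum shares (default reference = the whole study area). Confidence
intervals use the normal approximation on the weighted-Poisson
variance. Denominators are mid-period population x years observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import STRATA


@dataclass
class StandardizedRate:
    rate: float      # annual events per 100,000
    lo: float
    hi: float
    crude: float
    events: float
    denom: float     # person-years


def standardized_rate(
    events: dict[str, float],
    denom: dict[str, float],
    reference: dict[str, float],
    alpha: float = 0.05,
) -> StandardizedRate:
    """Directly standardized annual rate per 100,000 with a normal CI.

    ``events``/``denom`` are per-stratum event counts and person-year
    denominators for the group; ``reference`` gives the reference
    population sizes whose shares weight the stratum rates. Strata with
    zero denominator but non-zero events raise; zero-denominator strata
    with zero reference weight are skipped.
    """
    w_tot = sum(reference.get(s, 0.0) for s in STRATA)
    if w_tot <= 0:
        raise ValueError("empty reference population")
    rate = var = 0.0
    tot_ev = tot_den = 0.0
    for s in STRATA:
        w = reference.get(s, 0.0) / w_tot
        ev = events.get(s, 0.0)
        den = denom.get(s, 0.0)
        tot_ev += ev
        tot_den += den
        if den <= 0:
            if ev > 0:
                raise ValueError(f"stratum {s} has events but zero denominator")
            continue
        r_s = ev / den
        rate += w * r_s
        var += (w / den) ** 2 * ev  # Poisson variance of the weighted rate
    z = stats.norm.ppf(1 - alpha / 2)
    scale = 1e5
    lo = max(0.0, (rate - z * np.sqrt(var)) * scale)
    hi = (rate + z * np.sqrt(var)) * scale
    crude = tot_ev / tot_den * scale if tot_den > 0 else np.nan
    return StandardizedRate(rate * scale, lo, hi, crude, tot_ev, tot_den)


def rates_by_profile(
    zones: pd.DataFrame,
    profile_of_zone: pd.Series,
    years: int,
    reference: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Standardized annual rate per 100,000 for each contextual profile.

    ``zones`` is the scan-style table with per-stratum ``pop_<s>`` and
    ``cases_<s>`` columns; ``profile_of_zone`` maps zone id -> profile
    label. The default reference is the whole study population.
    """
    if reference is None:
        reference = {s: float(zones[f"pop_{s}"].sum()) for s in STRATA}
    out = {}
    for prof, sub in zones.groupby(profile_of_zone, observed=True):
        ev = {s: float(sub[f"cases_{s}"].sum()) for s in STRATA}
        den = {s: float(sub[f"pop_{s}"].sum()) * years for s in STRATA}
        r = standardized_rate(ev, den, reference)
        out[str(prof)] = {
            "rate": r.rate, "ci_lo": r.lo, "ci_hi": r.hi,
            "crude": r.crude, "events": r.events, "person_years": r.denom,
        }
    return pd.DataFrame(out).T.rename_axis("profile")


def compare_profiles(table: pd.DataFrame) -> tuple[float, float]:
    """Chi-square homogeneity test of event counts across profiles.

    Expected counts are proportional to person-year denominators
    (columns ``events`` and ``person_years`` as produced by
    :func:`rates_by_profile`). Returns (statistic, p).
    """
    if len(table) < 2:
        raise ValueError("need >= 2 profiles")
    obs = table["events"].to_numpy(float)
    den = table["person_years"].to_numpy(float)
    exp = obs.sum() * den / den.sum()
    if (exp <= 0).any():
        raise ValueError("zero expected count in some profile")
    stat = float(((obs - exp) ** 2 / exp).sum())
    p = float(stats.chi2.sf(stat, df=len(obs) - 1))
    return stat, p


def cluster_profile_crosstab(
    zones: pd.DataFrame,
    high_cluster_zones: list[int],
    low_cluster_zones: list[int],
    profile_of_zone: pd.Series,
    binary_features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Contrast the high- and low-risk clusters' populations.

    Rows: each profile label (percent of cluster population in that
    profile) and each optional binary neighbourhood feature (percent of
    cluster population for which it holds), with a chi-square p per row
    (2x2 on population counts). Percentages are population-weighted.
    """
    if not high_cluster_zones or not low_cluster_zones:
        raise ValueError("empty cluster")
    hi = zones.loc[high_cluster_zones]
    lo = zones.loc[low_cluster_zones]
    n_hi = float(hi["population"].sum())
    n_lo = float(lo["population"].sum())

    def _row(in_hi: float, in_lo: float) -> tuple[float, float, float]:
        tbl = np.array([[in_hi, n_hi - in_hi], [in_lo, n_lo - in_lo]])
        tbl = np.maximum(tbl, 0.0)
        if tbl.sum() == 0 or (tbl.sum(axis=0) == 0).any() or (tbl.sum(axis=1) == 0).any():
            return 100 * in_hi / n_hi, 100 * in_lo / n_lo, np.nan
        chi2, p, _, _ = stats.chi2_contingency(tbl, correction=False)
        return 100 * in_hi / n_hi, 100 * in_lo / n_lo, float(p)

    rows = {}
    prof = profile_of_zone
    for lab in sorted(prof.unique()):
        in_hi = float(hi.loc[prof.reindex(hi.index) == lab, "population"].sum())
        in_lo = float(lo.loc[prof.reindex(lo.index) == lab, "population"].sum())
        rows[f"profile_{lab}"] = _row(in_hi, in_lo)
    if binary_features is not None:
        for feat in binary_features.columns:
            f = binary_features[feat].astype(bool)
            in_hi = float(hi.loc[f.reindex(hi.index).fillna(False), "population"].sum())
            in_lo = float(lo.loc[f.reindex(lo.index).fillna(False), "population"].sum())
            rows[feat] = _row(in_hi, in_lo)
    return pd.DataFrame(
        rows, index=["pct_high_cluster", "pct_low_cluster", "p_value"]
    ).T.rename_axis("characteristic")
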