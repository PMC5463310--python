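"""Multiple Factor Analysis and Ward clustering into contextual profiles.

MFA balances several groups of variables (socioeconomic, public
resources, psychosocial) in one global PCA: each group is first analysed
separately (PCA for quantitative groups, MCA-style scaling for
qualitative ones) and its variables are divided by the square root of
the group's first eigenvalue, so every group's leading dimension carries
unit inertia and no group dominates by size alone. A plain PCA of the
weighted matrix then yields the global components (Escofier-Pages
weighting).

The retained component scores (default 10, preserving most of the
variability) feed a hierarchical agglomerative clustering with Ward's
minimum-variance criterion, cut into k classes (default 5). Classes are
relabelled A (least deprived) to E (most deprived) by a composite
deprivation score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .config import PROFILE_LABELS

#: variables entering the composite deprivation score used to order labels
DEPRIVATION_SCORE_VARS = ("unemployment_rate", "pct_precarious_jobs", "pct_safety_net")


@dataclass(frozen=True)
class VariableGroup:
    name: str
    variables: tuple[str, ...]
    kind: str  # "quantitative" | "qualitative"

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "qualitative"):
            raise ValueError(f"unknown group kind {self.kind!r}")
        if not self.variables:
            raise ValueError(f"group {self.name!r} has no variables")


@dataclass
class MfaResult:
    eigenvalues: np.ndarray            # all positive eigenvalues of the global PCA
    explained: np.ndarray              # percent of total inertia, non-increasing
    scores: pd.DataFrame               # retained component scores per observation
    group_first_eigenvalues: dict[str, float]
    loadings: pd.DataFrame             # weighted-column loadings (V) per component
    column_groups: pd.Series           # weighted-matrix column -> group name


@dataclass
class NdiPartition:
    labels: pd.Series                  # per-observation profile label A..E
    linkage: np.ndarray                # scipy linkage matrix
    heights: np.ndarray                # merge heights (non-decreasing)
    k: int


# ---------------------------------------------------------------------------
# group preprocessing


def _top_eigenvalue(z: np.ndarray) -> float:
    n = len(z)
    s = np.linalg.svd(z, compute_uv=False)
    return float(s[0] ** 2 / n) if len(s) else 0.0


def _quantitative_block(df: pd.DataFrame, group: VariableGroup) -> tuple[np.ndarray, list[str]]:
    cols = []
    names = []
    for v in group.variables:
        x = df[v].to_numpy(float)
        sd = x.std()
        if sd == 0:
            warnings.warn(f"constant variable {v!r} dropped from group {group.name!r}")
            continue
        cols.append((x - x.mean()) / sd)
        names.append(v)
    if not cols:
        raise ValueError(f"group {group.name!r} has no non-constant variable")
    return np.column_stack(cols), names


def _qualitative_block(df: pd.DataFrame, group: VariableGroup) -> tuple[np.ndarray, list[str]]:
    q = len(group.variables)
    cols = []
    names = []
    for v in group.variables:
        levels = pd.unique(df[v].astype(str))
        if len(levels) < 2:
            raise ValueError(f"qualitative variable {v!r} has a single level")
        for lev in sorted(levels):
            ind = (df[v].astype(str) == lev).to_numpy(float)
            p = ind.mean()
            # correspondence-analysis scaling of the centred indicator
            cols.append((ind - p) / np.sqrt(q * p))
            names.append(f"{v}={lev}")
    return np.column_stack(cols), names


def mfa(
    df: pd.DataFrame, groups: list[VariableGroup], n_components: int = 10
) -> MfaResult:
    """Multiple Factor Analysis of ``df`` over the given variable groups.

    ``df`` must be complete (impute or drop missing rows upstream).
    Returns scores on the retained components, eigenvalues and the
    percentage of inertia explained per component (non-increasing).
    """
    if df.isna().any().any():
        raise ValueError("MFA input contains missing values; impute or drop upstream")
    n_vars = sum(len(g.variables) for g in groups)
    if n_vars < 2:
        raise ValueError("MFA needs at least 2 variables")

    blocks: list[np.ndarray] = []
    names: list[str] = []
    col_groups: list[str] = []
    group_l1: dict[str, float] = {}
    for g in groups:
        z, block_names = (
            _quantitative_block(df, g) if g.kind == "quantitative" else _qualitative_block(df, g)
        )
        l1 = _top_eigenvalue(z)
        if l1 <= 0:
            raise ValueError(f"group {g.name!r} has zero inertia")
        group_l1[g.name] = l1
        blocks.append(z / np.sqrt(l1))
        names.extend(block_names)
        col_groups.extend([g.name] * len(block_names))

    w = np.hstack(blocks)
    n = len(w)
    u, s, vt = np.linalg.svd(w, full_matrices=False)
    pos = s > 1e-12 * s[0]
    u, s, vt = u[:, pos], s[pos], vt[pos]
    eig = s**2 / n
    explained = 100.0 * eig / eig.sum()
    m = min(n_components, len(eig))
    scores = pd.DataFrame(
        u[:, :m] * s[:m], index=df.index, columns=[f"F{i+1}" for i in range(m)]
    )
    loadings = pd.DataFrame(vt.T, index=names, columns=[f"F{i+1}" for i in range(len(eig))])
    return MfaResult(eig, explained, scores, group_l1, loadings, pd.Series(col_groups, index=names))


def group_contributions(result: MfaResult, component: int = 1) -> pd.Series:
    """Share of a component's inertia contributed by each variable group."""
    col = f"F{component}"
    v = result.loadings[col] ** 2
    contrib = v.groupby(result.column_groups).sum()
    return contrib / contrib.sum()


# ---------------------------------------------------------------------------
# Ward clustering and labelling


def composite_deprivation(df: pd.DataFrame, variables=DEPRIVATION_SCORE_VARS) -> pd.Series:
    """Composite deprivation score: sum of standardized deprivation-facing
    variables (higher = more deprived). Used only to *order* class labels."""
    parts = []
    for v in variables:
        if v in df.columns:
            x = df[v].astype(float)
            sd = x.std(ddof=0)
            parts.append((x - x.mean()) / (sd if sd > 0 else 1.0))
    if not parts:
        raise ValueError("no deprivation variables available for label ordering")
    return sum(parts)


def ward_hac(
    scores: pd.DataFrame, k: int = 5, deprivation: pd.Series | None = None
) -> NdiPartition:
    """Agglomerative clustering of MFA scores with Ward's criterion.

    Cuts the dendrogram into ``k`` non-empty classes and labels them
    A -> E by ascending mean composite deprivation (alphabetical order
    of cluster id when no deprivation score is supplied).
    """
    x = scores.to_numpy(float)
    if not np.isfinite(x).all():
        raise ValueError("scores must be finite")
    n = len(x)
    if k > n:
        raise ValueError(f"k={k} > {n} observations")
    z = linkage(x, method="ward")
    raw = fcluster(z, t=k, criterion="maxclust")

    clusters = np.unique(raw)
    if deprivation is not None:
        dep = deprivation.reindex(scores.index).to_numpy(float)
        order = sorted(clusters, key=lambda c: float(np.nanmean(dep[raw == c])))
    else:
        order = list(clusters)
    if len(clusters) <= len(PROFILE_LABELS):
        name_of = {c: PROFILE_LABELS[i] for i, c in enumerate(order)}
    else:
        name_of = {c: f"P{i+1}" for i, c in enumerate(order)}
    labels = pd.Series([name_of[c] for c in raw], index=scores.index, name="profile")
    return NdiPartition(labels, z, z[:, 2].copy(), k)


def profile_table(
    df: pd.DataFrame,
    labels: pd.Series,
    quantitative: list[str] | None = None,
    qualitative: list[str] | None = None,
) -> pd.DataFrame:
    """Per-class description: mean of each quantitative variable, modal
    level of each qualitative variable (classes as columns)."""
    labels = labels.reindex(df.index)
    if labels.isna().any():
        raise ValueError("labels missing for some observations")
    quantitative = quantitative if quantitative is not None else [
        c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])
    ]
    qualitative = qualitative or []
    out: dict[str, dict] = {}
    for cls, sub in df.groupby(labels, observed=True):
        if len(sub) == 0:
            raise ValueError(f"empty class {cls!r}")
        col: dict[str, object] = {}
        for v in quantitative:
            col[v] = float(sub[v].mean())
        for v in qualitative:
            col[v] = sub[v].mode().iloc[0]
        out[str(cls)] = col
    return pd.DataFrame(out)
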