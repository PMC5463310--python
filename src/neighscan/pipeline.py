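"""Config-driven pipeline: generate -> grid -> indicators -> profiles ->
zones -> rates -> scan, with a reproducible artefact manifest.

Each stage reads its inputs from the output directory (so partial runs
resume from existing artefacts), logs parameters and row counts, and
records SHA-256 digests of inputs and outputs in ``manifest.json``.
One seed in the config fans out to the stochastic stages via fixed
offsets, so re-running any stage subset is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram

from . import accessibility, io, rates, synthetic, zones
from . import mfa as mfa_mod
from . import scan as scan_mod
from .config import (
    PROFILE_LABELS,
    STRATA,
    ZONE_PRESETS,
    AccessibilityParams,
    CityConfig,
    ZoneDesignParams,
    config_digest,
    read_config,
    write_config,
)
from .grid import Grid, assemble_cells, zone_clip
from .synthetic import SOCIO_VARIABLES

logger = logging.getLogger(__name__)

STAGES = ("generate", "grid", "indicators", "profiles", "zones", "rates", "scan")

#: stage -> (producing stage of each required artefact)
_DEPS: dict[str, dict[str, str]] = {
    "generate": {},
    "grid": {"blocks.geojson": "generate", "buildings.geojson": "generate"},
    "indicators": {"cells.csv": "grid", "amenities.geojson": "generate"},
    "profiles": {"cells.csv": "grid", "indicators.csv": "indicators"},
    "zones": {"cells.csv": "grid", "partition.csv": "profiles"},
    "rates": {"zone_table.csv": "zones"},
    "scan": {"zone_table.csv": "zones", "zones.csv": "zones"},
}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _check_inputs(stage: str, outdir: Path) -> None:
    for fname, producer in _DEPS[stage].items():
        if not (outdir / fname).exists():
            raise FileNotFoundError(
                f"stage {stage!r} needs {fname!r}; run stage {producer!r} first"
            )


# ---------------------------------------------------------------------------
# stages


def stage_generate(cfg: CityConfig, outdir: Path) -> list[Path]:
    blocks, buildings, amenities = synthetic.generate_city(cfg)
    cases = synthetic.simulate_cases(blocks, cfg, buildings, seed=cfg.seed + 1)
    io.write_blocks(outdir / "blocks.geojson", blocks)
    io.write_buildings(outdir / "buildings.geojson", buildings)
    io.write_amenities(outdir / "amenities.geojson", amenities)
    io.write_cases(outdir / "cases.csv", cases)
    write_config(cfg, outdir / "config.txt")
    logger.info(
        "generate: %d blocks, %d buildings, %d amenities, %d cases",
        len(blocks), len(buildings), len(amenities), len(cases),
    )
    return [outdir / f for f in
            ("blocks.geojson", "buildings.geojson", "amenities.geojson", "cases.csv", "config.txt")]


def stage_grid(cfg: CityConfig, outdir: Path) -> list[Path]:
    blocks = io.read_blocks(outdir / "blocks.geojson")
    buildings = io.read_buildings(outdir / "buildings.geojson")
    grid = Grid.from_extent(cfg.extent, cfg.cell_size)
    weights = zone_clip(blocks, grid, buildings)
    cells = assemble_cells(grid, blocks, buildings, weights)
    cells.to_csv(outdir / "cells.csv")
    logger.info(
        "grid: %d cells (%d inhabited), cell size %.0f m",
        len(cells), int(cells["inhabited"].sum()), cfg.cell_size,
    )
    return [outdir / "cells.csv"]


def _load_cells(cfg: CityConfig, outdir: Path) -> tuple[Grid, pd.DataFrame]:
    grid = Grid.from_extent(cfg.extent, cfg.cell_size)
    cells = pd.read_csv(outdir / "cells.csv", index_col="cell_id")
    return grid, cells


def stage_indicators(cfg: CityConfig, outdir: Path) -> list[Path]:
    grid, cells = _load_cells(cfg, outdir)
    amenities = io.read_amenities(outdir / "amenities.geojson")
    graph = synthetic.street_graph(cfg)
    ind = accessibility.build_indicators(cells, grid, amenities, graph, AccessibilityParams())
    ind.to_csv(outdir / "indicators.csv")
    logger.info("indicators: %d cells x %d indicators", *ind.shape)
    return [outdir / "indicators.csv"]


def _mfa_input(cells: pd.DataFrame, ind: pd.DataFrame) -> tuple[pd.DataFrame, list[mfa_mod.VariableGroup]]:
    """Assemble the MFA table on inhabited cells with the three groups.

    Psychosocial indicators are re-expressed as ordered quintile
    categories (very_low .. very_high) so the analysis exercises the
    qualitative (MCA) branch the way mixed contextual data would.
    """
    inhabited = cells[cells["inhabited"]]
    df = inhabited.join(ind, how="left")

    socio_vars = [v for v in SOCIO_VARIABLES if v in df.columns]
    resource_vars = [
        v for v in ("dist_healthcare", "dist_sports", "park_index", "transit_index")
        if v in df.columns and not df[v].isna().all()
    ]
    levels = ["very_low", "low", "medium", "high", "very_high"]
    psy_src = {
        "retail_level": df[[c for c in df.columns if c.startswith("retail_")]].sum(axis=1),
        "civic_level": df[[c for c in df.columns if c.startswith("civic_")]].sum(axis=1),
        "school_level": df["school_index"],
    }
    psy_vars = []
    for name, series in psy_src.items():
        df[name] = pd.qcut(series.rank(method="first"), 5, labels=levels).astype(str)
        psy_vars.append(name)

    use = socio_vars + resource_vars + psy_vars
    n_missing = int(df[use].isna().any(axis=1).sum())
    if n_missing:
        logger.info("imputing %d cells with missing indicator values (column median)", n_missing)
        for v in socio_vars + resource_vars:
            df[v] = df[v].fillna(df[v].median())
    groups = [
        mfa_mod.VariableGroup("socioeconomic", tuple(socio_vars), "quantitative"),
        mfa_mod.VariableGroup("public_resources", tuple(resource_vars), "quantitative"),
        mfa_mod.VariableGroup("psychosocial", tuple(psy_vars), "qualitative"),
    ]
    groups = [g for g in groups if g.variables]
    return df, groups


def stage_profiles(cfg: CityConfig, outdir: Path, k: int = 5, n_components: int = 10) -> list[Path]:
    _, cells = _load_cells(cfg, outdir)
    ind = pd.read_csv(outdir / "indicators.csv", index_col="cell_id")
    df, groups = _mfa_input(cells, ind)
    res = mfa_mod.mfa(df, groups, n_components=n_components)
    dep = mfa_mod.composite_deprivation(df)
    part = mfa_mod.ward_hac(res.scores, k=k, deprivation=dep)

    res.scores.to_csv(outdir / "scores.csv")
    part.labels.rename("profile").to_frame().to_csv(outdir / "partition.csv")
    quant = [v for g in groups if g.kind == "quantitative" for v in g.variables]
    qual = [v for g in groups if g.kind == "qualitative" for v in g.variables]
    mfa_mod.profile_table(df, part.labels, quant, qual).to_csv(outdir / "profile_table.csv")

    fig, ax = plt.subplots(figsize=(8, 4))
    dendrogram(part.linkage, ax=ax, no_labels=True, color_threshold=0)
    ax.set_ylabel("Ward distance")
    fig.savefig(outdir / "dendrogram.png", dpi=110)
    plt.close(fig)

    explained = ", ".join(f"{e:.1f}" for e in res.explained[:4])
    logger.info("profiles: %d cells, first components explain %s%% of inertia", len(df), explained)
    return [outdir / f for f in ("scores.csv", "partition.csv", "profile_table.csv", "dendrogram.png")]


def stage_zones(cfg: CityConfig, outdir: Path, preset: str = "balanced",
                iterations: int | None = None) -> list[Path]:
    grid, cells = _load_cells(cfg, outdir)
    part = pd.read_csv(outdir / "partition.csv", index_col="cell_id")["profile"]
    inhabited = cells[cells["inhabited"]].copy()
    inhabited["profile"] = part.reindex(inhabited.index)
    inhabited["ndi_score"] = zones.ndi_numeric(inhabited["profile"])

    params = ZoneDesignParams(seed=cfg.seed + 2, **ZONE_PRESETS[preset])
    if iterations is not None:
        params.iterations = iterations
    labels0 = zones.initial_partition(inhabited, params.target_pop, params.seed, cfg.cell_size)
    labels, trace = zones.anneal(inhabited, labels0, params, cfg.cell_size)
    zone_list = zones.build_zones(inhabited, labels, grid)

    cases = io.read_cases(outdir / "cases.csv")
    ztab = scan_mod.scan_input_from_zones(zone_list, inhabited, cases, grid)
    modal = {
        z.id: max(z.profile_counts, key=z.profile_counts.get) if z.profile_counts else "?"
        for z in zone_list
    }
    ztab["profile"] = pd.Series(modal)
    ztab.to_csv(outdir / "zone_table.csv")

    q = zones.quality(inhabited, labels, params, cfg.cell_size)
    zdf = pd.DataFrame(
        {
            "zone_id": [z.id for z in zone_list],
            "n_cells": [len(z.cell_ids) for z in zone_list],
            "population": [z.population for z in zone_list],
            "profile_mode": [modal[z.id] for z in zone_list],
            "p2a": [zones.p2a_cells(len(z.cell_ids), int(round(z.perimeter / cfg.cell_size)), cfg.cell_size)
                    for z in zone_list],
        }
    ).set_index("zone_id")
    zdf.to_csv(outdir / "zones.csv")
    trace.to_csv(outdir / "zone_trace.csv", index=False)
    io.write_geojson(
        outdir / "zones.geojson",
        (
            {"type": "Feature",
             "geometry": io.mapping(z.polygon),
             "properties": {"id": z.id, "population": z.population, "profile": modal[z.id]}}
            for z in zone_list if z.polygon is not None
        ),
    )
    pd.DataFrame(
        {"cell_id": inhabited.index, "zone_id": labels}
    ).to_csv(outdir / "cell_zones.csv", index=False)
    logger.info(
        "zones: %d zones (preset %s), IAC=%.3f, mean P2A=%.2f, pop RMS=%.3f",
        len(zone_list), preset, q.iac, q.mean_p2a, q.pop_rms,
    )
    return [outdir / f for f in
            ("zone_table.csv", "zones.csv", "zones.geojson", "zone_trace.csv", "cell_zones.csv")]


def stage_rates(cfg: CityConfig, outdir: Path) -> list[Path]:
    ztab = pd.read_csv(outdir / "zone_table.csv", index_col="zone_id")
    prof = ztab.pop("profile")
    tbl = rates.rates_by_profile(ztab, prof, years=cfg.years)
    stat, p = rates.compare_profiles(tbl)
    tbl["chi2_stat"] = stat
    tbl["chi2_p"] = p
    tbl.to_csv(outdir / "rates_by_profile.csv")
    logger.info("rates: chi2=%.2f p=%.2g across %d profiles", stat, p, len(tbl))
    return [outdir / "rates_by_profile.csv"]


def stage_scan(cfg: CityConfig, outdir: Path, direction: str = "both",
               n_reps: int = 999, max_pop_frac: float = 0.5, adjust: str = "none") -> list[Path]:
    ztab = pd.read_csv(outdir / "zone_table.csv", index_col="zone_id")
    prof = ztab.pop("profile")
    directions = ["high", "low"] if direction == "both" else [direction]
    all_clusters: list[scan_mod.ScanCluster] = []
    for d in directions:
        all_clusters.extend(
            scan_mod.scan(ztab, d, n_reps=n_reps, adjust=adjust,
                      max_pop_frac=max_pop_frac, seed=cfg.seed + 3)
        )
    rows = [
        {
            "direction": c.direction, "rank": c.rank, "centre_zone": c.centre_zone,
            "radius_m": c.radius, "n_zones": len(c.zone_ids), "population": c.population,
            "expected": c.expected, "observed": c.observed, "rr": c.rr,
            "llr": c.llr, "p_value": c.p_value,
            "zone_ids": ";".join(map(str, c.zone_ids)),
        }
        for c in all_clusters
    ]
    pd.DataFrame(rows).to_csv(outdir / "clusters.csv", index=False)

    hi = [c for c in all_clusters if c.direction == "high"]
    lo = [c for c in all_clusters if c.direction == "low"]
    if hi and lo:
        ct = rates.cluster_profile_crosstab(ztab, hi[0].zone_ids, lo[0].zone_ids, prof)
        ct.to_csv(outdir / "crosstab.csv")
    _plot_maps(cfg, outdir, all_clusters)
    logger.info("scan: %d clusters reported (%s)", len(all_clusters), direction)
    return [outdir / "clusters.csv"]


def _plot_maps(cfg: CityConfig, outdir: Path, clusters: list[scan_mod.ScanCluster]) -> None:
    try:
        cells = pd.read_csv(outdir / "cells.csv", index_col="cell_id")
        part = pd.read_csv(outdir / "partition.csv", index_col="cell_id")["profile"]
    except FileNotFoundError:
        return
    inhabited = cells[cells["inhabited"]]
    colors = dict(zip(PROFILE_LABELS, ["#2c7bb6", "#abd9e9", "#ffffbf", "#fdae61", "#d7191c"]))
    fig, ax = plt.subplots(figsize=(6, 6))
    lab = part.reindex(inhabited.index)
    ax.scatter(inhabited["x"], inhabited["y"],
               c=[colors.get(v, "#999999") for v in lab], s=14, marker="s")
    ax.set_title("Contextual profiles (A least .. E most deprived)")
    ax.set_aspect("equal")
    fig.savefig(outdir / "profiles_map.png", dpi=110)

    ztab = pd.read_csv(outdir / "zone_table.csv", index_col="zone_id")
    for c in clusters:
        if c.rank != 1:
            continue
        col = "red" if c.direction == "high" else "blue"
        cx = ztab.loc[c.centre_zone, "x"]
        cy = ztab.loc[c.centre_zone, "y"]
        ax.add_patch(plt.Circle((cx, cy), max(c.radius, cfg.cell_size / 2),
                                fill=False, color=col, lw=2))
    ax.set_title("Profiles with most-likely high (red) / low (blue) clusters")
    fig.savefig(outdir / "clusters_map.png", dpi=110)
    plt.close(fig)


_STAGE_FN = {
    "generate": stage_generate,
    "grid": stage_grid,
    "indicators": stage_indicators,
    "profiles": stage_profiles,
    "zones": stage_zones,
    "rates": stage_rates,
    "scan": stage_scan,
}


def run_pipeline(
    config_path: str | Path | CityConfig,
    outdir: str | Path,
    stages: list[str] | None = None,
    **stage_kwargs,
) -> dict:
    """Execute the requested stages in dependency order; return the manifest.

    ``stages=None`` runs everything. Missing upstream artefacts raise a
    named error telling which stage to run. The manifest (also written
    to ``manifest.json``) records the config hash, seed, and per-stage
    input/output digests; deterministic stages reproduce identical
    digests under the same config and seed.
    """
    cfg = config_path if isinstance(config_path, CityConfig) else read_config(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    todo = [s for s in STAGES if stages is None or s in stages]
    if stages is not None:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    from importlib.metadata import version as _pkg_version

    try:
        ver = _pkg_version("neighscan")
    except Exception:
        ver = "unknown"
    manifest: dict = {
        "config_hash": config_digest(cfg),
        "seed": cfg.seed,
        "version": ver,
        "stages": [],
    }
    for stage in todo:
        _check_inputs(stage, outdir)
        t0 = time.time()
        inputs = {
            f: _digest(outdir / f) for f in _DEPS[stage] if (outdir / f).exists()
        }
        kwargs = {
            k: v for k, v in stage_kwargs.items()
            if k in _STAGE_FN[stage].__code__.co_varnames
        }
        outputs = _STAGE_FN[stage](cfg, outdir, **kwargs)
        manifest["stages"].append(
            {
                "stage": stage,
                "inputs": inputs,
                "outputs": {p.name: _digest(p) for p in outputs},
                "elapsed_s": round(time.time() - t0, 3),
            }
        )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
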