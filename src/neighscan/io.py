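"""GeoJSON / CSV serialization of the pipeline's spatial artefacts.

GeoJSON is plain JSON; geometries go through
``shapely.geometry.mapping``/``shape``. Coordinates are planar metres, so
files carry no CRS member (consumers treat them as a local metric frame).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from shapely.geometry import mapping, shape

from .synthetic import AmenitySite, Building, CensusBlock


def write_geojson(path: str | Path, features: Iterable[dict]) -> None:
    fc = {"type": "FeatureCollection", "features": list(features)}
    Path(path).write_text(json.dumps(fc))


def read_geojson(path: str | Path) -> list[dict]:
    fc = json.loads(Path(path).read_text())
    return fc["features"]


def _feature(geom, props: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": props}


def write_blocks(path: str | Path, blocks: list[CensusBlock]) -> None:
    feats = []
    for b in blocks:
        props = {"id": b.id, "population": b.population, "deprivation": b.deprivation}
        props.update({f"strata_{k}": v for k, v in b.strata.items()})
        props.update(b.socioeconomic)
        feats.append(_feature(b.polygon, props))
    write_geojson(path, feats)


def read_blocks(path: str | Path) -> list[CensusBlock]:
    blocks = []
    for f in read_geojson(path):
        p = dict(f["properties"])
        strata = {k[len("strata_"):]: int(v) for k, v in p.items() if k.startswith("strata_")}
        socio = {
            k: float(v)
            for k, v in p.items()
            if k not in ("id", "population", "deprivation") and not k.startswith("strata_")
        }
        blocks.append(
            CensusBlock(
                int(p["id"]), shape(f["geometry"]), int(p["population"]),
                strata, socio, float(p.get("deprivation", 0.0)),
            )
        )
    return blocks


def write_buildings(path: str | Path, buildings: list[Building]) -> None:
    write_geojson(
        path,
        (
            _feature(b.footprint, {"id": b.id, "height": b.height, "block_id": b.block_id})
            for b in buildings
        ),
    )


def read_buildings(path: str | Path) -> list[Building]:
    return [
        Building(
            int(f["properties"]["id"]), shape(f["geometry"]),
            float(f["properties"]["height"]), int(f["properties"]["block_id"]),
        )
        for f in read_geojson(path)
    ]


def write_amenities(path: str | Path, sites: list[AmenitySite]) -> None:
    write_geojson(
        path,
        (_feature(s.geometry, {"id": s.id, "layer": s.layer, **s.attributes}) for s in sites),
    )


def read_amenities(path: str | Path) -> list[AmenitySite]:
    sites = []
    for f in read_geojson(path):
        p = dict(f["properties"])
        sid, layer = int(p.pop("id")), str(p.pop("layer"))
        sites.append(AmenitySite(sid, layer, shape(f["geometry"]), p))
    return sites


def write_cases(path: str | Path, cases: pd.DataFrame) -> None:
    cases.to_csv(path, index=False)


def read_cases(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
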