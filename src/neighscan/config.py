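"""Configuration objects shared across the pipeline.

All coordinates are planar metres (the study area is small enough that
projection effects are negligible); all percentage-type socioeconomic
variables live on the 0-100 scale throughout the package; all incidence
rates are annual events per 100,000 inhabitants.

The on-disk configuration format is a flat ``key = value`` text file with
dotted keys for nested fields (see :func:`read_config`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

#: sex x age-band strata used for rates, adjustment and standardization
STRATA: tuple[str, ...] = ("f_35_54", "f_55_74", "m_35_54", "m_55_74")

#: NDI profile labels, least (A) to most (E) deprived
PROFILE_LABELS: tuple[str, ...] = ("A", "B", "C", "D", "E")

#: amenity layers the generator and accessibility module understand
AMENITY_LAYERS: tuple[str, ...] = (
    "park", "bus_stop", "tram_stop", "retail", "school",
    "civic_association", "healthcare", "sports",
)

RETAIL_CATEGORIES: tuple[str, ...] = ("itinerant", "food", "non_food", "services")
ASSOCIATION_TYPES: tuple[str, ...] = ("religious", "political", "volunteer")
SCHOOL_GRADES: tuple[str, ...] = ("ZEP", "AR", "other")


@dataclass(frozen=True)
class PlantedCluster:
    """A circular multiplicative risk field planted in the synthetic city."""

    cx: float
    cy: float
    radius: float
    rr: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("planted cluster radius must be > 0")
        if self.rr <= 0:
            raise ValueError("planted cluster relative risk must be > 0")

    def contains(self, x: float, y: float) -> bool:
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.radius**2


def _default_amenity_intensities() -> dict[str, float]:
    # points (or park polygons) per km^2; loosely urban-French densities
    return {
        "park": 0.8,
        "bus_stop": 8.0,
        "tram_stop": 1.5,
        "retail": 8.0,
        "school": 1.5,
        "civic_association": 4.0,
        "healthcare": 2.0,
        "sports": 1.5,
    }


def _default_amenity_coupling() -> dict[str, float]:
    # log-linear coupling between layer intensity and the deprivation field.
    # Positive = deprived areas better equipped (the empirical pattern in the
    # study area: an inverse relation between deprivation and amenity access).
    return {
        "park": 0.3,
        "bus_stop": 0.5,
        "tram_stop": 0.5,
        "retail": 0.5,
        "school": 0.3,
        "civic_association": 0.5,
        "healthcare": 0.3,
        "sports": 0.5,
    }


def _default_baseline_rates() -> dict[str, float]:
    # annual MI events per 100,000, by sex x age band; male and older strata
    # higher, the canonical incidence pattern
    return {
        "f_35_54": 200.0,
        "f_55_74": 1000.0,
        "m_35_54": 1000.0,
        "m_55_74": 3000.0,
    }


@dataclass
class CityConfig:
    """Parameters of the synthetic metropolitan area generator."""

    seed: int = 0
    width: float = 6000.0
    height: float = 6000.0
    n_blocks: int = 36
    target_block_pop: float = 2000.0
    #: strength of the latent centre-periphery deprivation field (0 = flat)
    gradient_strength: float = 1.0
    #: optional linear tilt (unit vector) added to the radial field
    gradient_ux: float = 0.0
    gradient_uy: float = 0.0
    amenity_intensities: dict[str, float] = field(default_factory=_default_amenity_intensities)
    amenity_coupling: dict[str, float] = field(default_factory=_default_amenity_coupling)
    baseline_rates: dict[str, float] = field(default_factory=_default_baseline_rates)
    planted_clusters: list[PlantedCluster] = field(default_factory=list)
    years: int = 8
    #: "mid_period" (population x years) or "person_years" (identical here;
    #: exposed because register denominator handling varies between studies)
    denominator: str = "mid_period"
    cell_size: float = 250.0
    road_spacing: float = 500.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("extent area must be > 0")
        if self.n_blocks < 2:
            raise ValueError("need at least 2 census blocks")
        if self.years < 1:
            raise ValueError("years must be >= 1")
        for name, v in self.amenity_intensities.items():
            if v < 0:
                raise ValueError(f"amenity intensity {name!r} must be >= 0")
        for name, v in self.baseline_rates.items():
            if v < 0:
                raise ValueError(f"baseline rate {name!r} must be >= 0")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (0.0, 0.0, self.width, self.height)


@dataclass
class ZoneDesignParams:
    """Simulated-annealing zone-design parameters.

    The objective is ``w_pop * sum(((pop_z - target)/target)^2)
    + w_homog * (1 - IAC) + w_shape * mean(P2A)``.
    """

    target_pop: float = 2000.0
    w_pop: float = 1.0
    w_homog: float = 1.0
    w_shape: float = 0.5
    t0: float = 1.0
    decay: float = 0.999
    iterations: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.w_pop, self.w_homog, self.w_shape) < 0:
            raise ValueError("weights must be >= 0")
        if self.w_pop == self.w_homog == self.w_shape == 0:
            raise ValueError("at least one weight must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


#: six shipped weighting presets (population target / homogeneity / shape),
#: echoing the experimental conditions a zone-design study would sweep
ZONE_PRESETS: dict[str, dict[str, float]] = {
    "population": {"w_pop": 1.0, "w_homog": 0.0, "w_shape": 0.0},
    "homogeneity": {"w_pop": 0.1, "w_homog": 1.0, "w_shape": 0.05},
    "shape": {"w_pop": 0.1, "w_homog": 0.0, "w_shape": 1.0},
    "pop_homog": {"w_pop": 0.5, "w_homog": 0.5, "w_shape": 0.0},
    "pop_shape": {"w_pop": 0.5, "w_homog": 0.0, "w_shape": 0.5},
    "balanced": {"w_pop": 1.0, "w_homog": 1.0, "w_shape": 0.5},
}


@dataclass
class AccessibilityParams:
    """Radii, catchments and weights of the amenity indicators (metres)."""

    bus_catchment: float = 300.0
    tram_catchment: float = 400.0
    retail_radius: float = 200.0
    school_radius: float = 500.0
    # socio-educational grading weights; higher = more favourable context
    school_weights: dict[str, float] = field(
        default_factory=lambda: {"ZEP": 1.0, "AR": 2.0, "other": 3.0}
    )
    # park attraction radii by area class (ha thresholds 1 and 10)
    park_radius_small: float = 100.0
    park_radius_medium: float = 500.0
    park_radius_large: float = 1000.0
    park_rule: str = "count"  # count | max | area_weighted


# ---------------------------------------------------------------------------
# flat key=value config file


def _flatten(obj: Any, prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    if isinstance(obj, dict):
        for k, v in obj.items():
            out.update(_flatten(v, f"{prefix}{k}."))
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            out.update(_flatten(v, f"{prefix}{i}."))
        out[f"{prefix}_len"] = len(obj)
    else:
        out[prefix.rstrip(".")] = obj
    return out


def write_config(cfg: CityConfig, path: str | Path) -> None:
    """Serialize a :class:`CityConfig` to a flat ``key = value`` text file."""
    lines = [f"{k} = {v}" for k, v in sorted(_flatten(cfg).items())]
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_scalar(s: str) -> Any:
    s = s.strip()
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s


def read_config(path: str | Path) -> CityConfig:
    """Parse a flat key=value file back into a :class:`CityConfig`."""
    flat: dict[str, Any] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        flat[key.strip()] = _parse_scalar(val)

    kwargs: dict[str, Any] = {}
    dicts: dict[str, dict[str, float]] = {
        "amenity_intensities": {}, "amenity_coupling": {}, "baseline_rates": {},
    }
    clusters: dict[int, dict[str, float]] = {}
    for k, v in flat.items():
        head, _, rest = k.partition(".")
        if head in dicts:
            dicts[head][rest] = float(v)
        elif head == "planted_clusters":
            if rest == "_len":
                continue
            idx, _, fld = rest.partition(".")
            clusters.setdefault(int(idx), {})[fld] = float(v)
        else:
            kwargs[k] = v
    for name, d in dicts.items():
        if d:
            kwargs[name] = d
    kwargs["planted_clusters"] = [
        PlantedCluster(**clusters[i]) for i in sorted(clusters)
    ]
    return CityConfig(**kwargs)


def config_digest(cfg: CityConfig) -> str:
    """Stable hash of a config, used in the run manifest."""
    blob = json.dumps(_flatten(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
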