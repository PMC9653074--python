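"""Synthetic study region with planted socio-spatial structure.

Generates a fully synthetic city — communities, subcommunities with
populations, three concentric urbanity zones, census-style deprivation
indicators, and retailer point patterns — with every planted parameter
known, so the whole exposure/deprivation/statistics pipeline can be
validated by parameter recovery without any external data.

Design of the plant
-------------------
* Communities sit on a jittered lattice over a square extent; urbanity
  (urban_center / urban_area / suburb) is assigned by radial distance
  from the city centre, emulating a ring-road classification.
* The four census indicators are rates in (0, 1) generated as
  inverse-logit of a Gaussian variable whose mean rises (or falls) with
  normalized distance from the centre — a smooth deprivation gradient
  plus noise.
* Retailers of each type are drawn from an inhomogeneous Poisson
  process, simulated exactly by thinning a homogeneous process at the
  maximum intensity. The intensity is piecewise constant over
  nearest-centroid community territories:

      lambda_c = baseline[type][zone_c] * effect[type][zone_c]**((q_c - 1)/4)

  where q_c is the community's deprivation quintile (computed from the
  generated indicators with the same standardisation and ranking rules
  the index stage applies) and ``effect`` is the planted Q5:Q1
  intensity ratio in that zone. Piecewise constancy makes
  :func:`planted_truth` an exact read-through of the configuration.

Default parameter values emulate a large East-Asian megacity retail
environment: availability roughly 6:4:1 across centre/area/suburb,
convenience stores the most common type, an availability gradient that
rises with deprivation in the centre and falls with deprivation
elsewhere, and suburbs more deprived than the centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit

from .deprivation import INDICATORS, assign_quintiles, compute_deprivation

__all__ = [
    "ZONES",
    "RETAILER_TYPES",
    "ALL_TYPES",
    "IndicatorGradient",
    "IntensityParams",
    "SyntheticCityConfig",
    "generate_city",
    "planted_truth",
    "write_city",
    "communities_geojson",
]

ZONES = ("urban_center", "urban_area", "suburb")
RETAILER_TYPES = ("convenience_store", "supermarket", "tobacco_only")
#: analysis-only selector for the pooled retailer set; never stored in data
ALL_TYPES = "all"


class ConfigurationError(ValueError):
    """Invalid synthetic-city configuration."""


@dataclass(frozen=True)
class IndicatorGradient:
    """Logit-scale generator for one census rate indicator.

    rate = expit(intercept + slope * dnorm + Normal(0, noise_sd)) where
    dnorm is distance from the city centre normalized to [0, 1] at the
    extent edge. A positive slope plants higher (more deprived) rates
    further out.
    """

    intercept: float
    slope: float
    noise_sd: float = 1.5


@dataclass(frozen=True)
class IntensityParams:
    """Planted retailer intensity for one retailer type.

    baseline: outlets/km² per urbanity zone (the Q1 intensity).
    deprivation_effect: per-zone Q5:Q1 multiplicative ratio; the
    intensity in quintile q is baseline * effect**((q-1)/4), so
    effect > 1 plants availability rising with deprivation, effect < 1
    falling, effect == 1 no deprivation structure.
    """

    baseline: Mapping[str, float]
    deprivation_effect: Mapping[str, float]

    def intensity(self, zone: str, quintile: int) -> float:
        return float(
            self.baseline[zone] * self.deprivation_effect[zone] ** ((quintile - 1) / 4.0)
        )


def _default_gradients() -> dict[str, IndicatorGradient]:
    # noise dominates the radial trend at the indicator level so that every
    # urbanity zone spans all five city-wide quintiles (as in real cities),
    # while the summed deprivation index still correlates with distance
    return {
        "unemployment_rate": IndicatorGradient(-2.5, 1.0),
        "low_skilled_rate": IndicatorGradient(-0.8, 1.0),
        "low_education_rate": IndicatorGradient(-0.5, 1.2),
        "non_home_ownership_rate": IndicatorGradient(-1.0, 0.8),
    }


def _default_intensities() -> dict[str, IntensityParams]:
    return {
        "convenience_store": IntensityParams(
            baseline={"urban_center": 11.0, "urban_area": 5.7, "suburb": 1.2},
            deprivation_effect={"urban_center": 2.0, "urban_area": 0.7, "suburb": 0.6},
        ),
        "supermarket": IntensityParams(
            baseline={"urban_center": 3.5, "urban_area": 3.1, "suburb": 1.1},
            deprivation_effect={"urban_center": 1.2, "urban_area": 0.7, "suburb": 0.6},
        ),
        "tobacco_only": IntensityParams(
            baseline={"urban_center": 5.0, "urban_area": 2.9, "suburb": 0.3},
            deprivation_effect={"urban_center": 1.6, "urban_area": 0.7, "suburb": 0.4},
        ),
    }


@dataclass(frozen=True)
class SyntheticCityConfig:
    """Full parameterisation of a synthetic city.

    Identical seed + config produce bit-identical output tables.
    """

    seed: int = 0
    extent_m: float = 20_000.0
    ring_radii_m: tuple[float, float] = (4_000.0, 9_000.0)
    n_communities: int = 500
    subcommunities_per_community: tuple[int, int] = (1, 5)
    population_range: tuple[int, int] = (500, 5_000)
    deprivation_gradient: Mapping[str, IndicatorGradient] = field(
        default_factory=_default_gradients
    )
    intensity_params: Mapping[str, IntensityParams] = field(
        default_factory=_default_intensities
    )

    def validate(self) -> None:
        if not self.extent_m > 0:
            raise ConfigurationError(f"extent_m must be > 0, got {self.extent_m}")
        r1, r2 = self.ring_radii_m
        if not (0 < r1 < r2):
            raise ConfigurationError(f"ring_radii_m must be strictly increasing, got {self.ring_radii_m}")
        if r2 >= self.extent_m / 2:
            raise ConfigurationError(
                f"outer ring radius {r2} must be < extent_m/2 = {self.extent_m / 2}"
            )
        lo, hi = self.subcommunities_per_community
        if not (1 <= lo <= hi):
            raise ConfigurationError(f"bad subcommunities_per_community range {lo}-{hi}")
        plo, phi = self.population_range
        if not (0 < plo <= phi):
            raise ConfigurationError(f"populations must be > 0, got range {plo}-{phi}")
        for rtype in RETAILER_TYPES:
            params = self.intensity_params[rtype]
            for zone in ZONES:
                if params.baseline[zone] < 0:
                    raise ConfigurationError(f"negative intensity for {rtype}/{zone}")
                if params.deprivation_effect[zone] <= 0:
                    raise ConfigurationError(f"non-positive deprivation effect for {rtype}/{zone}")

    @property
    def area_km2(self) -> float:
        return (self.extent_m / 1000.0) ** 2

    def zone_of(self, dist_m: np.ndarray) -> np.ndarray:
        """Urbanity class from radial distance to the city centre."""
        r1, r2 = self.ring_radii_m
        zones = np.full(np.shape(dist_m), "suburb", dtype=object)
        zones[np.asarray(dist_m) < r2] = "urban_area"
        zones[np.asarray(dist_m) < r1] = "urban_center"
        return zones


def _community_table(config: SyntheticCityConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_communities
    side = int(math.ceil(math.sqrt(n)))
    cell = config.extent_m / side
    cells = rng.choice(side * side, size=n, replace=False)
    ci, cj = np.divmod(cells, side)
    cx = (cj + rng.uniform(0.05, 0.95, n)) * cell
    cy = (ci + rng.uniform(0.05, 0.95, n)) * cell
    center = config.extent_m / 2.0
    dist = np.hypot(cx - center, cy - center)
    zones = config.zone_of(dist)
    for zone in ZONES:
        if not (zones == zone).any():
            raise ConfigurationError(f"ring {zone!r} contains zero communities")
    dnorm = np.clip(dist / center, 0.0, 1.0)
    df = pd.DataFrame(
        {
            "community_id": [f"C{i:04d}" for i in range(n)],
            "cx_m": cx,
            "cy_m": cy,
            "urbanity": zones.astype(str),
        }
    )
    for name in INDICATORS:
        g = config.deprivation_gradient[name]
        latent = g.intercept + g.slope * dnorm + rng.normal(0.0, g.noise_sd, n)
        df[name] = expit(latent)
    return df


def _subcommunity_table(
    config: SyntheticCityConfig, communities: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    lo, hi = config.subcommunities_per_community
    counts = rng.integers(lo, hi + 1, size=len(communities))
    plo, phi = config.population_range
    side = int(math.ceil(math.sqrt(config.n_communities)))
    jitter_sd = config.extent_m / side / 4.0
    rows = []
    for (_, com), k in zip(communities.iterrows(), counts):
        offsets = rng.normal(0.0, jitter_sd, size=(k, 2))
        pops = rng.integers(plo, phi + 1, size=k)
        for s in range(k):
            rows.append(
                {
                    "id": f"{com['community_id']}-S{s}",
                    "community_id": com["community_id"],
                    "cx_m": float(np.clip(com["cx_m"] + offsets[s, 0], 0, config.extent_m)),
                    "cy_m": float(np.clip(com["cy_m"] + offsets[s, 1], 0, config.extent_m)),
                    "population": int(pops[s]),
                }
            )
    return pd.DataFrame(rows)


def _planted_quintiles(communities: pd.DataFrame) -> np.ndarray:
    """Deprivation quintile of each community, from generated indicators.

    Uses the same standardisation and ranking rules as the index stage,
    so downstream recomputation reproduces the plant exactly.
    """
    indexed = assign_quintiles(compute_deprivation(communities))
    return indexed["deprivation_quintile"].to_numpy()


def _retailer_table(
    config: SyntheticCityConfig, communities: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    quintiles = _planted_quintiles(communities)
    zones = communities["urbanity"].to_numpy()
    tree = cKDTree(communities.loc[:, ["cx_m", "cy_m"]].to_numpy(dtype=float))
    rows = []
    for rtype in RETAILER_TYPES:
        params = config.intensity_params[rtype]
        lam = np.array(
            [params.intensity(z, int(q)) for z, q in zip(zones, quintiles)]
        )
        lam_max = float(lam.max())
        if lam_max == 0.0:
            continue
        n_prop = rng.poisson(lam_max * config.area_km2)
        xy = rng.uniform(0.0, config.extent_m, size=(n_prop, 2))
        u = rng.uniform(0.0, 1.0, size=n_prop)
        if n_prop == 0:
            continue
        _, nearest = tree.query(xy)
        keep = u < lam[nearest] / lam_max
        prefix = {"convenience_store": "CS", "supermarket": "SM", "tobacco_only": "TO"}[rtype]
        for k, (x, y) in enumerate(xy[keep]):
            rows.append(
                {
                    "id": f"{prefix}{k:05d}",
                    "retailer_type": rtype,
                    "x_m": float(x),
                    "y_m": float(y),
                }
            )
    return pd.DataFrame(rows, columns=["id", "retailer_type", "x_m", "y_m"])


def generate_city(
    config: SyntheticCityConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (communities, subcommunities, retailers) tables.

    All randomness flows through one generator seeded from
    ``config.seed``; rerunning with the same config is bit-identical.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    communities = _community_table(config, rng)
    subcommunities = _subcommunity_table(config, communities, rng)
    retailers = _retailer_table(config, communities, rng)
    return communities, subcommunities, retailers


def planted_truth(config: SyntheticCityConfig) -> pd.DataFrame:
    """Exact planted intensity (outlets/km²) per type × zone × quintile.

    Pure read-through of the configuration, including rows for the
    pooled ``"all"`` type; the ground truth that recovered availability
    medians are compared against.
    """
    config.validate()
    rows = []
    for zone in ZONES:
        for q in range(1, 6):
            total = 0.0
            for rtype in RETAILER_TYPES:
                lam = config.intensity_params[rtype].intensity(zone, q)
                rows.append(
                    {"retailer_type": rtype, "urbanity": zone, "quintile": q, "intensity": lam}
                )
                total += lam
            rows.append(
                {"retailer_type": ALL_TYPES, "urbanity": zone, "quintile": q, "intensity": total}
            )
    return pd.DataFrame(rows)


def write_city(
    out_dir: str | Path,
    communities: pd.DataFrame,
    subcommunities: pd.DataFrame,
    retailers: pd.DataFrame,
) -> dict[str, Path]:
    """Write the three tables as UTF-8 CSV; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("communities", communities),
        ("subcommunities", subcommunities),
        ("retailers", retailers),
    ):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def communities_geojson(communities: pd.DataFrame) -> dict:
    """GeoJSON FeatureCollection of community centroids (planar coords)."""
    features = []
    for _, row in communities.iterrows():
        props = {
            k: (row[k] if not isinstance(row[k], np.generic) else row[k].item())
            for k in communities.columns
            if k not in ("cx_m", "cy_m")
        }
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(row["cx_m"]), float(row["cy_m"])]},
                "properties": props,
            }
        )
    return {"type": "FeatureCollection", "features": features}
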