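"""Planted-parameter recovery experiments on synthetic cities.

These experiments validate the full exposure pipeline by simulation:
generate a city with known planted structure, run density →
deprivation → population-weighted aggregation → stratified medians,
and check that the analysis recovers the plant.

Two canonical experiments:

* :func:`urbanity_ordering_recovery` — a 6:4:1 availability plant
  across urban_center : urban_area : suburb with no deprivation
  structure; recovery means the median availability by urbanity is
  strictly ordered centre > area > suburb.
* :func:`deprivation_divergence` — the same zone baselines plus an
  availability–deprivation gradient confined to the urban centre
  (planted Q5:Q1 intensity ratio 6); recovery means the urban-centre
  per-quintile median profile rises monotonically Q1→Q5 while the
  city-wide profile does not, the divergence signature of a
  centre-specific socioeconomic gradient.

The experiment city is deliberately smaller than the generator default
(16 km extent, 350 communities, enlarged centre ring) so that repeated
simulation across many seeds stays cheap while every urbanity zone
still spans all five city-wide deprivation quintiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import run_full_analysis
from .deprivation import assign_quintiles, compute_deprivation
from .exposure import aggregate_tra
from .synthetic import ALL_TYPES, IntensityParams, SyntheticCityConfig, generate_city

__all__ = [
    "recovery_city_config",
    "urbanity_ordering_recovery",
    "deprivation_divergence",
    "DivergenceResult",
]

#: per-type suburb baselines (outlets/km²); zone ratios are 6:4:1
_TYPE_BASELINES = {"convenience_store": 1.2, "supermarket": 0.8, "tobacco_only": 0.5}


def recovery_city_config(
    seed: int, center_deprivation_effect: float = 1.0
) -> SyntheticCityConfig:
    """Experiment city: 6:4:1 zone plant, optional centre-only deprivation effect."""
    intensity = {
        rtype: IntensityParams(
            baseline={"urban_center": 6 * b, "urban_area": 4 * b, "suburb": b},
            deprivation_effect={
                "urban_center": center_deprivation_effect,
                "urban_area": 1.0,
                "suburb": 1.0,
            },
        )
        for rtype, b in _TYPE_BASELINES.items()
    }
    return SyntheticCityConfig(
        seed=seed,
        extent_m=16_000.0,
        ring_radii_m=(5_000.0, 7_000.0),
        n_communities=350,
        intensity_params=intensity,
    )


def _median_tra_by_urbanity(seed: int) -> pd.Series:
    config = recovery_city_config(seed)
    communities, subcommunities, retailers = generate_city(config)
    indexed = assign_quintiles(compute_deprivation(communities))
    exposure = aggregate_tra(subcommunities, retailers=retailers)
    pooled = exposure.loc[exposure["retailer_type"] == ALL_TYPES].merge(
        indexed.loc[:, ["community_id", "urbanity"]], on="community_id"
    )
    return pooled.groupby("urbanity")["tra"].median()


def urbanity_ordering_recovery(n_seeds: int = 100, seed: int = 0) -> int:
    """Number of seeds (out of ``n_seeds``) recovering centre > area > suburb.

    Seeds run from ``seed`` to ``seed + n_seeds - 1``.
    """
    recovered = 0
    for s in range(seed, seed + n_seeds):
        med = _median_tra_by_urbanity(s)
        if med["urban_center"] > med["urban_area"] > med["suburb"]:
            recovered += 1
    return recovered


@dataclass(frozen=True)
class DivergenceResult:
    """Recovered quintile profiles for the centre-confined deprivation plant."""

    center_profile: np.ndarray  # median TRA at Q1..Q5, urban centre
    city_profile: np.ndarray  # median TRA at Q1..Q5, city-wide
    center_monotone_increasing: bool
    city_monotone_increasing: bool


def deprivation_divergence(
    seed: int, center_deprivation_effect: float = 6.0
) -> DivergenceResult:
    """Run the centre-confined deprivation plant and report recovered profiles."""
    config = recovery_city_config(seed, center_deprivation_effect)
    communities, subcommunities, retailers = generate_city(config)
    indexed = assign_quintiles(compute_deprivation(communities))
    exposure = aggregate_tra(subcommunities, retailers=retailers)
    results = run_full_analysis(exposure, indexed, bootstrap_reps=50, seed=seed)
    center = results.quintile_profile("urban_center").to_numpy()
    city = results.quintile_profile("city").to_numpy()
    return DivergenceResult(
        center_profile=center,
        city_profile=city,
        center_monotone_increasing=bool(np.all(np.diff(center) > 0)),
        city_monotone_increasing=bool(np.all(np.diff(city) > 0)),
    )
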