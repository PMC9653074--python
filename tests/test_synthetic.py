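"""Synthetic city generator: determinism, planted structure, Poisson counts."""

import io

import numpy as np
import pandas as pd
import pytest

import tobaccoscape as ts
from tobaccoscape.synthetic import ConfigurationError

from conftest import uniform_intensities


def zero_intensities():
    return {
        rtype: ts.IntensityParams(
            baseline={zone: 0.0 for zone in ts.ZONES},
            deprivation_effect={zone: 1.0 for zone in ts.ZONES},
        )
        for rtype in ts.RETAILER_TYPES
    }


def test_zero_intensity_yields_zero_retailers():
    cfg = ts.SyntheticCityConfig(
        seed=1, extent_m=10_000, ring_radii_m=(2_000, 4_000), n_communities=60,
        intensity_params=zero_intensities(),
    )
    _, _, retailers = ts.generate_city(cfg)
    assert len(retailers) == 0


def test_same_seed_gives_byte_identical_tables(small_city_config):
    def as_bytes():
        frames = ts.generate_city(small_city_config)
        out = []
        for df in frames:
            buf = io.StringIO()
            df.to_csv(buf, index=False)
            out.append(buf.getvalue())
        return out

    assert as_bytes() == as_bytes()


def test_different_seeds_differ(small_city_config):
    import dataclasses

    other = dataclasses.replace(small_city_config, seed=small_city_config.seed + 1)
    _, _, r1 = ts.generate_city(small_city_config)
    _, _, r2 = ts.generate_city(other)
    assert not r1.equals(r2)


def test_poisson_count_oracle():
    """Uniform 10 outlets/km² on 10×10 km: mean count over 200 seeds in 1000 ± 3√1000."""
    counts = []
    for seed in range(200):
        cfg = ts.SyntheticCityConfig(
            seed=seed, extent_m=10_000, ring_radii_m=(2_000, 4_000),
            n_communities=50, intensity_params=uniform_intensities(10.0),
        )
        _, _, retailers = ts.generate_city(cfg)
        counts.append(len(retailers))
    assert abs(np.mean(counts) - 1000.0) < 3 * np.sqrt(1000.0)


def test_urbanity_assignment_by_ring_radius(small_city, small_city_config):
    communities, _, _ = small_city
    center = small_city_config.extent_m / 2
    dist = np.hypot(communities["cx_m"] - center, communities["cy_m"] - center)
    r1, r2 = small_city_config.ring_radii_m
    expected = np.where(dist < r1, "urban_center", np.where(dist < r2, "urban_area", "suburb"))
    assert (communities["urbanity"].to_numpy() == expected).all()


def test_all_outputs_within_extent_and_valid(small_city, small_city_config):
    communities, subcommunities, retailers = small_city
    e = small_city_config.extent_m
    for df, xc, yc in [(communities, "cx_m", "cy_m"), (subcommunities, "cx_m", "cy_m"), (retailers, "x_m", "y_m")]:
        assert df[xc].between(0, e).all() and df[yc].between(0, e).all()
    assert (subcommunities["population"] > 0).all()
    assert set(subcommunities["community_id"]) <= set(communities["community_id"])
    assert set(retailers["retailer_type"]) <= set(ts.RETAILER_TYPES)  # never "all"
    for name in ts.INDICATORS:
        assert communities[name].between(0, 1).all()


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError, match="increasing"):
        ts.SyntheticCityConfig(ring_radii_m=(5_000, 4_000)).validate()
    with pytest.raises(ConfigurationError, match="extent_m/2"):
        ts.SyntheticCityConfig(extent_m=10_000, ring_radii_m=(2_000, 6_000)).validate()
    with pytest.raises(ConfigurationError, match="extent_m"):
        ts.SyntheticCityConfig(extent_m=-5.0).validate()
    with pytest.raises(ConfigurationError, match="populations"):
        ts.SyntheticCityConfig(population_range=(0, 100)).validate()


def test_empty_ring_names_the_ring():
    # a tiny centre ring on a coarse lattice catches no community centroids
    cfg = ts.SyntheticCityConfig(
        seed=2, extent_m=20_000, ring_radii_m=(10.0, 9_000.0), n_communities=20
    )
    with pytest.raises(ConfigurationError, match="urban_center"):
        ts.generate_city(cfg)


def test_planted_truth_uniform_config_equal_strata():
    cfg = ts.SyntheticCityConfig(intensity_params=uniform_intensities(9.0))
    truth = ts.planted_truth(cfg)
    pooled = truth.loc[truth["retailer_type"] == ts.ALL_TYPES, "intensity"]
    assert np.allclose(pooled, 9.0)


def test_planted_truth_reads_through_zone_ratio():
    params = {
        rtype: ts.IntensityParams(
            baseline={"urban_center": 5.0, "urban_area": 2.0, "suburb": 1.0},
            deprivation_effect={z: 1.0 for z in ts.ZONES},
        )
        for rtype in ts.RETAILER_TYPES
    }
    truth = ts.planted_truth(ts.SyntheticCityConfig(intensity_params=params))
    pooled = truth.loc[truth["retailer_type"] == ts.ALL_TYPES].pivot(
        index="quintile", columns="urbanity", values="intensity"
    )
    assert np.allclose(pooled["urban_center"] / pooled["suburb"], 5.0)


def test_planted_truth_monotone_deprivation_multiplier():
    truth = ts.planted_truth(
        ts.SyntheticCityConfig(intensity_params=uniform_intensities(6.0, deprivation_effect=2.5))
    )
    for (_, _), grp in truth.groupby(["retailer_type", "urbanity"]):
        profile = grp.sort_values("quintile")["intensity"].to_numpy()
        assert np.all(np.diff(profile) > 0)


def test_uniform_city_flatter_than_planted_gradient():
    """KDE spatial variation under a uniform plant is below a 5:1 gradient plant."""
    gradient = {
        rtype: ts.IntensityParams(
            baseline={"urban_center": 25.0, "urban_area": 10.0, "suburb": 5.0},
            deprivation_effect={z: 1.0 for z in ts.ZONES},
        )
        for rtype in ts.RETAILER_TYPES
    }
    cvs = {}
    for name, params in [("uniform", uniform_intensities(15.0)), ("gradient", gradient)]:
        cfg = ts.SyntheticCityConfig(
            seed=8, extent_m=10_000, ring_radii_m=(2_000, 4_000),
            n_communities=80, intensity_params=params,
        )
        _, _, retailers = ts.generate_city(cfg)
        q = np.random.default_rng(9).uniform(1_000, 9_000, (100, 2))
        dens = ts.kde_at_points(q, retailers)
        cvs[name] = dens.std() / dens.mean()
    assert cvs["uniform"] < cvs["gradient"]


def test_geojson_export_shape(small_city):
    communities, _, _ = small_city
    geo = ts.communities_geojson(communities)
    assert geo["type"] == "FeatureCollection"
    assert len(geo["features"]) == len(communities)
    feat = geo["features"][0]
    assert feat["geometry"]["type"] == "Point"
    assert "urbanity" in feat["properties"]
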