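import numpy as np
import pandas as pd
import pytest

import tobaccoscape as ts


@pytest.fixture(scope="session")
def small_city_config() -> ts.SyntheticCityConfig:
    """Compact city used across tests: 100 communities on a 10 km extent."""
    return ts.SyntheticCityConfig(
        seed=5, extent_m=10_000.0, ring_radii_m=(2_000.0, 4_000.0), n_communities=100
    )


@pytest.fixture(scope="session")
def small_city(small_city_config):
    communities, subcommunities, retailers = ts.generate_city(small_city_config)
    return communities, subcommunities, retailers


@pytest.fixture(scope="session")
def indexed_small_city(small_city):
    communities, _, _ = small_city
    return ts.assign_quintiles(ts.compute_deprivation(communities))


def uniform_intensities(total_per_km2: float, deprivation_effect: float = 1.0):
    """Intensity params planting the same total density in every stratum."""
    share = total_per_km2 / len(ts.RETAILER_TYPES)
    return {
        rtype: ts.IntensityParams(
            baseline={zone: share for zone in ts.ZONES},
            deprivation_effect={zone: deprivation_effect for zone in ts.ZONES},
        )
        for rtype in ts.RETAILER_TYPES
    }


@pytest.fixture(scope="session")
def random_subcommunities():
    """Random community/subcommunity fixture with positive populations."""
    rng = np.random.default_rng(11)
    rows = []
    for c in range(40):
        for s in range(rng.integers(1, 5)):
            rows.append(
                {
                    "id": f"C{c:03d}-S{s}",
                    "community_id": f"C{c:03d}",
                    "cx_m": float(rng.uniform(0, 5000)),
                    "cy_m": float(rng.uniform(0, 5000)),
                    "population": int(rng.integers(100, 5000)),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def random_retailers():
    rng = np.random.default_rng(12)
    n = 300
    return pd.DataFrame(
        {
            "id": [f"R{i:04d}" for i in range(n)],
            "retailer_type": rng.choice(ts.RETAILER_TYPES, size=n),
            "x_m": rng.uniform(0, 5000, n),
            "y_m": rng.uniform(0, 5000, n),
        }
    )
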