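"""Population-weighted neighborhood tobacco retail availability (TRA).

A community's availability is the population-weighted mean of the
kernel densities at its subcommunity centroids::

    TRA_i = sum_j(KDE_j * pop_j) / sum_j(pop_j)

where j runs over the subcommunities of community i, KDE_j is the
retailer density (outlets/km²) at the j-th centroid and pop_j its
population. Densities are evaluated exactly at the centroids by
default; evaluation off a precomputed raster (bilinear) is available to
mirror a grid-extraction workflow.

Availability for ``"all"`` retailers is formed as the sum of the three
per-type centroid densities, which by linearity of the kernel estimator
equals the density of the pooled point set.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .density import DensityConfig, DensitySurface, kde_at_points
from .synthetic import ALL_TYPES, RETAILER_TYPES

__all__ = ["aggregate_tra"]


def _centroid_densities(
    subcommunities: pd.DataFrame,
    retailers: pd.DataFrame | None,
    surfaces: Mapping[str, DensitySurface] | None,
    config: DensityConfig,
    types: tuple[str, ...],
) -> dict[str, np.ndarray]:
    """Per-type density at every subcommunity centroid; 'all' = sum of types."""
    pts = subcommunities.loc[:, ["cx_m", "cy_m"]].to_numpy(dtype=float)
    per_type: dict[str, np.ndarray] = {}
    for rtype in types:
        if surfaces is not None:
            per_type[rtype] = surfaces[rtype].bilinear(pts)
        else:
            sub = retailers.loc[retailers["retailer_type"] == rtype]
            per_type[rtype] = kde_at_points(pts, sub, config)
    per_type[ALL_TYPES] = sum(per_type[t] for t in types)
    return per_type


def aggregate_tra(
    subcommunities: pd.DataFrame,
    retailers: pd.DataFrame | None = None,
    surfaces: Mapping[str, DensitySurface] | None = None,
    config: DensityConfig | None = None,
    types: Iterable[str] = RETAILER_TYPES,
) -> pd.DataFrame:
    """Population-weighted availability per community and retailer type.

    Parameters
    ----------
    subcommunities
        Columns ``community_id, cx_m, cy_m, population``; populations
        must be non-negative and each community's total positive.
    retailers
        Point table with ``retailer_type, x_m, y_m`` (exact evaluation);
        either this or ``surfaces`` must be given.
    surfaces
        Mapping retailer_type -> :class:`DensitySurface` for raster
        (bilinear) evaluation instead of exact evaluation.
    config
        Kernel settings for exact evaluation (default 800 m quartic).

    Returns
    -------
    Long-format DataFrame ``community_id, retailer_type, tra,
    n_subcommunities`` including the pooled ``"all"`` type, sorted by
    community then type.

    Raises
    ------
    ValueError
        If neither input is provided, populations are negative, or any
        community's population total is zero (the weighted-mean
        denominator is undefined; offending community_ids listed).
    """
    if retailers is None and surfaces is None:
        raise ValueError("provide either retailers (exact) or surfaces (raster)")
    config = config or DensityConfig()
    types = tuple(types)

    pops = subcommunities["population"].to_numpy(dtype=float)
    if (pops < 0).any():
        bad = subcommunities.loc[pops < 0, "community_id"].tolist()
        raise ValueError(f"negative populations for community_ids: {bad[:20]}")
    totals = subcommunities.groupby("community_id")["population"].sum()
    empty = totals.index[totals <= 0].tolist()
    if empty:
        raise ValueError(
            f"zero total population (TRA denominator undefined) for community_ids: {empty[:20]}"
        )

    densities = _centroid_densities(subcommunities, retailers, surfaces, config, types)

    cid = subcommunities["community_id"].to_numpy()
    order = totals.index  # groupby-sorted community ids
    counts = pd.Series(1, index=cid).groupby(level=0).sum().loc[order].to_numpy()

    # per-type TRA first; the pooled type is their sum, so additivity across
    # types holds exactly, matching the linearity of the kernel estimator
    tra_by_type: dict[str, np.ndarray] = {}
    for rtype in types:
        weighted = pd.Series(densities[rtype] * pops).groupby(cid).sum()
        tra_by_type[rtype] = weighted.loc[order].to_numpy() / totals.to_numpy()
    tra_by_type[ALL_TYPES] = sum(tra_by_type[t] for t in types)

    records = []
    for rtype in types + (ALL_TYPES,):
        for community, value, n_sub in zip(order, tra_by_type[rtype], counts):
            records.append(
                {
                    "community_id": community,
                    "retailer_type": rtype,
                    "tra": float(value),
                    "n_subcommunities": int(n_sub),
                }
            )
    out = pd.DataFrame.from_records(records)
    return out.sort_values(["community_id", "retailer_type"], ignore_index=True)
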