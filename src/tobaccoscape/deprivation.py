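"""Census-based neighborhood deprivation index.

Four community-level census rates — unemployment, low-skilled workers,
low educational attainment, non-home ownership — are each standardized
to Z-scores and summed with equal weights, in the tradition of the
Carstairs and Townsend indices. All four indicators increase with
deprivation, so no sign flips are applied and a higher composite score
means a more deprived community. Communities are then ranked city-wide
into quintiles Q1 (least deprived) to Q5 (most deprived).

Conventions (fixed, documented): Z-scores use the sample standard
deviation (ddof=1); quintiles are rank-based over the whole city, and a
block of tied scores shares the quintile of its mean rank, so identical
communities are never split across quintiles.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "INDICATORS",
    "compute_deprivation",
    "assign_quintiles",
]

#: the four deprivation-increasing census rate indicators, in canonical order
INDICATORS = (
    "unemployment_rate",
    "low_skilled_rate",
    "low_education_rate",
    "non_home_ownership_rate",
)


def compute_deprivation(communities: pd.DataFrame) -> pd.DataFrame:
    """Attach per-indicator Z-scores and the composite deprivation score.

    Parameters
    ----------
    communities
        One row per community with the four indicator columns
        (:data:`INDICATORS`) as finite proportions.

    Returns
    -------
    A copy with ``z_<indicator>`` columns and ``deprivation_score``
    (the unweighted sum of the four Z-scores; higher = more deprived).

    Raises
    ------
    ValueError
        If fewer than two communities, an indicator is missing or
        non-finite (offending community_ids listed), or an indicator
        has zero variance (named).
    """
    missing_cols = [c for c in INDICATORS if c not in communities.columns]
    if missing_cols:
        raise ValueError(f"missing indicator column(s): {missing_cols}")
    if len(communities) < 2:
        raise ValueError(f"need at least 2 communities, got {len(communities)}")

    out = communities.copy()
    values = out.loc[:, list(INDICATORS)].astype(float)
    bad = ~np.isfinite(values.to_numpy()).all(axis=1)
    if bad.any():
        ids = (
            out.loc[bad, "community_id"].tolist()
            if "community_id" in out.columns
            else out.index[bad].tolist()
        )
        raise ValueError(f"non-finite indicator values for community_ids: {ids[:20]}")

    for name in INDICATORS:
        col = values[name].to_numpy()
        sd = col.std(ddof=1)
        # ptp catches constant columns whose float mean is not exactly
        # representable (sd ~ 1e-17 instead of 0)
        if sd == 0 or np.ptp(col) == 0:
            raise ValueError(f"indicator {name!r} has zero variance")
        out[f"z_{name}"] = (col - col.mean()) / sd

    out["deprivation_score"] = sum(out[f"z_{name}"] for name in INDICATORS)
    return out


def assign_quintiles(communities: pd.DataFrame) -> pd.DataFrame:
    """Attach city-wide deprivation quintiles (1 = least, 5 = most deprived).

    Ranks ``deprivation_score`` with mid-ranks for ties and maps rank r
    (of n) to quintile ceil(5r/n); a tie block is placed by its mean
    rank, so tied communities always share a quintile.
    """
    if "deprivation_score" not in communities.columns:
        raise ValueError("deprivation_score missing; run compute_deprivation first")
    n = len(communities)
    if n < 5:
        raise ValueError(f"need at least 5 communities for quintiles, got {n}")
    out = communities.copy()
    ranks = rankdata(out["deprivation_score"].to_numpy(), method="average")
    out["deprivation_quintile"] = np.clip(
        np.ceil(5.0 * ranks / n).astype(int), 1, 5
    )
    return out
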