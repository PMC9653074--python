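"""Model/Results interface for the socio-spatial availability analysis.

:class:`TobaccoRetailAnalysis` binds a community table (with urbanity
and deprivation quintiles) to a long-format availability table (TRA per
community × retailer type); its :meth:`~TobaccoRetailAnalysis.fit`
runs the full statistical layer and returns a
:class:`TobaccoRetailAnalysisResults` holding

* ``table1`` — availability distribution by urbanity stratum and
  retailer type: n, median, bootstrap 95% CI, skewness, kurtosis;
* ``table2`` — per-deprivation-quintile medians with the
  Kruskal–Wallis H, df, p and epsilon-squared per stratum × type;

plus a text ``summary()`` and quintile-profile plotting. Strata are
the whole city and each of the three urbanity zones; quintiles are
always the city-wide assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import GroupTestResult, epsilon_squared, kruskal_wallis, median_summary
from .synthetic import ALL_TYPES, RETAILER_TYPES, ZONES

__all__ = ["TobaccoRetailAnalysis", "TobaccoRetailAnalysisResults", "run_full_analysis"]

STRATA = ("city",) + ZONES


class TobaccoRetailAnalysis:
    """Stratified rank-based analysis of neighborhood retail availability.

    Parameters
    ----------
    communities
        One row per community with ``community_id``, ``urbanity`` and
        ``deprivation_quintile`` columns (see the deprivation module).
    exposure
        Long-format availability with ``community_id``,
        ``retailer_type`` and ``tra`` columns (see the exposure
        module), including the pooled ``"all"`` type.
    bootstrap_reps
        Bootstrap resamples for the median CIs (default 1000).
    """

    def __init__(
        self,
        communities: pd.DataFrame,
        exposure: pd.DataFrame,
        bootstrap_reps: int = 1000,
    ):
        required = {"community_id", "urbanity", "deprivation_quintile"}
        missing = required - set(communities.columns)
        if missing:
            raise ValueError(f"communities table missing columns: {sorted(missing)}")
        required = {"community_id", "retailer_type", "tra"}
        missing = required - set(exposure.columns)
        if missing:
            raise ValueError(f"exposure table missing columns: {sorted(missing)}")
        self.bootstrap_reps = bootstrap_reps
        meta = communities.loc[:, ["community_id", "urbanity", "deprivation_quintile"]]
        self.data = exposure.merge(meta, on="community_id", how="inner", validate="many_to_one")
        if self.data.empty:
            raise ValueError("no overlap between exposure and communities tables")
        present = set(self.data["retailer_type"])
        self.retailer_types = (ALL_TYPES,) + tuple(
            t for t in RETAILER_TYPES if t in present
        )

    # statsmodels-style alternate constructor
    @classmethod
    def from_dataframes(
        cls,
        communities: pd.DataFrame,
        exposure: pd.DataFrame,
        bootstrap_reps: int = 1000,
    ) -> "TobaccoRetailAnalysis":
        return cls(communities, exposure, bootstrap_reps=bootstrap_reps)

    def _stratum_frame(self, stratum: str) -> pd.DataFrame:
        if stratum == "city":
            return self.data
        return self.data.loc[self.data["urbanity"] == stratum]

    def fit(self, seed: int | None = None) -> "TobaccoRetailAnalysisResults":
        """Run every stratum × retailer-type summary and quintile test."""
        table1_rows = []
        table2_rows = []
        tests: dict[tuple[str, str], GroupTestResult] = {}
        for stratum in STRATA:
            frame = self._stratum_frame(stratum)
            for rtype in self.retailer_types:
                values = frame.loc[frame["retailer_type"] == rtype]
                if values.empty:
                    raise ValueError(f"no availability rows for stratum {stratum!r}, type {rtype!r}")
                summ = median_summary(
                    values["tra"].to_numpy(),
                    reps=self.bootstrap_reps,
                    seed=seed,
                    label=f"{stratum}/{rtype}",
                )
                table1_rows.append(
                    {
                        "stratum": stratum,
                        "retailer_type": rtype,
                        "n": summ.n,
                        "median": summ.median,
                        "ci_low": summ.ci_low,
                        "ci_high": summ.ci_high,
                        "skewness": summ.skewness,
                        "kurtosis": summ.kurtosis,
                    }
                )

                groups, medians = [], {}
                for q in range(1, 6):
                    cell = values.loc[values["deprivation_quintile"] == q, "tra"].to_numpy()
                    if cell.size == 0:
                        raise ValueError(
                            f"empty cell: stratum {stratum!r} × quintile Q{q} for type {rtype!r}"
                        )
                    groups.append(cell)
                    medians[q] = float(np.median(cell))
                H, df, p = kruskal_wallis(groups)
                eps2 = epsilon_squared(H, len(values))
                tests[(stratum, rtype)] = GroupTestResult(
                    stratum=stratum,
                    retailer_type=rtype,
                    H=H,
                    df=df,
                    p_value=p,
                    epsilon_squared=eps2,
                    n_total=len(values),
                    group_medians=medians,
                )
                table2_rows.append(
                    {
                        "stratum": stratum,
                        "retailer_type": rtype,
                        **{f"median_q{q}": medians[q] for q in range(1, 6)},
                        "H": H,
                        "df": df,
                        "p_value": p,
                        "epsilon_squared": eps2,
                        "n": len(values),
                    }
                )
        return TobaccoRetailAnalysisResults(
            model=self,
            table1=pd.DataFrame(table1_rows),
            table2=pd.DataFrame(table2_rows),
            tests=tests,
            seed=seed,
        )


@dataclass
class TobaccoRetailAnalysisResults:
    """Fitted tables and tests from :class:`TobaccoRetailAnalysis`."""

    model: TobaccoRetailAnalysis
    table1: pd.DataFrame
    table2: pd.DataFrame
    tests: dict
    seed: int | None = None

    def quintile_profile(self, stratum: str, retailer_type: str = ALL_TYPES) -> pd.Series:
        """Per-quintile median availability for one stratum × type."""
        test = self.tests[(stratum, retailer_type)]
        return pd.Series(test.group_medians, name="median_tra").rename_axis("quintile")

    def summary(self) -> str:
        """Human-readable fit summary in the style of a results table."""
        lines = ["Neighborhood tobacco retail availability — stratified rank analysis", ""]
        lines.append(
            f"{'stratum':<14}{'type':<20}{'n':>6}{'median':>9}{'95% CI':>18}"
            f"{'H':>10}{'p':>10}{'eps^2':>7}"
        )
        for _, r1 in self.table1.iterrows():
            key = (r1["stratum"], r1["retailer_type"])
            t = self.tests[key]
            ci = f"({r1['ci_low']:.2f}, {r1['ci_high']:.2f})"
            p = "<.001" if t.p_value < 0.001 else f"{t.p_value:.3f}"
            lines.append(
                f"{r1['stratum']:<14}{r1['retailer_type']:<20}{r1['n']:>6d}"
                f"{r1['median']:>9.2f}{ci:>18}{t.H:>10.2f}{p:>10}{t.epsilon_squared:>7.2f}"
            )
        lines.append("")
        lines.append("Kruskal-Wallis across city-wide deprivation quintiles Q1 (least) .. Q5 (most);")
        lines.append("eps^2 = H/(n-1); medians in outlets/km^2.")
        return "\n".join(lines)

    def plot_quintile_profiles(self, retailer_type: str = ALL_TYPES, ax=None):
        """Median availability across deprivation quintiles, one line per stratum."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        for stratum in STRATA:
            prof = self.quintile_profile(stratum, retailer_type)
            ax.plot(prof.index, prof.values, marker="o", label=stratum)
        ax.set_xlabel("Deprivation quintile (1 = least deprived)")
        ax.set_ylabel("Median availability (outlets/km²)")
        ax.set_title(f"Availability by deprivation quintile — {retailer_type}")
        ax.set_xticks(range(1, 6))
        ax.legend()
        return ax


def run_full_analysis(
    exposure: pd.DataFrame,
    communities: pd.DataFrame,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> TobaccoRetailAnalysisResults:
    """One-call convenience wrapper: build the model and fit it."""
    return TobaccoRetailAnalysis(communities, exposure, bootstrap_reps=bootstrap_reps).fit(seed=seed)
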