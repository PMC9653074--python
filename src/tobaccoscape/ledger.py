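"""Data-cleaning ledger bookkeeping.

Point-of-interest retail data arrive noisy (duplicates, closed or
misclassified outlets) and are cleaned in ordered steps. The ledger
records, for each step, how many records came in, how many were
removed, and against which declared baseline the exclusion percentage
is reported, and enforces that the counts chain consistently:
``records_out = records_in - records_removed`` and each step starts
from the previous step's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["CleaningStep", "CleaningLedger", "summarize_ledger"]


@dataclass(frozen=True)
class CleaningStep:
    label: str
    records_in: int
    records_removed: int
    baseline_in: int  # denominator for the reported exclusion percentage

    @property
    def records_out(self) -> int:
        return self.records_in - self.records_removed


@dataclass
class CleaningLedger:
    """Ordered, internally consistent record of cleaning steps."""

    steps: list[CleaningStep] = field(default_factory=list)

    def add_step(
        self,
        label: str,
        records_in: int,
        records_removed: int,
        baseline_in: int | None = None,
    ) -> CleaningStep:
        """Append a step; baseline defaults to the step's own input count."""
        if records_in < 0 or records_removed < 0:
            raise ValueError(f"step {label!r}: negative counts")
        if records_removed > records_in:
            raise ValueError(
                f"step {label!r}: removed {records_removed} exceeds input {records_in}"
            )
        if self.steps and records_in != self.steps[-1].records_out:
            raise ValueError(
                f"step {label!r}: records_in {records_in} != previous step's "
                f"records_out {self.steps[-1].records_out}"
            )
        step = CleaningStep(
            label=label,
            records_in=records_in,
            records_removed=records_removed,
            baseline_in=records_in if baseline_in is None else baseline_in,
        )
        self.steps.append(step)
        return step

    @property
    def records_retained(self) -> int:
        if not self.steps:
            raise ValueError("empty ledger")
        return self.steps[-1].records_out


def summarize_ledger(ledger: CleaningLedger) -> pd.DataFrame:
    """Per-step retention and exclusion percentages (2 dp).

    ``pct_excluded = records_removed / baseline_in * 100`` with the
    baseline as declared per step; ``pct_retained`` complements it
    against the same baseline.
    """
    if not ledger.steps:
        raise ValueError("empty ledger")
    rows = []
    for step in ledger.steps:
        if step.baseline_in <= 0:
            raise ValueError(f"step {step.label!r}: non-positive baseline")
        pct = round(step.records_removed / step.baseline_in * 100.0, 2)
        rows.append(
            {
                "label": step.label,
                "records_in": step.records_in,
                "records_removed": step.records_removed,
                "records_out": step.records_out,
                "baseline_in": step.baseline_in,
                "pct_excluded": pct,
                "pct_retained": round(100.0 - pct, 2),
            }
        )
    return pd.DataFrame(rows)
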