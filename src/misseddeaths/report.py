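"""Aggregation of per-group detection counts into cohort-level tables.

Totals for "all cancers combined" are the element-wise sums over the
individual diagnosis groups (the group list itself excludes non-melanoma
skin cancer), with the percentage of missed deaths recomputed from the
summed counts.  Rounding is half-up to the displayed precision, matching
published registry tables.
"""

from __future__ import annotations

import dataclasses
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources

import pandas as pd

__all__ = [
    "GroupSummary",
    "aggregate_groups",
    "emigration_rate",
    "load_example_group_counts",
    "load_example_emigration",
    "write_group_table",
]


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    """Detection counts for one diagnosis group."""

    diagnosis_group: str
    n_patients: int
    n_deaths: int
    n_missed: int

    def __post_init__(self) -> None:
        if self.n_missed > self.n_patients - self.n_deaths:
            raise ValueError("more flags than alive patients in group")

    @property
    def pct_missed_of_deaths(self) -> float:
        if self.n_deaths == 0:
            return 0.0
        return 100.0 * self.n_missed / self.n_deaths


def aggregate_groups(
    summaries: list[GroupSummary] | pd.DataFrame, decimals: int = 2
) -> dict:
    """Column sums over diagnosis groups plus the recomputed percentage.

    Accepts a list of :class:`GroupSummary` or a DataFrame with columns
    ``n_patients, n_deaths, n_missed``.  The total percentage is summed
    missed / summed deaths · 100, rounded half-up to ``decimals``.
    """
    if isinstance(summaries, pd.DataFrame):
        rows = summaries
    else:
        rows = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
    if len(rows) == 0:
        return {"n_patients": 0, "n_deaths": 0, "n_missed": 0, "pct_missed_of_deaths": 0.0}
    n_patients = int(rows["n_patients"].sum())
    n_deaths = int(rows["n_deaths"].sum())
    n_missed = int(rows["n_missed"].sum())
    pct = 100.0 * n_missed / n_deaths if n_deaths else 0.0
    return {
        "n_patients": n_patients,
        "n_deaths": n_deaths,
        "n_missed": n_missed,
        "pct_missed_of_deaths": _round_half_up(pct, decimals),
    }


def emigration_rate(emigrations: int, persons: int, decimals: int = 1) -> float:
    """Emigrations per 100 registered persons, rounded half-up."""
    if persons <= 0:
        raise ValueError("persons must be positive")
    return _round_half_up(100.0 * emigrations / persons, decimals)


def _load_data_csv(name: str) -> pd.DataFrame:
    with resources.files("misseddeaths").joinpath("data", name).open() as fh:
        return pd.read_csv(fh)


def load_example_group_counts(source: str = "german") -> pd.DataFrame:
    """Published per-diagnosis-group detection counts (worked example data).

    ``source`` is ``"german"`` (pooled German federal-state registries) or
    ``"seer"`` (US SEER-18, whites).  Columns: diagnosis_group, n_patients,
    n_deaths, n_missed.
    """
    if source not in {"german", "seer"}:
        raise ValueError("source must be 'german' or 'seer'")
    return _load_data_csv(f"{source}_group_counts.csv")


def load_example_emigration() -> pd.DataFrame:
    """Published emigration counts from the Hamburg registry catchment area."""
    return _load_data_csv("hamburg_emigration.csv")


def write_group_table(
    summaries: list[GroupSummary], path, fmt: str = "csv", decimals: int = 2
) -> None:
    """Write the per-group table plus totals row as CSV or Markdown."""
    rows = [
        {
            **dataclasses.asdict(s),
            "pct_missed_of_deaths": _round_half_up(s.pct_missed_of_deaths, decimals),
        }
        for s in summaries
    ]
    total = aggregate_groups(summaries, decimals=decimals)
    rows.append({"diagnosis_group": "all combined", **total})
    df = pd.DataFrame(rows)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "md":
        with open(path, "w") as fh:
            fh.write(df.to_markdown(index=False))
    else:
        raise ValueError("fmt must be 'csv' or 'md'")
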