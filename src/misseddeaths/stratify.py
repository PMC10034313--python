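"""Partition a prepared cohort into the detection strata.

Base partition: diagnosis group × sex × age group at diagnosis (15-54,
55-74, 75+).  A base cell is further split by stage only when every observed
non-missing stage level holds at least ``min_cases_per_stage`` patients
(default 500); in that case missing-stage records form an additional stratum
of their own.  Strata are disjoint and cover the cohort.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .config import CohortConfig

__all__ = ["Stratum", "build_strata", "strata_summary"]

ALL_STAGES = "all-stages"
MISSING_STAGE = "missing"


@dataclasses.dataclass
class Stratum:
    diagnosis_group: str
    sex: str
    age_group: str
    stage: str  # a stage level or "all-stages"
    records: pd.DataFrame

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.diagnosis_group, self.sex, self.age_group, self.stage)

    @property
    def n_patients(self) -> int:
        return len(self.records)

    @property
    def n_deaths(self) -> int:
        return int((self.records["status"] == "dead").sum())

    @property
    def death_fraction(self) -> float:
        return self.n_deaths / self.n_patients if self.n_patients else 0.0

    def __repr__(self) -> str:  # compact: keys + sizes
        return (
            f"Stratum({self.diagnosis_group!r}, {self.sex!r}, {self.age_group!r}, "
            f"{self.stage!r}, n={self.n_patients}, deaths={self.n_deaths})"
        )


def build_strata(df: pd.DataFrame, config: CohortConfig | None = None) -> list[Stratum]:
    """Build the analysis strata for a prepared cohort.

    Only non-empty cells are emitted (a sex-specific diagnosis group yields
    no opposite-sex strata).
    """
    config = config or CohortConfig()
    if len(df) == 0:
        return []
    df = df.copy()
    df["age_group"] = config.age_group_of(df["age_dx"].to_numpy())

    strata: list[Stratum] = []
    for (dg, sex, ag), cell in df.groupby(
        ["diagnosis_group", "sex", "age_group"], sort=True, observed=True
    ):
        stage_counts = cell["stage"].value_counts()
        observed_levels = [s for s in stage_counts.index if s != MISSING_STAGE]
        split = len(observed_levels) > 0 and all(
            stage_counts[s] >= config.min_cases_per_stage for s in observed_levels
        )
        if split:
            for stage, sub in cell.groupby("stage", sort=True):
                strata.append(Stratum(dg, sex, ag, str(stage), sub))
        else:
            strata.append(Stratum(dg, sex, ag, ALL_STAGES, cell))
    return strata


def strata_summary(strata: list[Stratum]) -> pd.DataFrame:
    """One row per stratum: key columns plus size, deaths, death fraction."""
    return pd.DataFrame(
        {
            "diagnosis_group": [s.diagnosis_group for s in strata],
            "sex": [s.sex for s in strata],
            "age_group": [s.age_group for s in strata],
            "stage": [s.stage for s in strata],
            "n_patients": [s.n_patients for s in strata],
            "n_deaths": [s.n_deaths for s in strata],
            "death_fraction": [s.death_fraction for s in strata],
        }
    )
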