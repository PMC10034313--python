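"""Algorithm configuration.

All tunable constants of the missed-death detection pipeline live in a single
:class:`CohortConfig`.  Defaults correspond to the published calibration for
pooled national registry data: a 5-year period window, 35/30-year estimation
horizons, the 99.9th starting percentile with 0.05-point convergence steps and
0.5-point iteration steps, a 90 % classification cutoff, a cap of 5 % of
deaths on the number of flags per stratum, a 10 % death-fraction threshold
below which the scoring fallback replaces the logistic classifier, and the
International Cancer Survival Standard age weights 0.19/0.52/0.29.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

__all__ = ["CohortConfig"]


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclass
class CohortConfig:
    """Constants controlling cohort preparation, estimation and detection.

    Parameters
    ----------
    follow_up_end : datetime.date
        Administrative end of registry follow-up; alive patients are censored
        here and the period window ends here.
    period_window_years : int
        Width of the period-analysis calendar window (most recent years of
        follow-up used for estimation).
    max_follow_up_young, max_follow_up_old : float
        Estimation horizon in years for patients younger than 55 at diagnosis
        and for older patients, respectively.
    age_group_breaks : sequence of int
        Lower bounds of the age groups at diagnosis (default 15/55/75, i.e.
        groups 15-54, 55-74, 75+).
    min_cases_per_stage : int
        Minimum number of patients required in *every* observed stage level
        before a diagnosis/sex/age cell is further split by stage.
    outlier_start_percentile : float
        Starting percentile defining outlier deaths (both follow-up time and
        age at exit at or above this percentile among the deceased).
    percentile_step_converge : float
        Decrement applied while the outlier logistic regression has no events
        or does not converge.
    percentile_step_iterate : float
        Decrement applied between detection iterations.
    prob_cutoff : float
        Predicted probability at or above which an alive patient is
        classified as a missed death.
    max_missed_fraction_of_deaths : float
        Per-stratum cap: flag sets whose size strictly exceeds this fraction
        of the stratum's deaths are rejected.
    min_death_fraction_for_logit : float
        Strata in which fewer than this fraction of patients died use the
        scoring fallback instead of the logistic classifier.
    alpha : float
        Significance level both for the Wald tests on the regression
        coefficients and for the one-sided curve tests.
    icss_weights : sequence of float
        Age-standardisation weights for the three age groups.
    percentile_floor : float
        Hard lower bound on the percentile schedule; guarantees termination.
    """

    follow_up_end: dt.date = dt.date(2016, 12, 31)
    period_window_years: int = 5
    max_follow_up_young: float = 35.0
    max_follow_up_old: float = 30.0
    age_group_breaks: Sequence[int] = (15, 55, 75)
    min_cases_per_stage: int = 500
    outlier_start_percentile: float = 99.9
    percentile_step_converge: float = 0.05
    percentile_step_iterate: float = 0.5
    prob_cutoff: float = 0.90
    max_missed_fraction_of_deaths: float = 0.05
    min_death_fraction_for_logit: float = 0.10
    alpha: float = 0.05
    icss_weights: Sequence[float] = (0.19, 0.52, 0.29)
    percentile_floor: float = 50.0

    def __post_init__(self) -> None:
        self.follow_up_end = _as_date(self.follow_up_end)
        self.age_group_breaks = tuple(int(a) for a in self.age_group_breaks)
        self.icss_weights = tuple(float(w) for w in self.icss_weights)
        if abs(sum(self.icss_weights) - 1.0) > 1e-9:
            raise ValueError("icss_weights must sum to 1")
        if not 0.0 < self.prob_cutoff < 1.0:
            raise ValueError("prob_cutoff must lie in (0, 1)")
        for name in ("outlier_start_percentile", "percentile_floor"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ValueError(f"{name} must lie in (0, 100)")
        if len(self.icss_weights) != len(self.age_group_breaks):
            raise ValueError("need one ICSS weight per age group")

    # age-group helpers -------------------------------------------------

    @property
    def age_group_labels(self) -> tuple[str, ...]:
        breaks = self.age_group_breaks
        labels = [f"{lo}-{hi - 1}" for lo, hi in zip(breaks[:-1], breaks[1:])]
        labels.append(f"{breaks[-1]}+")
        return tuple(labels)

    def age_group_of(self, age) -> str:
        """Age-group label for an age at diagnosis (scalar or array-like)."""
        import numpy as np
        import pandas as pd

        breaks = list(self.age_group_breaks) + [np.inf]
        out = pd.cut(
            np.atleast_1d(np.asarray(age, dtype=float)),
            bins=breaks,
            right=False,
            labels=list(self.age_group_labels),
        ).astype(object)
        if np.ndim(age) == 0:
            return out[0]
        return np.asarray(out)

    def horizon_for(self, age_at_diagnosis: float) -> int:
        """Estimation horizon in whole years for an age at diagnosis."""
        young = age_at_diagnosis < self.age_group_breaks[1]
        return int(self.max_follow_up_young if young else self.max_follow_up_old)

    # serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["follow_up_end"] = self.follow_up_end.isoformat()
        d["age_group_breaks"] = list(self.age_group_breaks)
        d["icss_weights"] = list(self.icss_weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
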