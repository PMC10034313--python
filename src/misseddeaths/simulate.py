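"""Synthetic registry cohorts and the missed-death evaluation harness.

Real population-based registry data are access-restricted, so evaluation
runs on synthetic cohorts that emulate their structure: a mixture cure model
for disease-specific ("excess") mortality layered on top of life-table
background mortality, uniform diagnosis dates over the registry's operating
years, and administrative censoring at follow-up end.  Missed deaths are
then *injected* by relabelling a random sample of deceased patients as alive
with exit at follow-up end — exactly the error mechanism (failed linkage,
unregistered emigration) the detector is meant to find — and detection
quality is summarised as sensitivity (percent of injected cases flagged) and
the false-positive share among flags, alongside relative-survival curves
before correction, after correction, and on the uninjected truth cohort.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Sequence

import numpy as np
import pandas as pd

from .config import CohortConfig
from .detect import StratumResult, run_stratum
from .lifetable import LifeTable
from .registry import DAYS_PER_YEAR, add_followup_columns, prepare_cohort
from .relsurv import SurvivalCurve, estimate_period_rs
from .stratify import Stratum

__all__ = [
    "SimScenario",
    "SimulationResult",
    "generate_cohort",
    "inject_missed_deaths",
    "evaluate",
    "run_experiment",
]


@dataclasses.dataclass
class SimScenario:
    """Study design for one synthetic stratum.

    The default scenario is a colorectal-like cancer in men aged 55-74:
    a cure fraction of 0.35 (long-term survivors whose mortality reverts to
    the population's) and an exponential excess hazard of 0.15/year among
    the non-cured, giving ~66 % 5-year relative survival.  Diagnoses are
    uniform over 1976-2016 with follow-up ending 2016-12-31, mirroring a
    registry operating for four decades.
    """

    n_patients: int = 50_000
    diagnosis_group: str = "intestine"
    sex: str = "male"
    age_range: tuple[int, int] = (55, 74)
    diagnosis_years: tuple[int, int] = (1976, 2016)
    excess_rate: float = 0.15  # events/year among the non-cured
    weibull_shape: float = 1.0  # 1.0 = exponential
    cure_fraction: float = 0.35
    injected_fraction: float = 0.05
    replicates: int = 5
    seed: int = 0
    stage: str = "missing"
    registry: str = "sim"

    def __post_init__(self) -> None:
        if self.excess_rate <= 0 or self.weibull_shape <= 0:
            raise ValueError("hazard parameters must be positive")
        if not 0.0 <= self.cure_fraction <= 1.0:
            raise ValueError("cure fraction must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    @classmethod
    def from_yaml(cls, path) -> "SimScenario":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("age_range", "diagnosis_years"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _sample_background_death(
    rng: np.random.Generator,
    lifetable: LifeTable,
    sex: str,
    age_dx: np.ndarray,
    year_dx: np.ndarray,
    max_years: int,
) -> np.ndarray:
    """Years from diagnosis to background (population-mortality) death.

    Walks the life table one attained year at a time; deaths beyond
    ``max_years`` (past follow-up end, where they could never be observed)
    are returned as +inf.  Within-year timing is uniform.
    """
    n = len(age_dx)
    t = np.full(n, np.inf)
    pending = np.ones(n, dtype=bool)
    for k in range(max_years):
        if not pending.any():
            break
        p = lifetable.annual_survival(sex, age_dx[pending] + k, year_dx[pending] + k)
        u = rng.random(p.shape[0])
        died = u > p
        idx = np.nonzero(pending)[0][died]
        t[idx] = k + rng.random(idx.shape[0])
        pending[idx] = False
    return t


def generate_cohort(
    scenario: SimScenario,
    lifetable: LifeTable,
    config: CohortConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw one synthetic cohort for a scenario.

    Time to death is the minimum of (a) an excess-event time from the
    mixture cure model (infinite for the cured) and (b) a background death
    time sampled from the life table; follow-up is administratively censored
    at ``config.follow_up_end``.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = scenario.n_patients

    y0, y1 = scenario.diagnosis_years
    start = dt.date(y0, 1, 1).toordinal()
    end = min(dt.date(y1, 12, 31).toordinal(), config.follow_up_end.toordinal())
    dx_ord = rng.integers(start, end + 1, size=n)
    date_dx = pd.to_datetime([dt.date.fromordinal(int(o)) for o in dx_ord])

    a0, a1 = scenario.age_range
    age_dx = rng.integers(a0, a1 + 1, size=n)

    # excess-event time: cure mass + Weibull(shape, scale=1/rate)
    cured = rng.random(n) < scenario.cure_fraction
    t_excess = np.where(
        cured,
        np.inf,
        rng.weibull(scenario.weibull_shape, size=n) / scenario.excess_rate,
    )

    fu_admin = (config.follow_up_end.toordinal() - dx_ord) / DAYS_PER_YEAR
    max_years = int(np.ceil(fu_admin.max())) + 1
    year_dx = pd.DatetimeIndex(date_dx).year.to_numpy()
    t_background = _sample_background_death(
        rng, lifetable, scenario.sex, age_dx, year_dx, max_years
    )

    t_death = np.minimum(t_excess, t_background)
    dead = t_death <= fu_admin
    fu = np.where(dead, t_death, fu_admin)
    exit_ord = dx_ord + np.round(fu * DAYS_PER_YEAR).astype(int)
    exit_ord = np.minimum(exit_ord, config.follow_up_end.toordinal())
    date_exit = pd.to_datetime([dt.date.fromordinal(int(o)) for o in exit_ord])

    df = pd.DataFrame(
        {
            "patient_id": [f"{scenario.registry}-{i:07d}" for i in range(n)],
            "diagnosis_group": scenario.diagnosis_group,
            "sex": scenario.sex,
            "age_dx": age_dx,
            "date_dx": date_dx,
            "date_exit": date_exit,
            "status": np.where(dead, "dead", "alive"),
            "stage": scenario.stage,
            "dco": False,
            "registry": scenario.registry,
        }
    )
    return add_followup_columns(df)


def inject_missed_deaths(
    df: pd.DataFrame,
    fraction: float,
    config: CohortConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, set]:
    """Relabel a random sample of deceased patients as alive at follow-up end.

    Returns the modified copy and the set of injected patient ids (the truth
    labels for sensitivity/false-positive evaluation).  The sample size is
    round(fraction × number of deaths); a fraction too small to select one
    record yields no injection and a warning.
    """
    import warnings

    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    dead_idx = df.index[df["status"] == "dead"].to_numpy()
    if len(dead_idx) == 0:
        raise ValueError("cohort has no deaths to inject from")
    k = int(round(fraction * len(dead_idx)))
    if k == 0:
        warnings.warn("injected fraction selects zero records", stacklevel=2)
        return df.copy(), set()
    chosen = rng.choice(dead_idx, size=k, replace=False)
    out = df.copy()
    out.loc[chosen, "status"] = "alive"
    out.loc[chosen, "date_exit"] = pd.Timestamp(config.follow_up_end)
    out = add_followup_columns(out)
    return out, set(out.loc[chosen, "patient_id"])


@dataclasses.dataclass
class SimulationResult:
    """Detection-quality metrics for one replicate (or averaged)."""

    n_simulated: int
    n_flagged: int
    n_detected_and_simulated: int
    n_deaths: int
    rs_before: SurvivalCurve | None = None
    rs_after: SurvivalCurve | None = None
    rs_truth: SurvivalCurve | None = None

    @property
    def sensitivity(self) -> float:
        """Percent of injected missed deaths that were flagged."""
        if self.n_simulated == 0:
            return float("nan")
        return 100.0 * self.n_detected_and_simulated / self.n_simulated

    @property
    def false_positive(self) -> float:
        """Percent of flags that were not injected (0 when nothing flagged)."""
        if self.n_flagged == 0:
            return 0.0
        return 100.0 * (self.n_flagged - self.n_detected_and_simulated) / self.n_flagged

    @property
    def flagged_pct_of_deaths(self) -> float:
        if self.n_deaths == 0:
            return 0.0
        return 100.0 * self.n_flagged / self.n_deaths

    def metrics_row(self) -> dict:
        return {
            "n_simulated": self.n_simulated,
            "n_flagged": self.n_flagged,
            "n_detected_and_simulated": self.n_detected_and_simulated,
            "n_deaths": self.n_deaths,
            "sensitivity_pct": self.sensitivity,
            "false_positive_pct": self.false_positive,
            "flagged_pct_of_deaths": self.flagged_pct_of_deaths,
        }


def evaluate(truth: set, flagged: set, deaths_total: int) -> SimulationResult:
    """Sensitivity = |truth ∩ flagged| / |truth| · 100; false-positive share
    = |flagged \\ truth| / |flagged| · 100."""
    overlap = len(truth & flagged)
    return SimulationResult(
        n_simulated=len(truth),
        n_flagged=len(flagged),
        n_detected_and_simulated=overlap,
        n_deaths=deaths_total,
    )


def run_replicate(
    scenario: SimScenario,
    lifetable: LifeTable,
    config: CohortConfig,
    seed: int,
) -> tuple[SimulationResult, StratumResult]:
    """Generate → inject → prepare → detect → evaluate, once."""
    raw = generate_cohort(scenario, lifetable, config, seed=seed)
    truth_cohort = prepare_cohort(raw, config)
    horizon = config.horizon_for(scenario.age_range[0])
    rs_truth = estimate_period_rs(truth_cohort, lifetable, config, horizon)

    if scenario.injected_fraction > 0:
        injected, truth = inject_missed_deaths(
            raw, scenario.injected_fraction, config, seed=seed + 1
        )
    else:
        injected, truth = raw, set()
    cohort = prepare_cohort(injected, config)
    age_group = config.age_group_of(scenario.age_range[0])
    stratum = Stratum(
        scenario.diagnosis_group, scenario.sex, age_group, scenario.stage, cohort
    )
    det = run_stratum(stratum, lifetable, config)
    n_deaths_observed = stratum.n_deaths

    result = evaluate(truth, det.flagged_ids, n_deaths_observed)
    result.rs_before = det.initial_curve
    result.rs_after = det.final_curve
    result.rs_truth = rs_truth
    return result, det


def run_experiment(
    scenario: SimScenario,
    lifetable: LifeTable,
    config: CohortConfig | None = None,
    seeds: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, list[SimulationResult]]:
    """Run all replicates of a scenario and tabulate the metrics.

    Per-replicate seeds are derived from ``scenario.seed`` unless given
    explicitly.  Returns a one-row-per-replicate DataFrame (with an appended
    ``mean`` row) and the raw per-replicate results.
    """
    config = config or CohortConfig()
    if seeds is None:
        root = np.random.SeedSequence(scenario.seed)
        seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(scenario.replicates)]
    rows, results = [], []
    for rep, seed in enumerate(seeds):
        res, det = run_replicate(scenario, lifetable, config, seed)
        row = {"replicate": rep, "seed": seed, **res.metrics_row()}
        for year in (5, 10, 15, 20):
            for label, curve in (
                ("rs_before", res.rs_before),
                ("rs_after", res.rs_after),
                ("rs_truth", res.rs_truth),
            ):
                val = curve.rs_at(year) if curve is not None else float("nan")
                row[f"{label}_{year}y_pct"] = 100.0 * val
        rows.append(row)
        results.append(res)
    table = pd.DataFrame(rows)
    mean_row = table.drop(columns=["replicate", "seed"]).mean(numeric_only=True)
    mean_row["replicate"] = "mean"
    table = pd.concat([table, mean_row.to_frame().T], ignore_index=True)
    return table, results
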