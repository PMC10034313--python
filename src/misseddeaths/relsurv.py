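"""Period-analysis relative survival with Ederer II expected survival.

The estimation grid is annual follow-up intervals j = 1..J, interval j
covering follow-up time (j-1, j].  Under period analysis only person-time
falling inside a recent calendar window contributes: patients diagnosed
earlier enter an interval late (left truncation), patients whose follow-up
leaves the window are withdrawn there.

Observed survival uses the actuarial (life-table) estimator with the classic
half-weight convention for within-interval withdrawals and late entrants,

    p̂(j) = 1 - d(j) / n'(j),     n'(j) = n(j) - (w(j) + l(j)) / 2,

with Greenwood standard errors.  Expected survival follows the Ederer II
principle: the interval expected survival p*(j) is the mean annual population
survival probability over exactly the patients at risk in interval j, looked
up at their attained age and calendar year at the interval start.  Relative
survival is the ratio of the two cumulative curves and may exceed 100 % —
which on long follow-up is the signature of missed deaths.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd

from .config import CohortConfig
from .lifetable import LifeTable
from .registry import DAYS_PER_YEAR

__all__ = [
    "PeriodWindow",
    "Contributions",
    "SurvivalCurve",
    "period_contributions",
    "observed_survival",
    "expected_survival_ederer2",
    "relative_survival",
    "conditional_rs",
    "age_standardize",
    "estimate_period_rs",
]

@dataclasses.dataclass(frozen=True)
class PeriodWindow:
    """Calendar window (start, end] restricting the person-time used."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must be after start")

    @classmethod
    def from_config(cls, config: CohortConfig) -> "PeriodWindow":
        end = config.follow_up_end
        try:
            start = end.replace(year=end.year - config.period_window_years)
        except ValueError:  # Feb 29
            start = end.replace(year=end.year - config.period_window_years, day=28)
        return cls(start, end)


@dataclasses.dataclass
class Contributions:
    """Per-interval aggregates of the period-analysis person-time.

    ``at_risk`` is the boolean (n_records, horizon) matrix of interval
    membership; the remaining matrices mark deaths, within-interval
    withdrawals and late entrants.  ``age_start``/``year_start`` give each
    record's attained age and calendar year at the start of each interval
    (for the Ederer II lookup); ``sex`` is carried along per record.
    """

    at_risk: np.ndarray
    death: np.ndarray
    withdrawal: np.ndarray
    late_entry: np.ndarray
    age_start: np.ndarray
    year_start: np.ndarray
    sex: np.ndarray
    horizon: int

    @property
    def n(self) -> np.ndarray:
        return self.at_risk.sum(axis=0)

    @property
    def d(self) -> np.ndarray:
        return self.death.sum(axis=0)

    @property
    def n_effective(self) -> np.ndarray:
        return (
            self.n
            - 0.5 * self.withdrawal.sum(axis=0)
            - 0.5 * self.late_entry.sum(axis=0)
        )

    def to_frame(self) -> pd.DataFrame:
        """Long per-(record, interval) view, one row per contribution."""
        rec, j = np.nonzero(self.at_risk)
        return pd.DataFrame(
            {
                "record": rec,
                "interval": j + 1,
                "death": self.death[rec, j],
                "withdrawal": self.withdrawal[rec, j],
                "late_entry": self.late_entry[rec, j],
                "age_start": self.age_start[rec, j],
                "year_start": self.year_start[rec, j],
            }
        )


def period_contributions(
    df: pd.DataFrame, window: PeriodWindow, horizon: int
) -> Contributions:
    """Decompose each record's follow-up into period-window interval contributions.

    A record contributes to interval j iff the calendar time it spends in
    follow-up interval (j-1, j] intersects the window; deaths are counted in
    the interval containing the death time, provided it falls inside the
    window.
    """
    n = len(df)
    fu = df["fu_time"].to_numpy(dtype=float)
    dead = (df["status"].to_numpy() == "dead")
    dx = pd.to_datetime(df["date_dx"])
    t_entry = (pd.Timestamp(window.start) - dx).dt.days.to_numpy() / DAYS_PER_YEAR
    t_end = (pd.Timestamp(window.end) - dx).dt.days.to_numpy() / DAYS_PER_YEAR

    j = np.arange(1, horizon + 1, dtype=float)  # (J,)
    entry = np.maximum(j - 1.0, t_entry[:, None])  # (n, J)
    limit = np.minimum(fu, t_end)[:, None]
    exit_ = np.minimum(j, limit)

    at_risk = exit_ > entry
    death = (
        dead[:, None]
        & at_risk
        & (fu[:, None] <= j)
        & (fu[:, None] <= t_end[:, None])
        & (fu[:, None] > entry)
    )
    withdrawal = at_risk & ~death & (exit_ < j)
    late = at_risk & (entry > (j - 1.0))

    age_dx = df["age_dx"].to_numpy(dtype=int)
    year_dx = dx.dt.year.to_numpy()
    k = np.arange(horizon)
    age_start = age_dx[:, None] + k[None, :]
    year_start = year_dx[:, None] + k[None, :]

    return Contributions(
        at_risk=at_risk,
        death=death,
        withdrawal=withdrawal,
        late_entry=late,
        age_start=age_start,
        year_start=year_start,
        sex=df["sex"].to_numpy(),
        horizon=horizon,
    )


@dataclasses.dataclass
class SurvivalCurve:
    """Observed/expected/relative cumulative survival per follow-up year.

    Arrays are indexed by follow-up year 1..J (``years``).  ``rs`` is stored
    on the probability scale; :attr:`rs_percent` reports percentages.
    """

    years: np.ndarray
    n_risk: np.ndarray
    deaths: np.ndarray
    s_obs: np.ndarray
    se_obs: np.ndarray
    s_exp: np.ndarray | None = None
    rs: np.ndarray | None = None
    se_rs: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.years)

    @property
    def rs_percent(self) -> np.ndarray:
        return None if self.rs is None else 100.0 * self.rs

    @property
    def se_rs_percent(self) -> np.ndarray:
        return None if self.se_rs is None else 100.0 * self.se_rs

    def rs_at(self, year: int) -> float:
        """Relative survival (probability scale) at a follow-up year."""
        idx = np.where(self.years == year)[0]
        if len(idx) == 0:
            return float("nan")
        return float(self.rs[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "fu_year": self.years,
                "n_risk": self.n_risk,
                "deaths": self.deaths,
                "s_obs": self.s_obs,
                "se_obs": self.se_obs,
            }
        )
        if self.s_exp is not None:
            out["s_exp"] = self.s_exp
        if self.rs is not None:
            out["rs_percent"] = self.rs_percent
            out["se_percent"] = self.se_rs_percent
        return out


def observed_survival(contrib: Contributions) -> SurvivalCurve:
    """Actuarial observed survival with Greenwood standard errors.

    The curve is truncated at the last interval with a positive effective
    number at risk.
    """
    n = contrib.n.astype(float)
    d = contrib.d.astype(float)
    n_eff = contrib.n_effective.astype(float)

    valid = n_eff > 0
    if not valid.any():
        return SurvivalCurve(
            years=np.array([], dtype=int),
            n_risk=np.array([], dtype=int),
            deaths=np.array([], dtype=int),
            s_obs=np.array([]),
            se_obs=np.array([]),
        )
    last = int(np.max(np.nonzero(valid)[0])) + 1
    # an interior empty interval truncates the curve there
    first_gap = np.nonzero(~valid[:last])[0]
    if len(first_gap):
        last = int(first_gap[0])
    n, d, n_eff = n[:last], d[:last], n_eff[:last]

    p = 1.0 - d / n_eff
    s = np.cumprod(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where((n_eff - d) > 0, d / (n_eff * (n_eff - d)), np.inf)
        var = s**2 * np.cumsum(terms)
    se = np.sqrt(var)
    se[~np.isfinite(se)] = 0.0  # S has hit zero: variance degenerate

    return SurvivalCurve(
        years=np.arange(1, last + 1),
        n_risk=n.astype(int),
        deaths=d.astype(int),
        s_obs=s,
        se_obs=se,
    )


def expected_survival_ederer2(
    contrib: Contributions, lifetable: LifeTable, length: int | None = None
) -> np.ndarray:
    """Cumulative expected survival, Ederer II weighting.

    For interval j the annual population survival probability of every
    patient at risk in j (attained age and calendar year at interval start,
    clamped to the life-table coverage) is averaged; the cumulative curve is
    the running product of these interval means.
    """
    J = contrib.horizon if length is None else length
    p_exp = np.ones(J)
    for jj in range(J):
        mask = contrib.at_risk[:, jj]
        if not mask.any():
            p_exp[jj] = 1.0
            continue
        p = lifetable.annual_survival(
            contrib.sex[mask], contrib.age_start[mask, jj], contrib.year_start[mask, jj]
        )
        p_exp[jj] = float(np.mean(p))
    return np.cumprod(p_exp)


def relative_survival(curve: SurvivalCurve, s_exp: np.ndarray) -> SurvivalCurve:
    """Attach expected and relative survival to an observed curve.

    RS(j) = S_obs(j)/S_exp(j); the standard error treats the expected curve
    as fixed, se_RS = se_obs / S_exp.
    """
    J = len(curve)
    s_exp = np.asarray(s_exp, dtype=float)[:J]
    rs = curve.s_obs / s_exp
    return SurvivalCurve(
        years=curve.years,
        n_risk=curve.n_risk,
        deaths=curve.deaths,
        s_obs=curve.s_obs,
        se_obs=curve.se_obs,
        s_exp=s_exp,
        rs=rs,
        se_rs=curve.se_obs / s_exp,
    )


def conditional_rs(curve: SurvivalCurve) -> np.ndarray:
    """1-year conditional relative survival, cRS(j) = RS(j)/RS(j-1), RS(0)=1."""
    if curve.rs is None:
        raise ValueError("curve carries no relative survival")
    prev = np.concatenate([[1.0], curve.rs[:-1]])
    with np.errstate(divide="ignore", invalid="ignore"):
        return curve.rs / prev


def age_standardize(
    curves: dict[str, SurvivalCurve], weights: dict[str, float]
) -> SurvivalCurve:
    """Weighted combination of per-age-group curves (ICSS standardisation).

    Curves are combined up to the shortest common follow-up; the standard
    error of the weighted sum is sqrt(Σ w² se²).
    """
    keys = list(curves)
    if set(keys) != set(weights):
        raise ValueError("need exactly one weight per age-group curve")
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    J = min(len(c) for c in curves.values())
    if J == 0:
        raise ValueError("cannot standardise empty curves")
    w = np.array([weights[k] for k in keys])
    rs = np.array([curves[k].rs[:J] for k in keys])
    se = np.array([curves[k].se_rs[:J] for k in keys])
    s_obs = np.array([curves[k].s_obs[:J] for k in keys])
    s_exp = np.array([curves[k].s_exp[:J] for k in keys])
    return SurvivalCurve(
        years=np.arange(1, J + 1),
        n_risk=np.sum([curves[k].n_risk[:J] for k in keys], axis=0),
        deaths=np.sum([curves[k].deaths[:J] for k in keys], axis=0),
        s_obs=w @ s_obs,
        se_obs=np.sqrt((w**2) @ (np.array([curves[k].se_obs[:J] for k in keys]) ** 2)),
        s_exp=w @ s_exp,
        rs=w @ rs,
        se_rs=np.sqrt((w**2) @ (se**2)),
    )


def estimate_period_rs(
    df: pd.DataFrame,
    lifetable: LifeTable,
    config: CohortConfig,
    horizon: int,
    window: PeriodWindow | None = None,
) -> SurvivalCurve:
    """Full period-analysis relative-survival estimate for one stratum."""
    window = window or PeriodWindow.from_config(config)
    contrib = period_contributions(df, window, horizon)
    obs = observed_survival(contrib)
    if len(obs) == 0:
        return obs
    s_exp = expected_survival_ederer2(contrib, lifetable, length=len(obs))
    return relative_survival(obs, s_exp)
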