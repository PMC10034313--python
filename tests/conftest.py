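import datetime as dt

import numpy as np
import pandas as pd
import pytest

from misseddeaths import CohortConfig, PatientRecord, records_to_frame
from misseddeaths.lifetable import (
    LifeTable,
    make_constant_lifetable,
    make_gompertz_lifetable,
)
from misseddeaths.relsurv import PeriodWindow


@pytest.fixture(scope="session")
def config():
    return CohortConfig()


@pytest.fixture(scope="session")
def gompertz_lt():
    return make_gompertz_lifetable()


@pytest.fixture(scope="session")
def unit_lt():
    """Degenerate life table with no background mortality."""
    return make_constant_lifetable(1.0, years=range(1990, 2020))


def constant_lt(p, years=range(1990, 2020)):
    return make_constant_lifetable(p, years=years)


@pytest.fixture(scope="session")
def wide_window():
    """Period window covering all calendar time used in the toy fixtures."""
    return PeriodWindow(dt.date(1970, 1, 1), dt.date(2030, 1, 1))


def make_patient(
    pid,
    status="alive",
    age=60,
    dx="2000-01-01",
    exit="2010-01-01",
    group="g1",
    sex="male",
    stage="missing",
    dco=False,
):
    return PatientRecord(
        patient_id=str(pid),
        diagnosis_group=group,
        sex=sex,
        age_dx=age,
        date_dx=dt.date.fromisoformat(dx),
        date_exit=dt.date.fromisoformat(exit),
        status=status,
        stage=stage,
        dco=dco,
    )


def cohort_frame(records):
    return records_to_frame(records)


@pytest.fixture
def toy3():
    """Three-person cohort for the hand-computed actuarial table.

    Same diagnosis date; one death in year 1, two within-interval
    withdrawals in year 2.
    """
    return cohort_frame(
        [
            make_patient("a", status="dead", dx="2000-01-01", exit="2000-07-01"),
            make_patient("b", status="alive", dx="2000-01-01", exit="2001-07-01"),
            make_patient("c", status="alive", dx="2000-01-01", exit="2001-12-31"),
        ]
    )


def brute_force_actuarial(df, window, horizon):
    """Independent per-person actuarial life table with delayed entry.

    Pure-python loop over persons and intervals; the oracle for the
    vectorised period estimator.  Withdrawals and late entrants weighted 1/2.
    """
    days_per_year = 365.25
    rows = []
    for _, r in df.iterrows():
        fu = (pd.Timestamp(r["date_exit"]) - pd.Timestamp(r["date_dx"])).days / days_per_year
        t_entry = (pd.Timestamp(window.start) - pd.Timestamp(r["date_dx"])).days / days_per_year
        t_end = (pd.Timestamp(window.end) - pd.Timestamp(r["date_dx"])).days / days_per_year
        rows.append((fu, r["status"] == "dead", t_entry, t_end))
    n = np.zeros(horizon)
    d = np.zeros(horizon)
    w = np.zeros(horizon)
    late = np.zeros(horizon)
    for fu, dead, t_entry, t_end in rows:
        for j in range(1, horizon + 1):
            entry = max(j - 1, t_entry)
            exit_ = min(j, fu, t_end)
            if exit_ <= entry:
                continue
            n[j - 1] += 1
            died_here = dead and entry < fu <= j and fu <= t_end
            if died_here:
                d[j - 1] += 1
            elif exit_ < j:
                w[j - 1] += 1
            if entry > j - 1:
                late[j - 1] += 1
    n_eff = n - 0.5 * w - 0.5 * late
    p = np.ones(horizon)
    mask = n_eff > 0
    p[mask] = 1.0 - d[mask] / n_eff[mask]
    return n, d, n_eff, np.cumprod(p)
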