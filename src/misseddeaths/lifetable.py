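"""Population life tables: annual survival by sex, single age and calendar year.

Expected ("background") survival is looked up from a period life table with
annual survival probabilities p(sex, age, year) = 1 - q(sex, age, year).
Ages above the table maximum reuse the oldest-age value; calendar years
outside the table's coverage are clamped to the nearest available year, so
diagnoses predating the life-table series still receive a well-defined
expected survival.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["LifeTable", "read_lifetable", "read_hmd", "make_gompertz_lifetable"]

MAX_AGE = 99


class LifeTable:
    """Annual population survival probabilities on a (sex, age, year) grid.

    Internally a dense ``(age, year)`` array per sex for O(1) vectorised
    lookups.  Construct from a long DataFrame with columns
    ``sex, age, year, px`` (annual survival, in (0, 1]).
    """

    def __init__(self, data: pd.DataFrame):
        required = {"sex", "age", "year", "px"}
        if not required.issubset(data.columns):
            raise ValueError(f"life table needs columns {sorted(required)}")
        px = data["px"].to_numpy(dtype=float)
        if np.any((px <= 0) | (px > 1)):
            raise ValueError("annual survival probabilities must lie in (0, 1]")
        self._grids: dict[str, np.ndarray] = {}
        years = np.sort(data["year"].unique()).astype(int)
        self.year_min, self.year_max = int(years[0]), int(years[-1])
        self.age_max = int(data["age"].max())
        for sex, sub in data.groupby("sex"):
            ages = np.sort(sub["age"].unique())
            if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
                raise ValueError(f"ages not contiguous for sex={sex!r}")
            grid = (
                sub.pivot_table(index="age", columns="year", values="px")
                .reindex(index=np.arange(0, self.age_max + 1))
                .reindex(columns=np.arange(self.year_min, self.year_max + 1))
            )
            if grid.isna().any().any():
                # ages below the table minimum or missing years: fill from
                # nearest available cell (age upward/downward, year sideways)
                grid = grid.ffill(axis=0).bfill(axis=0).ffill(axis=1).bfill(axis=1)
            self._grids[str(sex)] = grid.to_numpy(dtype=float)

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(self._grids)

    def annual_survival(self, sex, age, year):
        """p(sex, age, year); vectorised over ``age`` and ``year``.

        Ages above the table maximum use the oldest tabulated age; calendar
        years outside coverage use the nearest covered year.
        """
        if isinstance(sex, str):
            grid = self._grids.get(sex)
            if grid is None:
                raise KeyError(f"sex {sex!r} not in life table (have {self.sexes})")
            age_i = np.clip(np.asarray(age, dtype=int), 0, self.age_max)
            year_i = np.clip(np.asarray(year, dtype=int), self.year_min, self.year_max)
            return grid[age_i, year_i - self.year_min]
        # heterogeneous sexes: elementwise
        sex_a, age_a, year_a = np.broadcast_arrays(
            np.asarray(sex, dtype=object), np.asarray(age), np.asarray(year)
        )
        out = np.empty(sex_a.shape, dtype=float)
        for s in np.unique(sex_a):
            m = sex_a == s
            out[m] = self.annual_survival(str(s), age_a[m], year_a[m])
        return out

    def expected_curve(self, sex: str, start_age: int, start_year: int, horizon: int):
        """Cumulative expected survival over ``horizon`` annual intervals.

        Element ``k`` (0-based) is the probability of surviving ``k + 1``
        years from (``start_age``, ``start_year``), i.e. the product of
        annual survival probabilities with age and calendar year advancing
        together.
        """
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        k = np.arange(horizon)
        p = self.annual_survival(sex, start_age + k, start_year + k)
        return np.cumprod(p)


def read_lifetable(path) -> LifeTable:
    """Read a long-format life-table CSV with columns sex, age, year, px."""
    df = pd.read_csv(path)
    return LifeTable(df)


def read_hmd(path, sex_map: dict | None = None) -> LifeTable:
    """Read a Human-Mortality-Database-style period table (Year, Age, qx).

    Accepts either a per-sex file with columns ``Year, Age, qx`` plus a
    ``sex`` column, or whitespace-delimited HMD text.  Stores px = 1 - qx.
    ``Age`` entries like ``"110+"`` are truncated to their numeric part.
    """
    try:
        df = pd.read_csv(path)
        if not {"Year", "Age", "qx"}.issubset(df.columns):
            raise ValueError
    except ValueError:
        df = pd.read_csv(path, sep=r"\s+", skiprows=2)
    if "sex" not in df.columns:
        raise ValueError("HMD reader requires a 'sex' column (male/female)")
    if sex_map:
        df["sex"] = df["sex"].map(lambda s: sex_map.get(s, s))
    age = df["Age"].astype(str).str.replace("+", "", regex=False).astype(int)
    qx = pd.to_numeric(df["qx"], errors="coerce")
    out = pd.DataFrame(
        {
            "sex": df["sex"],
            "age": age,
            "year": df["Year"].astype(int),
            "px": 1.0 - qx,
        }
    ).dropna()
    out = out[out["px"] > 0]
    return LifeTable(out)


def make_constant_lifetable(
    p: float = 1.0,
    years: Iterable[int] = (2000,),
    sexes: Iterable[str] = ("male", "female"),
    age_max: int = MAX_AGE,
) -> LifeTable:
    """Degenerate table with the same annual survival everywhere (testing aid)."""
    rows = [
        {"sex": s, "age": a, "year": y, "px": p}
        for s in sexes
        for y in years
        for a in range(age_max + 1)
    ]
    return LifeTable(pd.DataFrame(rows))


def make_gompertz_lifetable(
    years: Iterable[int] = range(1993, 2017),
    a_male: float = 3.0e-5,
    a_female: float = 1.6e-5,
    b: float = 0.095,
    q_cap: float = 0.7,
    age_max: int = MAX_AGE,
) -> LifeTable:
    """Synthetic all-cause life table with Gompertz mortality q(x) = A·e^(B·x).

    A stylised stand-in for national period life tables: exponential rise of
    the annual death probability with age, capped at ``q_cap``, constant over
    calendar years.  Defaults give q(70) ≈ 2.3 % (men) and a remaining life
    expectancy in the range typical of high-income countries.
    """
    ages = np.arange(age_max + 1)
    frames = []
    for sex, a_coef in (("male", a_male), ("female", a_female)):
        q = np.minimum(q_cap, a_coef * np.exp(b * ages))
        for y in years:
            frames.append(
                pd.DataFrame({"sex": sex, "age": ages, "year": int(y), "px": 1.0 - q})
            )
    return LifeTable(pd.concat(frames, ignore_index=True))
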