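"""Registry cohort container, I/O and data-preparation filters.

A cohort is a :class:`pandas.DataFrame` with one row per registered case and
the canonical columns

``patient_id, diagnosis_group, sex, age_dx, date_dx, date_exit, status,
stage, dco, registry``

plus the derived follow-up columns ``fu_time`` (years from diagnosis to exit,
day-level precision) and ``fu_age`` (age at exit).  :func:`read_patients`
builds such a frame from a delimited text export, rejecting rows that violate
the record invariants with row-level diagnostics; :func:`prepare_cohort`
applies the standard survival-analysis filters (DCO/autopsy exclusion, last
primary only, adult ages, horizon truncation).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import CohortConfig

__all__ = [
    "COLUMNS",
    "PatientRecord",
    "ReadReport",
    "read_patients",
    "write_patients",
    "records_to_frame",
    "add_followup_columns",
    "prepare_cohort",
]

COLUMNS = (
    "patient_id",
    "diagnosis_group",
    "sex",
    "age_dx",
    "date_dx",
    "date_exit",
    "status",
    "stage",
    "dco",
    "registry",
)

DAYS_PER_YEAR = 365.25

_SEXES = {"male", "female"}
_STATUSES = {"dead", "alive"}
_TRUTHY = {"1", "true", "yes", "t", "y"}
_FALSY = {"0", "false", "no", "f", "n", ""}


@dataclasses.dataclass(frozen=True)
class PatientRecord:
    """A single registry case; mainly a construction/round-trip convenience.

    The vectorised pipeline operates on DataFrames, but a frozen dataclass
    gives tests and callers an explicit, validated row type.
    """

    patient_id: str
    diagnosis_group: str
    sex: str
    age_dx: int
    date_dx: dt.date
    date_exit: dt.date
    status: str
    stage: str = "missing"
    dco: bool = False
    registry: str = ""

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.status not in _STATUSES:
            raise ValueError(f"status must be one of {_STATUSES}")
        if self.date_exit < self.date_dx:
            raise ValueError("exit date precedes diagnosis date")
        if self.age_dx < 15:
            raise ValueError("age at diagnosis below 15")

    @property
    def fu_time(self) -> float:
        return (self.date_exit - self.date_dx).days / DAYS_PER_YEAR

    @property
    def fu_age(self) -> float:
        return self.age_dx + self.fu_time


@dataclasses.dataclass
class ReadReport:
    """Outcome of :func:`read_patients`: accepted rows and rejected rows."""

    n_read: int
    n_accepted: int
    row_errors: list[tuple[int, str]]

    @property
    def n_rejected(self) -> int:
        return len(self.row_errors)


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Build a cohort frame from :class:`PatientRecord` objects."""
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    df["age_dx"] = df["age_dx"].astype(int) if len(df) else df["age_dx"]
    df["date_dx"] = pd.to_datetime(df["date_dx"])
    df["date_exit"] = pd.to_datetime(df["date_exit"])
    df["dco"] = df["dco"].astype(bool) if len(df) else df["dco"]
    return add_followup_columns(df)


def add_followup_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Attach/refresh the derived ``fu_time`` and ``fu_age`` columns."""
    df = df.copy()
    days = (df["date_exit"] - df["date_dx"]).dt.days.astype(float)
    df["fu_time"] = days / DAYS_PER_YEAR
    df["fu_age"] = df["age_dx"] + df["fu_time"]
    return df


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"not a boolean flag: {value!r}")


def read_patients(
    path,
    schema: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> tuple[pd.DataFrame, ReadReport]:
    """Read a delimited patient file into a validated cohort frame.

    Parameters
    ----------
    path : path-like
        CSV/TSV file with a header row; dates ISO-8601.
    schema : mapping, optional
        Maps canonical column names (:data:`COLUMNS`) to the file's column
        names, so differently-labelled registry exports can be ingested
        without code changes.  Canonical names are used where omitted.
    sep : str, optional
        Field separator; inferred from the file extension by default.

    Returns
    -------
    (frame, report)
        ``frame`` holds the accepted records with derived follow-up columns;
        ``report`` lists rejected rows as ``(row_number, reason)`` pairs
        (row numbers are 1-based data rows).

    Raises
    ------
    ValueError
        If a mandatory column is absent from the file (configuration error,
        as opposed to recoverable row errors).
    """
    schema = dict(schema or {})
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    colmap = {canon: schema.get(canon, canon) for canon in COLUMNS}
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")

    errors: list[tuple[int, str]] = []
    rows = []
    for i, row in enumerate(raw.itertuples(index=False), start=1):
        vals = {canon: getattr(row, colmap[canon]) for canon in COLUMNS}
        try:
            rec = PatientRecord(
                patient_id=str(vals["patient_id"]),
                diagnosis_group=str(vals["diagnosis_group"]),
                sex=str(vals["sex"]).strip().lower(),
                age_dx=int(vals["age_dx"]),
                date_dx=dt.date.fromisoformat(str(vals["date_dx"]).strip()),
                date_exit=dt.date.fromisoformat(str(vals["date_exit"]).strip()),
                status=str(vals["status"]).strip().lower(),
                stage=str(vals["stage"]) or "missing",
                dco=_parse_bool(vals["dco"]),
                registry=str(vals["registry"]),
            )
        except (ValueError, TypeError) as exc:
            errors.append((i, str(exc)))
            continue
        rows.append(rec)

    frame = records_to_frame(rows)
    report = ReadReport(n_read=len(raw), n_accepted=len(rows), row_errors=errors)
    return frame, report


def write_patients(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a cohort frame back to delimited text (ISO dates, 0/1 flags)."""
    out = df.loc[:, list(COLUMNS)].copy()
    out["date_dx"] = pd.to_datetime(out["date_dx"]).dt.strftime("%Y-%m-%d")
    out["date_exit"] = pd.to_datetime(out["date_exit"]).dt.strftime("%Y-%m-%d")
    out["dco"] = out["dco"].astype(int)
    out.to_csv(path, sep=sep, index=False)


def prepare_cohort(df: pd.DataFrame, config: CohortConfig | None = None) -> pd.DataFrame:
    """Apply the survival-analysis preparation filters.

    In order: drop death-certificate-only/autopsy cases; for patients with
    multiple primaries keep only the record with the latest diagnosis date;
    drop ages below 15; administratively censor follow-up at the horizon for
    the patient's age group (35 years if diagnosed before age 55, 30 years
    otherwise) — a record truncated before its death becomes a censored
    (alive) record.  Idempotent.
    """
    import warnings

    config = config or CohortConfig()
    df = df.copy()

    df = df.loc[~df["dco"].astype(bool)]
    # last primary per patient: keep the latest diagnosis date (stable on ties)
    order = df.assign(_ord=np.arange(len(df)))
    order = order.sort_values(["date_dx", "_ord"], kind="stable")
    df = order.drop_duplicates("patient_id", keep="last").drop(columns="_ord")
    df = df.loc[df["age_dx"] >= config.age_group_breaks[0]]
    df = df.sort_index()

    max_fu = np.where(
        df["age_dx"] < config.age_group_breaks[1],
        config.max_follow_up_young,
        config.max_follow_up_old,
    )
    df = add_followup_columns(df)
    over = df["fu_time"].to_numpy() > max_fu
    if over.any():
        trunc_days = np.floor(max_fu * DAYS_PER_YEAR).astype("timedelta64[D]")
        new_exit = df["date_dx"].to_numpy() + trunc_days
        df.loc[over, "date_exit"] = new_exit[over]
        df.loc[over, "status"] = "alive"
        df = add_followup_columns(df)

    if len(df) == 0:
        warnings.warn("prepared cohort is empty", stacklevel=2)
    return df.reset_index(drop=True)
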