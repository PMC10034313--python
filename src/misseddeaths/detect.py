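"""Iterative missed-death classification.

Registry patients whose death was never linked back to their record (failed
linkage, unregistered emigration) appear as immortal long-term survivors and
inflate long-term relative survival beyond 100 %.  The detector exploits a
simple observation: because alive patients are censored at follow-up end,
the longest follow-up times and highest attained ages in a homogeneous
stratum should belong to *deceased* patients.  Within each stratum:

1.  Relative survival is estimated by period analysis.  If the curve neither
    exceeds population survival nor rises again after its minimum, nothing
    is done.
2.  Deceased patients with both follow-up time and age at exit at or above a
    high percentile (start 99.9) are labelled outliers, and a logistic
    regression  logit P(outlier) = b0 + b1·fu_age + b2·fu_time  is fitted on
    the deceased.  The fit is applied to the alive patients; those with
    predicted probability >= 90 % are classified as missed deaths and
    excluded, and the survival estimate is repeated with the percentile
    lowered by 0.5 points per iteration until the curve looks regular.
3.  Strata with few deaths (< 10 %), a non-significant regression, or an
    implausibly large flag set (> 5 % of deaths) instead rank the alive
    patients by the Euclidean norm sqrt(fu_age^2 + fu_time^2) and flag the
    top tail, with the same percentile schedule and the same 5 % cap.

All flag sets are cumulative across iterations, never contain deceased
patients, and never exceed 5 % of the stratum's deaths at return.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .config import CohortConfig
from .lifetable import LifeTable
from .relsurv import PeriodWindow, SurvivalCurve, estimate_period_rs
from .stratify import Stratum

__all__ = [
    "LogitModel",
    "StratumResult",
    "ZeroEventsError",
    "flag_outlier_deaths",
    "fit_outlier_logit",
    "predict_missed",
    "score_records",
    "classify_by_score",
    "rs_exceeds_population",
    "rs_increases_after_min",
    "run_stratum",
]


class ZeroEventsError(ValueError):
    """The outlier definition produced no events (or no non-events)."""


@dataclasses.dataclass
class LogitModel:
    """Fitted outlier regression logit P = b0 + b1·fu_age + b2·fu_time."""

    beta0: float
    beta1: float
    beta2: float
    se1: float
    se2: float
    p1: float
    p2: float
    converged: bool

    def significant(self, alpha: float) -> bool:
        return min(self.p1, self.p2) < alpha

    def predict(self, fu_age, fu_time) -> np.ndarray:
        eta = self.beta0 + self.beta1 * np.asarray(fu_age) + self.beta2 * np.asarray(
            fu_time
        )
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-eta))


@dataclasses.dataclass
class IterationRecord:
    percentile: float
    n_outlier_events: int
    n_flagged: int
    stop_reason: str


@dataclasses.dataclass
class StratumResult:
    key: tuple
    flagged_ids: set
    classifier: str  # "logit" | "score" | "none"
    iterations: list[IterationRecord]
    initial_curve: SurvivalCurve | None
    final_curve: SurvivalCurve | None
    n_patients: int
    n_deaths: int

    @property
    def n_flagged(self) -> int:
        return len(self.flagged_ids)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "percentile": [it.percentile for it in self.iterations],
                "n_outlier_events": [it.n_outlier_events for it in self.iterations],
                "n_flagged": [it.n_flagged for it in self.iterations],
                "stop_reason": [it.stop_reason for it in self.iterations],
            }
        )


# ---------------------------------------------------------------------------
# classifier primitives
# ---------------------------------------------------------------------------


def _quantile(x: np.ndarray, percentile: float) -> float:
    return float(np.percentile(x, percentile, method="linear"))


def flag_outlier_deaths(deaths: pd.DataFrame, percentile: float) -> np.ndarray:
    """Outlier deaths: follow-up time AND age at exit both at/above the
    marginal percentile among the deceased (inclusive at the threshold)."""
    if len(deaths) < 2:
        raise ValueError("need at least 2 deceased records to define outliers")
    fu_time = deaths["fu_time"].to_numpy(dtype=float)
    fu_age = deaths["fu_age"].to_numpy(dtype=float)
    qt = _quantile(fu_time, percentile)
    qa = _quantile(fu_age, percentile)
    return (fu_time >= qt) & (fu_age >= qa)


def fit_outlier_logit(deaths: pd.DataFrame, outlier_flags: np.ndarray) -> LogitModel:
    """Maximum-likelihood fit of the outlier regression on deceased patients.

    Raises :class:`ZeroEventsError` when the flags contain no event (or no
    non-event); returns ``converged=False`` on non-convergence or complete /
    quasi-complete separation.
    """
    y = np.asarray(outlier_flags, dtype=float)
    n_events = int(y.sum())
    if n_events == 0 or n_events == len(y):
        raise ZeroEventsError(f"{n_events} outlier events among {len(y)} deaths")
    X = sm.add_constant(
        deaths[["fu_age", "fu_time"]].to_numpy(dtype=float), has_constant="add"
    )
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(
                method="newton", maxiter=100, tol=1e-8, disp=False, warn_convergence=False
            )
        params, bse, pvalues = fit.params, fit.bse, fit.pvalues
        converged = bool(fit.mle_retvals.get("converged", False))
    except (np.linalg.LinAlgError, Exception):
        return LogitModel(0.0, 0.0, 0.0, np.inf, np.inf, 1.0, 1.0, converged=False)
    # separation shows up as exploding coefficients or standard errors
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse)):
        converged = False
    elif np.max(np.abs(params[1:])) > 1e3 or np.max(bse) > 1e4:
        converged = False
    p1 = float(pvalues[1]) if np.isfinite(pvalues[1]) else 1.0
    p2 = float(pvalues[2]) if np.isfinite(pvalues[2]) else 1.0
    return LogitModel(
        beta0=float(params[0]),
        beta1=float(params[1]),
        beta2=float(params[2]),
        se1=float(bse[1]),
        se2=float(bse[2]),
        p1=p1,
        p2=p2,
        converged=converged,
    )


def predict_missed(model: LogitModel, alive: pd.DataFrame, cutoff: float) -> set:
    """Ids of alive records with predicted missed-death probability >= cutoff."""
    if not model.converged:
        raise ValueError("cannot predict from a non-converged model")
    p = model.predict(
        alive["fu_age"].to_numpy(dtype=float), alive["fu_time"].to_numpy(dtype=float)
    )
    return set(alive.loc[p >= cutoff, "patient_id"])


def score_records(alive: pd.DataFrame) -> np.ndarray:
    """Euclidean norm sqrt(fu_age^2 + fu_time^2) of the alive records."""
    return np.hypot(
        alive["fu_age"].to_numpy(dtype=float), alive["fu_time"].to_numpy(dtype=float)
    )


def classify_by_score(alive: pd.DataFrame, percentile: float) -> set:
    """Ids of alive records whose score is at/above the given percentile
    (computed among the alive records themselves; ties included)."""
    if len(alive) == 0:
        return set()
    scores = score_records(alive)
    q = _quantile(scores, percentile)
    return set(alive.loc[scores >= q, "patient_id"])


# ---------------------------------------------------------------------------
# curve tests
# ---------------------------------------------------------------------------


def rs_exceeds_population(curve: SurvivalCurve, config: CohortConfig) -> bool:
    """True iff relative survival significantly exceeds 100 % somewhere
    (one-sided z-test at level alpha on any follow-up year)."""
    if curve is None or curve.rs is None or len(curve) == 0:
        return False
    z = norm.ppf(1.0 - config.alpha)
    return bool(np.any(curve.rs - z * curve.se_rs > 1.0))


def rs_increases_after_min(curve: SurvivalCurve, config: CohortConfig) -> bool:
    """True iff the curve rises significantly after its minimum: with
    j* = argmin RS, the one-sided z-test on RS(J) - RS(j*) at level alpha."""
    if curve is None or curve.rs is None or len(curve) < 2:
        return False
    z = norm.ppf(1.0 - config.alpha)
    j_star = int(np.argmin(curve.rs))
    if j_star == len(curve) - 1:
        return False
    diff = curve.rs[-1] - curve.rs[j_star]
    se = np.hypot(curve.se_rs[-1], curve.se_rs[j_star])
    return bool(diff > z * se)


def _needs_correction(curve: SurvivalCurve, config: CohortConfig) -> bool:
    return rs_exceeds_population(curve, config) or rs_increases_after_min(curve, config)


# ---------------------------------------------------------------------------
# per-stratum control flow
# ---------------------------------------------------------------------------


def run_stratum(
    stratum: Stratum,
    lifetable: LifeTable,
    config: CohortConfig | None = None,
    window: PeriodWindow | None = None,
) -> StratumResult:
    """Run the full detection loop on one stratum.

    Returns the cumulative flag set (ids of alive records classified as
    missed deaths), the classifier that produced it, the per-iteration trace
    and the relative-survival curves before and after exclusion.
    """
    config = config or CohortConfig()
    window = window or PeriodWindow.from_config(config)
    records = stratum.records
    horizon = config.horizon_for(
        config.age_group_breaks[1] - 1
        if stratum.age_group == config.age_group_labels[0]
        else config.age_group_breaks[1]
    )

    deaths = records.loc[records["status"] == "dead"]
    alive = records.loc[records["status"] == "alive"]
    n_deaths = len(deaths)
    cap = config.max_missed_fraction_of_deaths * n_deaths

    def estimate(excluded: set) -> SurvivalCurve:
        if excluded:
            sub = records.loc[~records["patient_id"].isin(excluded)]
        else:
            sub = records
        return estimate_period_rs(sub, lifetable, config, horizon, window)

    def result(flags, classifier, iterations, curve0, curve):
        return StratumResult(
            key=stratum.key,
            flagged_ids=set(flags),
            classifier=classifier,
            iterations=iterations,
            initial_curve=curve0,
            final_curve=curve,
            n_patients=stratum.n_patients,
            n_deaths=n_deaths,
        )

    iterations: list[IterationRecord] = []
    curve0 = estimate(set()) if len(records) else None

    if n_deaths == 0 or len(records) == 0:
        return result(set(), "none", iterations, curve0, curve0)
    if not _needs_correction(curve0, config):
        return result(set(), "none", iterations, curve0, curve0)

    use_score = stratum.death_fraction < config.min_death_fraction_for_logit
    flags: set = set()
    percentile = config.outlier_start_percentile
    curve = curve0

    if not use_score and n_deaths >= 2:
        while percentile >= config.percentile_floor:
            # convergence sub-loop: lower by 0.05 until the regression has
            # events and converges
            model = None
            n_events = 0
            while percentile >= config.percentile_floor:
                out = flag_outlier_deaths(deaths, percentile)
                n_events = int(out.sum())
                try:
                    model = fit_outlier_logit(deaths, out)
                except ZeroEventsError:
                    model = None
                if model is not None and model.converged:
                    break
                percentile = round(percentile - config.percentile_step_converge, 6)
            if model is None or not model.converged:
                iterations.append(
                    IterationRecord(percentile, n_events, len(flags), "floor")
                )
                return result(flags, "logit", iterations, curve0, curve)
            if not model.significant(config.alpha):
                iterations.append(
                    IterationRecord(
                        percentile, n_events, len(flags), "not_significant->score"
                    )
                )
                use_score = True
                break
            remaining_alive = alive.loc[~alive["patient_id"].isin(flags)]
            new = predict_missed(model, remaining_alive, config.prob_cutoff)
            candidate = flags | new
            if len(candidate) > cap:
                iterations.append(
                    IterationRecord(percentile, n_events, len(flags), "cap->score")
                )
                use_score = True
                break
            if new:
                flags = candidate
                curve = estimate(flags)
            iterations.append(IterationRecord(percentile, n_events, len(flags), ""))
            if not _needs_correction(curve, config):
                iterations[-1].stop_reason = "rs_ok"
                return result(flags, "logit", iterations, curve0, curve)
            percentile = round(percentile - config.percentile_step_iterate, 6)
        else:
            iterations.append(IterationRecord(percentile, 0, len(flags), "floor"))
            return result(flags, "logit", iterations, curve0, curve)

    # scoring path (chosen directly, or fallen back to); flags restart
    flags = set()
    curve = curve0
    percentile = config.outlier_start_percentile
    while percentile >= config.percentile_floor:
        remaining_alive = alive.loc[~alive["patient_id"].isin(flags)]
        new = classify_by_score(remaining_alive, percentile)
        candidate = flags | new
        if len(candidate) > cap:
            iterations.append(IterationRecord(percentile, 0, len(flags), "cap"))
            return result(flags, "score", iterations, curve0, curve)
        if new:
            flags = candidate
            curve = estimate(flags)
        iterations.append(IterationRecord(percentile, 0, len(flags), ""))
        if not _needs_correction(curve, config):
            iterations[-1].stop_reason = "rs_ok"
            return result(flags, "score", iterations, curve0, curve)
        percentile = round(percentile - config.percentile_step_iterate, 6)
    iterations.append(IterationRecord(percentile, 0, len(flags), "floor"))
    return result(flags, "score", iterations, curve0, curve)
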