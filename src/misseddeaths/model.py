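"""Model/Results facade over the detection pipeline.

:class:`MissedDeathModel` is constructed from a patient cohort, a population
life table and a configuration; :meth:`MissedDeathModel.fit` runs
preparation → stratification → per-stratum detection and returns a
:class:`DetectionResults` carrying the flag sets, iteration traces,
before/after survival curves and tabular summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CohortConfig
from .detect import StratumResult, run_stratum
from .lifetable import LifeTable, read_lifetable
from .registry import prepare_cohort, read_patients
from .relsurv import SurvivalCurve, age_standardize
from .report import GroupSummary, aggregate_groups
from .stratify import Stratum, build_strata, strata_summary

__all__ = ["MissedDeathModel", "DetectionResults"]


class MissedDeathModel:
    """Missed-death detection model for a registry cohort.

    Parameters
    ----------
    patients : pandas.DataFrame
        Cohort frame with the canonical registry columns (see
        :mod:`misseddeaths.registry`).  Preparation filters are applied at
        construction unless ``prepared=True``.
    lifetable : LifeTable
        Population annual survival probabilities.
    config : CohortConfig, optional
        Algorithm constants; defaults are the published calibration.
    """

    def __init__(
        self,
        patients: pd.DataFrame,
        lifetable: LifeTable,
        config: CohortConfig | None = None,
        prepared: bool = False,
    ):
        self.config = config or CohortConfig()
        self.lifetable = lifetable
        self.cohort = patients if prepared else prepare_cohort(patients, self.config)
        self.strata: list[Stratum] = build_strata(self.cohort, self.config)

    @classmethod
    def from_files(
        cls,
        patients_path,
        lifetable_path,
        config: CohortConfig | None = None,
        schema=None,
    ) -> "MissedDeathModel":
        patients, report = read_patients(patients_path, schema=schema)
        if report.n_rejected:
            import warnings

            warnings.warn(
                f"{report.n_rejected} of {report.n_read} rows rejected on read",
                stacklevel=2,
            )
        return cls(patients, read_lifetable(lifetable_path), config)

    def fit(self, verbose: bool = False) -> "DetectionResults":
        """Run the detection loop in every stratum."""
        results = []
        for stratum in self.strata:
            res = run_stratum(stratum, self.lifetable, self.config)
            results.append(res)
            if verbose:
                print(
                    f"{stratum.key}: classifier={res.classifier} "
                    f"flags={res.n_flagged}/{res.n_deaths} deaths"
                )
        return DetectionResults(self, results)


class DetectionResults:
    """Fitted detection results: flags, traces, curves and summaries."""

    def __init__(self, model: MissedDeathModel, stratum_results: list[StratumResult]):
        self.model = model
        self.stratum_results = stratum_results

    @property
    def flagged_ids(self) -> set:
        out: set = set()
        for r in self.stratum_results:
            out |= r.flagged_ids
        return out

    @property
    def n_flagged(self) -> int:
        return len(self.flagged_ids)

    def corrected_cohort(self) -> pd.DataFrame:
        """The cohort with flagged records excluded."""
        flags = self.flagged_ids
        return self.model.cohort.loc[~self.model.cohort["patient_id"].isin(flags)]

    def stratum_table(self) -> pd.DataFrame:
        base = strata_summary(self.model.strata)
        base["classifier"] = [r.classifier for r in self.stratum_results]
        base["n_flagged"] = [r.n_flagged for r in self.stratum_results]
        base["n_iterations"] = [len(r.iterations) for r in self.stratum_results]
        return base

    def group_summaries(self) -> list[GroupSummary]:
        tab = self.stratum_table()
        out = []
        for dg, sub in tab.groupby("diagnosis_group", sort=True):
            out.append(
                GroupSummary(
                    diagnosis_group=str(dg),
                    n_patients=int(sub["n_patients"].sum()),
                    n_deaths=int(sub["n_deaths"].sum()),
                    n_missed=int(sub["n_flagged"].sum()),
                )
            )
        return out

    def group_table(self) -> pd.DataFrame:
        rows = [
            {
                "diagnosis_group": g.diagnosis_group,
                "n_patients": g.n_patients,
                "n_deaths": g.n_deaths,
                "n_missed": g.n_missed,
                "pct_missed_of_deaths": g.pct_missed_of_deaths,
            }
            for g in self.group_summaries()
        ]
        return pd.DataFrame(rows)

    def totals(self) -> dict:
        return aggregate_groups(self.group_summaries())

    def standardized_curve(
        self, diagnosis_group: str, sex: str, corrected: bool = True
    ) -> SurvivalCurve | None:
        """ICSS age-standardised relative survival for one diagnosis/sex.

        Uses the per-age-group final (corrected) or initial curves, pooling
        stage strata is not attempted: requires unsplit (all-stages) strata
        for each of the three age groups.
        """
        cfg = self.model.config
        labels = cfg.age_group_labels
        curves = {}
        for stratum, res in zip(self.model.strata, self.stratum_results):
            if stratum.diagnosis_group != diagnosis_group or stratum.sex != sex:
                continue
            curve = res.final_curve if corrected else res.initial_curve
            if curve is not None and curve.rs is not None and len(curve):
                curves[stratum.age_group] = curve
        if set(curves) != set(labels):
            return None
        weights = dict(zip(labels, cfg.icss_weights))
        return age_standardize(curves, weights)

    def summary(self) -> str:
        """Human-readable run summary."""
        tot = self.totals()
        tab = self.stratum_table()
        by_cls = tab["classifier"].value_counts().to_dict()
        lines = [
            "Missed-death detection results",
            "=" * 34,
            f"strata analysed:        {len(self.stratum_results)}",
            f"  logistic classifier:  {by_cls.get('logit', 0)}",
            f"  scoring fallback:     {by_cls.get('score', 0)}",
            f"  no correction needed: {by_cls.get('none', 0)}",
            f"patients:               {tot['n_patients']:,}",
            f"deaths:                 {tot['n_deaths']:,}",
            f"classified missed:      {tot['n_missed']:,}"
            f" ({tot['pct_missed_of_deaths']:.2f}% of deaths)",
            "",
            "Per-group counts:",
            self.group_table().to_string(index=False),
        ]
        return "\n".join(lines)

    def flags_frame(self) -> pd.DataFrame:
        """One row per flagged patient: id, stratum key, classifier."""
        rows = []
        for r in self.stratum_results:
            for pid in sorted(r.flagged_ids):
                rows.append(
                    {
                        "patient_id": pid,
                        "diagnosis_group": r.key[0],
                        "sex": r.key[1],
                        "age_group": r.key[2],
                        "stage": r.key[3],
                        "classifier": r.classifier,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "patient_id",
                "diagnosis_group",
                "sex",
                "age_group",
                "stage",
                "classifier",
            ],
        )

    def plot_curves(self, stratum_index: int = 0, ax=None):
        """Before/after relative-survival curves for one stratum."""
        import matplotlib.pyplot as plt

        res = self.stratum_results[stratum_index]
        if ax is None:
            _, ax = plt.subplots()
        for label, curve in (
            ("before exclusion", res.initial_curve),
            ("after exclusion", res.final_curve),
        ):
            if curve is not None and curve.rs is not None:
                ax.plot(curve.years, curve.rs_percent, marker="o", label=label)
        ax.axhline(100.0, color="grey", ls="--", lw=0.8)
        ax.set_xlabel("follow-up year")
        ax.set_ylabel("relative survival [%]")
        ax.set_title(" / ".join(map(str, res.key)))
        ax.legend()
        return ax
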