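"""Cohort-level evaluation of score models: discrimination and calibration.

:class:`ScoreEvaluation` is the validation counterpart of
:class:`~cesofa.derivation.ScoreDerivation`: point it at a cohort and one or
two score models and ``fit`` returns an :class:`EvalReport` holding AUCs with
DeLong confidence intervals, the paired DeLong comparison, the category-free
NRI, and a quintile calibration table with the Hosmer-Lemeshow test.

Predicted mortality probabilities for the NRI and the calibration analysis
come from a univariable logistic re-fit of the outcome on each composite
score within the evaluated cohort (scores are points, not probabilities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort
from .evalstats import (
    AucResult,
    CalibrationResult,
    NriResult,
    RocComparison,
    auc,
    delong_test,
    fit_logistic,
    hosmer_lemeshow,
    nri,
)
from .scoring import ScoreModel, score_cohort

__all__ = ["ScoreEvaluation", "EvalReport", "plot_calibration"]


def _score_probability(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones_like(scores, dtype=float), scores.astype(float)])
    return fit_logistic(design, y, names=["intercept", "score"]).fitted


class ScoreEvaluation:
    """Evaluate ``model`` (vs an optional ``baseline``) on a cohort."""

    def __init__(
        self,
        cohort: Cohort,
        model: ScoreModel,
        baseline: ScoreModel | None = None,
        n_calibration_groups: int = 5,
    ):
        if len(cohort) == 0:
            raise ValueError("empty cohort")
        self.cohort = cohort
        self.model = model
        self.baseline = baseline
        self.n_calibration_groups = n_calibration_groups

    def fit(self) -> "EvalReport":
        y = self.cohort.outcome
        scores = score_cohort(self.cohort, self.model)
        model_auc = auc(scores, y)
        prob = _score_probability(scores, y)
        calibration = hosmer_lemeshow(prob, y, n_groups=self.n_calibration_groups)

        baseline_auc = comparison = reclassification = None
        if self.baseline is not None:
            base_scores = score_cohort(self.cohort, self.baseline)
            baseline_auc = auc(base_scores, y)
            comparison = delong_test(scores, base_scores, y)
            reclassification = nri(_score_probability(base_scores, y), prob, y)

        return EvalReport(
            cohort_label=self.cohort.label,
            n=len(self.cohort),
            mortality=self.cohort.mortality,
            model_name=self.model.name,
            model_auc=model_auc,
            baseline_name=self.baseline.name if self.baseline else None,
            baseline_auc=baseline_auc,
            delong=comparison,
            nri=reclassification,
            calibration=calibration,
        )


@dataclass
class EvalReport:
    """Discrimination + calibration report for one model on one cohort."""

    cohort_label: str
    n: int
    mortality: float
    model_name: str
    model_auc: AucResult
    baseline_name: str | None
    baseline_auc: AucResult | None
    delong: RocComparison | None
    nri: NriResult | None
    calibration: CalibrationResult

    def to_dict(self) -> dict:
        def auc_dict(a: AucResult) -> dict:
            return {"auc": a.auc, "se": a.se, "ci95": list(a.ci95),
                    "n_events": a.n_events, "n_nonevents": a.n_nonevents}

        doc = {
            "cohort": self.cohort_label,
            "n": self.n,
            "mortality": self.mortality,
            "model": {"name": self.model_name, **auc_dict(self.model_auc)},
            "calibration": {
                "groups": self.calibration.groups.to_dict(orient="records"),
                "hosmer_lemeshow": {
                    "statistic": self.calibration.hl_statistic,
                    "df": self.calibration.hl_df,
                    "p": self.calibration.hl_p,
                },
            },
        }
        if self.baseline_auc is not None:
            doc["baseline"] = {"name": self.baseline_name, **auc_dict(self.baseline_auc)}
            doc["delong"] = {
                "auc_model": self.delong.auc1, "auc_baseline": self.delong.auc2,
                "z": self.delong.z, "p": self.delong.p,
                "degenerate": self.delong.degenerate,
            }
            doc["nri"] = {
                "nri": self.nri.nri,
                "event_component": self.nri.event_component,
                "nonevent_component": self.nri.nonevent_component,
                "z": self.nri.z, "p": self.nri.p,
            }
        return doc

    def summary(self) -> str:
        lines = [
            f"Evaluation of {self.model_name!r} on cohort {self.cohort_label!r} "
            f"(n = {self.n}, mortality = {self.mortality:.1%})",
            f"  {self.model_name}: {self.model_auc}",
        ]
        if self.baseline_auc is not None:
            lines.append(f"  {self.baseline_name}: {self.baseline_auc}")
            lines.append(f"  {self.delong}")
            lines.append(f"  {self.nri}")
        lines.append("Calibration (predicted-risk quantile groups):")
        lines.append("  " + str(self.calibration).replace("\n", "\n  "))
        return "\n".join(lines)


def plot_calibration(report: EvalReport, path) -> None:
    """Observed vs mean predicted mortality per risk group, with CIs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = report.calibration.groups
    fig, ax = plt.subplots(figsize=(5, 5))
    yerr = np.vstack([g["observed"] - g["ci_low"], g["ci_high"] - g["observed"]])
    ax.errorbar(g["mean_predicted"], g["observed"], yerr=yerr, fmt="o-", capsize=3,
                label=report.model_name)
    lim = max(g["mean_predicted"].max(), g["ci_high"].max()) * 1.05
    ax.plot([0, lim], [0, lim], "--", color="grey", lw=1, label="ideal")
    ax.set_xlabel("Mean predicted probability of 30-day mortality")
    ax.set_ylabel("Observed proportion")
    ax.set_title(
        f"{report.model_name} calibration "
        f"(HL p = {report.calibration.hl_p:.3f})"
    )
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
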