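"""End-to-end analysis pipeline: from a cohort to the full result report.

Stage order is fixed: dosimetric extraction -> univariate battery ->
multivariable logistic model -> LKB MLE fit -> per-patient NTCP -> ROC for
V20 and for NTCP -> Youden cut-offs -> confusion metrics -> stratified
incidence -> plan-constraint checks. Stages that need both outcome classes
(fit, ROC) degrade gracefully on degenerate cohorts: they are marked
skipped, never silently dropped.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats as sps

from .cohort import Cohort, VX_LEVELS
from .errors import DegenerateDataError, RankError
from .fit import FitConfig, FitResult, fit_mle
from .lkb import ntcp_for_patient
from .stats import (
    ContingencyTable2x2,
    chi_square_2x2,
    confusion_at_cutoff,
    logistic_fit,
    roc_curve,
    stratified_incidence,
    two_sample_t_from_samples,
)

#: ipsilateral-lung plan limits used at treatment planning
PLAN_LIMITS = {"v20_pct": 30.0, "mean_dose_gy": 20.0}

#: covariates entering the multivariable logistic model
DEFAULT_MULTIVARIATE = ("v5", "v10", "v15", "v20", "v25", "mean_dose_gy", "chemo_cycles")


@dataclass(frozen=True)
class PlanViolation:
    name: str
    limit: float
    observed: float


def check_plan_constraints(record) -> list[PlanViolation]:
    """Check a record against the ipsilateral-lung plan limits.

    V20 must stay below 30% and the mean lung dose below 20 Gy.
    """
    out = []
    v20 = record.v(20.0)
    if v20 >= PLAN_LIMITS["v20_pct"]:
        out.append(PlanViolation("ipsilateral_v20_pct", PLAN_LIMITS["v20_pct"], v20))
    md = record.mean_dose_gy
    if md >= PLAN_LIMITS["mean_dose_gy"]:
        out.append(PlanViolation("ipsilateral_mean_dose_gy", PLAN_LIMITS["mean_dose_gy"], md))
    return out


@dataclass
class AnalysisConfig:
    fit_config: FitConfig = field(default_factory=FitConfig)
    cutoff_strategy: str = "youden"
    continuity_correction: bool = True
    multivariate_covariates: tuple[str, ...] = DEFAULT_MULTIVARIATE


@dataclass
class AnalysisReport:
    """All pipeline outputs plus provenance; serialises to JSON."""

    label: str
    n_patients: int
    n_events: int
    univariate_clinical: list[dict]
    univariate_dosimetric: list[dict]
    multivariate: dict | None
    fit_result: FitResult | None
    ntcp: list[float] | None
    roc_v20: dict | None
    roc_ntcp: dict | None
    confusion_v20: dict | None
    confusion_ntcp: dict | None
    stratification_ntcp: dict | None
    constraint_violations: dict[str, list[dict]]
    skipped: dict[str, str]
    config: dict

    def to_json(self) -> str:
        d = asdict(self)
        if self.fit_result is not None:
            d["fit_result"] = json.loads(self.fit_result.to_json())
        d["config"] = self.config
        return json.dumps(d, indent=2)


def _roc_summary(roc) -> dict:
    return {
        "auc": roc.auc,
        "auc_ci": list(roc.auc_ci),
        "best_cutoff": roc.best_cutoff,
        "youden_j": roc.youden_j,
        "points": [
            {"threshold": float(t), "sensitivity": float(se), "specificity": float(sp)}
            for t, se, sp in zip(roc.thresholds, roc.sensitivities, roc.specificities)
        ],
    }


def _confusion_summary(cm) -> dict:
    return {
        "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn,
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
        "accuracy": cm.accuracy,
        "ppv": cm.ppv,
        "npv": cm.npv,
    }


def _clinical_univariate(frame, correction: bool) -> list[dict]:
    """Chi-square association of each categorical covariate with the outcome."""
    out = []
    y = frame["rili_binary"].to_numpy()

    def table_for(mask):
        a = int(np.sum(mask & (y == 1)))
        b = int(np.sum(mask & (y == 0)))
        c = int(np.sum(~mask & (y == 1)))
        d = int(np.sum(~mask & (y == 0)))
        return ContingencyTable2x2(a, b, c, d)

    binary_factors = {
        "age_le_60": frame["age"].to_numpy() <= 60,
        "chemo_cycles_le_6": frame["chemo_cycles"].to_numpy() <= 6,
        "breast_conserving": frame["surgery"].to_numpy() == "breast_conserving",
    }
    for name, mask in binary_factors.items():
        try:
            stat, p = chi_square_2x2(table_for(mask), correction)
            out.append({"factor": name, "test": "chi2", "statistic": stat, "p_value": p})
        except DegenerateDataError:
            out.append({"factor": name, "test": "chi2", "statistic": None, "p_value": None})
    # stage has three levels: r x c chi-square without Yates
    stage = frame["stage"].to_numpy()
    tab = np.array(
        [[np.sum((stage == s) & (y == v)) for v in (1, 0)] for s in ("I", "II", "III")]
    )
    tab = tab[tab.sum(axis=1) > 0]
    if tab.shape[0] >= 2 and (tab.sum(axis=0) > 0).all():
        stat, p, _, _ = sps.chi2_contingency(tab, correction=False)
        out.append({"factor": "stage", "test": "chi2_rxc", "statistic": float(stat), "p_value": float(p)})
    else:
        out.append({"factor": "stage", "test": "chi2_rxc", "statistic": None, "p_value": None})
    return out


def _dosimetric_univariate(frame) -> list[dict]:
    """Two-sample t tests of each dosimetric summary between outcome groups."""
    out = []
    y = frame["rili_binary"].to_numpy()
    cols = [f"v{x}" for x in VX_LEVELS] + ["mean_dose_gy", "max_dose_gy"]
    for col in cols:
        vals = frame[col].to_numpy(dtype=float)
        g1, g0 = vals[y == 1], vals[y == 0]
        row = {
            "factor": col,
            "mean_injury": float(g1.mean()) if g1.size else None,
            "sd_injury": float(g1.std(ddof=1)) if g1.size > 1 else None,
            "mean_no_injury": float(g0.mean()) if g0.size else None,
            "sd_no_injury": float(g0.std(ddof=1)) if g0.size > 1 else None,
        }
        try:
            res = two_sample_t_from_samples(g1, g0)
            row.update({"t": res.statistic, "df": res.df, "p_value": res.p_value})
        except Exception:
            row.update({"t": None, "df": None, "p_value": None})
        out.append(row)
    return out


def run_analysis(cohort: Cohort, config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the full study workflow on a cohort and collect every table."""
    cfg = config or AnalysisConfig()
    cohort.require_nonempty()
    frame = cohort.to_frame()
    y = frame["rili_binary"].to_numpy(dtype=float)
    n_events = int(y.sum())
    skipped: dict[str, str] = {}

    univariate_clinical = _clinical_univariate(frame, cfg.continuity_correction)
    univariate_dosimetric = _dosimetric_univariate(frame)

    multivariate = None
    fit_result = None
    ntcp_scores = None
    roc_v20 = roc_ntcp = None
    conf_v20 = conf_ntcp = None
    strat = None

    two_classes = 0 < n_events < len(cohort)
    if not two_classes:
        reason = "cohort has a single outcome class"
        for stage_name in ("multivariate", "lkb_fit", "ntcp", "roc_v20", "roc_ntcp",
                           "confusion", "stratification"):
            skipped[stage_name] = reason
    else:
        X = frame[list(cfg.multivariate_covariates)].to_numpy(dtype=float)
        try:
            res = logistic_fit(X, y, names=list(cfg.multivariate_covariates))
            multivariate = {
                "names": res.names,
                "coef": res.coef.tolist(),
                "se": res.se.tolist(),
                "odds_ratios": res.odds_ratios.tolist(),
                "ci_low": res.ci_low.tolist(),
                "ci_high": res.ci_high.tolist(),
                "p_values": res.p_values.tolist(),
                "converged": res.converged,
                "separation": res.separation,
                "condition_number": res.condition_number,
            }
        except RankError as exc:
            skipped["multivariate"] = str(exc)

        fit_result = fit_mle(cohort, cfg.fit_config)
        ntcp_scores = [ntcp_for_patient(r, fit_result.params) for r in cohort]

        v20 = frame["v20"].to_numpy(dtype=float)
        roc_v20_full = roc_curve(v20, y)
        roc_ntcp_full = roc_curve(np.asarray(ntcp_scores), y)
        roc_v20 = _roc_summary(roc_v20_full)
        roc_ntcp = _roc_summary(roc_ntcp_full)
        conf_v20 = _confusion_summary(
            confusion_at_cutoff(v20, y, roc_v20_full.best_cutoff)
        )
        conf_ntcp = _confusion_summary(
            confusion_at_cutoff(np.asarray(ntcp_scores), y, roc_ntcp_full.best_cutoff)
        )
        si = stratified_incidence(np.asarray(ntcp_scores), y, roc_ntcp_full.best_cutoff)
        strat = asdict(si)

    violations = {}
    for r in cohort:
        v = check_plan_constraints(r)
        if v:
            violations[r.patient_id] = [asdict(x) for x in v]

    return AnalysisReport(
        label=cohort.label,
        n_patients=len(cohort),
        n_events=n_events,
        univariate_clinical=univariate_clinical,
        univariate_dosimetric=univariate_dosimetric,
        multivariate=multivariate,
        fit_result=fit_result,
        ntcp=ntcp_scores,
        roc_v20=roc_v20,
        roc_ntcp=roc_ntcp,
        confusion_v20=conf_v20,
        confusion_ntcp=conf_ntcp,
        stratification_ntcp=strat,
        constraint_violations=violations,
        skipped=skipped,
        config={
            "cutoff_strategy": cfg.cutoff_strategy,
            "continuity_correction": cfg.continuity_correction,
            "multivariate_covariates": list(cfg.multivariate_covariates),
            "fit_config": json.loads(cfg.fit_config.to_json()),
        },
    )
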