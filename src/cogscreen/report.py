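"""Pipeline orchestration: simulate/load -> adjust -> analyze -> dual cut-offs -> report.

Produces machine-readable artifacts for each requested score field and
patient grouping:

* a per-threshold metrics TSV (every number in the summary is recomputable
  from it — no hidden state);
* a summary TSV with one row per cut-off strategy (cut-off label, CCR,
  sensitivity/specificity with exact binomial CIs, AUC with percentile
  bootstrap CI);
* the dual-cutoff sensitivity/specificity curve TSV and result JSON;
* a run log (seed, versions, provenance) for reproducibility.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adjust import NormModel, apply_adjustments
from .cohort import Group, StudyDataset, read_cohort
from .cutoffs import (
    CutoffChoice,
    balanced_cutoff,
    cutoff_label,
    display_percent,
    evaluate_cutoff,
    fixed_cutoff,
    metrics_at_all_thresholds,
    metrics_table,
    percentile_cutoff,
    youden_cutoff,
)
from .dualcut import cumulative_curves, find_dual_cutoffs, zone_summary
from .inference import bootstrap_ci
from .roc import auc
from .simulate import CohortSpec, default_cohort_spec, simulate_study

DEFAULT_STRATEGIES = ("fixed", "balanced", "youden", "percentile")


class ConfigError(ValueError):
    """The analysis configuration is internally inconsistent."""


@dataclass
class AnalysisConfig:
    """Configuration of one analysis run."""

    input_path: str | None = None
    cohort_spec: CohortSpec | None = None
    score_fields: tuple[str, ...] = ("moca_adj",)
    patient_groups: tuple[Group, ...] = (Group.MILD, Group.MAJOR)
    control_group: Group = Group.NF
    strategies: tuple[str, ...] = DEFAULT_STRATEGIES
    fixed_t: float = 25
    percentile_q: float = 0.10
    percentile_reference: Group = Group.NC
    dual_patient_group: Group = Group.MILD
    dual_control_group: Group = Group.NC
    dual_target_sens: float = 0.90
    dual_target_spec: float = 0.90
    dual_mode: str = "strict"
    edu_adjust: bool = True
    norm_model: NormModel | None = None
    ci_level: float = 0.95
    n_boot: int = 2000
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        patients = set(self.patient_groups)
        if not patients:
            raise ConfigError("patient group set is empty")
        if self.control_group in patients:
            raise ConfigError("patient and control group sets must be disjoint")
        unknown = [s for s in self.strategies if s not in DEFAULT_STRATEGIES]
        if unknown:
            raise ConfigError(f"unknown strategies: {unknown}")
        valid_fields = {"moca_adj", "moca_raw", "moca_z", "mmse"}
        bad = [f for f in self.score_fields if f not in valid_fields]
        if bad:
            raise ConfigError(f"unknown score fields: {bad}")


def load_dataset(cfg: AnalysisConfig) -> StudyDataset:
    if cfg.input_path is not None:
        ds = read_cohort(cfg.input_path)
    else:
        spec = cfg.cohort_spec or default_cohort_spec(seed=cfg.seed)
        ds = simulate_study(spec)
    return apply_adjustments(ds, model=cfg.norm_model, edu_adjust=cfg.edu_adjust)


def _choice_row(field_name: str, choice: CutoffChoice, auc_value: float,
                auc_ci: tuple[float, float]) -> dict:
    m = choice.metrics
    return {
        "score_field": field_name,
        "strategy": choice.strategy,
        "cutoff": choice.threshold,
        "cutoff_label": choice.label,
        "ccr_pct": display_percent(m.ccr),
        "sensitivity_pct": display_percent(m.sensitivity),
        "specificity_pct": display_percent(m.specificity),
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "ccr": m.ccr,
        "youden_j": m.youden_j,
        "sens_ci_low": m.ci_sens.lower if m.ci_sens else np.nan,
        "sens_ci_high": m.ci_sens.upper if m.ci_sens else np.nan,
        "spec_ci_low": m.ci_spec.lower if m.ci_spec else np.nan,
        "spec_ci_high": m.ci_spec.upper if m.ci_spec else np.nan,
        "auc": auc_value,
        "auc_ci_low": auc_ci[0],
        "auc_ci_high": auc_ci[1],
    }


@dataclass
class AnalysisReport:
    summary: pd.DataFrame
    thresholds: dict[str, pd.DataFrame]
    dual_curve: pd.DataFrame
    dual_result: dict
    zone_counts: pd.DataFrame
    log: dict
    dataset: StudyDataset = field(repr=False, default=None)


def run_analysis(cfg: AnalysisConfig) -> AnalysisReport:
    """Run the full accuracy pipeline; deterministic for identical config + seed."""
    cfg.validate()
    ds = load_dataset(cfg)

    summary_rows = []
    thresholds: dict[str, pd.DataFrame] = {}
    for field_name in cfg.score_fields:
        pos = ds.scores(cfg.patient_groups, field_name)
        neg = ds.scores([cfg.control_group], field_name)
        metrics = metrics_at_all_thresholds(pos, neg, ci_level=cfg.ci_level)
        thresholds[field_name] = metrics_table(metrics)
        auc_value = auc(pos, neg)
        ci = bootstrap_ci(auc, [pos, neg], n_boot=cfg.n_boot,
                          level=cfg.ci_level, seed=cfg.seed)
        auc_ci = (ci.lower, ci.upper)

        for strategy in cfg.strategies:
            if strategy == "fixed":
                choice = fixed_cutoff(pos, neg, cfg.fixed_t, ci_level=cfg.ci_level)
            elif strategy == "balanced":
                choice = balanced_cutoff(metrics)
            elif strategy == "youden":
                choice = youden_cutoff(metrics)
            else:  # percentile: derived on the reference controls, validated here
                ref = ds.scores([cfg.percentile_reference], field_name)
                choice = percentile_cutoff(ref, q=cfg.percentile_q)
                choice.metrics = evaluate_cutoff(pos, neg, choice.threshold,
                                                 ci_level=cfg.ci_level)
            if choice.metrics is None:
                choice.metrics = evaluate_cutoff(pos, neg, choice.threshold,
                                                 ci_level=cfg.ci_level)
            summary_rows.append(_choice_row(field_name, choice, auc_value, auc_ci))
    summary = pd.DataFrame(summary_rows)

    dual_field = cfg.score_fields[0]
    pat = ds.scores([cfg.dual_patient_group], dual_field)
    con = ds.scores([cfg.dual_control_group], dual_field)
    curves = cumulative_curves(pat, con)
    dual = find_dual_cutoffs(curves, target_sens=cfg.dual_target_sens,
                             target_spec=cfg.dual_target_spec, mode=cfg.dual_mode)
    zones = zone_summary(ds, dual, score_field=dual_field)

    log = {
        "cogscreen_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "provenance": ds.provenance,
        "n_records": len(ds),
        "patient_groups": [g.value for g in cfg.patient_groups],
        "control_group": cfg.control_group.value,
        "score_fields": list(cfg.score_fields),
    }
    report = AnalysisReport(
        summary=summary, thresholds=thresholds,
        dual_curve=curves.to_frame(), dual_result=dual.to_dict(),
        zone_counts=zones, log=log, dataset=ds,
    )
    if cfg.outdir is not None:
        write_report(report, cfg.outdir)
    return report


def write_report(report: AnalysisReport, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    for field_name, table in report.thresholds.items():
        table.to_csv(out / f"thresholds_{field_name}.tsv", sep="\t", index=False)
    report.dual_curve.to_csv(out / "dual_cutoff_curve.tsv", sep="\t", index=False)
    (out / "dual_cutoff.json").write_text(
        json.dumps(report.dual_result, indent=2) + "\n"
    )
    report.zone_counts.to_csv(out / "zone_counts.tsv", sep="\t")
    (out / "run_log.json").write_text(json.dumps(report.log, indent=2) + "\n")
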