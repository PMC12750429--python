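"""End-to-end orchestration: synthesize/load -> features -> stats -> predict.

Every stage writes a plain-text artifact (trial CSVs, ``features.csv``,
``stats_report.csv``, ``prediction_report.json``) so each can be re-run
and inspected independently; the final report embeds the resolved
configuration and seed for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as trial_io
from . import prediction, stats
from .features import FEATURE_COLUMNS, LABEL_COLUMN, feature_table
from .synthetic import CohortConfig, generate_cohort

log = logging.getLogger("slrwalk")


@dataclass
class RunConfig:
    """All stage parameters of one reproducible pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    synthesize: bool = True
    cohort_dir: str | None = None          # input cohort when not synthesizing
    cohort: CohortConfig = field(default_factory=CohortConfig)
    write_trials: bool = False             # write per-patient trial CSVs
    onset_threshold_deg: float = 2.0
    onset_min_hold_s: float = 0.2
    window_s: float = 10.0
    acc_summary: str = "mean"
    cv_folds: int = 10
    threshold: float = 0.5
    n_bootstrap: int = 2000
    evaluation_mode: str = "in_sample"

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["emg"] = dataclasses.asdict(self.cohort.emg)
        return d


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def prediction_report_dict(report: prediction.PredictionReport) -> dict:
    d: dict = {"n_imputed": report.n_imputed, "error": report.error}
    d["lasso"] = {
        "optimal_lambda": report.screen.optimal_lambda,
        "nonzero": report.screen.nonzero,
        "coefficients": {k: v for k, v in report.screen.coefficients.items() if v != 0.0},
        "n_folds": report.screen.n_folds,
    }
    d["candidates"] = [
        {"pair": list(c.pair), "aic": c.aic, "separated": c.separated} for c in report.candidates
    ]
    if report.best is not None:
        b = report.best
        d["best"] = {
            "pair": list(b.pair), "aic": b.aic, "params": b.params, "bse": b.bse,
            "p_values": b.p_values, "odds_ratios": b.odds_ratios,
            "or_ci": {k: list(v) for k, v in b.or_ci.items()}, "separated": b.separated,
        }
    if report.evaluation is not None:
        e = report.evaluation
        d["evaluation"] = {
            "mode": e.mode, "threshold": e.threshold,
            "confusion": {"tp": e.tp, "fn": e.fn, "fp": e.fp, "tn": e.tn},
            "accuracy": e.accuracy, "sensitivity": e.sensitivity, "specificity": e.specificity,
            "auc": e.auc, "auc_ci": list(e.auc_ci),
            "roc": {"fpr": e.roc_fpr.tolist(), "tpr": e.roc_tpr.tolist()},
        }
    return d


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write artifacts under ``config.out_dir``, return the report."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthesize:
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        log.info("synthesizing cohort: %d per group, seed %d", cohort_cfg.n_per_group, config.seed)
        records, _truth = generate_cohort(cohort_cfg)
        if config.write_trials:
            trial_io.write_cohort(records, out / "cohort")
        else:
            trial_io.covariates_frame(records).to_csv(out / "covariates.csv", index=False)
    elif config.cohort_dir:
        records = trial_io.read_cohort(config.cohort_dir)
    else:
        raise ValueError("either synthesize=True or cohort_dir must be given")

    for rec in records:
        for finding in trial_io.validate_record(rec):
            if finding.severity == "error":
                raise RuntimeError(f"patient {rec.patient_id}: {finding.message}")
            log.warning("patient %s: %s", rec.patient_id, finding.message)

    log.info("extracting features for %d patients", len(records))
    table = feature_table(
        records,
        onset_threshold_deg=config.onset_threshold_deg,
        onset_min_hold_s=config.onset_min_hold_s,
        window_s=config.window_s,
        acc_summary=config.acc_summary,
    )
    table.to_csv(out / "features.csv", index=False)

    stats_report = stats.group_comparison_table(
        table.drop(columns=["patient_id"]), label_column=LABEL_COLUMN,
        continuous=[c for c in FEATURE_COLUMNS if c != "sex"], categorical=["sex"],
    )
    stats_report.to_csv(out / "stats_report.csv", index=False)

    pred = prediction.build_prediction_model(
        table, seed=config.seed, n_folds=config.cv_folds,
        threshold=config.threshold, evaluation_mode=config.evaluation_mode,
        n_bootstrap=config.n_bootstrap,
    )
    report = {
        "config": config.resolved(),
        "n_patients": len(records),
        "stats": stats_report.to_dict(orient="records"),
        "prediction": prediction_report_dict(pred),
        "runtime_s": round(time.time() - t0, 2),
    }
    with open(out / "prediction_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    with open(out / "summary.txt", "w", encoding="utf-8") as fh:
        fh.write(summarize(report))
    return report


def summarize(report: dict) -> str:
    """Human-readable run summary."""
    p = report["prediction"]
    lines = [
        f"patients: {report['n_patients']}",
        f"imputed values: {p['n_imputed']}",
        f"lasso nonzero predictors: {', '.join(p['lasso']['nonzero']) or '(none)'}",
    ]
    for c in p.get("candidates", []):
        lines.append(f"  candidate {c['pair'][0]} + {c['pair'][1]}: AIC {c['aic']:.2f}"
                     + (" (separated)" if c["separated"] else ""))
    if "best" in p:
        b = p["best"]
        lines.append(f"selected model: {b['pair'][0]} + {b['pair'][1]} (AIC {b['aic']:.2f})")
    if "evaluation" in p:
        e = p["evaluation"]
        lines.append(
            f"accuracy {e['accuracy']:.3f}, sensitivity {e['sensitivity']:.3f}, "
            f"specificity {e['specificity']:.3f}, AUC {e['auc']:.3f} "
            f"(95% CI {e['auc_ci'][0]:.3f}-{e['auc_ci'][1]:.3f}) [{e['mode']}]"
        )
    if p.get("error"):
        lines.append(f"note: {p['error']}")
    return "\n".join(lines) + "\n"
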