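"""Human-readable run reports: DVH tables, metric summaries, weight history.

File names are fixed: ``dvh.csv``, ``metrics.csv``, ``weights_history.csv``,
``solver_trace.csv``, ``plan_report.json`` and, when a configuration is
supplied, ``config.yaml`` (the echo that makes the run reproducible).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import metrics
from .autoplan import AutoPlanResult, Prescription
from .config import RunConfig, save_config
from .phantom import Phantom

REPORT_FILES = (
    "dvh.csv",
    "metrics.csv",
    "weights_history.csv",
    "solver_trace.csv",
    "plan_report.json",
)


def dvh_table(dose: np.ndarray, phantom: Phantom, n_points: int = 201) -> pd.DataFrame:
    rows = []
    for name, mask in phantom.masks.items():
        if phantom.roles[name] == "body":
            continue
        curve = metrics.dvh(dose, mask, structure=name, n_points=n_points)
        rows.append(
            pd.DataFrame(
                {"structure": name, "dose_Gy": curve.dose_gy, "volume_pct": curve.volume_pct}
            )
        )
    return pd.concat(rows, ignore_index=True)


def metrics_table(dose: np.ndarray, phantom: Phantom, prescription: Prescription) -> pd.DataFrame:
    body = phantom.body_mask
    ptv_name = phantom.ptv_name
    rows = []
    for name, mask in phantom.masks.items():
        if phantom.roles[name] == "body":
            continue
        row = metrics.plan_metrics_row(dose, mask, name)
        if name == ptv_name:
            row["ci"] = metrics.conformity_index(dose, mask, body, prescription.ptv_min_dose)
            row["hi"] = metrics.homogeneity_index(dose, mask)
        else:
            row["ci"] = np.nan
            row["hi"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def weights_history_table(result: AutoPlanResult) -> pd.DataFrame:
    l = len(result.objective_spec)
    rows = []
    for rec in result.history.records:
        row = {
            "comp_iter": rec["comp_iter"],
            "inner_iter": rec["inner_iter"],
            "k": rec["k"],
            "objective": rec["objective"],
            "ptv_coverage_pct": rec["ptv_coverage_pct"],
        }
        for i in range(l):
            row[f"w_{i}"] = rec["weights"][i]
            row[f"factor_{i}"] = rec["factors"][i]
            row[f"subscore_{i}"] = rec["subscores"][i]
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(
    result: AutoPlanResult,
    phantom: Phantom,
    prescription: Prescription,
    out_dir: str | Path,
    config: Optional[RunConfig] = None,
) -> Path:
    """Write the full report bundle for a completed run; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dose = result.plan.dose

    dvh_table(dose, phantom).to_csv(out / "dvh.csv", index=False)
    metrics_table(dose, phantom, prescription).to_csv(out / "metrics.csv", index=False)
    weights_history_table(result).to_csv(out / "weights_history.csv", index=False)
    pd.DataFrame(
        [
            {"step": i, "objective": t["objective"], "grad_norm": t["grad_norm"]}
            for i, t in enumerate(result.plan.trace)
        ]
    ).to_csv(out / "solver_trace.csv", index=False)

    report = {
        "model": result.model,
        "acceptable": result.acceptable,
        "k_final": result.k_final,
        "objective": result.plan.objective,
        "subscores": result.plan.subscores.tolist(),
        "final_weights": np.asarray(result.weights).tolist(),
        "n_solves": result.history.n_solves,
        "evaluation": {
            "ptv_satisfied": result.evaluation.ptv_satisfied,
            "ptv_coverage_pct": result.evaluation.ptv_coverage_pct,
            "all_satisfied": result.evaluation.all_satisfied,
            "criteria": result.evaluation.criteria,
        },
        "structure_metrics": metrics_table(dose, phantom, prescription).to_dict(
            orient="records"
        ),
    }
    with open(out / "plan_report.json", "w") as fh:
        json.dump(report, fh, indent=1)

    if config is not None:
        save_config(config, out / "config.yaml")
    return out
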