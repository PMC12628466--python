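"""End-to-end orchestration: simulate (or load) → flux → stoichiometry → ODC →
NIRS → hemoglobin audits, producing one machine-readable JSON report.

Each stage runs independently; a failing stage is recorded as failed in its
block and later stages still execute. Under a fixed seed and configuration the
report is deterministic (no timestamps are embedded).
"""

from __future__ import annotations

import json
import traceback
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__, flux, hb, nirs, odc, stoichiometry, synthetic

__all__ = ["run_pipeline", "report_to_json"]


def _stage(report: dict, name: str, fn) -> Any:
    try:
        result = fn()
        report[name] = {"status": "ok", **result}
        return result
    except Exception as exc:  # stage isolation: later stages still run
        report[name] = {
            "status": "failed",
            "error": f"{type(exc).__name__}: {exc}",
            "trace": traceback.format_exc(limit=3),
        }
        return None


def _flux_stage(study: synthetic.SyntheticStudy) -> dict:
    estimates = []
    for series in study.lactate_series():
        est = flux.estimate_flux(series)
        estimates.append(
            {
                "condition": series.meta["condition"],
                "timepoint": series.meta["timepoint"],
                "slope": est.slope,
            }
        )
    summary = flux.summarize_timecourse(pd.DataFrame(estimates))
    os_pre = summary.query("condition == 'oxidative_stress' and timepoint == 'pre'")
    ctl_pre = summary.query("condition == 'control' and timepoint == 'pre'")
    os_multiplier = float(os_pre["mean_flux"].iloc[0] / ctl_pre["mean_flux"].iloc[0])
    return {
        "summary": summary.to_dict(orient="records"),
        "estimated_os_multiplier": os_multiplier,
    }


def _stoich_stage() -> dict:
    out = {}
    for name in stoichiometry.PRESETS:
        summary = stoichiometry.preset(name)
        balance = stoichiometry.carbon_balance(summary, stoichiometry.PRESETS[name])
        out[name] = {
            "atp_net": summary.atp_net,
            "nadph": summary.nadph,
            "bpg23": summary.bpg23,
            "lactate": summary.lactate,
            "co2": summary.co2,
            "nadh_net": summary.nadh_net,
            "carbon_residual": balance.residual,
            "notes": list(summary.notes),
        }
    out["muscle_comparison"] = {
        "erythrocyte_atp_turnover_exercise_mM_per_h": stoichiometry.atp_turnover_scale(1.50, 3.0),
        "percent_of_muscle_turnover": stoichiometry.relative_rate(
            stoichiometry.atp_turnover_scale(1.50, 3.0), 18000.0
        ),
    }
    return {"scenarios": out}


def _odc_stage(study: synthetic.SyntheticStudy) -> dict:
    panels = (
        study.bloodgas_table.groupby(["condition", "timepoint"])[
            ["po2", "pco2", "ph", "dpg", "temp", "hct", "hb"]
        ]
        .mean()
        .reset_index()
    )
    rows = []
    for _, r in panels.iterrows():
        state = odc.BloodGasState(
            po2=r["po2"], pco2=r["pco2"], ph=r["ph"], dpg=r["dpg"],
            temp=r["temp"], hct=r["hct"], hb=r["hb"],
        )
        rows.append(
            {
                "condition": r["condition"],
                "timepoint": r["timepoint"],
                "p50_mmHg": odc.p50_adjusted(state),
                "sat_at_100_mmHg": odc.saturation(100.0, state),
            }
        )
    frame = pd.DataFrame(rows)

    def p50_of(cond, tp):
        return float(
            frame.query("condition == @cond and timepoint == @tp")["p50_mmHg"].iloc[0]
        )

    shifts = {
        cond: {
            "pre_p50": p50_of(cond, "pre"),
            "post_p50": p50_of(cond, "post0"),
            "delta_p50": p50_of(cond, "post0") - p50_of(cond, "pre"),
        }
        for cond in frame["condition"].unique()
    }
    return {"p50_table": rows, "pre_post_shifts": shifts}


def _nirs_stage(study: synthetic.SyntheticStudy, seed: int) -> dict:
    traces = study.nirs_traces
    if not traces:
        trace = synthetic.generate_nirs_trace(duration_s=600.0, phase="exercise", seed=seed)
        traces = (trace,)
    summaries = [nirs.exercise_summary(t) for t in traces]
    hhb_bins = np.mean([s.bins["hhb"] for s in summaries], axis=0)
    return {
        "n_traces": len(summaries),
        "mean_baseline_hhb": float(np.mean([s.baseline["hhb"] for s in summaries])),
        "mean_hhb_decile_bins": [float(v) for v in hhb_bins],
        "mean_hhb_recovery_60_90_120": [
            float(v) for v in np.mean([s.recovery["hhb"] for s in summaries], axis=0)
        ],
    }


def _hb_stage(config: Mapping[str, Any]) -> dict:
    panel_cfg = config.get("hb_panel", {"total_hb": 150.0, "plasma_hb": 0.02, "methb": 4.35})
    panel = hb.HbPanel(**panel_cfg)
    return {
        "functional_hb": hb.functional_hb(panel),
        "methb_percent": hb.methb_percent(panel),
        "unit": panel.unit,
    }


def run_pipeline(config: Mapping[str, Any] | None = None) -> dict:
    """Run every stage and return the report as a JSON-serializable dict.

    ``config`` keys (all optional): ``seed`` (int), ``n_participants``,
    ``include_nirs`` (bool), ``hb_panel`` (total_hb/plasma_hb/methb mapping).
    """
    config = dict(config or {})
    seed = int(config.get("seed", 0))
    n = int(config.get("n_participants", 20))
    include_nirs = bool(config.get("include_nirs", False))

    report: dict[str, Any] = {
        "package": "erythroflux",
        "version": __version__,
        "config": {"seed": seed, "n_participants": n, "include_nirs": include_nirs},
    }
    design = synthetic.StudyDesign(n_participants=n, rng_seed=seed)
    study = synthetic.generate_study(design, include_nirs=include_nirs)
    report["synthetic"] = {
        "status": "ok",
        "n_lactate_rows": int(len(study.lactate_table)),
        "n_bloodgas_rows": int(len(study.bloodgas_table)),
        "true_os_multiplier": study.effects.os_flux_multiplier,
    }
    _stage(report, "flux", lambda: _flux_stage(study))
    _stage(report, "stoichiometry", _stoich_stage)
    _stage(report, "odc", lambda: _odc_stage(study))
    _stage(report, "nirs", lambda: _nirs_stage(study, seed))
    _stage(report, "hb", lambda: _hb_stage(config))
    return report


def report_to_json(report: Mapping[str, Any]) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
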