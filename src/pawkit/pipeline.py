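"""End-to-end driver: simulate -> extract -> QC -> kinetics -> statistics.

Produces a deterministic report bundle (JSON plus CSV tables mirroring
the session-summary and treatment-effect table layouts) for a simulated
or ingested crossover study.  Identical configuration and seed yield a
byte-identical report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinetics as kin
from . import qc as qcmod
from .extraction import extract_trial
from .io import PipelineConfig
from .models import (
    EstimationError,
    fit_kinetic_mixed_model,
    dunnett_vs_baseline,
    fit_ordinal_repeated,
)
from .simulate import StudyDataset, simulate_study
from .stats import chisq_2x2, paired_auc_comparison, pain_auc_above_baseline

__all__ = ["run_pipeline", "session_summaries", "measured_trial_table"]

log = logging.getLogger("pawkit.pipeline")


def measured_trial_table(dataset: StudyDataset, mode: str = "ground_truth") -> pd.DataFrame:
    """Per-trial kinetic measurements for a whole study.

    ``mode="ground_truth"`` uses each trial's sidecar directly (fast; the
    default for full-size studies).  ``mode="render"`` renders every
    trial to pressure frames and runs the full extraction stage —
    identical columns, practical for reduced designs only.
    """
    if mode == "ground_truth":
        return dataset.trial_table()
    if mode != "render":
        raise ValueError(f"unknown extraction mode {mode!r}")
    rows = []
    base = dataset.trial_table()
    for tr, (_, row) in zip(dataset.trials, base.iterrows()):
        rec = tr.render(dataset.config)
        feet = extract_trial(rec, tr.ground_truth.body_weight_kg, tr.trial_type)
        op = tr.ground_truth.operated_limb
        no = "RF" if op == "LF" else "LF"
        r = row.to_dict()
        for limb, prefix in [(op, "op"), (no, "no")]:
            sel = [f for f in feet if f.limb == limb]
            r[f"{prefix}_pvf"] = float(np.mean([f.pvf_pct_bw for f in sel])) if sel else np.nan
            r[f"{prefix}_vi"] = float(np.mean([f.vi_pct_bw_s for f in sel])) if sel else np.nan
        if tr.trial_type == "land":
            timing = kin.landing_timing(feet, op, rec.frame_rate_hz)
            r["tf1f2_s"] = timing.tf1f2_s
            r["tf1f2_measurable"] = timing.measurable
            r["tf1h1_s"] = timing.tf1h1_s
        rows.append(r)
    return pd.DataFrame(rows)


def _apply_qc(trials: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Validity flags and best-k selection per session."""
    out = trials.copy()
    out["selected"] = False
    for (cat, period, tp, ttype), grp in out.groupby(
        ["cat", "period", "timepoint_h", "trial_type"], sort=True
    ):
        if ttype == "land":
            out.loc[grp.index, "selected"] = grp.index.isin(grp.index[: config.k_best])
            continue
        if config.qc_mode == "comfortable":
            target = float(out.loc[out["cat"] == cat, "velocity_mps"].median())
        else:
            target = config.qc_target_velocity
        flags = [
            qcmod.validate_walking_trial(
                row, target=target,
                vel_tol=config.qc_velocity_tol, acc_tol=config.qc_accel_tol,
            ).valid
            for _, row in grp.iterrows()
        ]
        out.loc[grp.index, "valid"] = flags
        valid_idx = [i for i, ok in zip(grp.index, flags) if ok]
        ranked, _ = qcmod.select_best_trials(
            valid_idx, k=config.k_best, target_velocity=target,
            velocity_of=lambda i: out.loc[i, "velocity_mps"],
            accel_of=lambda i: out.loc[i, "accel_mps2"],
        )
        out.loc[ranked, "selected"] = True
    return out


def session_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Per cat x period x timepoint x trial-type kinetic summaries."""
    rows = []
    for (cat, period, tp, ttype), grp in trials.groupby(
        ["cat", "period", "timepoint_h", "trial_type"], sort=True
    ):
        sel = grp[grp["selected"]] if "selected" in grp.columns else grp
        if sel.empty:
            continue
        s = kin.session_summary(sel)
        rows.append(
            {
                "cat": cat,
                "period": period,
                "treatment": grp["treatment"].iloc[0],
                "timepoint_h": tp,
                "trial_type": ttype,
                "n_trials": s.n_trials,
                "op_pvf": s.op_pvf_mean,
                "no_pvf": s.no_pvf_mean,
                "op_vi": s.op_vi_mean,
                "no_vi": s.no_vi_mean,
                "si_pvf": s.si_pvf_mean,
                "si_vi": s.si_vi_mean,
                "tf1f2": s.tf1f2_mean,
                "tf1h1": s.tf1h1_mean,
                "ntf1f2": s.ntf1f2,
            }
        )
    return pd.DataFrame(rows)


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run the full study pipeline and write the report bundle.

    Returns the report dict; writes ``report.json`` and CSV tables under
    ``config.out_dir``.
    """
    config = config or PipelineConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    simcfg = config.sim_config()

    log.info("stage: simulate (seed=%d)", config.seed)
    dataset = simulate_study(simcfg, config.seed, config.n_walk, config.n_land)

    log.info("stage: extract (%s)", config.extraction_mode)
    try:
        trials = measured_trial_table(dataset, config.extraction_mode)
    except Exception as e:
        raise RuntimeError(f"[extract] stage failed: {e}") from e

    log.info("stage: qc")
    trials = _apply_qc(trials, config)

    log.info("stage: kinetics")
    summaries = session_summaries(trials)
    land = summaries[summaries["trial_type"] == "land"]
    walk = summaries[summaries["trial_type"] == "walk"]
    land_deltas = kin.baseline_adjust(land)
    walk_deltas = kin.baseline_adjust(walk)

    log.info("stage: statistics")
    effects = {"landing": {}, "walking": {}}
    for scope, deltas, responses in [
        ("landing", land_deltas, config.landing_responses),
        ("walking", walk_deltas, config.walking_responses),
    ]:
        for resp in responses:
            if resp not in deltas.columns or deltas[resp].dropna().empty:
                continue
            try:
                res = fit_kinetic_mixed_model(deltas, resp)
            except EstimationError as e:
                effects[scope][resp] = {"error": str(e)}
                continue
            effects[scope][resp] = {
                "treatment_effect": res.treatment_effect,
                "treatment_pvalue": res.treatment_pvalue,
                "contrasts": res.contrasts().to_dict("records"),
                "significant_timepoints_h": res.significant_timepoints(config.alpha),
            }

    control_deltas = land_deltas[land_deltas["treatment"] == "control"]
    dunnett = {
        resp: dunnett_vs_baseline(
            control_deltas, resp, seed=config.seed, n_mc=50_000
        ).to_dict("records")
        for resp in ("op_pvf", "no_pvf", "si_pvf", "si_vi")
    }

    # measurable inter-forelimb delay: baseline vs post-op in the control arm
    ctl = trials[(trials["trial_type"] == "land") & (trials["treatment"] == "control")]
    base_mask = ctl["timepoint_h"] < 0
    # rows: post-op, baseline; cols: measurable, not — OR > 1 means
    # landings stagger more after surgery
    tab = [
        [int(ctl.loc[~base_mask, "tf1f2_measurable"].sum()),
         int((~ctl.loc[~base_mask, "tf1f2_measurable"].astype(bool)).sum())],
        [int(ctl.loc[base_mask, "tf1f2_measurable"].sum()),
         int((~ctl.loc[base_mask, "tf1f2_measurable"].astype(bool)).sum())],
    ]
    chi = chisq_2x2(tab)

    pain_df = dataset.pain_table()
    aucs = {}
    for ps in dataset.pain:
        aucs.setdefault(ps.treatment, {})[ps.cat] = pain_auc_above_baseline(
            ps.times_h, ps.scores, ps.baseline
        )
    cats = sorted(aucs["control"])
    auc_cmp = paired_auc_comparison(
        [aucs["control"][c] for c in cats], [aucs["er_bup"][c] for c in cats]
    )
    try:
        pain_fit = fit_ordinal_repeated(pain_df, method=config.ordinal_method)
        pain_report = {
            "effect_table": pain_fit.effect_table().to_dict("records"),
            "crossing_times_h": {
                f"period{p}_{t}": str(ct) for (p, t), ct in pain_fit.crossing_times().items()
            },
        }
    except EstimationError as e:
        pain_report = {"error": str(e)}

    report = {
        "config": config.to_dict(),
        "counts": {
            "trials": int(len(trials)),
            "kinetic_sessions": int(summaries.groupby(["cat", "period", "timepoint_h"]).ngroups),
            "kinetic_timepoints_per_period": int(
                trials.loc[trials["timepoint_h"] >= 0, "timepoint_h"].nunique()
            ),
            "pain_timepoints_per_period": int(
                pain_df.loc[~pain_df["is_baseline"], "time_h"].nunique()
            ),
        },
        "qc": {
            "walking_valid_fraction": float(
                trials.loc[trials["trial_type"] == "walk", "valid"].mean()
            ),
        },
        "effects": effects,
        "dunnett_control_landing": dunnett,
        "ntf1f2": {
            "table": tab,
            "chi2": chi.statistic,
            "pvalue": chi.pvalue,
            "odds_ratio": chi.odds_ratio,
        },
        "pain": {
            "auc_per_cat": {t: {str(c): v for c, v in d.items()} for t, d in aucs.items()},
            "paired_t_p": auc_cmp.t_p,
            "signed_rank_p": auc_cmp.signed_rank_p,
            "direction": auc_cmp.direction,
            "rescue_flags": {
                f"cat{ps.cat}_period{ps.period}": ps.rescue for ps in dataset.pain
            },
            "model": pain_report,
        },
    }
    report = _round_floats(report)

    trials.to_csv(out / "trial_table.csv", index=False)
    summaries.to_csv(out / "session_summaries.csv", index=False)
    land_deltas.to_csv(out / "landing_deltas.csv", index=False)
    walk_deltas.to_csv(out / "walking_deltas.csv", index=False)
    pain_df.to_csv(out / "pain_scores.csv", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
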