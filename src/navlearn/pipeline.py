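"""End-to-end orchestration: generate -> metrics -> models -> report.

A pipeline run produces, under the output directory: the raw synthetic
tables (``trials.csv``, ``tracker.csv``, ``gaze.csv``), per-trial metric
tables (``trial_metrics.csv``, ``gaze_trial_metrics.csv``), model fits
(``model_fits.json``), strategy clusters (``clusters.csv``), benchmark
actor curves (``curves.csv``), a learning-curve figure, and a manifest
recording the seed, configuration hash and every artifact written.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import actors as ac
from . import gaze_metrics as gm
from . import learning_models as lm
from . import strategy_clustering as sc
from . import trajectory_metrics as tm
from . import synthetic_world as sw
from .config import RunConfig

logger = logging.getLogger(__name__)


def _curves_frame(curve_dict: dict[str, ac.AccuracyCurve]) -> pd.DataFrame:
    rows = []
    for name, curve in curve_dict.items():
        for i, (m, s) in enumerate(zip(curve.mean, curve.sem), start=1):
            rows.append({"curve": name, "trial_in_block": i, "mean": m, "sem": s})
    return pd.DataFrame(rows)


def _empirical_curves(table: pd.DataFrame) -> ac.AccuracyCurve:
    """Per-trial mean correctness across biased blocks and participants."""
    d = table[(table["condition"] != "control")].dropna(subset=["correct"])
    runs = [g.sort_values("trial_in_block")["correct"].to_numpy(dtype=bool)
            for _, g in d.groupby(["participant_id", "block_index"])]
    return ac.accuracy_curve(runs)


def _actor_curves(trials: pd.DataFrame, seed: int) -> dict[str, ac.AccuracyCurve]:
    """Ideal and WSLS actors exposed to the same open-side sequences."""
    d = trials[trials["condition"] != "control"]
    open_blocks = []
    for _, g in d.groupby(["participant_id", "block_index"]):
        g = g.sort_values("trial_in_block")
        open_blocks.append(np.where(g["guard_side"].to_numpy() == "left",
                                    "right", "left"))
    out = {}
    for policy in ("ideal", "wsls"):
        runs = ac.run_policy_on_blocks(open_blocks, policy, seed=seed)
        out[policy] = ac.accuracy_curve(runs)
    return out


def _learning_figure(curves: pd.DataFrame, threshold_trial, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axis = plt.subplots(figsize=(7, 4.5))
    styles = {"empirical": dict(color="black", marker="o", ls="none"),
              "logistic_fit": dict(color="purple", ls="--"),
              "exponential_fit": dict(color="darkorange", ls=":"),
              "ideal": dict(color="green", ls="-"),
              "wsls": dict(color="tab:blue", ls="-")}
    for name, g in curves.groupby("curve"):
        st = styles.get(name, {})
        axis.errorbar(g["trial_in_block"], g["mean"],
                      yerr=g["sem"] if name == "empirical" else None,
                      label=name, **st)
    if threshold_trial is not None:
        axis.axvline(threshold_trial, color="gray", ls=":", lw=1,
                     label=f"80% threshold (trial {threshold_trial})")
    axis.set_xlabel("trial within block")
    axis.set_ylabel("proportion correct")
    axis.set_ylim(0, 1.05)
    axis.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic-experiment analysis; returns the manifest.

    Stages run in order (generate, movement metrics, gaze metrics,
    models, actors, clustering, report); a failure raises with the stage
    name after writing a manifest of the stages completed so far.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.master_seed, "config": config.to_dict(),
                "config_hash": config.config_hash(), "stages": [], "artifacts": []}
    stage = "generate"
    try:
        data = sw.generate_experiment(
            config.experiment_id, config.n_participants, seed=config.master_seed,
            n_trials=config.n_trials, bias=config.bias, with_gaze=config.with_gaze)
        manifest["artifacts"] += sw.write_csvs(data, out)
        manifest["stages"].append(stage)

        stage = "metrics"
        metrics = tm.compute_trial_metrics(
            data["tracker"], data["trials"],
            commitment_threshold=config.commitment_threshold)
        metrics.to_csv(out / "trial_metrics.csv", index=False, float_format="%.6f")
        manifest["artifacts"].append(str(out / "trial_metrics.csv"))
        manifest["stages"].append(stage)

        stage = "gaze"
        gaze_table = None
        if config.with_gaze and data["gaze"] is not None:
            params = gm.IdtParams(config.idt_dispersion, config.idt_min_duration)
            gaze_table = gm.compute_gaze_metrics(data["gaze"], data["tracker"],
                                                 data["trials"], params)
            gaze_table.to_csv(out / "gaze_trial_metrics.csv", index=False,
                              float_format="%.6f")
            manifest["artifacts"].append(str(out / "gaze_trial_metrics.csv"))
        manifest["stages"].append(stage)

        stage = "fit"
        table = lm.build_trial_table(data["trials"], metrics, gaze_table)
        fits: dict[str, dict] = {}
        if config.experiment_id == 1:
            fits["expdecay"] = lm.fit_expdecay_mixed(table).to_dict()
            fits["expdecay_random_slopes"] = lm.fit_expdecay_mixed(
                table, random_slopes=True).to_dict()
            fits["block_position"] = lm.fit_block_position_model(table).to_dict()
            ctrl = table[table["condition"] == "control"]
            per_part = ctrl.groupby("participant_id")["last_x"].mean()
            fits["control_bias_ttest"] = lm.one_sample_t(per_part, 0.0)
        else:
            logistic = lm.fit_logistic_learning(table)
            fits["logistic"] = logistic.to_dict()
            fits["exponential_curve"] = lm.fit_exponential_learning_curve(table).to_dict()
            thr = lm.predict_threshold_trial(logistic, 0.8, config.n_trials)
            fits["threshold_trial"] = {"threshold": thr.threshold, "trial": thr.trial}
            ctrl = table[(table["condition"] == "control")].dropna(subset=["correct"])
            fits["control_chance"] = lm.bootstrap_mean_ci(
                ctrl["correct"], seed=config.master_seed)
        if gaze_table is not None:
            for name, f in lm.fit_gaze_models(table).items():
                fits[f"gaze_{name}"] = f.to_dict()
        with open(out / "model_fits.json", "w") as fh:
            json.dump(fits, fh, indent=2, default=float)
        manifest["artifacts"].append(str(out / "model_fits.json"))
        manifest["stages"].append(stage)

        stage = "actors"
        curves = {}
        if config.experiment_id == 2:
            curves["empirical"] = _empirical_curves(table)
            curves.update(_actor_curves(data["trials"], config.master_seed))
            comparison = {
                "ideal": ac.compare_curves(curves["empirical"], curves["ideal"]),
                "wsls": ac.compare_curves(curves["empirical"], curves["wsls"]),
            }
            with open(out / "curve_comparison.json", "w") as fh:
                json.dump(comparison, fh, indent=2, default=float)
            manifest["artifacts"].append(str(out / "curve_comparison.json"))
            cdf = _curves_frame(curves)
            cdf.to_csv(out / "curves.csv", index=False, float_format="%.6f")
            manifest["artifacts"].append(str(out / "curves.csv"))
        manifest["stages"].append(stage)

        stage = "cluster"
        if config.experiment_id == 1:
            feats = sc.compute_features(lm.build_trial_table(data["trials"], metrics))
            result = sc.cluster_participants(feats, weight=config.cluster_weight,
                                             k=config.cluster_k,
                                             seed=config.master_seed)
            result.assignments.to_csv(out / "clusters.csv", index=False,
                                      float_format="%.6f")
            manifest["artifacts"].append(str(out / "clusters.csv"))
        manifest["stages"].append(stage)

        stage = "report"
        if config.experiment_id == 2 and curves:
            # add model-fit curves for the figure
            t_idx = np.arange(1, config.n_trials + 1)
            from scipy.special import expit
            lf = fits["logistic"]["coefficients"]
            logit_curve = expit(lf["Intercept"]["estimate"]
                                + lf["trial_in_block"]["estimate"] * t_idx)
            ef = fits["exponential_curve"]["coefficients"]
            exp_curve = np.clip(ef["a"]["estimate"]
                                - ef["b"]["estimate"]
                                * np.exp(-ef["c"]["estimate"] * t_idx), 0, 1)
            cdf = _curves_frame(curves)
            extra = pd.DataFrame(
                [{"curve": "logistic_fit", "trial_in_block": int(t), "mean": m, "sem": 0.0}
                 for t, m in zip(t_idx, logit_curve)]
                + [{"curve": "exponential_fit", "trial_in_block": int(t), "mean": m,
                    "sem": 0.0} for t, m in zip(t_idx, exp_curve)])
            _learning_figure(pd.concat([cdf, extra], ignore_index=True),
                             fits["threshold_trial"]["trial"],
                             out / "learning_curves.png")
            manifest["artifacts"].append(str(out / "learning_curves.png"))
        manifest["stages"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["artifacts"].append(str(out / "manifest.json"))
    return manifest
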