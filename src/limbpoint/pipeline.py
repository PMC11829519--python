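"""End-to-end pipeline: file formats, per-trial processing, cohort tables, stats.

Plain-text formats keep every stage inspectable:

* trial markers: CSV with header ``time,hip_x,hip_y,knee_x,knee_y,ankle_x,
  ankle_y,toe_x,toe_y`` (s, m), one row per sample, with a JSON metadata
  sidecar (participant, block, vision, combo, seed) next to each trial;
* participants: one JSON per participant (anthropometrics, ROM, group);
* proprioception sessions, cohort metrics and model tables: CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics, endpoint, kinematics, proprioception, stats, synthetic
from .limb_model import Anthropometrics, LimbModel
from .protocol import combo_from_label, combo_label, make_target

log = logging.getLogger("limbpoint")

MARKER_COLUMNS = ["time"] + [f"{m}_{ax}" for m in ("hip", "knee", "ankle", "toe") for ax in "xy"]


@dataclass
class RunConfig:
    """Serializable configuration of a pipeline run.

    Every stochastic stage receives an explicit seed derived from ``seed``.
    """

    data_dir: str = "data"
    out_dir: str = "results"
    seed: int = 0
    simulate: bool = True
    fs: float = 65.0
    filter_cutoff: float = 6.0
    filter_order: int = 2
    fraction: float = 0.6
    n_control: int = 12
    n_sci: int = 16
    trials_per_combo_per_block: int = 6
    marker_noise_sd: float = 0.002
    alpha: float = 0.05
    adjust: str = "sidak"
    d_scale: str = "total"
    outcomes: tuple = ("h_error", "v_error", "log_area",
                       "torque_hip", "torque_knee", "torque_ankle")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outcomes"] = list(self.outcomes)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded)."""
        d = self.to_dict()
        d.pop("data_dir", None)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# trial and participant IO

def write_trial_csv(path: Path, time: np.ndarray, markers: dict, meta: dict) -> None:
    df = pd.DataFrame({"time": time})
    for m in ("hip", "knee", "ankle", "toe"):
        df[f"{m}_x"] = markers[m][:, 0]
        df[f"{m}_y"] = markers[m][:, 1]
    df.to_csv(path, index=False, float_format="%.6f")
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_trial_csv(path: Path) -> tuple[np.ndarray, dict, dict]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # surface file context for malformed input
        raise ValueError(f"malformed trial CSV {path}: {exc}") from exc
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV {path} missing columns {missing}")
    markers = {
        m: df[[f"{m}_x", f"{m}_y"]].to_numpy(float) for m in ("hip", "knee", "ankle", "toe")
    }
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return df["time"].to_numpy(float), markers, meta


def write_participant_json(path: Path, profile: synthetic.ParticipantProfile) -> None:
    path.write_text(json.dumps({
        "id": profile.pid,
        "group": profile.group,
        "anthropometrics": profile.anthropometrics.to_dict(),
        "rom_deg": profile.rom_deg,
        "rho": profile.rho,
    }, indent=1))


def read_participant_json(path: Path) -> dict:
    d = json.loads(path.read_text())
    d["anthropometrics"] = Anthropometrics.from_dict(d["anthropometrics"])
    return d


# ---------------------------------------------------------------------------
# per-trial processing

@dataclass
class TrialMetrics:
    """End-point and motor-strategy metrics of one pointing trial."""

    h_error: float                 # cm, anterior-positive
    v_error: float                 # cm, upward-positive
    area: float                    # m^2
    log_area: float
    movement_time: float           # s
    mean_torque: np.ndarray        # (3,) N m flexor-positive, hip/knee/ankle
    phase: kinematics.ReversalPhase


def process_trial(
    model: LimbModel,
    markers: dict,
    fs: float,
    target_point: np.ndarray,
    cutoff: float = 6.0,
    filter_data: bool = True,
) -> TrialMetrics:
    """Run one trial through the full measurement chain.

    Filter, crop to the moving portion, segment the reversal phase, decompose
    torques, and compute end-point metrics.  Raises
    :class:`~limbpoint.kinematics.ReversalDetectionError` when the toe-speed
    profile has no out-and-back structure.
    """
    kin = kinematics.analyze_markers(markers, fs, cutoff=cutoff, filter_data=filter_data)
    kin = kinematics.crop_to_movement(kin)
    phase = kinematics.detect_reversal_phase(kin.toe_speed)
    decomp = dynamics.decompose_torques(model, kin)
    mean_tq = dynamics.mean_muscle_torque(decomp, phase)
    toe = kin.markers["toe"]
    h, v = endpoint.endpoint_errors(toe[phase.reversal], target_point)
    area = endpoint.foot_path_area(toe, phase)
    return TrialMetrics(
        h_error=h,
        v_error=v,
        area=area,
        log_area=endpoint.log_area(area),
        movement_time=kinematics.movement_time(phase, fs),
        mean_torque=mean_tq,
        phase=phase,
    )


def cohort_metric_table(cohort: synthetic.Cohort, cutoff: float = 6.0) -> pd.DataFrame:
    """Long cohort table: one row per analyzable trial plus participant columns.

    Trials whose reversal phase cannot be detected are skipped and counted in
    the log.  The ankle-only target carries the ``uncollapsed`` class and is
    excluded by the statistics stage.
    """
    prof_by_id = {p.pid: p for p in cohort.profiles}
    proprio = proprioception.score_sessions(cohort.proprioception)
    pooled = proprio[proprio["joint"] == "pooled"].pivot_table(
        index="participant", columns="test", values="score"
    )
    rows = []
    n_failed = 0
    for trial in cohort.trials:
        rec = trial.record
        prof = prof_by_id[rec_pid(trial)]
        try:
            m = process_trial(
                prof.model, trial.markers, trial.fs, trial.target.target_point, cutoff=cutoff
            )
        except kinematics.ReversalDetectionError:
            n_failed += 1
            continue
        rows.append(dict(
            participant=prof.pid,
            group=prof.group,
            target=rec.target_class,
            combo=combo_label(rec.combo),
            vision=rec.vision,
            block=rec.block,
            h_error=m.h_error,
            v_error=m.v_error,
            area_cm2=m.area * 1e4,
            log_area=m.log_area,
            movement_time=m.movement_time,
            torque_hip=m.mean_torque[0],
            torque_knee=m.mean_torque[1],
            torque_ankle=m.mean_torque[2],
            max_rom=max(prof.rom_deg.values()),
            rho=prof.rho,
            mds=float(pooled.loc[prof.pid, "mds"]) if prof.pid in pooled.index else np.nan,
            jps=float(pooled.loc[prof.pid, "jps"]) if prof.pid in pooled.index else np.nan,
        ))
    if n_failed:
        log.warning("reversal detection failed on %d trials (excluded)", n_failed)
    return pd.DataFrame(rows)


def rec_pid(trial: synthetic.SimulatedTrial) -> str:
    """Participant id attached to a trial."""
    return trial.pid


# ---------------------------------------------------------------------------
# full run

def run_pipeline(config: RunConfig) -> dict:
    """Simulate (or load) a cohort, compute the metric table, and fit the models.

    Returns a dict with the metric table, model results, contrasts and paths
    of everything written.  Deterministic given (config, seed).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir / "run.log")
    log.info("run config hash %s", config.config_hash())

    if config.simulate:
        cc = synthetic.CohortConfig(
            n_control=config.n_control,
            n_sci=config.n_sci,
            trials_per_combo_per_block=config.trials_per_combo_per_block,
            fs=config.fs,
            fraction=config.fraction,
            marker_noise_sd=config.marker_noise_sd,
        )
        cohort = synthetic.simulate_cohort(cc, seed=config.seed)
    else:
        cohort = load_cohort(Path(config.data_dir), fs=config.fs, fraction=config.fraction)
    table = cohort_metric_table(cohort, cutoff=config.filter_cutoff)
    table.insert(0, "config_hash", config.config_hash())
    metrics_path = out_dir / "cohort_metrics.csv"
    table.to_csv(metrics_path, index=False)
    log.info("wrote %d trial rows to %s", len(table), metrics_path)

    proprio_scores = proprioception.score_sessions(cohort.proprioception)
    proprio_scores.to_csv(out_dir / "proprioception_scores.csv", index=False)

    results = {}
    contrast_rows = []
    model_rows = []
    for outcome in config.outcomes:
        try:
            res = stats.fit_group_model(table, outcome, alpha=config.alpha)
        except Exception as exc:
            log.warning("model for %s failed: %s", outcome, exc)
            continue
        results[outcome] = res
        model_rows.append(dict(
            outcome=outcome, structure=res.structure, aic=res.aic,
            marginal_r2=res.marginal_r2, f2=stats.cohens_f2(res.marginal_r2),
            p_group_target=res.interaction_pvalues.get("group:target"),
            p_group_vision=res.interaction_pvalues.get("group:vision"),
            singular=res.singular,
        ))
        for c in stats.posthoc_group_contrasts(res, adjust=config.adjust,
                                               d_scale=config.d_scale):
            contrast_rows.append(dict(outcome=outcome, target=c.target,
                                      estimate=c.estimate, se=c.se,
                                      ci_low=c.ci_low, ci_high=c.ci_high,
                                      p=c.p, p_adjusted=c.p_adjusted, d=c.cohens_d))
    pd.DataFrame(model_rows).to_csv(out_dir / "model_summary.csv", index=False)
    pd.DataFrame(contrast_rows).to_csv(out_dir / "group_contrasts.csv", index=False)
    _write_report(out_dir / "report.txt", config, results, contrast_rows)
    return dict(table=table, models=results, contrasts=contrast_rows,
                out_dir=out_dir, cohort=cohort)


def export_cohort(cohort: synthetic.Cohort, data_dir: Path) -> None:
    """Write a simulated cohort in the on-disk trial/participant formats."""
    data_dir.mkdir(parents=True, exist_ok=True)
    for prof in cohort.profiles:
        write_participant_json(data_dir / f"participant_{prof.pid}.json", prof)
    for trial in cohort.trials:
        rec = trial.record
        pid = rec_pid(trial)
        name = f"trial_{pid}_{rec.trial_index:03d}"
        write_trial_csv(data_dir / f"{name}.csv", trial.time, trial.markers, meta=dict(
            participant=pid, block=rec.block, vision=rec.vision,
            combo=combo_label(rec.combo), seed=trial.seed, fs=trial.fs,
            target_point=list(map(float, trial.target.target_point)),
        ))
    cohort.proprioception.to_csv(data_dir / "proprioception_trials.csv", index=False)


def load_cohort(data_dir: Path, fs: float = 65.0, fraction: float = 0.6) -> synthetic.Cohort:
    """Load trials and participants written by :func:`export_cohort`."""
    profiles = []
    for p in sorted(data_dir.glob("participant_*.json")):
        d = read_participant_json(p)
        profiles.append(synthetic.ParticipantProfile(
            pid=d["id"], group=d["group"], anthropometrics=d["anthropometrics"],
            rom_deg={k: float(v) for k, v in d["rom_deg"].items()},
            rho=float(d.get("rho", 0.0)),
        ))
    prof_by_id = {p.pid: p for p in profiles}
    trials = []
    targets = {}
    home = np.zeros(3)
    for path in sorted(data_dir.glob("trial_*.csv")):
        time, markers, meta = read_trial_csv(path)
        prof = prof_by_id[meta["participant"]]
        combo = combo_from_label(meta["combo"])
        key = (prof.pid, combo)
        if key not in targets:
            targets[key] = make_target(prof.model, home, prof.rom_deg, combo, fraction=fraction)
        from .protocol import ScheduleRecord, collapse_target_class
        rec = ScheduleRecord(block=int(meta["block"]), vision=meta["vision"],
                             combo=combo, target_class=collapse_target_class(combo),
                             trial_index=int(path.stem.rsplit("_", 1)[-1]))
        trial = synthetic.SimulatedTrial(
            record=rec, target=targets[key], fs=float(meta.get("fs", fs)),
            time=time, commanded_torque=np.full((len(time), 3), np.nan),
            seg_rad=np.full((len(time), 3), np.nan),
            omega=np.full((len(time), 3), np.nan),
            alpha=np.full((len(time), 3), np.nan),
            markers=markers, out_duration=np.nan, seed=int(meta.get("seed", -1)),
            pid=prof.pid,
        )
        trials.append(trial)
    proprio_path = data_dir / "proprioception_trials.csv"
    proprio = pd.read_csv(proprio_path) if proprio_path.exists() else pd.DataFrame()
    cc = synthetic.CohortConfig(fs=fs, fraction=fraction)
    return synthetic.Cohort(config=cc, profiles=profiles, targets=targets,
                            trials=trials, proprioception=proprio)


def _setup_logging(logfile: Path) -> None:
    log.setLevel(logging.INFO)
    have = {getattr(h, "_limbpoint_tag", None) for h in log.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler(sys.stderr)
        h._limbpoint_tag = "stderr"
        log.addHandler(h)
    fh = logging.FileHandler(logfile)
    fh._limbpoint_tag = "file"
    log.addHandler(fh)


def _write_report(path: Path, config: RunConfig, results: dict, contrasts: list) -> None:
    lines = [
        "limbpoint pipeline report",
        f"config hash: {config.config_hash()}",
        f"seed: {config.seed}",
        "",
    ]
    for outcome, res in results.items():
        lines += [
            f"outcome: {outcome}",
            f"  selected structure: {res.structure}",
            f"  marginal R^2 = {res.marginal_r2:.3f}, f^2 = {stats.cohens_f2(res.marginal_r2):.3f}",
            f"  AIC = {res.aic:.1f}; interactions: " + ", ".join(
                f"{k} p={v:.4g}" for k, v in res.interaction_pvalues.items()
            ),
        ]
        for c in contrasts:
            if c["outcome"] == outcome:
                lines.append(
                    f"  SCI-control @ {c['target']}: {c['estimate']:.4g} "
                    f"[{c['ci_low']:.4g}, {c['ci_high']:.4g}], p_adj={c['p_adjusted']:.4g}, "
                    f"d={c['d']:.2f}"
                )
        lines.append("")
    path.write_text("\n".join(lines))
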