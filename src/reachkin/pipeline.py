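"""End-to-end orchestration: simulate → preprocess → segment → kinematics → inference.

``run_pipeline`` drives a whole multi-participant study from one config and
one seed, producing the per-trial kinematics table, the per-condition
descriptives, the model-comparison table and a reconciled run report.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .betaglmm import fit_ladder
from .compare import descriptives, lrt_ladder, model_comparison
from .io import write_events, write_report, write_trace
from .kinematics import KinematicsConfig, process_trial
from .preprocess import CalibrationError, calibrate
from .segment import VALID_CORRECT, parse_events
from .sensor import AccelTrace, SensorParams
from .session import BetaGlmmParams, SubjectEffects, TaskParams, gen_session

log = logging.getLogger("reachkin")


@dataclass
class PipelineConfig:
    """Everything a run needs; every tolerance and bound lives here."""

    out_dir: Path = Path("pipeline_out")
    seed: int = 0
    n_participants: int = 19
    simulate: bool = True
    #: (trace_csv, events_csv) pairs for load mode
    inputs: list = field(default_factory=list)
    task: TaskParams = field(default_factory=TaskParams)
    sensor: SensorParams = field(default_factory=SensorParams)
    glmm: BetaGlmmParams = field(default_factory=BetaGlmmParams)
    kin: KinematicsConfig = field(default_factory=KinematicsConfig)
    models: tuple = ("mb0", "mb1", "mb2", "mb3")
    quad_order: int = 15
    calibration_mode: str = "reference"
    min_calibration_window_s: float = 0.5
    write_raw: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current) and isinstance(value, dict):
                setattr(cfg, key, dataclasses.replace(current, **value))
            elif key == "out_dir":
                cfg.out_dir = Path(value)
            elif key == "models":
                cfg.models = tuple(value)
            else:
                setattr(cfg, key, value)
        return cfg


def process_session(trace: AccelTrace, events_df: pd.DataFrame,
                    config: PipelineConfig, participant: str) -> pd.DataFrame:
    """Calibrate one recording and extract per-trial kinematics."""
    events = parse_events(events_df)
    rest = [(0.0, events[0].P)] if events else []
    rest += [(ev.P, ev.S) for ev in events if ev.S is not None]
    try:
        calibrated, report = calibrate(
            trace, rest, mode=config.calibration_mode,
            min_window_s=config.min_calibration_window_s)
        fallback = np.asarray([0.0, 0.0, 1.0])
    except CalibrationError as exc:
        log.warning("%s: calibration failed (%s); using raw trace", participant, exc)
        calibrated = trace
        fallback = None
    rows = []
    for ev in events:
        tk = process_trial(calibrated, ev, config.kin, fallback_gravity_g=fallback)
        rows.append(dict(participant=participant, trial=tk.trial,
                         condition=tk.condition, validity=tk.validity,
                         rt_ms=tk.rt_ms, md_ms=tk.md_ms, srt_ms=tk.srt_ms,
                         tpv_pct=tk.tpv_pct, retained=tk.retained,
                         flags=";".join(tk.flags)))
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full study and write all stage artifacts under ``out_dir``.

    Returns the run report as a dict (also written as JSON).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sessions = []
    if config.simulate:
        study_ss = np.random.SeedSequence(config.seed)
        subj_seeds = study_ss.spawn(config.n_participants + 1)
        rng_subj = np.random.default_rng(subj_seeds[-1])
        for i in range(config.n_participants):
            pid = f"p{i + 1:02d}"
            b = rng_subj.normal(0.0, config.glmm.sigma_b)
            sess = gen_session(
                task=config.task, sensor=config.sensor, glmm=config.glmm,
                subject=SubjectEffects(participant=pid, tpv_intercept_shift=b),
                seed=int(subj_seeds[i].generate_state(1)[0] % (2**31)),
            )
            if config.write_raw:
                write_trace(sess.trace, out / f"{pid}_trace.csv")
                write_events(sess.events, out / f"{pid}_events.csv")
            sessions.append((pid, sess.trace, sess.events))
    else:
        from .io import read_events, read_trace
        for i, (trace_path, events_path) in enumerate(config.inputs):
            pid = f"p{i + 1:02d}"
            sessions.append((pid, read_trace(trace_path), read_events(events_path)))

    kin_frames = [process_session(trace, ev, config, pid)
                  for pid, trace, ev in sessions]
    kin = pd.concat(kin_frames, ignore_index=True)
    kin.to_csv(out / "kinematics.csv", index=False)

    desc = descriptives(kin)
    desc["by_condition"].to_csv(out / "descriptives.csv", index=False)

    table = kin[(kin["validity"] == VALID_CORRECT) & kin["retained"]].copy()
    table["tpv"] = table["tpv_pct"] / 100.0
    table = table[["participant", "condition", "srt_ms", "tpv"]]

    model_block = None
    if table["participant"].nunique() >= 2 and len(table) > 20:
        fits = [f for f in fit_ladder(table, order=config.quad_order)
                if f.spec.name in config.models]
        comparison = model_comparison(fits)
        lrt = lrt_ladder(fits)
        model_block = dict(
            comparison=comparison.to_dict(orient="records"),
            lrt=lrt.to_dict(orient="records"),
            fits=[dict(model=f.name, k=f.k, n=f.n, loglik=f.loglik,
                       aicc=f.aicc, sigma_b=f.sigma_b, phi=f.phi,
                       beta={name: float(b) for name, b in zip(f.beta_names, f.beta)},
                       converged=f.converged)
                  for f in fits],
        )
        write_report(model_block, out / "model_comparison.json")
    else:
        log.warning("too few retained trials/participants for model fitting")

    counts = desc["counts"]
    n_valid = counts["correct"] + counts["incorrect"]
    report = dict(
        seed=config.seed,
        software_version=__version__,
        config=_config_echo(config),
        participants=sorted(kin["participant"].unique().tolist()),
        stage_counts=dict(
            trials_total=int(len(kin)),
            **counts,
            tpv_retained=int(((kin["validity"] == VALID_CORRECT) & kin["retained"]).sum()),
            glmm_rows=int(len(table)),
        ),
        counts_reconcile=bool(
            len(kin) == n_valid + counts["omission"] + counts["anticipation"]
            and counts["correct"] == counts["tpv_excluded"]
            + int(((kin["validity"] == VALID_CORRECT) & kin["retained"]).sum())
        ),
        models=model_block is not None,
    )
    write_report(report, out / "report.json")
    return report


def _config_echo(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, Path):
            return str(obj)
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj
    return {f.name: enc(getattr(config, f.name))
            for f in dataclasses.fields(config)}
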