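"""Plain-text dataset layout and configuration files.

A generated dataset is one directory per subject with one sub-directory per
time point::

    dataset/
      config.yaml                 flat key-value generator configuration
      truth.tsv                   subject, timepoint, quantity, value, units
      S00/Ctrl/
        torque.tsv                2 columns: time_s, torque_nm
        emg_vl.tsv                time_s, emg_mv
        events.tsv                time_s, kind, context
        passive_torque.tsv / passive_emg_vl.tsv / passive_emg_bf.tsv
        swe_frame0.tsv ... swe_frame4.tsv     speed maps, m/s
        swe_manifest.tsv          frame file, timestamp, ROI (0-based,
                                  half-open: row0 col0 height width)

Traces are 2-column delimited text; maps are plain numeric matrices.  The
maps carry shear-wave *speed*: conversion to modulus is the analysis
pipeline's job.
"""

from __future__ import annotations

from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import (GeneratorConfig, NoiseConfig, QuantityCalibration)
from .cohort import Cohort, RenderedSession, SubjectTruth, TRIAL
from .elastography import Roi, SweClip
from .signals import EMGTrace, StimulusEvent, TorqueTrace
from .twitch import TwitchShape, solve_twitch_shape

_FLOAT_FMT = "%.8g"


# ---------------------------------------------------------------- config

def save_config(config: GeneratorConfig, path) -> None:
    """Write a generator configuration as a flat YAML mapping."""
    data = {
        "n_subjects": config.n_subjects,
        "timepoints": list(config.timepoints),
        "sampling_rate": config.sampling_rate,
        "map_rows": config.map_shape[0],
        "map_cols": config.map_shape[1],
        "pixel_pitch_mm": config.pixel_pitch_mm,
        "roi_side": config.roi_side,
        "n_frames": config.n_frames,
        "seed": config.seed,
        "noise": asdict(config.noise),
        "calibration": {
            name: {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cal).items() if k != "name"}
            for name, cal in config.calibration.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path) -> GeneratorConfig:
    data = yaml.safe_load(Path(path).read_text())
    base = GeneratorConfig()
    cal = {}
    for name, rec in data.get("calibration", {}).items():
        rec = dict(rec)
        rec["trajectory"] = tuple(rec["trajectory"])
        cal[name] = QuantityCalibration(name=name, **rec)
    return GeneratorConfig(
        n_subjects=data.get("n_subjects", base.n_subjects),
        timepoints=tuple(data.get("timepoints", base.timepoints)),
        calibration=cal or dict(base.calibration),
        sampling_rate=data.get("sampling_rate", base.sampling_rate),
        map_shape=(data.get("map_rows", base.map_shape[0]),
                   data.get("map_cols", base.map_shape[1])),
        pixel_pitch_mm=data.get("pixel_pitch_mm", base.pixel_pitch_mm),
        roi_side=data.get("roi_side", base.roi_side),
        n_frames=data.get("n_frames", base.n_frames),
        noise=NoiseConfig(**data.get("noise", {})),
        seed=data.get("seed", base.seed),
    )


# ---------------------------------------------------------------- traces

def _write_trace(path: Path, trace, value_name: str) -> None:
    pd.DataFrame({"time_s": trace.times,
                  value_name: trace.samples}).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _read_trace(path: Path, cls, rate_hint=None, **kwargs):
    arr = pd.read_csv(path, sep="\t").to_numpy(dtype=float)
    t, y = arr[:, 0], arr[:, 1]
    rate = rate_hint or 1.0 / float(np.median(np.diff(t)))
    return cls(y, rate, start_time=float(t[0]), **kwargs)


def _write_events(path: Path, events) -> None:
    df = pd.DataFrame([(ev.time, ev.kind, ev.context) for ev in events],
                      columns=["time_s", "kind", "context"])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _read_events(path: Path) -> list[StimulusEvent]:
    df = pd.read_csv(path, sep="\t")
    return [StimulusEvent(float(r.time_s), str(r.kind), str(r.context))
            for r in df.itertuples()]


# ---------------------------------------------------------------- dataset

def write_dataset(cohort: Cohort, out_dir) -> Path:
    """Write a cohort as the plain-text dataset layout; returns the root."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    save_config(cohort.config, root / "config.yaml")
    (root / "seed.txt").write_text(f"{cohort.seed}\n")

    truth_rows = []
    units = {name: cal.units for name, cal in
             cohort.config.calibration.items()}
    units["mrtr"] = "Nm/ms"
    for truth in cohort.truths:
        for q, vals in truth.values.items():
            for tp, v in zip(cohort.config.timepoints, vals):
                truth_rows.append((truth.subject_id, tp, q, v,
                                   units.get(q, "")))
    pd.DataFrame(truth_rows, columns=["subject", "timepoint", "quantity",
                                      "value", "units"]).to_csv(
        root / "truth.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    for truth, subj_sessions in zip(cohort.truths, cohort.sessions):
        for sess in subj_sessions:
            d = root / f"S{truth.subject_id:02d}" / sess.timepoint
            d.mkdir(parents=True, exist_ok=True)
            _write_trace(d / "torque.tsv", sess.torque, "torque_nm")
            _write_trace(d / "emg_vl.tsv", sess.emg_vl, "emg_mv")
            _write_events(d / "events.tsv", sess.torque.events)
            _write_trace(d / "passive_torque.tsv", sess.passive_torque,
                         "torque_nm")
            _write_trace(d / "passive_emg_vl.tsv", sess.passive_emg_vl,
                         "emg_mv")
            _write_trace(d / "passive_emg_bf.tsv", sess.passive_emg_bf,
                         "emg_mv")
            manifest = []
            for k, frame in enumerate(sess.swe.frames):
                fname = f"swe_frame{k}.tsv"
                pd.DataFrame(frame).to_csv(d / fname, sep="\t", index=False,
                                           header=False,
                                           float_format=_FLOAT_FMT)
                r = sess.swe.roi
                manifest.append((fname, float(k * sess.swe.frame_interval_s),
                                 r.row0, r.col0, r.height, r.width))
            pd.DataFrame(manifest, columns=["frame_file", "timestamp_s",
                                            "roi_row0", "roi_col0",
                                            "roi_height", "roi_width"]
                         ).to_csv(d / "swe_manifest.tsv", sep="\t",
                                  index=False)
    return root


def read_dataset(root) -> Cohort:
    """Read a dataset directory back into a :class:`Cohort`.

    Twitch shapes are re-solved from the stored truth so the cohort object
    is fully equivalent for analysis.
    """
    root = Path(root)
    config = load_config(root / "config.yaml")
    seed = int((root / "seed.txt").read_text().strip()) \
        if (root / "seed.txt").exists() else config.seed
    truth_df = pd.read_csv(root / "truth.tsv", sep="\t")

    truths, sessions = [], []
    subject_ids = sorted(truth_df["subject"].unique())
    for sid in subject_ids:
        sub = truth_df[truth_df["subject"] == sid]
        values = {}
        for q in sub["quantity"].unique():
            qq = sub[sub["quantity"] == q].set_index("timepoint")
            values[q] = qq.loc[list(config.timepoints), "value"].to_numpy(
                dtype=float)
        truth = SubjectTruth(int(sid), values)
        truths.append(truth)
        subj_sessions = []
        for t_index, tp in enumerate(config.timepoints):
            d = root / f"S{sid:02d}" / tp
            events = _read_events(d / "events.tsv")
            torque = _read_trace(d / "torque.tsv", TorqueTrace,
                                 config.sampling_rate)
            torque.events = events
            emg = _read_trace(d / "emg_vl.tsv", EMGTrace,
                              config.sampling_rate, channel="VL")
            emg.events = list(events)
            man = pd.read_csv(d / "swe_manifest.tsv", sep="\t")
            frames = [pd.read_csv(d / f, sep="\t", header=None
                                  ).to_numpy(dtype=float)
                      for f in man["frame_file"]]
            r0 = man.iloc[0]
            roi = Roi(int(r0.roi_row0), int(r0.roi_col0),
                      int(r0.roi_height), int(r0.roi_width))
            swe = SweClip(frames, roi, config.pixel_pitch_mm, 1.0)
            p = truth.at("tw_pot", t_index)
            shape = solve_twitch_shape(truth.at("ct", t_index),
                                       truth.at("hrt", t_index),
                                       truth.at("mrtd", t_index) / p,
                                       rate=config.sampling_rate)
            subj_sessions.append(RenderedSession(
                int(sid), tp, torque, emg, swe,
                _read_trace(d / "passive_torque.tsv", TorqueTrace,
                            config.sampling_rate),
                _read_trace(d / "passive_emg_vl.tsv", EMGTrace,
                            config.sampling_rate, channel="VL"),
                _read_trace(d / "passive_emg_bf.tsv", EMGTrace,
                            config.sampling_rate, channel="BF"),
                shape))
        sessions.append(subj_sessions)
    return Cohort(config, seed, truths, sessions)


def write_summary(summary, out_dir, run_log: dict | None = None) -> Path:
    """Write a cohort summary as delimited tables (+ optional run log)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("values", "absolute", "changes", "anova", "lsd",
                 "excluded"):
        df = getattr(summary, name)
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                  float_format=_FLOAT_FMT)
    if run_log:
        (out / "run_log.yaml").write_text(yaml.safe_dump(run_log,
                                                         sort_keys=False))
    return out
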