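"""Synthetic cohort generator.

Generates a full synthetic fatigue experiment with the statistical structure
of the emulated study: per-subject ground-truth trajectories for every
measured quantity, plus rendered raw signals (torque and EMG at 2 kHz) and
shear-wave elastography clips at each of the 7 protocol time points.

Generative model per subject and quantity: a baseline B ~ N(ctrl_mean,
ctrl_sd) (truncated at 5% of the control mean) and a signed fractional end
change d ~ N(end_change_mean, end_change_sd) are drawn once; the trajectory
is v(t) = B * (1 + d * g(t)), where g(t) is the normalized group-mean change
shape (g(Ctrl) = 0, g(end) = 1).  Quantities the study found unchanged use
d = 0.  The cohort mean of per-subject end changes therefore recovers the
configured end-change mean by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .calibration import GeneratorConfig
from .elastography import Roi, SweClip
from .errors import InvalidTruthError
from .signals import (DOUBLET, RESTING, SINGLE, SUPERIMPOSED, EMGTrace,
                      StimulusEvent, TorqueTrace)
from .twitch import (TwitchShape, doublet_waveform, smoothed_derivative,
                     solve_twitch_shape, superimposed_increment_waveform)

__all__ = [
    "SubjectTruth", "RenderedSession", "Cohort", "draw_subject_truth",
    "render_twitch", "render_mvc_trial", "render_swe_clip",
    "render_passive_scan", "generate_cohort", "TRIAL",
]

#: bounds on the dimensionless twitch shape factor s = MRTD * CT / P.
#: Lower bound: a rise reaching P at CT cannot have max slope below P/CT,
#: and the capped-rise family's own floor is ~1.4*P/CT.  Upper bound: s
#: far above the observed ~3 forces an implausibly spike-like rise.
MRTD_SHAPE_FACTOR_BOUNDS = (1.45, 4.5)

HRT_BOUNDS_MS = (20.0, 340.0)   # keeps tau_d = HRT/ln2 inside [10, 500] ms


@dataclass(frozen=True)
class TrialTimeline:
    """Timing of one measurement block (seconds from trial start)."""

    rest_pre: float = 0.5
    ramp: float = 0.25
    plateau: float = 5.0
    sup_offset: float = 3.0      # superimposed doublet, into the plateau
    post_doublet: float = 3.0    # potentiated doublet after cessation
    post_twitch: float = 3.0     # single twitch after the doublet
    tail: float = 1.5
    rms_window: tuple[float, float] = (2.3, 2.8)  # into the plateau

    @property
    def plateau_start(self) -> float:
        return self.rest_pre + self.ramp

    @property
    def t_sup(self) -> float:
        return self.plateau_start + self.sup_offset

    @property
    def cessation(self) -> float:
        return self.plateau_start + self.plateau

    @property
    def t_doublet(self) -> float:
        return self.cessation + self.post_doublet

    @property
    def t_twitch(self) -> float:
        return self.t_doublet + self.post_twitch

    @property
    def duration(self) -> float:
        return self.t_twitch + self.tail


TRIAL = TrialTimeline()


@dataclass
class SubjectTruth:
    """Ground-truth values for one subject: quantity -> 7 time-point array."""

    subject_id: int
    values: dict[str, np.ndarray]

    def at(self, quantity: str, t_index: int) -> float:
        return float(self.values[quantity][t_index])


@dataclass
class RenderedSession:
    """Rendered signals of one subject at one time point."""

    subject_id: int
    timepoint: str
    torque: TorqueTrace          # MVC trial + resting stimulations
    emg_vl: EMGTrace
    swe: SweClip
    passive_torque: TorqueTrace  # during the 5-s elastography scan
    passive_emg_vl: EMGTrace
    passive_emg_bf: EMGTrace
    shape: TwitchShape


@dataclass
class Cohort:
    config: GeneratorConfig
    seed: int
    truths: list[SubjectTruth]
    sessions: list[list[RenderedSession]] = field(repr=False)

    @property
    def n_subjects(self) -> int:
        return len(self.truths)


def draw_subject_truth(config: GeneratorConfig, subject_index: int,
                       rng: np.random.Generator) -> SubjectTruth:
    """Draw one subject's ground-truth trajectories for every quantity."""
    values: dict[str, np.ndarray] = {}
    for name, cal in config.calibration.items():
        g = cal.shape_g()
        baseline = rng.normal(cal.ctrl_mean, cal.ctrl_sd)
        baseline = max(baseline, 0.05 * cal.ctrl_mean)
        d = 0.0
        if cal.changes:
            d = rng.normal(cal.end_change_mean_pct, cal.end_change_sd_pct) / 100.0
            # keep the whole trajectory positive (no sign flips)
            gmax = float(np.max(np.abs(g)))
            if gmax > 0:
                d = float(np.clip(d, -0.95 / gmax, 20.0 / gmax))
        values[name] = baseline * (1.0 + d * g)

    if "val" in values:
        values["val"] = np.clip(values["val"], 1.0, 100.0)
    if "hrt" in values:
        values["hrt"] = np.clip(values["hrt"], *HRT_BOUNDS_MS)
    # scans in the emulated study all passed the relaxation gate; keep the
    # rendered passive activity strictly inside it (exclusion handling is
    # exercised with crafted sessions instead)
    for key in ("vl_passive_rms", "bf_passive_rms"):
        if key in values:
            values[key] = np.clip(values[key], None, 0.008)
    if {"mrtd", "tw_pot", "ct"} <= values.keys():
        # keep the shape factor s = MRTD*CT/P inside its physiological
        # band at every time point by rescaling the whole MRTD trajectory;
        # a common rescale preserves the per-subject percent changes
        lo, hi = MRTD_SHAPE_FACTOR_BOUNDS
        s = values["mrtd"] * values["ct"] / values["tw_pot"]
        lam_min = lo / float(np.min(s))
        lam_max = hi / float(np.max(s))
        if lam_min <= lam_max:
            lam = float(np.clip(1.0, lam_min, lam_max))
        else:   # irreconcilable draw combination: split the difference
            lam = float(np.sqrt(lam_min * lam_max))
        if lam != 1.0:
            values["mrtd"] = values["mrtd"] * lam
        # guarantee solvability cell-wise (only reachable after the
        # irreconcilable fallback, ~3e-4 of subjects)
        values["mrtd"] = np.clip(values["mrtd"],
                                 lo * values["tw_pot"] / values["ct"],
                                 hi * values["tw_pot"] / values["ct"])
    return SubjectTruth(subject_index, values)


def _twitch_shape_at(truth: SubjectTruth, t_index: int,
                     rate: float) -> TwitchShape:
    p = truth.at("tw_pot", t_index)
    return solve_twitch_shape(truth.at("ct", t_index),
                              truth.at("hrt", t_index),
                              truth.at("mrtd", t_index) / p, rate=rate)


def render_twitch(shape: TwitchShape, p_nm: float, emd_ms: float,
                  t_stim: float = 0.5, rate: float = 2000.0,
                  duration: float | None = None, noise_sd: float = 0.0,
                  rng: np.random.Generator | None = None) -> TorqueTrace:
    """Render a single resting potentiated twitch into a torque trace.

    The trace is zero until ``t_stim + EMD``; the peak equals ``p_nm``.
    """
    if p_nm < 0:
        raise InvalidTruthError(f"peak torque must be >= 0, got {p_nm}")
    if duration is None:
        duration = t_stim + (emd_ms + shape.ct + 6.0 * shape.hrt) / 1000.0 + 0.2
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    if t_stim < 0 or t_stim >= duration:
        from .errors import EventPlacementError
        raise EventPlacementError(f"t_stim {t_stim} outside trace span")
    tau_ms = (t - t_stim - emd_ms / 1000.0) * 1000.0
    y = p_nm * shape.waveform(tau_ms)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        y = y + rng.normal(0.0, noise_sd, n)
    return TorqueTrace(y, rate, events=[StimulusEvent(t_stim, SINGLE, RESTING)])


def _bandlimited_noise(n: int, rate: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Zero-mean noise band-limited to the surface-EMG 10-500 Hz band."""
    sos = sps.butter(4, [10.0, min(500.0, 0.49 * rate)],
                     btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, rng.standard_normal(n))


def _scaled_to_rms(x: np.ndarray, window: slice, target_rms: float
                   ) -> np.ndarray:
    """Rescale so the RMS over ``window`` equals ``target_rms`` exactly."""
    if target_rms <= 0:
        return np.zeros_like(x)
    cur = float(np.sqrt(np.mean(x[window] ** 2)))
    return x * (target_rms / cur) if cur > 0 else x


def _mwave_wavelet(rate: float) -> np.ndarray:
    """Unit peak-to-peak biphasic M-wave wavelet (12 ms, Hann-windowed)."""
    dur = 0.012
    n = max(int(round(dur * rate)), 4)
    t = np.arange(n) / rate
    w = np.sin(2.0 * np.pi * t / dur) * np.hanning(n)
    return w / (w.max() - w.min())


def render_mvc_trial(truth: SubjectTruth, t_index: int,
                     config: GeneratorConfig, rng: np.random.Generator,
                     shape: TwitchShape | None = None,
                     timeline: TrialTimeline = TRIAL
                     ) -> tuple[TorqueTrace, EMGTrace]:
    """Render one measurement block: MVC with superimposed doublet, then
    (at rest) a potentiated doublet and a potentiated single twitch.

    The voluntary profile is a 250-ms ramp to a 5-s plateau at
    MVC * (1 + N(0, plateau_cv)); the superimposed doublet is delivered 3 s
    into the plateau with evoked increment Db_pot * (1 - VAL/100); the
    potentiated doublet and twitch follow 3 and 6 s after cessation.  The
    VL EMG holds band-limited activity at RMS = (RMS/Mmax)*Mmax during the
    plateau and an M-wave wavelet (peak-to-peak = Mmax) at each stimulus.
    """
    rate = config.sampling_rate
    tl = timeline
    val = truth.at("val", t_index)
    if not 0.0 < val <= 100.0:
        raise InvalidTruthError(f"VAL must be in (0, 100], got {val}")
    mvc = truth.at("mvc", t_index)
    db = truth.at("db_pot", t_index)
    p_tw = truth.at("tw_pot", t_index)
    emd = truth.at("emd", t_index)
    if shape is None:
        shape = _twitch_shape_at(truth, t_index, rate)

    n = int(round(tl.duration * rate))
    t = np.arange(n) / rate
    plateau_level = mvc * (1.0 + rng.normal(0.0, config.noise.plateau_cv))

    # voluntary profile: cosine ramps, flat plateau
    y = np.zeros(n)
    up = (t >= tl.rest_pre) & (t < tl.plateau_start)
    y[up] = plateau_level * 0.5 * (1 - np.cos(np.pi * (t[up] - tl.rest_pre) / tl.ramp))
    y[(t >= tl.plateau_start) & (t < tl.cessation)] = plateau_level
    down = (t >= tl.cessation) & (t < tl.cessation + tl.ramp)
    y[down] = plateau_level * 0.5 * (1 + np.cos(np.pi * (t[down] - tl.cessation) / tl.ramp))

    # superimposed doublet: brief evoked increment on top of the plateau
    amp_sup = db * (1.0 - val / 100.0)
    tau_sup = (t - tl.t_sup - emd / 1000.0) * 1000.0
    y += amp_sup * superimposed_increment_waveform(shape, tau_sup, emd_ms=emd)

    # resting stimulations: potentiated doublet, then single twitch
    tau_db = (t - tl.t_doublet - emd / 1000.0) * 1000.0
    y += db * doublet_waveform(shape, tau_db)
    tau_tw = (t - tl.t_twitch - emd / 1000.0) * 1000.0
    y += p_tw * shape.waveform(tau_tw)

    if config.noise.torque_noise_sd > 0:
        y += rng.normal(0.0, config.noise.torque_noise_sd, n)

    events = [StimulusEvent(tl.t_sup, DOUBLET, SUPERIMPOSED),
              StimulusEvent(tl.t_doublet, DOUBLET, RESTING),
              StimulusEvent(tl.t_twitch, SINGLE, RESTING)]
    torque = TorqueTrace(y, rate, events=list(events))

    # --- EMG channel (VL) ---
    mmax = truth.at("mmax", t_index)
    rms_target = truth.at("rms_mmax", t_index) * mmax
    emg = _bandlimited_noise(n, rate, rng)
    active = (t >= tl.rest_pre) & (t < tl.cessation + tl.ramp)
    rms_w = slice(int((tl.plateau_start + tl.rms_window[0]) * rate),
                  int((tl.plateau_start + tl.rms_window[1]) * rate))
    emg = _scaled_to_rms(emg, rms_w, rms_target)
    emg[~active] *= (truth.at("vl_passive_rms", t_index) / rms_target
                     if rms_target > 0 else 0.0)
    wavelet = _mwave_wavelet(rate) * mmax
    for ev in events:
        pulses = (0.0, 0.010) if ev.kind == DOUBLET else (0.0,)
        for dp in pulses:
            i0 = int(round((ev.time + dp + 0.003) * rate))
            emg[i0:i0 + len(wavelet)] += wavelet[:max(0, n - i0)]
    emg_trace = EMGTrace(emg, rate, events=list(events), channel="VL")
    return torque, emg_trace


def render_swe_clip(mu_true: float, config: GeneratorConfig,
                    rng: np.random.Generator) -> SweClip:
    """Render a 5-frame shear-wave-speed clip for a resting muscle.

    Pixel value (m/s) = sqrt(mu_true) + eta_frame + eps_pixel with
    eta_frame ~ N(0, frame_speed_sd) shared within a frame and
    eps_pixel ~ N(0, pixel_speed_sd) independent per pixel.
    """
    if mu_true <= 0:
        raise InvalidTruthError(f"shear modulus must be positive, got {mu_true}")
    vs = float(np.sqrt(mu_true))  # rho = 1000 kg/m^3, mu in kPa
    rows, cols = config.map_shape
    frames = []
    for _ in range(config.n_frames):
        frame = np.full((rows, cols), vs)
        if config.noise.frame_speed_sd > 0:
            frame += rng.normal(0.0, config.noise.frame_speed_sd)
        if config.noise.pixel_speed_sd > 0:
            frame += rng.normal(0.0, config.noise.pixel_speed_sd,
                                (rows, cols))
        frames.append(np.clip(frame, 0.0, None))
    r0 = (rows - config.roi_side) // 2
    c0 = (cols - config.roi_side) // 2
    roi = Roi(r0, c0, config.roi_side, config.roi_side)
    return SweClip(frames, roi, config.pixel_pitch_mm, 1.0)


def render_passive_scan(truth: SubjectTruth, t_index: int,
                        config: GeneratorConfig, rng: np.random.Generator,
                        duration: float = 5.0
                        ) -> tuple[TorqueTrace, EMGTrace, EMGTrace]:
    """Passive torque and VL/BF EMG monitored during the 5-s SWE scan."""
    rate = config.sampling_rate
    n = int(round(duration * rate))
    level = truth.at("passive_torque", t_index)
    y = np.full(n, level)
    if config.noise.torque_noise_sd > 0:
        y += rng.normal(0.0, config.noise.torque_noise_sd, n)
    torque = TorqueTrace(y, rate)
    traces = []
    for ch, key in (("VL", "vl_passive_rms"), ("BF", "bf_passive_rms")):
        e = _bandlimited_noise(n, rate, rng)
        e = _scaled_to_rms(e, slice(0, n), truth.at(key, t_index))
        traces.append(EMGTrace(e, rate, channel=ch))
    return torque, traces[0], traces[1]


def generate_cohort(config: GeneratorConfig,
                    seed: int | None = None) -> Cohort:
    """Generate the full synthetic experiment (all subjects x time points).

    Deterministic: the same config and seed yield an identical dataset.
    Ground truth is stored alongside the rendered signals for recovery
    testing.
    """
    if seed is None:
        seed = config.seed
    root = np.random.default_rng(seed)
    subject_rngs = root.spawn(config.n_subjects)
    truths: list[SubjectTruth] = []
    sessions: list[list[RenderedSession]] = []
    for i, rng in enumerate(subject_rngs):
        truth = draw_subject_truth(config, i, rng)
        truths.append(truth)
        subj_sessions = []
        for t_index, label in enumerate(config.timepoints):
            shape = _twitch_shape_at(truth, t_index, config.sampling_rate)
            torque, emg = render_mvc_trial(truth, t_index, config, rng,
                                           shape=shape)
            swe = render_swe_clip(truth.at("mu", t_index), config, rng)
            p_tr, vl_tr, bf_tr = render_passive_scan(truth, t_index, config,
                                                     rng)
            subj_sessions.append(RenderedSession(
                i, label, torque, emg, swe, p_tr, vl_tr, bf_tr, shape))
        # maximal rate of torque relaxation is emergent from the shape model
        dt_ms = 1000.0 / config.sampling_rate
        mrtr = np.empty(len(config.timepoints))
        for t_index, sess in enumerate(subj_sessions):
            sh = sess.shape
            tau = np.arange(0.0, sh.ct + 6.0 * sh.hrt + 50.0, dt_ms)
            d = smoothed_derivative(sh.waveform(tau), dt_ms)
            mrtr[t_index] = -d.min() * truth.at("tw_pot", t_index)
        truth.values["mrtr"] = mrtr
        sessions.append(subj_sessions)
    return Cohort(config, seed, truths, sessions)
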