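"""Voluntary and electrically evoked torque metrics.

Extracts, from annotated torque traces: the MVC peak, evoked doublet and
twitch amplitudes, the six electromechanical twitch properties (P, EMD, CT,
HRT, MRTD, MRTR), the voluntary activation level (interpolated-twitch
technique) and the supramaximal stimulation intensity from a recruitment
curve.

Conventions shared with the synthetic renderer: torque derivatives are
central differences of a 5-sample moving-average-smoothed trace, reported
per ms; onsets are threshold crossings back-tracked to the last baseline
crossing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (EmptyInputError, EventPlacementError,
                     InsufficientBaselineError, InvalidDenominatorError,
                     NoPlateauError, NoResponseError, UnresolvedHRTError)
from .signals import RESTING, SUPERIMPOSED, TorqueTrace
from .twitch import smooth, smoothed_derivative

#: exclusion guard around superimposed stimuli when reading the MVC peak
MVC_STIM_GUARD_S = 0.150
#: baseline windows before a stimulus
ONSET_BASELINE_S = 0.100
AMPLITUDE_BASELINE_S = 0.025
#: search windows after a stimulus
ONSET_SEARCH_S = 0.150
PEAK_SEARCH_S = 0.300
SUPERIMPOSED_PEAK_S = 0.200
HRT_SEARCH_S = 0.500


@dataclass(frozen=True)
class TwitchProperties:
    """Electromechanical properties of one evoked twitch.

    P (Nm), EMD/CT/HRT (ms), MRTD/MRTR (Nm/ms).  ``mrtd_normalized`` and
    ``mrtr_normalized`` are the peak-torque-normalized variants (1/ms),
    stored for completeness.
    """

    p: float
    emd: float
    ct: float
    hrt: float
    mrtd: float
    mrtr: float
    onset_time: float   # s
    peak_time: float    # s
    mrtd_normalized: float = float("nan")
    mrtr_normalized: float = float("nan")


@dataclass(frozen=True)
class ActivationResult:
    db_superimposed: float
    db_potentiated: float
    val: float   # %


def mvc_peak(trace: TorqueTrace) -> float:
    """Peak voluntary torque (Nm).

    The maximum is taken over the voluntary-contraction window: resting
    stimulations (delivered after cessation) are excluded by stopping 0.5 s
    before the earliest resting stimulus, and a +/-150 ms guard around each
    superimposed stimulus keeps the evoked increment out of the peak.
    """
    if len(trace.samples) == 0:
        raise EmptyInputError("empty torque trace")
    mask = np.ones(len(trace.samples), dtype=bool)
    t = trace.times
    resting = trace.events_of(context=RESTING)
    if resting:
        mask &= t < min(ev.time for ev in resting) - 0.5
    for ev in trace.events_of(context=SUPERIMPOSED):
        mask &= ~(np.abs(t - ev.time) <= MVC_STIM_GUARD_S)
    if not mask.any():
        raise EmptyInputError("no samples outside stimulus guards")
    return float(trace.samples[mask].max())


def _baseline(trace: TorqueTrace, stim_time: float, window_s: float
              ) -> tuple[float, float, int]:
    i_stim = trace.index_at(stim_time)
    n_base = int(round(window_s * trace.rate))
    if i_stim - n_base < 0:
        raise InsufficientBaselineError(
            f"need {window_s * 1000:.0f} ms of pre-stimulus baseline")
    seg = trace.samples[i_stim - n_base:i_stim]
    return float(seg.mean()), float(seg.std()), i_stim


def detect_onset(trace: TorqueTrace, stim_time: float) -> float:
    """Torque onset (s) after a stimulus.

    First sample whose smoothed torque exceeds baseline mean +
    max(3*baseline SD, 0.5% of the evoked peak) and *stays* above it for
    5 ms (rejects isolated noise excursions), back-tracked on the raw trace
    to the last baseline crossing.  Resolution is one sample; exact at the
    sample level on noiseless traces.
    """
    bmean, bsd, i_stim = _baseline(trace, stim_time, ONSET_BASELINE_S)
    y = trace.samples
    ys = smooth(y)
    n_peak = min(int(PEAK_SEARCH_S * trace.rate), len(y) - i_stim)
    evoked_peak = y[i_stim:i_stim + n_peak].max() - bmean
    thr = bmean + max(3.0 * bsd, 0.005 * evoked_peak)
    n_search = min(int(ONSET_SEARCH_S * trace.rate), len(y) - i_stim)
    sustain = max(int(0.005 * trace.rate), 1)
    seg = ys[i_stim:i_stim + n_search + sustain] > thr
    run = np.convolve(seg.astype(int), np.ones(sustain, dtype=int),
                      mode="valid") == sustain
    above = np.nonzero(run[:n_search])[0]
    if len(above) == 0:
        raise NoResponseError(
            f"no torque response within {ONSET_SEARCH_S * 1000:.0f} ms "
            f"of stimulus at {stim_time:.3f} s")
    i = i_stim + int(above[0])
    eps = 1e-9 * abs(evoked_peak)   # numerical-zero band around baseline
    while i > i_stim and y[i] > bmean + eps:
        i -= 1
    return trace.start_time + i / trace.rate


def twitch_properties(trace: TorqueTrace, stim_time: float
                      ) -> TwitchProperties:
    """Electromechanical properties of a resting evoked twitch."""
    bmean, _, i_stim = _baseline(trace, stim_time, ONSET_BASELINE_S)
    onset = detect_onset(trace, stim_time)
    i_on = trace.index_at(onset)
    y = trace.samples
    rate = trace.rate
    dt_ms = 1000.0 / rate

    n_peak = min(int(PEAK_SEARCH_S * rate), len(y) - i_on)
    i_pk = i_on + int(np.argmax(y[i_on:i_on + n_peak]))
    # peak time from the raw argmax (the rendered apex is locally
    # symmetric); amplitude from the smoothed trace (noise-robust maximum)
    ys = smooth(y)
    p = float(ys[i_on:i_on + n_peak].max() - bmean)
    emd = (onset - stim_time) * 1000.0
    ct = (i_pk - i_on) * dt_ms

    n_hrt = min(int(HRT_SEARCH_S * rate), len(y) - i_pk)
    below = np.nonzero(y[i_pk:i_pk + n_hrt] < bmean + p / 2.0)[0]
    if len(below) == 0:
        raise UnresolvedHRTError(
            f"torque never fell below half-peak within "
            f"{HRT_SEARCH_S * 1000:.0f} ms of the peak")
    hrt = float(below[0]) * dt_ms

    d = smoothed_derivative(y, dt_ms)
    i_end = min(i_pk + n_hrt, len(y))
    mrtd = float(d[i_on:i_pk + 1].max()) if i_pk > i_on else 0.0
    mrtr = float(-d[i_pk:i_end].min())
    return TwitchProperties(
        p=p, emd=emd, ct=ct, hrt=hrt, mrtd=mrtd, mrtr=mrtr,
        onset_time=onset, peak_time=onset + ct / 1000.0,
        mrtd_normalized=mrtd / p if p > 0 else float("nan"),
        mrtr_normalized=mrtr / p if p > 0 else float("nan"))


def doublet_amplitude(trace: TorqueTrace, stim_time: float,
                      context: str = RESTING) -> float:
    """Evoked doublet amplitude (Nm) above its local baseline.

    Resting: peak within the post-stimulus search window minus the 25-ms
    pre-stimulus mean.  Superimposed: peak within 200 ms minus the voluntary
    torque level (25-ms mean immediately pre-stimulus).
    """
    bmean, _, i_stim = _baseline(trace, stim_time, AMPLITUDE_BASELINE_S)
    ys = smooth(trace.samples)
    window = SUPERIMPOSED_PEAK_S if context == SUPERIMPOSED else \
        PEAK_SEARCH_S + 0.2
    n = min(int(window * trace.rate), len(ys) - i_stim)
    if n <= 0:
        raise EventPlacementError("no samples after stimulus")
    return float(ys[i_stim:i_stim + n].max() - bmean)


def compute_val(db_superimposed: float, db_potentiated: float) -> float:
    """Voluntary activation level (%), interpolated-twitch technique:

        VAL = (1 - Db_superimposed / Db_potentiated) * 100

    clamped to [0, 100].
    """
    if db_potentiated <= 0:
        raise InvalidDenominatorError(
            f"potentiated doublet amplitude must be positive, "
            f"got {db_potentiated}")
    if db_superimposed < 0:
        db_superimposed = 0.0
    return float(np.clip((1.0 - db_superimposed / db_potentiated) * 100.0,
                         0.0, 100.0))


def supramaximal_intensity(recruitment, plateau_tol: float = 0.02) -> float:
    """Supramaximal stimulation intensity (mA) from a recruitment curve.

    ``recruitment`` is a sequence of (intensity mA, response amplitude)
    pairs at strictly increasing intensities.  The optimal intensity is the
    lowest from which every subsequent amplitude stays within
    ``plateau_tol`` of the curve maximum (plateau onset); the supramaximal
    intensity is 130% of it.  If the plateau would start only at the last
    point the curve is still rising and no plateau exists.
    """
    pairs = list(recruitment)
    if len(pairs) < 3:
        raise NoPlateauError("need at least 3 recruitment points")
    intensity = np.asarray([p[0] for p in pairs], dtype=float)
    amp = np.asarray([p[1] for p in pairs], dtype=float)
    if np.any(np.diff(intensity) <= 0):
        raise ValueError("intensities must be strictly increasing")
    amax = amp.max()
    within = amp >= (1.0 - plateau_tol) * amax
    # lowest index from which all subsequent amplitudes are on the plateau
    all_after = np.logical_and.accumulate(within[::-1])[::-1]
    idx = int(np.argmax(all_after))
    if not all_after[idx] or idx == len(pairs) - 1:
        raise NoPlateauError("response still rising at the highest intensity")
    return 1.3 * float(intensity[idx])
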