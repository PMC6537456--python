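"""Surface EMG metrics: plateau RMS, M-wave amplitude, normalization, and
the relaxation check that validates resting elastography scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (ContaminatedWindowError, EventPlacementError,
                     InvalidDenominatorError)
from .signals import EMGTrace, TorqueTrace

#: stimulus artifact half-width excluded from RMS windows
STIM_ARTIFACT_S = 0.020
#: M-wave search window after the stimulus
MWAVE_WINDOW_S = (0.002, 0.050)

#: relaxation thresholds during elastography scans (strict inequalities)
RELAXED_TORQUE_NM = 2.0
RELAXED_EMG_RMS_MV = 0.01


@dataclass(frozen=True)
class RelaxationCheck:
    passed: bool
    passive_torque: float   # Nm, mean over the scan
    vl_rms: float           # mV
    bf_rms: float           # mV


def emg_rms(trace: EMGTrace, window_start: float,
            window_len: float = 0.5) -> float:
    """Root-mean-square EMG (mV) over a window.

    The window must not overlap a +/-20 ms stimulus artifact.
    """
    i0 = trace.index_at(window_start)
    i1 = i0 + int(round(window_len * trace.rate))
    if i1 > len(trace.samples):
        raise EventPlacementError("RMS window extends past the trace")
    t_end = window_start + window_len
    for ev in trace.events:
        if (window_start - STIM_ARTIFACT_S < ev.time
                < t_end + STIM_ARTIFACT_S):
            raise ContaminatedWindowError(
                f"RMS window [{window_start:.3f}, {t_end:.3f}] s overlaps "
                f"the stimulus at {ev.time:.3f} s")
    return float(np.sqrt(np.mean(trace.samples[i0:i1] ** 2)))


def mwave_p2p(trace: EMGTrace, stim_time: float) -> float:
    """Peak-to-peak M-wave amplitude (mV) within [2, 50] ms post stimulus."""
    i0 = trace.index_at(stim_time + MWAVE_WINDOW_S[0])
    i1 = int(round((stim_time + MWAVE_WINDOW_S[1] - trace.start_time)
                   * trace.rate))
    if i1 > len(trace.samples):
        raise EventPlacementError("M-wave window extends past the trace")
    seg = trace.samples[i0:i1]
    return float(seg.max() - seg.min())


def normalized_rms(rms: float, mmax: float) -> float:
    """Voluntary EMG normalized to the M-wave: RMS / Mmax (a.u.)."""
    if mmax <= 0:
        raise InvalidDenominatorError(
            f"M-wave amplitude must be positive, got {mmax}")
    return rms / mmax


def check_relaxation(passive_torque: TorqueTrace, vl: EMGTrace,
                     bf: EMGTrace,
                     torque_threshold: float = RELAXED_TORQUE_NM,
                     emg_threshold: float = RELAXED_EMG_RMS_MV
                     ) -> RelaxationCheck:
    """Verify the muscle was relaxed during an elastography scan.

    Passes iff the mean passive torque is strictly below
    ``torque_threshold`` and each EMG channel's RMS is strictly below
    ``emg_threshold``.
    """
    torque_level = float(np.mean(passive_torque.samples))
    vl_rms = float(np.sqrt(np.mean(vl.samples ** 2)))
    bf_rms = float(np.sqrt(np.mean(bf.samples ** 2)))
    passed = (torque_level < torque_threshold and vl_rms < emg_threshold
              and bf_rms < emg_threshold)
    return RelaxationCheck(passed, torque_level, vl_rms, bf_rms)
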