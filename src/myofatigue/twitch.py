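"""Evoked-twitch waveform model and its shape solver.

A single potentiated twitch is modelled as a unit-peak waveform with three
independently controllable features: contraction time (CT), half relaxation
time (HRT) and the normalized maximal rate of torque development (MRTD/P).

* rise phase on [0, CT]: a saturating exponential
  ``B * (1 - exp(-tau/tau_r))**n`` joined C1 to a quadratic cap
  ``1 - a*(CT - tau)**2`` that covers the last 10% of the rise.  The cap
  puts the apex exactly at CT with genuine curvature, so the peak stays
  well-localized under measurement noise (a purely saturating rise is
  exponentially flat near its peak and its sampled argmax wanders);
* decay phase after CT: exponential with half-life HRT, i.e. a decay
  constant ``tau_d = HRT / ln 2``.

CT and HRT are exact by construction.  The rise time constant ``tau_r`` is
solved so that the *measured* peak slope -- computed exactly the way the
extraction pipeline measures it (2-kHz sampling, 5-sample moving average,
central difference) -- matches the requested normalized MRTD.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .errors import InfeasibleShapeError

LN2 = float(np.log(2.0))

#: parameter bounds of the shape family
TAU_R_BOUNDS = (1.0, 100.0)     # ms
TAU_D_BOUNDS = (10.0, 500.0)    # ms  (tau_d = HRT / ln2)

#: rise fraction where the quadratic peak cap takes over
CAP_VALUE = 0.90

#: smoothing window (samples) shared with the extraction pipeline
SMOOTH_WINDOW = 5


def smooth(y: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average used before differentiating torque."""
    kernel = np.ones(window) / window
    return np.convolve(np.asarray(y, float), kernel, mode="same")


def smoothed_derivative(y: np.ndarray, dt_ms: float,
                        window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Central-difference derivative (per ms) of the smoothed signal."""
    return np.gradient(smooth(y, window), dt_ms)


@lru_cache(maxsize=4096)
def _cap_params(ct: float, hrt: float, tau_r: float, n: float
                ) -> tuple[float, float, float, float, float]:
    """Parameters of the rounded apex: (tau_c, scale, curv, delta_d, tau_dec).

    Rise side: the scaled exponential rise meets the quadratic
    ``1 - curv*(tau - CT)^2`` C1-continuously at ``tau_c`` (value
    CAP_VALUE), apex exactly at CT.  Decay side: the same quadratic
    continues to ``CT + delta_d`` where an exponential with time constant
    ``tau_dec`` takes over C1-continuously, chosen so the waveform crosses
    half-peak exactly at CT + HRT.  The apex is therefore locally symmetric
    (unbiased sampled argmax under noise).  ``delta_d = 0`` marks the
    fallback to a plain exponential decay with half-life HRT (apex kinked;
    only for extreme HRT/curvature combinations).
    """
    def w(t):
        return (1.0 - np.exp(-t / tau_r)) ** n

    def wp(t):
        e = np.exp(-t / tau_r)
        return n * (1.0 - e) ** (n - 1.0) * e / tau_r

    def f(tc):
        return (ct - tc) * CAP_VALUE / w(tc) * wp(tc) - 2.0 * (1.0 - CAP_VALUE)

    grid = np.linspace(1e-6 * ct, ct * (1.0 - 1e-9), 128)
    vals = np.array([f(t) for t in grid])
    idx = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(idx) == 0:
        raise InfeasibleShapeError(
            f"no C1 peak-cap junction for CT={ct}, tau_r={tau_r}, n={n}")
    tc = brentq(f, grid[idx[-1]], grid[idx[-1] + 1], xtol=1e-10)
    scale = CAP_VALUE / w(tc)
    m_c = scale * wp(tc)
    curv = m_c * m_c / (4.0 * (1.0 - CAP_VALUE))

    # decay-side junction: quadratic until delta_d past the apex, then an
    # exponential whose constant keeps the half-decay exactly at CT + HRT
    def g(dd):
        v_j = 1.0 - curv * dd * dd
        tau_dec = v_j / (2.0 * curv * dd)
        return dd + tau_dec * np.log(2.0 * v_j) - hrt

    dd_max = np.sqrt(0.5 / curv) * (1.0 - 1e-9)
    if dd_max >= hrt or g(dd_max) > 0.0:
        delta_d, tau_dec = 0.0, hrt / LN2   # kinked fallback
    else:
        delta_d = brentq(g, 1e-9 / curv ** 0.5, dd_max, xtol=1e-10)
        v_j = 1.0 - curv * delta_d * delta_d
        tau_dec = v_j / (2.0 * curv * delta_d)
    return float(tc), float(scale), float(curv), float(delta_d), \
        float(tau_dec)


def twitch_waveform(tau_ms: np.ndarray, ct: float, hrt: float,
                    tau_r: float, n_rise: float = 2.0) -> np.ndarray:
    """Unit-peak twitch torque at times ``tau_ms`` (ms) after onset."""
    tc, scale, curv, delta_d, tau_dec = _cap_params(
        float(ct), float(hrt), float(tau_r), float(n_rise))
    tau = np.asarray(tau_ms, dtype=float)
    t = np.clip(tau, 0.0, None)
    rise = np.where(t <= tc,
                    scale * (1.0 - np.exp(-t / tau_r)) ** n_rise,
                    1.0 - curv * (ct - t) ** 2)
    v_j = 1.0 - curv * delta_d * delta_d
    decay = np.where(t <= ct + delta_d,
                     1.0 - curv * (t - ct) ** 2,
                     v_j * np.exp(-(t - ct - delta_d) / tau_dec))
    return np.where(tau <= 0.0, 0.0, np.where(tau <= ct, rise, decay))


@dataclass(frozen=True)
class TwitchShape:
    """Solved unit-peak twitch shape."""

    ct: float        # ms, onset -> peak (exact)
    hrt: float       # ms, peak -> half decay (exact)
    tau_r: float     # ms, rise time constant
    tau_d: float     # ms, decay constant (= hrt / ln2)
    n_rise: float = 2.0
    mrtd_clamped: bool = False   # True if requested MRTD was out of range

    def waveform(self, tau_ms: np.ndarray) -> np.ndarray:
        """Unit-peak torque at times ``tau_ms`` (ms) after onset."""
        return twitch_waveform(tau_ms, self.ct, self.hrt, self.tau_r,
                               self.n_rise)


def measured_mrtd_norm(ct: float, hrt: float, tau_r: float,
                       n_rise: float = 2.0, rate: float = 2000.0) -> float:
    """Peak slope (1/ms) of the unit-peak waveform, measured as the
    extraction pipeline does: sampled at ``rate``, 5-sample moving average,
    central difference."""
    dt_ms = 1000.0 / rate
    tau = np.arange(0.0, ct + 6.0 * hrt + 50.0, dt_ms)
    y = twitch_waveform(tau, ct, hrt, tau_r, n_rise)
    return float(smoothed_derivative(y, dt_ms).max())


def solve_twitch_shape(ct: float, hrt: float, mrtd_norm: float,
                       rate: float = 2000.0, strict: bool = False
                       ) -> TwitchShape:
    """Solve shape parameters reproducing (CT, HRT, MRTD/P).

    Parameters
    ----------
    ct, hrt:
        Contraction time and half relaxation time in ms (both > 0).
    mrtd_norm:
        Target normalized peak slope, in 1/ms (MRTD divided by peak
        torque).  The family floor is ~1.4/CT; no rise reaching its peak
        at CT can have a maximal slope below the mean slope 1/CT.
    strict:
        If True, raise :class:`InfeasibleShapeError` when the target MRTD
        is outside the family's range; otherwise return the closest
        achievable shape with ``mrtd_clamped=True``.
    """
    if ct <= 0 or hrt <= 0:
        raise InfeasibleShapeError(f"CT and HRT must be positive: {ct}, {hrt}")
    if mrtd_norm <= 0:
        raise InfeasibleShapeError(f"mrtd_norm must be positive: {mrtd_norm}")
    tau_d = hrt / LN2
    if not TAU_D_BOUNDS[0] <= tau_d <= TAU_D_BOUNDS[1]:
        raise InfeasibleShapeError(
            f"HRT {hrt} ms needs tau_d {tau_d:.1f} ms outside "
            f"{TAU_D_BOUNDS}")

    # measured MRTD decreases with tau_r down to a shallow minimum; solve
    # on the decreasing branch
    grid = np.geomspace(TAU_R_BOUNDS[0], TAU_R_BOUNDS[1], 24)
    vals = np.array([measured_mrtd_norm(ct, hrt, tr, rate=rate)
                     for tr in grid])
    i_min = int(np.argmin(vals))
    if mrtd_norm > vals[0]:
        if strict:
            raise InfeasibleShapeError(
                f"mrtd_norm {mrtd_norm:.4f} above family ceiling "
                f"{vals[0]:.4f} at CT={ct} ms")
        return TwitchShape(ct, hrt, grid[0], tau_d, mrtd_clamped=True)
    if mrtd_norm < vals[i_min]:
        if strict:
            raise InfeasibleShapeError(
                f"mrtd_norm {mrtd_norm:.4f} below family floor "
                f"{vals[i_min]:.4f} at CT={ct} ms")
        return TwitchShape(ct, hrt, grid[i_min], tau_d, mrtd_clamped=True)
    tau_r = brentq(
        lambda tr: measured_mrtd_norm(ct, hrt, tr, rate=rate) - mrtd_norm,
        grid[0], grid[i_min], xtol=1e-6)
    return TwitchShape(ct, hrt, float(tau_r), tau_d)


def doublet_waveform(shape: TwitchShape, tau_ms: np.ndarray,
                     gap_ms: float = 10.0) -> np.ndarray:
    """Unit-peak 100-Hz doublet: linear sum of two twitches ``gap_ms`` apart.

    No force-frequency saturation is modelled; the sum is rescaled to unit
    peak so the amplitude can be set independently.
    """
    tau = np.asarray(tau_ms, dtype=float)
    y = shape.waveform(tau) + shape.waveform(tau - gap_ms)
    dense = np.arange(0.0, shape.ct + gap_ms + 6.0 * shape.hrt, 0.25)
    peak = (shape.waveform(dense) + shape.waveform(dense - gap_ms)).max()
    return y / peak


def superimposed_increment_waveform(shape: TwitchShape, tau_ms: np.ndarray,
                                    gap_ms: float = 10.0,
                                    emd_ms: float = 0.0) -> np.ndarray:
    """Unit-peak evoked increment of a doublet superimposed on an MVC.

    In a near-maximally active muscle the evoked extra force is a brief
    transient, not a full resting doublet.  The rise follows the resting
    doublet shape (time-compressed only if the peak would land later than
    90 ms after the stimulus, EMD included); the decay is accelerated to a
    12-ms half-life and smoothly tapered to exactly zero 145 ms after the
    stimulus, so the evoked increment is confined to the +/-150 ms guard
    used when reading the voluntary peak.
    """
    tau = np.asarray(tau_ms, dtype=float)
    dense = np.arange(0.0, shape.ct + gap_ms + 6.0 * shape.hrt, 0.25)
    d = shape.waveform(dense) + shape.waveform(dense - gap_ms)
    i_pk = int(np.argmax(d))
    t_pk, peak = dense[i_pk], d[i_pk]
    kappa = min(1.0, (90.0 - min(emd_ms, 80.0)) / t_pk)
    t_pk_c = t_pk * kappa

    def rise(t):
        yr = shape.waveform(t / kappa) + shape.waveform(t / kappa - gap_ms)
        return yr / peak

    out = np.where(tau <= t_pk_c, rise(np.clip(tau, 0.0, None)),
                   np.exp(-(tau - t_pk_c) * LN2 / 12.0))
    out = np.where(tau <= 0.0, 0.0, out)
    # raised-cosine taper to exact zero over [125, 145] ms post-stimulus
    t_abs = tau + emd_ms
    taper = np.clip((145.0 - t_abs) / 20.0, 0.0, 1.0)
    taper = 0.5 - 0.5 * np.cos(np.pi * taper)
    return out * taper
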