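"""Study calibration and generator configuration.

The synthetic cohort emulates a single-group fatigue experiment: 15 subjects
perform 60 maximal voluntary contractions (MVCs) of the knee extensors, with
neuromuscular and elastographic measurements at 7 time points (control plus
after every 10 MVCs).  Each measured quantity is calibrated by its control
mean +/- SD, its group-mean trajectory over the 7 time points, and the
distribution of per-subject relative changes at exercise end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidCalibrationError

TIMEPOINTS = ("Ctrl", "MVC10", "MVC20", "MVC30", "MVC40", "MVC50", "MVC60")
N_TIMEPOINTS = len(TIMEPOINTS)


@dataclass(frozen=True)
class QuantityCalibration:
    """Calibration record for one measured quantity.

    Parameters
    ----------
    name:
        Short key used throughout the pipeline (e.g. ``"mvc"``).
    units:
        Physical units of the absolute values.
    ctrl_mean, ctrl_sd:
        Between-subject distribution of the control (non-fatigued) value.
    trajectory:
        Group-mean absolute values at the 7 protocol time points.  For
        quantities that do not change, a constant trajectory.
    end_change_mean_pct, end_change_sd_pct:
        Distribution of the per-subject relative change (in %) from control
        to exercise end; signed (negative = decrease).
    changes:
        Whether the quantity changes with fatigue.  If False the per-subject
        trajectory is flat at the baseline draw.
    """

    name: str
    units: str
    ctrl_mean: float
    ctrl_sd: float
    trajectory: tuple[float, ...]
    end_change_mean_pct: float = 0.0
    end_change_sd_pct: float = 0.0
    changes: bool = False

    def __post_init__(self) -> None:
        if self.ctrl_mean <= 0:
            raise InvalidCalibrationError(
                f"{self.name}: control mean must be positive, got {self.ctrl_mean}"
            )
        if self.ctrl_sd < 0:
            raise InvalidCalibrationError(f"{self.name}: negative control SD")
        if len(self.trajectory) != N_TIMEPOINTS:
            raise InvalidCalibrationError(
                f"{self.name}: trajectory must have {N_TIMEPOINTS} entries"
            )

    def shape_g(self) -> np.ndarray:
        """Normalized change shape g(t) with g(Ctrl)=0 and g(end)=1.

        g(t) = (m_t/m_0 - 1) / (m_end/m_0 - 1) for changing quantities, so a
        per-subject trajectory is v(t) = B * (1 + d * g(t)) where d is the
        subject's signed fractional end change.
        """
        m = np.asarray(self.trajectory, dtype=float)
        if not self.changes:
            return np.zeros(N_TIMEPOINTS)
        denom = m[-1] / m[0] - 1.0
        if denom == 0.0:
            raise InvalidCalibrationError(
                f"{self.name}: flat trajectory for a changing quantity"
            )
        return (m / m[0] - 1.0) / denom


def default_calibration() -> dict[str, QuantityCalibration]:
    """Calibration table of the emulated study (group means +/- SD).

    Trajectories are the published group means at Ctrl, MVC10 ... MVC60;
    end-change distributions are the published per-subject relative changes
    at exercise end.  Quantities reported as unchanged by fatigue (VAL,
    RMS/Mmax, Mmax, HRT, passive measures) are flagged ``changes=False``.
    """
    q = QuantityCalibration
    cal = [
        q("mvc", "Nm", 352.0, 68.0, (352, 270, 226, 208, 202, 192, 211),
          -38.4, 12.6, True),
        q("val", "%", 89.0, 3.9, (89.0,) * 7),
        q("rms_mmax", "a.u.", 0.06, 0.02, (0.06,) * 7),
        q("db_pot", "Nm", 114.3, 14.3, (114.3, 94.0, 81.6, 75.0, 71.9, 73.2, 70.8),
          -38.2, 10.8, True),
        q("tw_pot", "Nm", 77.9, 10.2, (77.9, 56.5, 46.7, 42.4, 41.1, 42.0, 39.6),
          -49.4, 12.6, True),
        q("mmax", "mV", 5.2, 2.8, (5.2,) * 7),
        q("emd", "ms", 28.8, 10.8, (28.8, 32.0, 32.1, 33.2, 33.1, 33.9, 35.0),
          21.9, 6.8, True),
        q("ct", "ms", 47.7, 9.5, (47.7, 50.6, 52.2, 52.8, 54.0, 56.0, 57.5),
          20.4, 10.4, True),
        q("mrtd", "Nm/ms", 4.8, 3.3, (4.8, 3.8, 2.7, 2.4, 2.3, 2.3, 2.2),
          -51.0, 12.7, True),
        q("hrt", "ms", 128.2, 39.7, (128.2,) * 7),
        q("mu", "kPa", 9.3, 2.0, (9.3, 8.1, 7.5, 7.4, 6.9, 6.7, 6.1),
          -34.7, 6.7, True),
        q("passive_torque", "Nm", 0.4, 0.1, (0.4,) * 7),
        q("vl_passive_rms", "mV", 0.004, 0.005, (0.004,) * 7),
        q("bf_passive_rms", "mV", 0.002, 0.001, (0.002,) * 7),
    ]
    return {c.name: c for c in cal}


@dataclass(frozen=True)
class NoiseConfig:
    """Rendering noise magnitudes (all artifact choices, exposed here)."""

    plateau_cv: float = 0.01          # trial-to-trial MVC plateau level CV
    torque_noise_sd: float = 0.05     # additive torque sensor noise, Nm
    frame_speed_sd: float = 0.045     # per-frame shear-speed offset, m/s
    pixel_speed_sd: float = 0.15      # per-pixel shear-speed noise, m/s


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the synthetic experiment generator."""

    n_subjects: int = 15
    timepoints: tuple[str, ...] = TIMEPOINTS
    calibration: dict[str, QuantityCalibration] = field(
        default_factory=default_calibration)
    sampling_rate: float = 2000.0     # Hz
    map_shape: tuple[int, int] = (40, 40)   # pixels, 1 mm pitch
    pixel_pitch_mm: float = 1.0
    roi_side: int = 12                # pixels (~1.44 cm^2)
    n_frames: int = 5                 # SWE clip frames, 1 Hz
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidCalibrationError("n_subjects must be >= 2")
        if self.sampling_rate <= 0:
            raise InvalidCalibrationError("sampling_rate must be positive")
        if self.roi_side > min(self.map_shape):
            raise InvalidCalibrationError("ROI does not fit inside the map")
        for cal in self.calibration.values():
            if len(cal.trajectory) != len(self.timepoints):
                raise InvalidCalibrationError(
                    f"{cal.name}: trajectory length != number of time points")

    def noiseless(self) -> "GeneratorConfig":
        """Copy of this config with all SDs and rendering noise set to zero.

        Useful for degenerate-cohort and round-trip testing: every subject
        then follows the group trajectories exactly.
        """
        cal = {
            name: replace(c, ctrl_sd=0.0, end_change_sd_pct=0.0)
            for name, c in self.calibration.items()
        }
        noise = NoiseConfig(plateau_cv=0.0, torque_noise_sd=0.0,
                            frame_speed_sd=0.0, pixel_speed_sd=0.0)
        return replace(self, calibration=cal, noise=noise)
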