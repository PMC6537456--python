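"""Shear-wave elastography: speed maps -> shear modulus, and clip reliability.

The scanner reports a 2-D map of shear-wave propagation speed Vs (m/s) at
1 Hz.  Assuming a purely elastic, homogeneous medium of density
rho = 1000 kg/m^3, the shear elastic modulus is mu = rho * Vs^2 (reported in
kPa; no factor of 3 -- this is the shear modulus, not Young's modulus).
Within a 5-s clip, the five region-of-interest means quantify intra-clip
reliability via a two-way consistency ICC and the standard error of
measurement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (EmptyInputError, InsufficientDataError,
                     InvalidSpeedError, RoiBoundsError)

MUSCLE_DENSITY = 1000.0  # kg/m^3


@dataclass(frozen=True)
class Roi:
    """Rectangular region of interest, 0-based half-open pixel coordinates."""

    row0: int
    col0: int
    height: int
    width: int

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row0, self.row0 + self.height),
                slice(self.col0, self.col0 + self.width))


@dataclass
class SweClip:
    """Sequence of shear-wave-speed maps with a shared ROI.

    ``frames`` is a list of 2-D arrays in m/s (1 x 1 mm pixels by default);
    frames are acquired at ``1/frame_interval`` Hz.
    """

    frames: list[np.ndarray]
    roi: Roi
    pixel_pitch_mm: float = 1.0
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise EmptyInputError("clip has no frames")
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        shape = self.frames[0].shape
        for f in self.frames:
            if f.ndim != 2 or f.shape != shape:
                raise RoiBoundsError("all frames must share one 2-D shape")
            if np.any(f < 0):
                raise InvalidSpeedError("negative shear-wave speed in map")
        r = self.roi
        if (r.row0 < 0 or r.col0 < 0 or r.height <= 0 or r.width <= 0
                or r.row0 + r.height > shape[0]
                or r.col0 + r.width > shape[1]):
            raise RoiBoundsError(f"ROI {r} outside map of shape {shape}")


@dataclass
class ModulusResult:
    per_frame_mu: np.ndarray   # kPa, one value per frame
    clip_mu: float             # kPa, arithmetic mean of per-frame values
    density: float = MUSCLE_DENSITY


@dataclass
class ReliabilityResult:
    icc: float        # fraction in (-inf, 1]
    sem: float        # same units as the input matrix
    n_subjects: int
    n_measures: int
    ms_subjects: float = field(default=float("nan"), repr=False)
    ms_error: float = field(default=float("nan"), repr=False)


def mu_from_speed(vs, density: float = MUSCLE_DENSITY):
    """Shear modulus in kPa from shear-wave speed in m/s: mu = rho*Vs^2/1000."""
    vs = np.asarray(vs, dtype=float)
    if np.any(vs < 0):
        raise InvalidSpeedError("shear-wave speed must be non-negative")
    mu = density * vs ** 2 / 1000.0
    return float(mu) if mu.ndim == 0 else mu


def roi_frame_modulus(clip: SweClip, density: float = MUSCLE_DENSITY
                      ) -> np.ndarray:
    """Per-frame ROI-mean shear modulus (kPa).

    Each ROI pixel is converted to modulus *before* averaging (the map is a
    modulus image pixel-wise); averaging speeds first and then squaring
    would bias the estimate low by the within-ROI speed variance.
    """
    rows, cols = clip.roi.slices()
    return np.array([float(np.mean(mu_from_speed(f[rows, cols], density)))
                     for f in clip.frames])


def clip_modulus(clip: SweClip, expected_frames: int = 5,
                 density: float = MUSCLE_DENSITY) -> ModulusResult:
    """Clip-level modulus: mean of the per-frame ROI means.

    Warns (without failing) if the clip does not hold the protocol's
    ``expected_frames`` frames.
    """
    per_frame = roi_frame_modulus(clip, density)
    if expected_frames is not None and len(per_frame) != expected_frames:
        warnings.warn(
            f"clip has {len(per_frame)} frames, protocol expects "
            f"{expected_frames}", stacklevel=2)
    return ModulusResult(per_frame, float(per_frame.mean()), density)


def icc_sem(matrix) -> ReliabilityResult:
    """Intra-clip reliability: two-way consistency single-measure ICC and SEM.

    ``matrix`` is subjects x repeated measures with no missing cells.  From
    the subjects x measures ANOVA decomposition:

        ICC = (MS_subjects - MS_error) / (MS_subjects + (k-1) * MS_error)
        SEM = sqrt(MS_error)

    (ICC(3,1) in the Shrout-Fleiss taxonomy; SEM is the typical error).
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InsufficientDataError(
            "need at least 2 subjects and 2 repeated measures")
    if not np.all(np.isfinite(x)):
        raise InsufficientDataError("matrix has missing cells")
    n, k = x.shape
    grand = x.mean()
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_meas = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_subj - ss_meas
    ms_subj = ss_subj / (n - 1)
    ms_err = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    denom = ms_subj + (k - 1) * ms_err
    icc = 1.0 if denom == 0.0 else (ms_subj - ms_err) / denom
    return ReliabilityResult(float(icc), float(np.sqrt(ms_err)), n, k,
                             float(ms_subj), float(ms_err))
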