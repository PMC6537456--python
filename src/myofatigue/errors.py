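"""Exception hierarchy for the myofatigue pipeline.

Every operation raises a subclass of :class:`MyofatigueError` so callers can
distinguish pipeline failures from programming errors.
"""


class MyofatigueError(Exception):
    """Base class for all package errors."""


class InvalidCalibrationError(MyofatigueError):
    """Calibration record is unusable (e.g. non-positive control mean)."""


class InvalidTruthError(MyofatigueError):
    """A ground-truth value is outside its physical domain."""


class InfeasibleShapeError(MyofatigueError):
    """No twitch shape parameters within bounds reproduce the targets."""


class EventPlacementError(MyofatigueError):
    """A stimulus or analysis window falls outside the trace span."""


class EmptyInputError(MyofatigueError):
    """An operation received an empty trace or clip."""


class NoResponseError(MyofatigueError):
    """No evoked torque onset detected after a stimulus."""


class UnresolvedHRTError(MyofatigueError):
    """Torque never fell below half-peak inside the relaxation window."""


class InsufficientBaselineError(MyofatigueError):
    """Not enough pre-stimulus samples to form a baseline."""


class InvalidDenominatorError(MyofatigueError):
    """A normalisation denominator is zero or negative."""


class NoPlateauError(MyofatigueError):
    """Recruitment curve still rising at the highest intensity."""


class ContaminatedWindowError(MyofatigueError):
    """An RMS window overlaps a stimulus artifact."""


class RoiBoundsError(MyofatigueError):
    """Region of interest extends outside the speed map."""


class InsufficientDataError(MyofatigueError):
    """Too few subjects or repeated measures for the statistic."""


class IncompleteDesignError(MyofatigueError):
    """Repeated-measures matrix has missing cells."""


class InvalidControlError(MyofatigueError):
    """Control (reference) value is zero; relative change undefined."""


class InvalidSpeedError(MyofatigueError):
    """Negative shear-wave speed."""
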