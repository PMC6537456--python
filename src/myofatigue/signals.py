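"""In-memory containers for torque and EMG traces.

Traces are uniformly sampled 1-D signals with an event log of electrical
stimulations.  Times are absolute seconds from the trace start_time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EventPlacementError

#: stimulation kinds
SINGLE = "single"
DOUBLET = "doublet100Hz"

#: stimulation contexts
SUPERIMPOSED = "superimposed"
RESTING = "resting"


@dataclass(frozen=True)
class StimulusEvent:
    """One (possibly grouped) electrical stimulation.

    ``time`` is the delivery time of the first pulse in seconds; a 100-Hz
    doublet is logged as one event (pulses 10 ms apart).
    """

    time: float
    kind: str          # SINGLE or DOUBLET
    context: str       # SUPERIMPOSED or RESTING


@dataclass
class Trace:
    samples: np.ndarray
    rate: float
    start_time: float = 0.0
    events: list[StimulusEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")
        end = self.start_time + len(self.samples) / self.rate
        for ev in self.events:
            if not (self.start_time <= ev.time < end):
                raise EventPlacementError(
                    f"stimulus at {ev.time:.3f} s outside trace span "
                    f"[{self.start_time:.3f}, {end:.3f})")

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.rate

    def index_at(self, t: float) -> int:
        """Sample index nearest to absolute time t (bounds-checked)."""
        i = int(round((t - self.start_time) * self.rate))
        if not 0 <= i < len(self.samples):
            raise EventPlacementError(f"time {t:.4f} s outside trace")
        return i

    def events_of(self, context: str | None = None,
                  kind: str | None = None) -> list[StimulusEvent]:
        return [ev for ev in self.events
                if (context is None or ev.context == context)
                and (kind is None or ev.kind == kind)]


@dataclass
class TorqueTrace(Trace):
    """Knee-extension torque in Nm sampled at ``rate`` Hz."""


@dataclass
class EMGTrace(Trace):
    """Surface EMG in mV; ``channel`` is the muscle (VL or BF)."""

    channel: str = "VL"
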