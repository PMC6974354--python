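"""Core containers for calcium-imaging trace analysis.

Everything downstream (baseline estimation, transient detection, coincidence
matching, behavior segmentation, tuning) consumes these small dataclasses.
Times are in seconds, sample indices are 0-based, and intervals are half-open
``[start, stop)`` throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

#: Compartments of a layer 5 pyramidal neuron along the somato-dendritic axis.
#: "p"/"d" prefixes denote proximal/distal portions of the trunk or tuft.
COMPARTMENTS = frozenset(
    {"soma", "pTrunk", "dTrunk", "trunk", "pTuft", "dTuft", "tuft", "tuft_branch"}
)

#: Ordered somatofugal chain used by the forward simulator.
DEFAULT_CHAIN = ("soma", "pTrunk", "dTrunk", "tuft")


class TraceKind(str, enum.Enum):
    RAW = "raw"
    DFF = "dff"


@dataclass
class Trace:
    """One ROI's fluorescence time series.

    Parameters
    ----------
    values
        Fluorescence samples, arbitrary units for ``kind='raw'`` or
        dimensionless dF/F0 for ``kind='dff'``. Uniformly sampled.
    fs
        Sampling rate in Hz.
    t0
        Time of the first sample in seconds.
    compartment
        One of :data:`COMPARTMENTS`.
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0
    trace_id: str = ""
    neuron_id: str = ""
    compartment: str = "soma"
    kind: str = TraceKind.RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("Trace.values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("Trace.values must be finite")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"Trace.fs must be positive and finite, got {self.fs}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {self.compartment!r}; expected one of "
                f"{sorted(COMPARTMENTS)}"
            )
        self.kind = TraceKind(self.kind)

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def with_values(self, values: np.ndarray, kind: str | TraceKind | None = None) -> "Trace":
        return replace(self, values=np.asarray(values, dtype=float),
                       kind=self.kind if kind is None else kind)


@dataclass
class TrialStructure:
    """Trial boundaries as half-open sample-index ranges ``[start, stop)``."""

    bounds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        prev_stop = 0
        for start, stop in self.bounds:
            if start < prev_stop:
                raise ValueError("trials must be ordered and non-overlapping")
            if stop <= start:
                raise ValueError("each trial must contain at least one sample")
            prev_stop = stop

    @classmethod
    def whole(cls, n_samples: int) -> "TrialStructure":
        """Darkness-only sessions have no trial structure: one trial."""
        return cls([(0, n_samples)])

    def validate_against(self, trace: Trace) -> None:
        if self.bounds and self.bounds[-1][1] > trace.n_samples:
            raise ValueError("trial extends beyond trace")


@dataclass
class Event:
    """A detected calcium-transient peak."""

    peak_time: float
    peak_index: int
    amplitude: float          # peak dF/F0 minus local pre-peak minimum
    norm_amplitude: float     # fraction of session-maximum amplitude, in [0, 1]

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("event amplitude must be non-negative")


@dataclass
class EventSeries:
    """Detected transients for one trace, ordered by peak time.

    Note that detection height (trace value at the peak, compared against
    ``threshold_multiplier * noise_sd``) and ``amplitude`` (peak minus the
    minimum over a backward window) are distinct quantities; an event's
    amplitude may legitimately fall below the detection threshold.
    """

    events: list[Event]
    trace_id: str = ""
    noise_sd: float = float("nan")
    threshold_multiplier: float = 2.8

    def __post_init__(self) -> None:
        times = [e.peak_time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event peak_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def peak_times(self) -> np.ndarray:
        return np.array([e.peak_time for e in self.events], dtype=float)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([e.amplitude for e in self.events], dtype=float)

    @property
    def norm_amplitudes(self) -> np.ndarray:
        return np.array([e.norm_amplitude for e in self.events], dtype=float)


@dataclass
class SpeedTrace:
    """Treadmill speed in cm/s, uniformly sampled."""

    speed: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=float)
        if self.fs <= 0:
            raise ValueError("SpeedTrace.fs must be positive")
        if np.any(self.speed < 0):
            raise ValueError("speeds must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.speed.size) / self.fs

    @property
    def duration(self) -> float:
        return self.speed.size / self.fs


@dataclass
class StimSchedule:
    """Drifting-grating trial schedule: onsets (s) and directions (deg)."""

    onsets: np.ndarray
    directions: np.ndarray
    stim_duration: float = 3.0
    gray_duration: float = 4.0

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.directions = np.asarray(self.directions, dtype=float)
        if self.onsets.size != self.directions.size:
            raise ValueError("onsets and directions must have equal length")
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if self.onsets.size > 1 and np.any(
            np.diff(self.onsets) < self.stim_duration + self.gray_duration - 1e-9
        ):
            raise ValueError("inter-onset interval shorter than stim + gray duration")

    @property
    def n_trials(self) -> int:
        return self.onsets.size

    @property
    def orientations(self) -> np.ndarray:
        """Directions collapsed to orientations, mod 180 degrees."""
        return np.mod(self.directions, 180.0)


class BehaviorState(enum.IntEnum):
    STATIONARY = 0
    LOCOMOTION = 1
    TRANSITION = 2
    EXCLUDED = 3


@dataclass
class BehaviorLabels:
    """Per-sample behavioral state plus the locomotion bout table."""

    states: np.ndarray        # int8 array of BehaviorState values
    fs: float
    bouts: list[tuple[float, float]] = field(default_factory=list)  # (onset_s, offset_s)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        for onset, offset in self.bouts:
            if onset >= offset:
                raise ValueError("bout onset must precede offset")

    def mask(self, state: BehaviorState) -> np.ndarray:
        return self.states == int(state)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.states.size) / self.fs

    def state_names(self) -> np.ndarray:
        lut = np.array([s.name.lower() for s in BehaviorState])
        return lut[self.states]
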