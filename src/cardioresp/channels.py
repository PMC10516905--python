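"""Core containers for physiological signals and event series.

A :class:`WaveformChannel` is a uniformly sampled signal (ECG or a
respiration belt); an :class:`EventSeries` is an ordered set of event
times (R peaks, breath landmarks) with derived inter-event intervals.
Both are thin frozen wrappers around numpy arrays so that every
processing stage can validate its input once and stay side-effect free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: channel roles used throughout the package
ROLE_ECG = "ecg"
ROLE_THORACIC = "thoracic"
ROLE_ABDOMINAL = "abdominal"
ROLES = (ROLE_ECG, ROLE_THORACIC, ROLE_ABDOMINAL)


class UnusableRecordingError(RuntimeError):
    """Raised when a recording fails a quality rule (e.g. too many
    flagged intervals or too few detected events) and must be excluded
    from the analysis.  Carries a machine-readable ``reason`` code."""

    def __init__(self, reason: str, message: str):
        self.reason = reason
        super().__init__(message)


@dataclass(frozen=True)
class WaveformChannel:
    """Uniformly sampled physiological signal.

    Parameters
    ----------
    samples : ndarray
        Signal values, arbitrary units.
    fs : float
        Sampling rate in Hz.
    role : str
        One of ``"ecg"``, ``"thoracic"``, ``"abdominal"``.
    """

    samples: np.ndarray
    fs: float
    role: str = ROLE_ECG

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.role not in ROLES:
            raise ValueError(f"unknown channel role {self.role!r}; expected one of {ROLES}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds (n samples at fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n) / self.fs

    def with_samples(self, samples: np.ndarray) -> "WaveformChannel":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class EventSeries:
    """Ordered event times (s) with derived inter-event intervals (ms)."""

    times: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.times.ndim != 1:
            raise ValueError("event times must be one-dimensional")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def intervals(self) -> np.ndarray:
        """Inter-event intervals in milliseconds."""
        return np.diff(self.times) * 1000.0


@dataclass(frozen=True)
class RRSeries:
    """RR interval series: beat times (s) plus intervals (ms).

    ``corrected_flags[i]`` marks interval i as artifact-corrected.
    Invariant: ``len(intervals) == len(beat_times) - 1`` and all
    intervals are positive.
    """

    beat_times: np.ndarray
    intervals: np.ndarray
    corrected_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        bt = np.asarray(self.beat_times, dtype=float)
        iv = np.asarray(self.intervals, dtype=float)
        if iv.size != bt.size - 1:
            raise ValueError(
                f"expected {bt.size - 1} intervals for {bt.size} beat times, got {iv.size}"
            )
        if bt.size >= 2 and not np.all(np.diff(bt) > 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(iv <= 0):
            raise ValueError("all RR intervals must be positive")
        flags = self.corrected_flags
        flags = np.zeros(iv.size, dtype=bool) if flags is None else np.asarray(flags, dtype=bool)
        if flags.size != iv.size:
            raise ValueError("corrected_flags must match intervals in length")
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "intervals", iv)
        object.__setattr__(self, "corrected_flags", flags)

    @classmethod
    def from_beat_times(cls, beat_times: np.ndarray) -> "RRSeries":
        bt = np.asarray(beat_times, dtype=float)
        return cls(beat_times=bt, intervals=np.diff(bt) * 1000.0)

    @property
    def n_intervals(self) -> int:
        return self.intervals.size

    @property
    def duration(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0]) if self.beat_times.size else 0.0


@dataclass(frozen=True)
class BreathEvents:
    """Breath landmarks: inhalation onsets (troughs), inhalation maxima
    (B peaks = exhalation onsets) and the breath-to-breath (BB)
    intervals between successive B peaks, in ms.

    Within each breath ``inhale_onset < peak_time``; B peaks alternate
    with troughs.
    """

    inhale_onsets: np.ndarray
    peak_times: np.ndarray
    corrected_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        on = np.asarray(self.inhale_onsets, dtype=float)
        pk = np.asarray(self.peak_times, dtype=float)
        if on.size >= 2 and not np.all(np.diff(on) > 0):
            raise ValueError("inhale onsets must be strictly increasing")
        if pk.size >= 2 and not np.all(np.diff(pk) > 0):
            raise ValueError("peak times must be strictly increasing")
        flags = self.corrected_flags
        nbb = max(pk.size - 1, 0)
        flags = np.zeros(nbb, dtype=bool) if flags is None else np.asarray(flags, dtype=bool)
        object.__setattr__(self, "inhale_onsets", on)
        object.__setattr__(self, "peak_times", pk)
        object.__setattr__(self, "corrected_flags", flags)

    @property
    def exhale_onsets(self) -> np.ndarray:
        """B peaks: the inhalation maxima mark the onset of exhalation."""
        return self.peak_times

    @property
    def bb_intervals(self) -> np.ndarray:
        """Breath-to-breath intervals between successive B peaks, ms."""
        return np.diff(self.peak_times) * 1000.0

    @property
    def n_breaths(self) -> int:
        return self.peak_times.size
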