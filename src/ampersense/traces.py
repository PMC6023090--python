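"""In-memory containers for raw electrochemistry time series.

Traces are thin frozen dataclasses around numpy arrays, validated on
construction.  They carry no unit magic: fields are always in the internal
convention (V, A, s); unit conversion happens in :mod:`ampersense.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np

from .errors import ScheduleError, TraceFormatError

__all__ = ["InjectionEvent", "InjectionSchedule", "VoltammogramTrace", "AmperogramTrace"]


@dataclass(frozen=True)
class InjectionEvent:
    """One addition to the electrochemical cell.

    ``delta_conc`` is the concentration increment delivered to the cell in
    mol/L (already divided by the cell volume by whoever built the event).
    """

    time: float
    analyte: str
    delta_conc: float

    def __post_init__(self) -> None:
        if self.delta_conc < 0:
            raise ScheduleError(f"negative addition at t={self.time}: {self.delta_conc}")


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered list of injections; times strictly increasing."""

    events: tuple[InjectionEvent, ...]

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ScheduleError(f"injection times must be strictly increasing, got {times}")

    @classmethod
    def uniform(
        cls,
        start: float,
        interval: float,
        n: int,
        delta_conc: float,
        analyte: str = "histamine",
    ) -> "InjectionSchedule":
        """Evenly spaced equal additions, the usual calibration protocol."""
        return cls(
            tuple(
                InjectionEvent(start + i * interval, analyte, delta_conc) for i in range(n)
            )
        )

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events])

    @property
    def cumulative_conc(self) -> np.ndarray:
        """Cumulative cell concentration (mol/L) after each event."""
        return np.cumsum([e.delta_conc for e in self.events])

    def __len__(self) -> int:
        return len(self.events)


def _as_float_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise TraceFormatError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise TraceFormatError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class VoltammogramTrace:
    """A cyclic voltammogram: potential (V) and current (A) at a known scan rate (V/s)."""

    potential: np.ndarray
    current: np.ndarray
    scan_rate: float
    cycle: np.ndarray | None = None
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "potential", _as_float_array(self.potential, "potential"))
        object.__setattr__(self, "current", _as_float_array(self.current, "current"))
        if len(self.potential) != len(self.current):
            raise TraceFormatError(
                f"potential ({len(self.potential)}) and current ({len(self.current)}) "
                "must have equal length"
            )
        if len(self.potential) < 16:
            raise TraceFormatError("a voltammogram needs at least 16 samples")
        if self.scan_rate <= 0:
            raise TraceFormatError(f"scan_rate must be positive, got {self.scan_rate}")
        if self.cycle is not None:
            object.__setattr__(self, "cycle", np.asarray(self.cycle, dtype=int))

    def __len__(self) -> int:
        return len(self.potential)

    def select_cycle(self, k: int) -> "VoltammogramTrace":
        if self.cycle is None:
            return self
        mask = self.cycle == k
        if not mask.any():
            raise TraceFormatError(f"cycle {k} not present in trace")
        return replace(
            self, potential=self.potential[mask], current=self.current[mask], cycle=self.cycle[mask]
        )


@dataclass(frozen=True)
class AmperogramTrace:
    """Constant-potential chronoamperogram plus the injection schedule that produced it."""

    time: np.ndarray
    current: np.ndarray
    schedule: InjectionSchedule | None = None
    sample_rate: float | None = None
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", _as_float_array(self.time, "time"))
        object.__setattr__(self, "current", _as_float_array(self.current, "current"))
        if len(self.time) != len(self.current):
            raise TraceFormatError(
                f"time ({len(self.time)}) and current ({len(self.current)}) "
                "must have equal length"
            )
        if len(self.time) >= 2 and not np.all(np.diff(self.time) > 0):
            raise TraceFormatError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])
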