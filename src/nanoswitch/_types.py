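"""Shared trajectory/state containers.

Kept in a private module so that :mod:`nanoswitch.kinetics` (which produces
these objects) and :mod:`nanoswitch.readout` (which consumes and re-infers
them) can both re-export the public names without a circular import.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

BOUND = "bound"
UNBOUND = "unbound"


@dataclass
class StateSequence:
    """Alternating bound/unbound dwell intervals of one particle.

    Intervals are contiguous, non-overlapping and strictly alternating;
    ``states[i]`` spans ``[t_start[i], t_end[i])`` seconds.
    """

    particle_id: int
    states: np.ndarray  # array of str, each BOUND or UNBOUND
    t_start: np.ndarray  # seconds
    t_end: np.ndarray  # seconds

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=object)
        self.t_start = np.asarray(self.t_start, dtype=float)
        self.t_end = np.asarray(self.t_end, dtype=float)
        n = len(self.states)
        if n == 0:
            raise InputError("state sequence must contain at least one interval")
        if not (len(self.t_start) == len(self.t_end) == n):
            raise InputError("states/t_start/t_end length mismatch")
        if np.any(self.t_end <= self.t_start):
            raise InputError("each interval requires t_end > t_start")
        if n > 1:
            if not np.allclose(self.t_end[:-1], self.t_start[1:]):
                raise InputError("intervals must be contiguous")
            pairs = zip(self.states[:-1], self.states[1:])
            if any(a == b for a, b in pairs):
                raise InputError("states must alternate")
        bad = set(self.states) - {BOUND, UNBOUND}
        if bad:
            raise InputError(f"unknown states: {sorted(bad)}")

    @property
    def duration(self) -> float:
        return float(self.t_end[-1] - self.t_start[0])

    @property
    def n_intervals(self) -> int:
        return len(self.states)

    def utb_times(self) -> np.ndarray:
        """Start times of bound intervals entered *from* an unbound interval.

        A sequence that begins bound contributes no event for its first
        interval: there is no observed unbound-to-bound transition into it.
        """
        is_bound = self.states == BOUND
        entered = is_bound.copy()
        entered[0] = False  # first interval has no predecessor
        return self.t_start[entered]

    def bound_fraction(self) -> float:
        is_bound = self.states == BOUND
        durations = self.t_end - self.t_start
        return float(durations[is_bound].sum() / durations.sum())

    def dwell_times(self, state: str, drop_censored: bool = True) -> np.ndarray:
        """Dwell durations in ``state``; boundary intervals are censored."""
        durations = self.t_end - self.t_start
        keep = self.states == state
        if drop_censored:
            keep = keep.copy()
            keep[0] = False
            keep[-1] = False
        return durations[keep]


@dataclass
class Trajectory:
    """Time-stamped 2-D positions of one tethered particle (µm)."""

    particle_id: int
    frame: np.ndarray
    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if not (len(self.frame) == len(self.t_s) == len(self.x_um) == len(self.y_um)):
            raise InputError("trajectory column length mismatch")
        if len(self.frame) and np.any(np.diff(self.frame) <= 0):
            raise InputError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class ActivityTrace:
    """Unbound-to-bound events per particle per minute, per interval."""

    t_min: np.ndarray  # interval midpoints, minutes
    counts: np.ndarray  # raw summed event counts per interval
    n_particles: int
    interval_minutes: float = 1.0
    activity: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise InputError("counts must be non-negative")
        if self.n_particles < 1:
            raise InputError("n_particles must be >= 1")
        if self.activity is None:
            self.activity = (
                self.counts / self.n_particles / self.interval_minutes
            ).astype(float)
        else:
            self.activity = np.asarray(self.activity, dtype=float)
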