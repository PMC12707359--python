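"""Trajectory → diffusivity → state calls → switching activity.

The readout chain follows the sensor's signal-processing order: a sliding
windowed diffusion estimate per particle, a hysteresis classifier that turns
the diffusivity series into alternating bound/unbound intervals, and a
counter that registers only unbound-to-bound (UTB) transitions per 1-min
interval.  The UTB count summed over particles, divided by particle count
and interval length, is the sensor's activity signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._types import BOUND, UNBOUND, ActivityTrace, StateSequence, Trajectory
from .errors import InputError

__all__ = [
    "Trajectory",
    "DiffusivitySeries",
    "ActivityTrace",
    "ReadoutConfig",
    "windowed_diffusion",
    "classify_states",
    "count_utb",
    "readout_experiment",
]


@dataclass
class DiffusivitySeries:
    """Windowed diffusion-coefficient estimates for one particle."""

    particle_id: int
    t_mid: np.ndarray  # seconds, window midpoints
    D: np.ndarray  # µm²/s
    window_frames: int
    stride_frames: int
    noise_corrected: bool = False

    def __post_init__(self) -> None:
        self.t_mid = np.asarray(self.t_mid, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        if len(self.t_mid) != len(self.D):
            raise InputError("t_mid/D length mismatch")
        if not self.noise_corrected and len(self.D) and np.any(self.D < 0):
            raise InputError("negative D̂ without noise correction enabled")


@dataclass(frozen=True)
class ReadoutConfig:
    """Parameters of the diffusivity estimator and state classifier.

    The 0.5 s window (15 frames at 30 Hz) with 50% overlap resolves bound
    dwells down to ~0.7 s, which keeps event recall above 90% for a ~10 s
    mean sandwich lifetime; longer windows lose too many short dwells.
    """

    window_frames: int = 15
    D_low: float = 0.05
    D_high: float = 0.15
    min_dwell_windows: int = 2
    noise_correction: bool = False
    sigma_loc: float = 0.02

    def __post_init__(self) -> None:
        if self.window_frames < 2:
            raise InputError("window_frames must be >= 2")
        if not self.D_low < self.D_high:
            raise InputError("D_low must be < D_high")
        if self.min_dwell_windows < 1:
            raise InputError("min_dwell_windows must be >= 1")


def windowed_diffusion(
    traj: Trajectory,
    window_frames: int = 15,
    noise_correction: bool = False,
    sigma_loc: float = 0.0,
) -> DiffusivitySeries:
    """Sliding-window diffusion estimate, D̂ = MSD₁/(4Δt).

    Windows of ``window_frames`` frames advance by ``window_frames // 2``
    frames; D̂ is the mean single-frame squared displacement (x and y summed)
    divided by 4Δt.  With ``noise_correction`` the static localization
    offset ``sigma_loc² / Δt`` is subtracted, which can yield negative D̂.
    """
    if window_frames < 2:
        raise InputError("window_frames must be >= 2")
    n = len(traj)
    if n < window_frames:
        raise InputError("trajectory shorter than one window")
    dts = np.diff(traj.t_s)
    if len(dts) and not np.allclose(dts, dts[0], rtol=1e-3, atol=1e-9):
        raise InputError("non-uniform frame spacing within trajectory")
    dt = float(dts[0])

    sq = np.diff(traj.x_um) ** 2 + np.diff(traj.y_um) ** 2  # length n-1
    stride = max(window_frames // 2, 1)
    starts = np.arange(0, n - window_frames + 1, stride)
    d_hat = np.empty(len(starts))
    t_mid = np.empty(len(starts))
    for j, s in enumerate(starts):
        seg = sq[s : s + window_frames - 1]
        d_hat[j] = seg.mean() / (4.0 * dt)
        t_mid[j] = traj.t_s[s : s + window_frames].mean()
    if noise_correction:
        d_hat = d_hat - sigma_loc**2 / dt
    return DiffusivitySeries(traj.particle_id, t_mid, d_hat, window_frames,
                             stride, noise_corrected=noise_correction)


def _runs(labels: np.ndarray):
    """(value, start, length) runs of a 1-D label array."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((labels[start], start, i - start))
            start = i
    return out


def classify_states(
    dser: DiffusivitySeries,
    thresholds: tuple[float, float] = (0.05, 0.15),
    min_dwell_windows: int = 2,
) -> StateSequence:
    """Hysteresis state caller on a diffusivity series.

    Switch to bound when D̂ < D_low, to unbound when D̂ > D_high; hold the
    current state inside the dead band.  Leading dead-band windows take the
    first decisive state.  Candidate dwells shorter than
    ``min_dwell_windows`` are merged into the surrounding state (shortest
    first), so output intervals alternate.
    """
    d_low, d_high = thresholds
    if not d_low < d_high:
        raise InputError("D_low must be < D_high")
    if min_dwell_windows < 1:
        raise InputError("min_dwell_windows must be >= 1")
    if len(dser.D) == 0:
        raise InputError("empty diffusivity series")

    raw = np.zeros(len(dser.D), dtype=int)  # +1 unbound, -1 bound, 0 hold
    raw[dser.D < d_low] = -1
    raw[dser.D > d_high] = +1

    labels = raw.copy()
    decisive = np.nonzero(labels)[0]
    if len(decisive) == 0:
        labels[:] = +1  # never leaves the dead band: call it unbound
    else:
        labels[: decisive[0]] = labels[decisive[0]]
        for i in range(decisive[0] + 1, len(labels)):
            if labels[i] == 0:
                labels[i] = labels[i - 1]

    # suppress dwells shorter than min_dwell_windows, shortest first
    while True:
        runs = _runs(labels)
        if len(runs) <= 1:
            break
        short = [r for r in runs if r[2] < min_dwell_windows]
        if not short:
            break
        _, start, length = min(short, key=lambda r: r[2])
        labels[start : start + length] *= -1

    runs = _runs(labels)
    t = dser.t_mid
    stride_dt = (t[1] - t[0]) if len(t) > 1 else 1.0
    states, starts, ends = [], [], []
    for j, (val, start, length) in enumerate(runs):
        t0 = t[start] if j > 0 else t[0]
        if j > 0:
            t0 = 0.5 * (t[start - 1] + t[start])
        if j < len(runs) - 1:
            nxt = runs[j + 1][1]
            t1 = 0.5 * (t[nxt - 1] + t[nxt])
        else:
            t1 = t[-1] + 0.5 * stride_dt
        states.append(BOUND if val == -1 else UNBOUND)
        starts.append(t0)
        ends.append(t1)
    return StateSequence(dser.particle_id, np.array(states, dtype=object),
                         np.array(starts), np.array(ends))


def count_utb(states: StateSequence | None, interval_edges_s: np.ndarray) -> np.ndarray:
    """UTB events per half-open interval ``[edge_i, edge_{i+1})``.

    An event is the start time of a bound interval that was entered from an
    unbound interval; bound-to-unbound transitions are ignored.  An event
    exactly on an edge belongs to the later interval.
    """
    edges = np.asarray(interval_edges_s, dtype=float)
    if len(edges) < 2:
        raise InputError("need at least two interval edges")
    if np.any(np.diff(edges) <= 0):
        raise InputError("interval edges must be strictly increasing")
    counts = np.zeros(len(edges) - 1, dtype=int)
    if states is None:
        return counts
    ev = states.utb_times()
    idx = np.searchsorted(edges, ev, side="right") - 1
    idx = idx[(idx >= 0) & (idx < len(counts))]
    np.add.at(counts, idx, 1)
    return counts


def readout_experiment(
    trajectories: list[Trajectory],
    interval_edges_s: np.ndarray,
    cfg: ReadoutConfig = ReadoutConfig(),
) -> tuple[ActivityTrace, int]:
    """Full readout over many particles.

    Returns the summed activity trace and the number of particles excluded
    for being shorter than one diffusivity window.
    """
    edges = np.asarray(interval_edges_s, dtype=float)
    if len(trajectories) == 0:
        raise InputError("need at least one trajectory")
    counts = np.zeros(len(edges) - 1, dtype=int)
    usable = 0
    excluded = 0
    for traj in trajectories:
        if len(traj) < cfg.window_frames:
            excluded += 1
            continue
        dser = windowed_diffusion(traj, cfg.window_frames,
                                  noise_correction=cfg.noise_correction,
                                  sigma_loc=cfg.sigma_loc)
        seq = classify_states(dser, (cfg.D_low, cfg.D_high),
                              cfg.min_dwell_windows)
        counts += count_utb(seq, edges)
        usable += 1
    if usable == 0:
        raise InputError("no usable particles (all shorter than one window)")
    interval_min = float(np.diff(edges).mean() / 60.0)
    mids_min = (edges[:-1] + np.diff(edges) / 2.0) / 60.0
    trace = ActivityTrace(t_min=mids_min, counts=counts, n_particles=usable,
                          interval_minutes=interval_min)
    return trace, excluded
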