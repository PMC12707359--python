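"""Stochastic simulator for a reversibly switching tethered-particle sensor.

A particle alternates between a mobile *unbound* state (confined by its
tether) and a tightly *bound* state formed when the analyte transiently
bridges the particle to the substrate.  Switching is a continuous-time
two-state Markov chain whose unbound-to-bound rate saturates with analyte
concentration,

    lambda_on(C) = lambda_bg + lambda_max * C / (EC50_kin + C),

while the bound-to-unbound rate ``k_off_sw`` is set by the lifetime of the
sandwich complex.  On top of the state sequence, :func:`render_trajectory`
produces a confined-diffusion x/y track with localization noise, and
:func:`generate_experiment` runs whole injection schedules (with slow
multiplicative sensor drift) either as Poisson event counts or as full
per-particle trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from ._types import BOUND, UNBOUND, ActivityTrace, StateSequence, Trajectory
from .errors import InputError

__all__ = [
    "KineticParams",
    "Injection",
    "SampleSchedule",
    "RawExperiment",
    "simulate_state_sequence",
    "render_trajectory",
    "generate_experiment",
    "preset_schedule",
    "drift_factor",
]

SCHEDULE_ROLES = ("blank", "calibrant", "norm_reference", "blind")


@dataclass(frozen=True)
class KineticParams:
    """Kinetic, geometric and optical parameters of the simulated sensor.

    Rates are s^-1, lengths µm, concentrations pM.  Defaults are declared
    artifact choices for a 1 µm particle on a ~75 nm dsDNA tether with a
    sandwich lifetime of ~10 s.
    """

    k_off_sw: float = 0.1
    lambda_max: float = 0.05
    EC50_kin: float = 1030.0
    lambda_bg: float = 2e-4
    D_free: float = 0.3
    D_bound: float = 0.05
    R_free: float = 0.28
    R_bound: float = 0.03
    sigma_loc: float = 0.02
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        nonneg = (
            "k_off_sw", "lambda_max", "lambda_bg", "D_free", "D_bound",
            "R_free", "R_bound", "sigma_loc",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.EC50_kin <= 0:
            raise InputError("EC50_kin must be > 0")
        if self.frame_rate <= 0:
            raise InputError("frame_rate must be > 0")
        if not self.R_bound < self.R_free:
            raise InputError("R_bound must be < R_free")
        if self.D_bound > self.D_free:
            raise InputError("D_bound must be <= D_free")

    def lambda_on(self, conc_pM: float) -> float:
        """Unbound-to-bound rate at analyte concentration ``conc_pM``."""
        if conc_pM < 0:
            raise InputError("concentration must be >= 0")
        return self.lambda_bg + self.lambda_max * conc_pM / (self.EC50_kin + conc_pM)

    def bound_fraction(self, conc_pM: float) -> float:
        """Stationary probability of the bound state."""
        lam = self.lambda_on(conc_pM)
        total = lam + self.k_off_sw
        if total == 0:
            return 0.0
        return lam / total

    def utb_rate(self, conc_pM: float) -> float:
        """Stationary unbound-to-bound event rate per particle (s^-1).

        Equals lambda_on * P(unbound) = lambda_on * k_off / (lambda_on + k_off).
        """
        lam = self.lambda_on(conc_pM)
        total = lam + self.k_off_sw
        if total == 0:
            return 0.0
        return lam * self.k_off_sw / total


@dataclass(frozen=True)
class Injection:
    concentration_pM: float
    role: str
    flow_duration_min: float = 1.0
    flow_rate_ul_min: float = 100.0
    n_measure_intervals: int = 10

    def __post_init__(self) -> None:
        if self.concentration_pM < 0:
            raise InputError("concentration must be >= 0")
        if self.role not in SCHEDULE_ROLES:
            raise InputError(f"role must be one of {SCHEDULE_ROLES}")
        if self.n_measure_intervals < 1:
            raise InputError("n_measure_intervals must be >= 1")
        if self.flow_duration_min < 0:
            raise InputError("flow_duration_min must be >= 0")


@dataclass(frozen=True)
class SampleSchedule:
    """Ordered sample injections plus the sensor's fractional drift per hour."""

    injections: tuple
    drift_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "injections", tuple(self.injections))
        if not self.injections:
            raise InputError("schedule needs at least one injection")
        if not 0 <= self.drift_rate < 1:
            raise InputError("drift_rate must be in [0, 1)")

    @property
    def total_duration_min(self) -> float:
        return sum(
            inj.flow_duration_min + inj.n_measure_intervals for inj in self.injections
        )


@dataclass
class RawExperiment:
    """Per-interval event counts for a whole schedule, plus optional raw data.

    ``records`` columns: t_min (interval midpoint on the experiment clock),
    injection_index, role, true_conc_pM, counts, n_particles.
    """

    records: "object"  # pandas.DataFrame
    schedule: SampleSchedule
    params: KineticParams
    n_particles: int
    mode: str
    seed: int | None = None
    trajectories: list | None = None
    gt_states: list | None = None
    interval_edges_s: np.ndarray | None = None

    def activity_trace(self) -> ActivityTrace:
        return ActivityTrace(
            t_min=self.records["t_min"].to_numpy(),
            counts=self.records["counts"].to_numpy(),
            n_particles=self.n_particles,
        )


def drift_factor(t_hours: float, drift_rate: float) -> float:
    """Multiplicative sensor decay, (1 - drift_rate)**t with t in hours."""
    return float((1.0 - drift_rate) ** t_hours)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_state_sequence(
    params: KineticParams,
    concentration_pM: float,
    duration_s: float,
    seed=None,
    particle_id: int = 0,
) -> StateSequence:
    """Draw one continuous-time two-state Markov path of length ``duration_s``.

    The initial state is drawn from the stationary distribution; dwell times
    are exponential with the state's exit rate.  The final interval is
    truncated at ``duration_s``.
    """
    if duration_s <= 0:
        raise InputError("duration must be > 0")
    if concentration_pM < 0:
        raise InputError("concentration must be >= 0")
    rng = _as_rng(seed)
    lam = params.lambda_on(concentration_pM)
    k_off = params.k_off_sw

    p_bound = params.bound_fraction(concentration_pM)
    state = BOUND if rng.random() < p_bound else UNBOUND

    states, starts, ends = [], [], []
    t = 0.0
    while t < duration_s:
        rate = k_off if state == BOUND else lam
        dwell = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        t_end = min(t + dwell, duration_s)
        states.append(state)
        starts.append(t)
        ends.append(t_end)
        t = t_end
        state = UNBOUND if state == BOUND else BOUND
    return StateSequence(particle_id, np.array(states, dtype=object),
                         np.array(starts), np.array(ends))


def render_trajectory(
    states: StateSequence,
    params: KineticParams,
    seed=None,
    t_offset_s: float = 0.0,
    frame_offset: int = 0,
) -> Trajectory:
    """Render an observed x/y track from a ground-truth state sequence.

    Overdamped Euler–Maruyama diffusion at the current state's coefficient,
    radially reflected inside a disc of the state's confinement radius
    centred on the tether anchor; i.i.d. Gaussian localization noise of SD
    ``sigma_loc`` is added per frame and axis.  ``t_offset_s``/``frame_offset``
    shift the output onto an experiment-wide clock.
    """
    if states.n_intervals == 0:  # pragma: no cover - StateSequence forbids this
        raise InputError("empty state sequence")
    rng = _as_rng(seed)
    dt = 1.0 / params.frame_rate
    duration = states.duration
    n_frames = int(math.floor(duration / dt)) + 1
    t_local = states.t_start[0] + dt * np.arange(n_frames)

    # state per frame via interval lookup
    idx = np.searchsorted(states.t_start, t_local, side="right") - 1
    idx = np.clip(idx, 0, states.n_intervals - 1)
    is_bound = states.states[idx] == BOUND

    step_sd_free = math.sqrt(2.0 * params.D_free * dt)
    step_sd_bound = math.sqrt(2.0 * params.D_bound * dt)
    normals = rng.normal(size=(n_frames, 2))

    xs = np.empty(n_frames)
    ys = np.empty(n_frames)
    x = y = 0.0
    r_free, r_bound = params.R_free, params.R_bound
    for i in range(n_frames):
        if is_bound[i]:
            sd, radius = step_sd_bound, r_bound
        else:
            sd, radius = step_sd_free, r_free
        if i > 0:
            x += sd * normals[i, 0]
            y += sd * normals[i, 1]
        r = math.hypot(x, y)
        if r > radius:
            # radial mirror at the confinement boundary; clip handles the
            # discontinuous shrink when a free particle binds far from anchor
            r_new = min(max(2.0 * radius - r, 0.0), radius)
            if r > 0:
                scale = r_new / r
                x *= scale
                y *= scale
        xs[i] = x
        ys[i] = y

    if params.sigma_loc > 0:
        noise = rng.normal(scale=params.sigma_loc, size=(n_frames, 2))
        xs = xs + noise[:, 0]
        ys = ys + noise[:, 1]

    return Trajectory(
        particle_id=states.particle_id,
        frame=frame_offset + np.arange(n_frames),
        t_s=t_offset_s + t_local,
        x_um=xs,
        y_um=ys,
    )


def _schedule_timeline(schedule: SampleSchedule):
    """Yield (injection_index, injection, measure_start_min) on one clock."""
    t = 0.0
    for k, inj in enumerate(schedule.injections):
        t += inj.flow_duration_min
        yield k, inj, t
        t += inj.n_measure_intervals


def generate_experiment(
    schedule: SampleSchedule,
    params: KineticParams,
    n_particles: int = 4000,
    mode: Literal["counts", "trajectories"] = "counts",
    seed=None,
) -> RawExperiment:
    """Simulate a full injection schedule.

    counts mode
        Per 1-min interval, events ~ Poisson(n_particles * utb_rate(C) * 60 s
        * drift(t_mid)); no per-particle state is kept.  Fast; suitable for
        thousands of particles.

    trajectories mode
        Every particle gets its own state sequence (drift applied to the
        binding rates at the start of each injection's measurement window)
        and a rendered trajectory; ground-truth counts come from the event
        log.  Flow periods are simulated implicitly: they advance the clock
        but produce no measurement records.
    """
    import pandas as pd

    if n_particles < 1:
        raise InputError("n_particles must be >= 1")
    if mode not in ("counts", "trajectories"):
        raise InputError(f"unknown mode {mode!r}")
    rng = _as_rng(seed)

    rows = []
    trajectories: list[Trajectory] = []
    gt_states: list[StateSequence] = []
    edges_s: list[float] = []

    for k, inj, t0 in _schedule_timeline(schedule):
        conc = inj.concentration_pM
        n_iv = inj.n_measure_intervals
        mids = t0 + 0.5 + np.arange(n_iv)  # minutes
        if mode == "counts":
            rate = params.utb_rate(conc)
            for m in mids:
                mean = n_particles * rate * 60.0 * drift_factor(m / 60.0, schedule.drift_rate)
                rows.append((m, k, inj.role, conc, int(rng.poisson(mean)), n_particles))
        else:
            d = drift_factor(t0 / 60.0, schedule.drift_rate)
            p = replace(params, lambda_max=params.lambda_max * d,
                        lambda_bg=params.lambda_bg * d)
            local_edges = 60.0 * (t0 + np.arange(n_iv + 1))  # seconds
            edges_s.extend(local_edges[:-1])
            edges_s.append(local_edges[-1])
            counts = np.zeros(n_iv, dtype=int)
            for pid in range(n_particles):
                sub = np.random.default_rng(rng.integers(0, 2**63 - 1))
                seq = simulate_state_sequence(p, conc, 60.0 * n_iv, seed=sub,
                                              particle_id=pid)
                traj = render_trajectory(seq, p, seed=sub,
                                         t_offset_s=60.0 * t0,
                                         frame_offset=0)
                ev = seq.utb_times() + 60.0 * t0
                hits = np.searchsorted(local_edges, ev, side="right") - 1
                hits = hits[(hits >= 0) & (hits < n_iv)]
                np.add.at(counts, hits, 1)
                # shift the ground-truth clock to match the trajectory
                gt_states.append(StateSequence(pid, seq.states,
                                               seq.t_start + 60.0 * t0,
                                               seq.t_end + 60.0 * t0))
                trajectories.append(traj)
            for m, c in zip(mids, counts):
                rows.append((m, k, inj.role, conc, int(c), n_particles))

    records = pd.DataFrame(
        rows,
        columns=["t_min", "injection_index", "role", "true_conc_pM", "counts",
                 "n_particles"],
    )
    return RawExperiment(
        records=records,
        schedule=schedule,
        params=params,
        n_particles=n_particles,
        mode=mode,
        trajectories=trajectories if mode == "trajectories" else None,
        gt_states=gt_states if mode == "trajectories" else None,
        interval_edges_s=np.unique(np.array(edges_s)) if edges_s else None,
    )


def preset_schedule(name: str) -> SampleSchedule:
    """Ready-made schedules mirroring the package's reference experiments."""
    if name == "figure3_series":
        concs = [0.0, 31.3, 62.5, 125.0, 250.0, 500.0, 1000.0]
        injections = []
        for _ in range(5):
            for c in concs:
                role = "blank" if c == 0 else (
                    "norm_reference" if c == 1000.0 else "calibrant")
                injections.append(Injection(c, role, flow_duration_min=1.0,
                                            n_measure_intervals=10))
            # trailing blank flushes let the series relax to background
            for _ in range(2):
                injections.append(Injection(0.0, "blank", flow_duration_min=1.0,
                                            n_measure_intervals=10))
        return SampleSchedule(tuple(injections), drift_rate=0.05)

    if name == "figure4_milk":
        samples = [125.0, 187.0, 254.0, 254.0, 380.0, 506.0]
        injections = []
        for _ in range(6):
            for c in samples:
                role = "norm_reference" if c in (125.0, 506.0) else "blind"
                injections.append(Injection(c, role, flow_duration_min=3.5,
                                            n_measure_intervals=8))
            injections.append(Injection(0.0, "blank", flow_duration_min=3.5,
                                        n_measure_intervals=8))
        return SampleSchedule(tuple(injections), drift_rate=0.05)

    if name == "figure5_blind":
        cal_concs = [62.5, 125.0, 250.0, 506.0, 1000.0]
        blind_concs = [150.0, 220.0, 340.0, 460.0]
        norm_pair = [125.0, 506.0]

        def cal_block():
            return [Injection(c, "calibrant", flow_duration_min=3.5,
                              n_measure_intervals=8) for c in cal_concs]

        def norm_block():
            return [Injection(c, "norm_reference", flow_duration_min=3.5,
                              n_measure_intervals=8) for c in norm_pair]

        injections = cal_block() + norm_block()
        # vary the order of the four blind samples between cycles
        blind_orders = [
            [0, 1, 2, 3, 0], [2, 0, 3, 1, 2], [1, 3, 0, 2, 1], [3, 2, 1, 0, 3],
        ]
        for cycle, order in enumerate(blind_orders):
            for j in order:  # five blind measurements, then a norm pair
                injections.append(Injection(blind_concs[j], "blind",
                                            flow_duration_min=3.5,
                                            n_measure_intervals=8))
            injections.extend(norm_block())
            injections.append(Injection(0.0, "blank", flow_duration_min=3.5,
                                        n_measure_intervals=8))
            if cycle == 1:  # recalibration block roughly every 4 h
                injections.extend(cal_block())
        return SampleSchedule(tuple(injections), drift_rate=0.05)

    raise InputError(f"unknown preset schedule {name!r}")
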