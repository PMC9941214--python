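"""Forward-Euler time stepping, initial conditions, and trajectory recording.

The model is first order, so a plain Euler scheme with the reference step
size dt = 0.1 reproduces the study's numerics.  Additive white noise of
strength ``d`` enters with Euler-Maruyama sqrt(dt) scaling by default (so
``d`` keeps a dt-independent meaning); the literal per-step reading is kept
available through ``ModelParams.noise_scaling``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    SwarmState,
    assign_chirality,
    pairwise_phase_offsets,
    rhs,
    sample_frequencies,
    wrap_angle,
)
from .params import FrequencySpec, ModelParams

__all__ = ["RunSchedule", "Trajectory", "SimulationDiverged", "init_state", "euler_step", "simulate"]


class SimulationDiverged(RuntimeError):
    """Raised when any coordinate leaves the configured bounding box."""


@dataclass(frozen=True)
class RunSchedule:
    """Numerical protocol: step size, final time, recording, and seeding.

    Defaults follow the reference protocol: 500 agents, dt = 0.1, final
    time 1000, initial positions uniform in a centred box of side 4 and
    phases uniform on [-pi, pi].
    """

    dt: float = 0.1
    T: float = 1000.0
    n: int = 500
    record_stride: int = 10
    seed: int = 0
    init_box: float = 4.0
    divergence_bound: float = 1e6

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.T < self.dt:
            raise ValueError(f"T must be at least dt, got T={self.T}, dt={self.dt}")
        if self.record_stride < 1:
            raise ValueError(f"record_stride must be >= 1, got {self.record_stride}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not self.init_box > 0:
            raise ValueError(f"init_box must be positive, got {self.init_box}")

    @property
    def n_steps(self) -> int:
        return max(1, int(math.ceil(self.T / self.dt - 1e-9)))


@dataclass
class Trajectory:
    """Time-ordered recorded frames plus full provenance."""

    frames: list[SwarmState]
    params: ModelParams | None = None
    spec: FrequencySpec | None = None
    schedule: RunSchedule | None = None

    @property
    def n_agents(self) -> int:
        return self.frames[0].n

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t for f in self.frames])

    @property
    def positions(self) -> np.ndarray:
        """(frames, N, 2) array of positions."""
        return np.stack([f.pos for f in self.frames])

    @property
    def phases(self) -> np.ndarray:
        return np.stack([f.phase for f in self.frames])

    @property
    def phases_unwrapped(self) -> np.ndarray:
        return np.stack([f.phase_unwrapped for f in self.frames])

    @property
    def angles_unwrapped(self) -> np.ndarray:
        """Cumulative centroid-relative angles, (frames, N)."""
        return np.stack([f.angle_unwrapped for f in self.frames])

    @property
    def final(self) -> SwarmState:
        return self.frames[-1]

    def frame_velocities(self) -> tuple[np.ndarray, np.ndarray]:
        """Finite-difference velocities over one recording interval.

        Returns (times, v) with v of shape (frames - 1, N, 2); v[k] is the
        forward difference between frames k and k+1, stamped at times[k].
        """
        if len(self.frames) < 2:
            raise ValueError("need at least two frames for finite-difference velocities")
        t = self.times
        dt = np.diff(t)
        v = np.diff(self.positions, axis=0) / dt[:, None, None]
        return t[:-1], v


def init_state(
    n: int,
    spec: FrequencySpec,
    params: ModelParams,
    box: float,
    rng: np.random.Generator,
) -> SwarmState:
    """Random initial state: positions uniform in a centred ``box`` x ``box``
    square, phases uniform on [-pi, pi], frequencies per ``spec``."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    pos = rng.uniform(-box / 2, box / 2, size=(n, 2))
    phase = rng.uniform(-np.pi, np.pi, size=n)
    omega = sample_frequencies(spec, n, rng)
    c, radii = assign_chirality(omega, params.speed)
    return SwarmState(pos=pos, phase=phase, omega=omega, c=c, R=radii, t=0.0)


def euler_step(
    state: SwarmState,
    params: ModelParams,
    dt: float,
    rng: np.random.Generator,
    offsets: tuple[np.ndarray, np.ndarray] | None = None,
    divergence_bound: float = 1e6,
) -> SwarmState:
    """One forward-Euler step (with additive noise when ``params.d > 0``)."""
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    dpos, dphase = rhs(state, params, offsets=offsets)
    dx = dt * dpos
    dth = dt * dphase
    if params.d > 0:
        scale = params.d * (math.sqrt(dt) if params.noise_scaling == "sqrt_dt" else 1.0)
        dx = dx + scale * rng.standard_normal(size=state.pos.shape)
        dth = dth + scale * rng.standard_normal(size=state.phase.shape)
    new_pos = state.pos + dx
    if np.abs(new_pos).max() > divergence_bound:
        raise SimulationDiverged(
            f"position magnitude exceeded {divergence_bound:g} at t={state.t + dt:g}"
        )
    new_unwrapped = state.phase_unwrapped + dth
    new_phase = wrap_angle(state.phase + dth)
    old_angle = state.centroid_angles()
    new_state = SwarmState(
        pos=new_pos,
        phase=new_phase,
        omega=state.omega,
        c=state.c,
        R=state.R,
        t=state.t + dt,
        phase_unwrapped=new_unwrapped,
        angle_unwrapped=state.angle_unwrapped,  # placeholder, fixed below
    )
    if state.n == 1:
        # a lone agent is its own centroid; for chiral motion its phase IS its
        # angular position about the orbit, so the angle advances with it
        new_state.angle_unwrapped = state.angle_unwrapped + (new_unwrapped - state.phase_unwrapped)
    else:
        new_state.angle_unwrapped = state.angle_unwrapped + wrap_angle(
            new_state.centroid_angles() - old_angle
        )
    return new_state


def simulate(
    spec: FrequencySpec,
    params: ModelParams,
    schedule: RunSchedule,
) -> Trajectory:
    """Run the full protocol and record every ``record_stride``-th frame.

    The initial and final states are always recorded.  Bit-for-bit
    reproducible given (seed, params, spec, schedule).
    """
    rng = np.random.default_rng(schedule.seed)
    state = init_state(schedule.n, spec, params, schedule.init_box, rng)
    offsets = (
        pairwise_phase_offsets(state.omega)
        if (params.freq_coupling and params.variant == "standard")
        else None
    )
    frames = [state.copy()]
    n_steps = schedule.n_steps
    for k in range(1, n_steps + 1):
        state = euler_step(
            state,
            params,
            schedule.dt,
            rng,
            offsets=offsets,
            divergence_bound=schedule.divergence_bound,
        )
        if k % schedule.record_stride == 0 or k == n_steps:
            frames.append(state.copy())
    return Trajectory(frames=frames, params=params, spec=spec, schedule=schedule)
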