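"""Core model state and the deterministic right-hand side of the dynamics.

The standard variant evolves positions and phases as

    dx_i/dt = v_i + (1/N) sum_{j != i} [ u_ij (A + J cos(th_j - th_i - Qx_ij))
                                         - B u_ij / r_ij ] H(sigma - r_ij)
    dth_i/dt = w_i + (K/N) sum_{j != i} sin(th_j - th_i - Qt_ij) / r_ij
                                         * H(sigma - r_ij)

with u_ij the unit vector from i toward j, r_ij the pair distance, H the
strict Heaviside gate of the coupling radius, and v_i = c_i n_i the inherent
chiral velocity (n_i orthogonal to the phase angle).  The pairwise offsets
Qx, Qt are zero unless frequency coupling is enabled, in which case
opposite-sign frequency pairs get (pi, pi/2) and same-sign pairs get (0, 0).

The embryonic variant replaces the kernels with (A + J cos) / r attraction,
B / r^3 repulsion (both along u_ij), and a distance-independent, ungated
phase coupling sin(th_j - th_i - alpha).

Noise is *not* part of the right-hand side; the integrator adds it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .params import FrequencySpec, ModelParams

__all__ = [
    "SwarmState",
    "sample_frequencies",
    "assign_chirality",
    "heading_vectors",
    "pairwise_phase_offsets",
    "rhs",
    "wrap_angle",
]


def wrap_angle(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to the half-open interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(x), 2.0 * np.pi)


def sample_frequencies(spec: FrequencySpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` natural frequencies from the distribution ``spec``.

    Split distributions (F2, F4, k_group with an uneven fit) require ``n``
    divisible by the number of groups so the population splits exactly.
    """
    if n < 1:
        raise ValueError(f"need at least one agent, got n={n}")
    kind = spec.kind
    if kind == "F1":
        return np.ones(n)
    if kind == "F2":
        if n % 2:
            raise ValueError(f"F2 requires an even agent count for the exact +1/-1 split, got n={n}")
        return np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
    if kind == "F3":
        return rng.uniform(1.0, spec.Omega, size=n)
    if kind == "F4":
        if n % 2:
            raise ValueError(f"F4 requires an even agent count for the exact half/half split, got n={n}")
        half = n // 2
        return np.concatenate(
            [rng.uniform(1.0, spec.Omega, size=half), rng.uniform(-spec.Omega, -1.0, size=half)]
        )
    if kind == "k_group":
        if n % spec.k:
            raise ValueError(f"k_group requires n divisible by k={spec.k}, got n={n}")
        values = np.linspace(1.0, spec.Omega, spec.k) if spec.k > 1 else np.array([1.0])
        return np.repeat(values, n // spec.k)
    # custom: cycle explicit values over the population
    values = np.asarray(spec.values, dtype=float)
    return values[np.arange(n) % len(values)]


def assign_chirality(omega: np.ndarray, speed: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-agent chirality coefficient c_i = omega_i * R_i and orbit radius R_i.

    With unit inherent speed, c_i = sign(omega_i) and R_i = 1 / |omega_i|,
    so faster oscillators revolve on tighter circles; speed 0 switches the
    inherent motion off entirely (c = R = 0).
    """
    omega = np.asarray(omega, dtype=float)
    if speed not in (0, 1, 0.0, 1.0):
        raise ValueError(f"speed must be 0 or 1, got {speed}")
    if speed == 0:
        return np.zeros_like(omega), np.zeros_like(omega)
    if np.any(np.abs(omega) < 1):
        raise ValueError("chiral agents require |omega| >= 1")
    return np.sign(omega) * speed, speed / np.abs(omega)


def heading_vectors(phase: np.ndarray) -> np.ndarray:
    """Unit vectors orthogonal to each phase angle, rows (cos(th+pi/2), sin(th+pi/2))."""
    phase = np.asarray(phase, dtype=float)
    return np.stack([np.cos(phase + np.pi / 2), np.sin(phase + np.pi / 2)], axis=-1)


def pairwise_phase_offsets(omega: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-coupling phase offsets (Qx, Qt) as N x N matrices.

    Entry (i, j) is (pi/2)|s_j - s_i| for Qx and (pi/4)|s_j - s_i| for Qt,
    with s the frequency sign, i.e. (0, 0) for same-sign pairs and
    (pi, pi/2) for opposite-sign pairs.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega == 0):
        raise ValueError("phase offsets are undefined for omega = 0 (division by |omega|)")
    s = np.sign(omega)
    gap = np.abs(s[None, :] - s[:, None])
    return (np.pi / 2) * gap, (np.pi / 4) * gap


@dataclass
class SwarmState:
    """Instantaneous state of the collective.

    Phases are stored wrapped to (-pi, pi]; ``phase_unwrapped`` and
    ``angle_unwrapped`` are cumulative companions maintained by the
    integrator (the latter tracks each agent's angular position about the
    collective centroid) so cycle counting never depends on post-hoc
    unwrapping of subsampled data.
    """

    pos: np.ndarray  # (N, 2)
    phase: np.ndarray  # (N,), wrapped
    omega: np.ndarray  # (N,)
    c: np.ndarray  # (N,) chirality coefficients
    R: np.ndarray  # (N,) revolution radii
    t: float = 0.0
    phase_unwrapped: np.ndarray | None = None
    angle_unwrapped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.atleast_2d(np.asarray(self.pos, dtype=float))
        self.phase = np.atleast_1d(np.asarray(self.phase, dtype=float))
        self.omega = np.atleast_1d(np.asarray(self.omega, dtype=float))
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        self.R = np.atleast_1d(np.asarray(self.R, dtype=float))
        n = self.pos.shape[0]
        if self.pos.shape != (n, 2):
            raise ValueError(f"pos must have shape (N, 2), got {self.pos.shape}")
        for name in ("phase", "omega", "c", "R"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
        if self.phase_unwrapped is None:
            self.phase_unwrapped = self.phase.copy()
        else:
            self.phase_unwrapped = np.atleast_1d(np.asarray(self.phase_unwrapped, dtype=float))
        if self.angle_unwrapped is None:
            self.angle_unwrapped = self.centroid_angles()
        else:
            self.angle_unwrapped = np.atleast_1d(np.asarray(self.angle_unwrapped, dtype=float))

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    def centroid_angles(self) -> np.ndarray:
        """Angular position of each agent about the collective centroid (atan2)."""
        rel = self.pos - self.pos.mean(axis=0)
        return np.arctan2(rel[:, 1], rel[:, 0])

    def velocities(self) -> np.ndarray:
        """Inherent chiral velocities v_i = c_i n_i."""
        return self.c[:, None] * heading_vectors(self.phase)

    def copy(self) -> "SwarmState":
        return SwarmState(
            pos=self.pos.copy(),
            phase=self.phase.copy(),
            omega=self.omega.copy(),
            c=self.c.copy(),
            R=self.R.copy(),
            t=self.t,
            phase_unwrapped=self.phase_unwrapped.copy(),
            angle_unwrapped=self.angle_unwrapped.copy(),
        )


def rhs(
    state: SwarmState,
    params: ModelParams,
    offsets: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic time derivatives (dpos, dphase) for every model variant.

    ``offsets`` may carry precomputed (Qx, Qt) matrices (they depend only on
    the frequency signs, so a simulation computes them once); when omitted
    and frequency coupling is on they are rebuilt from ``state.omega``.

    The 1/N prefactor is kept verbatim under local coupling.  Pair distances
    are floored at ``params.softening`` before any division so the repulsion
    singularity cannot overflow under finite time steps.
    """
    if not (np.all(np.isfinite(state.pos)) and np.all(np.isfinite(state.phase))):
        raise ValueError("non-finite state passed to rhs")
    n = state.n
    v = state.velocities()
    if n == 1:
        return v, state.omega.copy()
    if _kernels.HAVE_NUMBA:
        th = state.phase
        cth, sth = np.cos(th), np.sin(th)
        dpos = np.empty_like(state.pos)
        dphase = np.empty_like(th)
        if params.variant == "embryonic":
            _kernels.rhs_embryonic(
                state.pos, cth, sth,
                params.A, params.B, params.J, params.K,
                math.cos(params.alpha), math.sin(params.alpha),
                params.softening, dpos, dphase,
            )
        else:
            if params.freq_coupling and np.any(state.omega == 0):
                raise ValueError("phase offsets are undefined for omega = 0 (division by |omega|)")
            _kernels.rhs_standard(
                state.pos, cth, sth, np.sign(state.omega),
                params.A, params.B, params.J, params.K,
                min(params.sigma, 1e300), params.softening,  # fastmath: avoid literal inf
                bool(params.freq_coupling), dpos, dphase,
            )
        return v + dpos, state.omega + dphase
    return _rhs_numpy(state, params, v, offsets)


def _rhs_numpy(
    state: SwarmState,
    params: ModelParams,
    v: np.ndarray,
    offsets: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized NumPy evaluation of the same sums (numba-free fallback)."""
    n = state.n
    pos, th = state.pos, state.phase
    diff = pos[None, :, :] - pos[:, None, :]  # diff[i, j] = x_j - x_i
    r = np.hypot(diff[..., 0], diff[..., 1])
    np.fill_diagonal(r, 1.0)  # excluded from all sums; avoids 0/0
    np.maximum(r, params.softening, out=r)

    # cos/sin of (th_j - th_i) from outer products: no N^2 trig calls
    cth, sth = np.cos(th), np.sin(th)
    cos_d = np.outer(cth, cth) + np.outer(sth, sth)
    sin_d = np.outer(cth, sth) - np.outer(sth, cth)

    if params.variant == "embryonic":
        r2 = r * r
        w_x = (params.A + params.J * cos_d) / r2 - params.B / (r2 * r2)
        w_t = sin_d * np.cos(params.alpha) - cos_d * np.sin(params.alpha)
    else:
        if params.freq_coupling:
            if offsets is None:
                offsets = pairwise_phase_offsets(state.omega)
            qx, qt = offsets
            cos_x = cos_d * np.cos(qx) + sin_d * np.sin(qx)
            sin_t = sin_d * np.cos(qt) - cos_d * np.sin(qt)
        else:
            cos_x, sin_t = cos_d, sin_d
        w_x = (params.A + params.J * cos_x - params.B / r) / r
        w_t = sin_t / r
        if not params.is_global:
            gate = (params.sigma - r) > 0
            w_x = np.where(gate, w_x, 0.0)
            w_t = np.where(gate, w_t, 0.0)

    np.fill_diagonal(w_x, 0.0)
    np.fill_diagonal(w_t, 0.0)
    dpos = v + np.einsum("ij,ijk->ik", w_x, diff) / n
    dphase = state.omega + (params.K / n) * w_t.sum(axis=1)
    return dpos, dphase
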