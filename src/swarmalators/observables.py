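"""Global order parameters for swarmalator states and trajectories.

Four scalars summarise a collective state:

``S``
    circumferential space-phase order, max(|S+|, |S-|) with
    S± = (1/N) sum_j exp(i (phi_j ± th_j)), phi_j the angular position of
    agent j about the collective centroid.  S = 1 on a perfect phase wave
    (phase equals angular position up to sign and offset), S = 0 when
    angular position and phase are uncorrelated.
``Z``
    Kuramoto order parameter |(1/N) sum_j exp(i th_j)|: overall phase
    coherence.
``beta``
    distance between the mean positions of the positive- and
    negative-frequency subpopulations (cluster separation; only defined
    when both signs are present).
``gamma``
    fraction of agents that complete at least one full cycle of both phase
    and centroid-relative angle after a transient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .integrator import Trajectory
from .model import SwarmState

__all__ = [
    "space_phase_order",
    "kuramoto_order",
    "cluster_separation",
    "cycle_fraction",
    "OrderSeries",
    "compute_order_series",
    "windowed_order",
]

logger = logging.getLogger(__name__)

_CENTROID_TOL = 1e-12


def space_phase_order(state: SwarmState) -> tuple[float, float, float]:
    """Space-phase correlation moduli (S_plus, S_minus, S = max of the two).

    Agents exactly at the centroid have no defined angular position; they
    are excluded from the sum (with a log warning).
    """
    rel = state.pos - state.pos.mean(axis=0)
    radius = np.hypot(rel[:, 0], rel[:, 1])
    keep = radius > _CENTROID_TOL
    if not np.any(keep):
        raise ValueError("space-phase order undefined: every agent sits at the centroid")
    if not np.all(keep):
        logger.warning(
            "excluding %d agent(s) at the collective centroid from S", int((~keep).sum())
        )
    phi = np.arctan2(rel[keep, 1], rel[keep, 0])
    theta = state.phase[keep]
    s_plus = float(np.abs(np.mean(np.exp(1j * (phi + theta)))))
    s_minus = float(np.abs(np.mean(np.exp(1j * (phi - theta)))))
    return s_plus, s_minus, max(s_plus, s_minus)


def kuramoto_order(state: SwarmState) -> float:
    """Modulus of the mean phase phasor, in [0, 1]."""
    return float(np.abs(np.mean(np.exp(1j * state.phase))))


def cluster_separation(state: SwarmState) -> float:
    """Distance between the sign-group mean positions; NaN if one sign only."""
    pos_mask = state.omega > 0
    neg_mask = state.omega < 0
    if not (np.any(pos_mask) and np.any(neg_mask)):
        logger.warning("cluster separation undefined: single-sign frequency population")
        return float("nan")
    return float(
        np.linalg.norm(state.pos[pos_mask].mean(axis=0) - state.pos[neg_mask].mean(axis=0))
    )


def cycle_fraction(traj: Trajectory, transient: float | None = None) -> float:
    """Fraction of agents completing >= 1 full cycle of phase *and* centroid
    angle over the post-transient window (default transient: 20% of the run).
    """
    times = traj.times
    if transient is None:
        transient = 0.2 * times[-1]
    if transient >= times[-1]:
        raise ValueError(f"transient ({transient}) must precede the final time ({times[-1]})")
    start = int(np.searchsorted(times, transient))
    if start >= len(times) - 1:
        raise ValueError("post-transient window must contain at least two frames")
    dtheta = np.abs(traj.phases_unwrapped[-1] - traj.phases_unwrapped[start])
    dangle = np.abs(traj.angles_unwrapped[-1] - traj.angles_unwrapped[start])
    cycled = (dtheta >= 2 * np.pi) & (dangle >= 2 * np.pi)
    return float(cycled.mean())


@dataclass
class OrderSeries:
    """Per-frame order parameters aligned with a trajectory's frames."""

    times: np.ndarray
    S_plus: np.ndarray
    S_minus: np.ndarray
    S: np.ndarray
    Z: np.ndarray
    beta: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "S_plus": self.S_plus,
                "S_minus": self.S_minus,
                "S": self.S,
                "Z": self.Z,
                "beta": self.beta,
            }
        )


def compute_order_series(traj: Trajectory) -> OrderSeries:
    """Evaluate S±, S, Z, beta on every recorded frame."""
    out = {k: [] for k in ("S_plus", "S_minus", "S", "Z", "beta")}
    both_signs = np.any(traj.frames[0].omega > 0) and np.any(traj.frames[0].omega < 0)
    for frame in traj.frames:
        sp, sm, s = space_phase_order(frame)
        out["S_plus"].append(sp)
        out["S_minus"].append(sm)
        out["S"].append(s)
        out["Z"].append(kuramoto_order(frame))
        out["beta"].append(cluster_separation(frame) if both_signs else float("nan"))
    return OrderSeries(times=traj.times, **{k: np.array(v) for k, v in out.items()})


def windowed_order(traj: Trajectory, window_fraction: float = 0.1) -> float:
    """Mean S over the final ``window_fraction`` of the run (heat-map scalar)."""
    if not 0 < window_fraction <= 1:
        raise ValueError(f"window_fraction must be in (0, 1], got {window_fraction}")
    times = traj.times
    cutoff = times[-1] - window_fraction * (times[-1] - times[0])
    vals = [space_phase_order(f)[2] for f in traj.frames if f.t >= cutoff]
    return float(np.mean(vals))
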