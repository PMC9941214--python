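"""Fine-grained spatial statistics: g(r), phase-phase and velocity correlations.

The delta functions of the defining sums are resolved on a histogram grid
(default bin width 0.05).  Conventions:

* ``pair_correlation`` (g(r)) reports a density: the fraction of ordered
  pairs per unit distance, normalised by N(N-1) and by bin width, with no
  shell-area factor.  Bin values times bin widths therefore sum to 1 when
  the grid covers every pair distance.
* ``phase_correlation`` (C_theta_theta) is the conditional mean of
  n_i . n_j = cos(th_i - th_j) over the pairs found at distance r, so a
  globally synchronised state plateaus at exactly 1.  Raw pair counts are
  retained so any alternative normalisation is recoverable.
* ``velocity_autocorrelation`` uses finite-difference velocities over one
  recording interval (the model is first order, so instantaneous velocities
  are not part of the recorded state) and averages over agents, admissible
  post-transient times, and the ensemble.

Ensemble averages pool bin sums and counts across states/runs, which makes
averaging linear: count-weighted averaging of per-run curves equals the
pooled computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .integrator import Trajectory
from .model import SwarmState

__all__ = [
    "BinnedCurve",
    "pair_correlation",
    "phase_correlation",
    "velocity_autocorrelation",
    "support_radius",
    "decay_radius",
    "count_peaks",
    "find_peaks",
    "default_bin_edges",
]


def default_bin_edges(r_max: float = 15.0, width: float = 0.05) -> np.ndarray:
    """Uniform radial grid from 0 to ``r_max`` with the default 0.05 width."""
    return np.arange(0.0, r_max + width / 2, width)


@dataclass
class BinnedCurve:
    """A binned statistic over radius or time lag.

    ``value`` is NaN wherever ``count`` is zero (no contributing pairs or
    samples); ``n_ensemble`` records how many independent runs/states were
    pooled.
    """

    bin_edges: np.ndarray
    value: np.ndarray
    count: np.ndarray
    n_ensemble: int = 1

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.count = np.asarray(self.count, dtype=float)
        if self.bin_edges.ndim != 1 or len(self.bin_edges) < 2:
            raise ValueError("bin_edges must be a 1-D array with at least two edges")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        nbins = len(self.bin_edges) - 1
        if self.value.shape != (nbins,) or self.count.shape != (nbins,):
            raise ValueError("value and count must have one entry per bin")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "value": self.value,
                "count": self.count,
            }
        )


def _check_states(states: list[SwarmState]) -> None:
    if not states:
        raise ValueError("need at least one state")


def pair_correlation(states: list[SwarmState], bin_edges: np.ndarray) -> BinnedCurve:
    """Pair-distance density g(r), pooled over ``states``."""
    _check_states(states)
    bin_edges = np.asarray(bin_edges, dtype=float)
    widths = np.diff(bin_edges)
    if np.any(widths <= 0):
        raise ValueError("bin edges must be strictly increasing (no zero-width bins)")
    nbins = len(bin_edges) - 1
    total_fraction = np.zeros(nbins)
    total_count = np.zeros(nbins)
    for state in states:
        if state.n < 2:
            raise ValueError("pair correlation needs at least two agents")
        dists = pdist(state.pos)
        hist, _ = np.histogram(dists, bins=bin_edges)
        ordered = 2.0 * hist  # each unordered pair contributes twice
        total_fraction += ordered / (state.n * (state.n - 1))
        total_count += ordered
    value = total_fraction / (len(states) * widths)
    return BinnedCurve(bin_edges=bin_edges, value=value, count=total_count, n_ensemble=len(states))


def phase_correlation(states: list[SwarmState], bin_edges: np.ndarray) -> BinnedCurve:
    """Conditional mean of cos(th_i - th_j) over pairs at distance r."""
    _check_states(states)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing (no zero-width bins)")
    nbins = len(bin_edges) - 1
    total_cos = np.zeros(nbins)
    total_count = np.zeros(nbins)
    for state in states:
        if state.n < 2:
            raise ValueError("phase correlation needs at least two agents")
        dists = pdist(state.pos)
        iu, ju = np.triu_indices(state.n, k=1)
        cosd = np.cos(state.phase[iu] - state.phase[ju])
        sums, _ = np.histogram(dists, bins=bin_edges, weights=cosd)
        hist, _ = np.histogram(dists, bins=bin_edges)
        total_cos += 2.0 * sums
        total_count += 2.0 * hist
    with np.errstate(invalid="ignore"):
        value = np.where(total_count > 0, total_cos / np.maximum(total_count, 1), np.nan)
    return BinnedCurve(bin_edges=bin_edges, value=value, count=total_count, n_ensemble=len(states))


def velocity_autocorrelation(
    traj: Trajectory,
    lags: np.ndarray | list[float],
    transient_fraction: float = 0.5,
) -> BinnedCurve:
    """Velocity autocorrelation C(tau) = <(1/N) sum_i v_i(t) . v_i(t - tau)>.

    ``lags`` must sit (within rounding) on the recorded frame grid.  The
    average over t runs over frames in the post-transient window (the final
    ``1 - transient_fraction`` of the run).
    """
    t_frames, v = traj.frame_velocities()
    if len(t_frames) < 2:
        raise ValueError("need at least two velocity frames")
    frame_dt = t_frames[1] - t_frames[0]
    if not np.allclose(np.diff(t_frames), frame_dt):
        raise ValueError("velocity autocorrelation requires a uniform recording grid")
    lags = np.asarray(lags, dtype=float)
    steps = np.rint(lags / frame_dt).astype(int)
    if np.any(np.abs(steps * frame_dt - lags) > 1e-9 + 1e-9 * np.abs(lags)):
        raise ValueError("every lag must be an integer multiple of the recording interval")
    if np.any(steps < 0) or np.any(steps >= len(t_frames)):
        raise ValueError("lag exceeds trajectory span")
    t_total = t_frames[-1] - t_frames[0]
    t_start = t_frames[0] + transient_fraction * t_total
    n = v.shape[1]
    value = np.zeros(len(lags))
    count = np.zeros(len(lags))
    for k, step in enumerate(steps):
        admissible = np.nonzero((t_frames >= t_start) & (t_frames - step * frame_dt >= t_frames[0]))[0]
        admissible = admissible[admissible - step >= 0]
        if len(admissible) == 0:
            value[k] = np.nan
            continue
        dots = np.einsum("tij,tij->t", v[admissible], v[admissible - step]) / n
        value[k] = dots.mean()
        count[k] = len(admissible) * n
    half = frame_dt / 2
    edges = np.concatenate([lags - half, [lags[-1] + half]])
    return BinnedCurve(bin_edges=edges, value=value, count=count, n_ensemble=1)


def support_radius(curve: BinnedCurve, threshold_fraction: float = 0.01) -> float:
    """Right edge of the last bin exceeding ``threshold_fraction`` of the max."""
    if not 0 < threshold_fraction < 1:
        raise ValueError(f"threshold_fraction must be in (0, 1), got {threshold_fraction}")
    vals = np.where(curve.count > 0, curve.value, np.nan)
    if not np.any(np.nan_to_num(vals) > 0):
        raise ValueError("support radius undefined for an all-zero curve")
    vmax = np.nanmax(vals)
    above = np.nan_to_num(vals) > threshold_fraction * vmax
    last = np.nonzero(above)[0][-1]
    return float(curve.bin_edges[last + 1])


def decay_radius(curve: BinnedCurve, level: float = 0.1) -> float:
    """Smallest radius beyond which |value| stays below ``level``.

    Empty bins count as decayed.  Returns the left edge of the grid if the
    whole curve already sits below the level.
    """
    if not level > 0:
        raise ValueError(f"level must be positive, got {level}")
    vals = np.nan_to_num(np.where(curve.count > 0, curve.value, np.nan))
    above = np.abs(vals) >= level
    if not np.any(above):
        return float(curve.bin_edges[0])
    last = np.nonzero(above)[0][-1]
    return float(curve.bin_edges[last + 1])


def _smooth(values: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return values
    kernel = np.ones(width) / width
    padded = np.pad(values, width // 2, mode="edge")
    out = np.convolve(padded, kernel, mode="valid")
    return out[: len(values)]


def find_peaks(
    curve: BinnedCurve, window: tuple[float, float], smooth_width: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Strict local maxima of the lightly smoothed curve within ``window``.

    Returns (peak radii, peak values of the smoothed curve).  Empty bins
    contribute zero, matching the density reading of the statistic.
    """
    lo, hi = window
    centers = curve.centers
    sel = (centers >= lo) & (centers <= hi)
    if sel.sum() < 3:
        raise ValueError("window must contain at least three bins")
    vals = _smooth(np.nan_to_num(curve.value)[sel], smooth_width)
    mids = centers[sel]
    is_peak = (vals[1:-1] > vals[:-2]) & (vals[1:-1] > vals[2:])
    idx = np.nonzero(is_peak)[0] + 1
    return mids[idx], vals[idx]


def count_peaks(curve: BinnedCurve, window: tuple[float, float], smooth_width: int = 3) -> int:
    """Number of strict interior local maxima within ``window``."""
    return int(len(find_peaks(curve, window, smooth_width)[0]))
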