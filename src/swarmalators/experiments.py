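"""Reproducible experiment drivers.

Three entry points:

* :func:`scan_kj` — heat-map scans of the space-phase order parameter S
  over the (K, J) plane, several independent trials per cell.
* :func:`correlation_ensemble` — the local-coupling correlation protocol:
  many short noisy runs of the sigma-gated model (J = K = 1, d = 0.05,
  identical unit frequencies, dt = 0.25, T = 500, N = 300, box L = 4),
  pooled into ensemble-averaged g(r), phase-phase, and velocity
  autocorrelation curves.
* :func:`preset` — a catalog of named collective states with best-effort
  parameter locations (approximate entries are flagged).

Per-run seeds are derived with ``numpy.random.SeedSequence`` from the base
seed plus grid/trial indices, so every cell is independent and individually
re-runnable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .correlations import (
    BinnedCurve,
    default_bin_edges,
    pair_correlation,
    phase_correlation,
    velocity_autocorrelation,
)
from .integrator import RunSchedule, SimulationDiverged, Trajectory, simulate
from .observables import windowed_order
from .params import FrequencySpec, ModelParams

__all__ = ["ScanResult", "scan_kj", "correlation_ensemble", "preset", "preset_names", "PRESETS"]

logger = logging.getLogger(__name__)


def _derived_seed(*parts: int) -> int:
    """Stable independent seed from a base seed and indices (below 2**31)."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


@dataclass
class ScanResult:
    """Windowed S per (K, J) cell over independent trials, plus provenance."""

    K_values: np.ndarray
    J_values: np.ndarray
    S_trials: np.ndarray  # (nK, nJ, trials); NaN marks a diverged run
    params_base: ModelParams
    spec: FrequencySpec
    schedule: RunSchedule
    base_seed: int

    @property
    def S_mean(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.S_trials, axis=2)

    @property
    def S_sd(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.nanstd(self.S_trials, axis=2)

    @property
    def trials(self) -> int:
        return self.S_trials.shape[2]

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (K, J, trial)."""
        nk, nj, nt = self.S_trials.shape
        kk, jj, tt = np.meshgrid(self.K_values, self.J_values, np.arange(nt), indexing="ij")
        return pd.DataFrame(
            {"K": kk.ravel(), "J": jj.ravel(), "trial": tt.ravel(), "S": self.S_trials.ravel()}
        )

    def summary_frame(self) -> pd.DataFrame:
        kk, jj = np.meshgrid(self.K_values, self.J_values, indexing="ij")
        return pd.DataFrame(
            {
                "K": kk.ravel(),
                "J": jj.ravel(),
                "S_mean": self.S_mean.ravel(),
                "S_sd": self.S_sd.ravel(),
            }
        )


def scan_kj(
    spec: FrequencySpec,
    params_base: ModelParams,
    K_values: np.ndarray | list[float],
    J_values: np.ndarray | list[float],
    trials: int,
    schedule: RunSchedule,
    window_fraction: float = 0.1,
) -> ScanResult:
    """Scan the (K, J) plane, ``trials`` seeded runs per cell.

    Each run records the mean S over the final ``window_fraction`` of the
    trajectory.  A diverging cell is logged and stored as NaN, not fatal.
    """
    K_values = np.asarray(K_values, dtype=float)
    J_values = np.asarray(J_values, dtype=float)
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    if K_values.size == 0 or J_values.size == 0:
        raise ValueError("K and J grids must be non-empty")
    out = np.full((len(K_values), len(J_values), trials), np.nan)
    for ik, k in enumerate(K_values):
        for ij, j in enumerate(J_values):
            params = replace(params_base, K=float(k), J=float(j))
            for trial in range(trials):
                seed = _derived_seed(schedule.seed, ik, ij, trial)
                sched = replace(schedule, seed=seed)
                try:
                    traj = simulate(spec, params, sched)
                except SimulationDiverged as exc:
                    logger.warning("cell K=%g J=%g trial %d diverged: %s", k, j, trial, exc)
                    continue
                out[ik, ij, trial] = windowed_order(traj, window_fraction)
    return ScanResult(
        K_values=K_values,
        J_values=J_values,
        S_trials=out,
        params_base=params_base,
        spec=spec,
        schedule=schedule,
        base_seed=schedule.seed,
    )


def correlation_ensemble(
    sigma: float,
    n_ensemble: int = 20,
    base_seed: int = 0,
    bin_edges: np.ndarray | None = None,
    lags: np.ndarray | list[float] | None = None,
    schedule: RunSchedule | None = None,
    params: ModelParams | None = None,
) -> tuple[BinnedCurve, BinnedCurve, BinnedCurve]:
    """Ensemble-averaged (g(r), C_theta_theta(r), C_vv(tau)) curves for the
    local-coupling model at coupling radius ``sigma``.

    Defaults follow the correlation-protocol configuration: J = K = 1,
    d = 0.05, all natural frequencies equal to 1, dt = 0.25, T = 500,
    N = 300, initial box of side 4.  g and the phase-phase correlation are
    computed from the final frames of ``n_ensemble`` independently seeded
    runs; the velocity autocorrelation is averaged over the post-transient
    half of each run and pooled across the ensemble with count weights.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if n_ensemble < 1:
        raise ValueError(f"n_ensemble must be >= 1, got {n_ensemble}")
    if params is None:
        params = ModelParams(J=1.0, K=1.0, d=0.05, sigma=float(sigma))
    else:
        params = replace(params, sigma=float(sigma))
    if schedule is None:
        schedule = RunSchedule(dt=0.25, T=500.0, n=300, record_stride=8, init_box=4.0)
    spec = FrequencySpec(kind="F1")
    if bin_edges is None:
        bin_edges = default_bin_edges()
    finals = []
    cvv_sum = None
    cvv_count = None
    for run in range(n_ensemble):
        sched = replace(schedule, seed=_derived_seed(base_seed, run))
        traj = simulate(spec, params, sched)
        finals.append(traj.final)
        if lags is None:
            frame_dt = float(traj.times[1] - traj.times[0])
            span = traj.times[-2] - traj.times[0]
            lags = frame_dt * np.arange(0, min(int(span / frame_dt) + 1, 11))
        cvv = velocity_autocorrelation(traj, lags)
        weighted = np.nan_to_num(cvv.value) * cvv.count
        if cvv_sum is None:
            cvv_sum, cvv_count = weighted, cvv.count
            cvv_edges = cvv.bin_edges
        else:
            cvv_sum = cvv_sum + weighted
            cvv_count = cvv_count + cvv.count
    g = pair_correlation(finals, bin_edges)
    ctt = phase_correlation(finals, bin_edges)
    with np.errstate(invalid="ignore"):
        cvv_value = np.where(cvv_count > 0, cvv_sum / np.maximum(cvv_count, 1), np.nan)
    cvv_curve = BinnedCurve(
        bin_edges=cvv_edges, value=cvv_value, count=cvv_count, n_ensemble=n_ensemble
    )
    return g, ctt, cvv_curve


@dataclass(frozen=True)
class Preset:
    """A named collective state: configuration plus catalog metadata."""

    spec: FrequencySpec
    params: ModelParams
    schedule: RunSchedule
    note: str = ""
    approximate: bool = False


def _std(spec: FrequencySpec, note: str, approximate: bool = False, *, schedule: RunSchedule | None = None, **kw) -> Preset:
    return Preset(
        spec=spec,
        params=ModelParams(**kw),
        schedule=schedule or RunSchedule(),
        note=note,
        approximate=approximate,
    )


_LOCAL_SCHEDULE = RunSchedule(dt=0.25, T=500.0, n=300, record_stride=8, init_box=4.0)
_F1 = FrequencySpec(kind="F1")
_F2 = FrequencySpec(kind="F2")
_F3 = FrequencySpec(kind="F3")
_F4 = FrequencySpec(kind="F4")

PRESETS: dict[str, Preset] = {
    "static_sync": _std(_F1, "single synchronised static cluster", K=1.0, J=0.1),
    "static_async": _std(_F1, "disordered static cloud", K=-0.8, J=-0.5),
    "phase_wave": _std(_F1, "annulus with circumferentially travelling phase wave", K=-0.5, J=1.0),
    "splintered_phase_wave": _std(_F1, "phase wave broken into librating clusters", K=-0.1, J=1.0),
    "double_phase_wave": _std(_F2, "two concentric interacting phase waves", K=-0.5, J=1.0),
    "bouncing_clusters": _std(
        _F2, "two sync clusters oscillating between attraction and repulsion", True, K=0.5, J=1.0
    ),
    "static_antiphase": _std(
        _F2, "two phase-locked groups offset by a constant phase", True, K=1.8, J=0.0
    ),
    "radial_oscillation": _std(
        _F2, "mixed circular formation that periodically expands and contracts", True, K=0.5, J=-0.5
    ),
    "expanding_sync": _std(
        _F1, "synchronised circular formation that expands indefinitely", True, K=0.5, J=-0.5
    ),
    "vortex": _std(_F3, "single vortex of co-rotating chiral agents", K=-0.5, J=1.0, speed=1.0),
    "revolving_clusters": _std(
        _F3, "tight synchronised clusters revolving together", True, K=1.5, J=1.0, speed=1.0
    ),
    "fccs_double_vortex": _std(
        _F4,
        "two intersecting counter-rotating vortices under frequency coupling",
        True,
        K=0.5,
        J=1.0,
        speed=1.0,
        freq_coupling=True,
    ),
    "local_sync": _std(
        _F1,
        "single sync cluster under long-range local coupling",
        schedule=_LOCAL_SCHEDULE,
        K=1.0,
        J=1.0,
        d=0.05,
        sigma=5.0,
    ),
    "local_clusters": _std(
        _F1,
        "multiple weakly correlated sync clusters at intermediate coupling range",
        schedule=_LOCAL_SCHEDULE,
        K=1.0,
        J=1.0,
        d=0.05,
        sigma=3.0,
    ),
    "sync_crystal": _std(
        _F1,
        "crystal-like lattice with local phase coherence under short-range coupling",
        schedule=_LOCAL_SCHEDULE,
        K=1.0,
        J=1.0,
        d=0.05,
        sigma=0.5,
    ),
    "embryonic_wave": _std(
        _F1,
        "radial phase waves of the embryonic-oscillator variant",
        True,
        variant="embryonic",
        K=1.0,
        J=1.0,
        alpha=1.5,
    ),
}


def preset_names() -> list[str]:
    return sorted(PRESETS)


def preset(name: str) -> tuple[FrequencySpec, ModelParams, RunSchedule]:
    """Full configuration for a named collective state."""
    try:
        p = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; valid names: {', '.join(preset_names())}"
        ) from None
    return p.spec, p.params, p.schedule
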