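"""Model constants and natural-frequency distribution descriptors.

A swarmalator couples a 2D position to an internal oscillator phase.  The
pairwise dynamics are controlled by a small set of scalar constants:

``A``
    unit-vector spatial attraction coefficient (keeps the collective
    together; fixed to 1 throughout the reference study).
``B``
    power-law repulsion coefficient (prevents collapse to a point; also 1).
``J``
    space-phase interaction in [-1, 1]; J > 0 attracts like-phased agents,
    J < 0 repels them.
``K``
    Kuramoto-style phase coupling in [-1, 2], weighted by inverse distance.
``speed``
    inherent speed magnitude |c| in {0, 1}; 0 means non-chiral agents whose
    phase is a purely internal state, 1 means each agent follows an inherent
    circular orbit whose sense is set by the sign of its natural frequency.
``freq_coupling``
    enables pairwise phase offsets that make counter-rotating agents (with
    opposite-sign natural frequencies) repel similar phases.
``sigma``
    coupling radius; pairs farther apart than sigma do not interact at all
    (math.inf recovers global coupling).
``d``
    additive white-noise strength on both position and phase.
``variant``
    "standard" for the main model, "embryonic" for the variation with
    modified distance powers and a constant phase lag ``alpha`` that mimics
    aggregates of embryonic genetic oscillators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ModelParams", "FrequencySpec", "FREQUENCY_KINDS"]

_VARIANTS = ("standard", "embryonic")
_NOISE_SCALINGS = ("sqrt_dt", "per_step")
FREQUENCY_KINDS = ("F1", "F2", "F3", "F4", "k_group", "custom")


@dataclass(frozen=True)
class ModelParams:
    """All scalar model constants plus variant/chirality/noise switches."""

    A: float = 1.0
    B: float = 1.0
    J: float = 0.0
    K: float = 0.0
    speed: float = 0.0
    freq_coupling: bool = False
    sigma: float = math.inf
    d: float = 0.0
    variant: str = "standard"
    alpha: float = 0.0
    softening: float = 1e-6
    noise_scaling: str = "sqrt_dt"

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"A must be positive, got {self.A}")
        if not self.B > 0:
            raise ValueError(f"B must be positive, got {self.B}")
        if self.speed not in (0, 1, 0.0, 1.0):
            raise ValueError(f"speed must be 0 or 1, got {self.speed}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive (use math.inf for global coupling), got {self.sigma}")
        if self.d < 0:
            raise ValueError(f"noise strength d must be non-negative, got {self.d}")
        if not self.softening > 0:
            raise ValueError(f"softening must be positive, got {self.softening}")
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}, got {self.variant!r}")
        if self.noise_scaling not in _NOISE_SCALINGS:
            raise ValueError(f"noise_scaling must be one of {_NOISE_SCALINGS}, got {self.noise_scaling!r}")

    @property
    def is_global(self) -> bool:
        """True when the coupling radius never gates any pair."""
        return math.isinf(self.sigma)


@dataclass(frozen=True)
class FrequencySpec:
    """Descriptor of the natural-frequency distribution.

    Kinds
    -----
    F1       all agents share omega = 1 (identical, counterclockwise).
    F2       exactly half at +1, half at -1 (two counter-rotating groups).
    F3       i.i.d. uniform on [1, Omega].
    F4       half uniform on [1, Omega], half uniform on [-Omega, -1].
    k_group  n agents evenly split over k equally spaced values on
             [1, Omega] (multi-group concentric states).
    custom   explicit per-group values, cycled over agents.
    """

    kind: str = "F1"
    Omega: float = 3.0
    k: int = 2
    values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in FREQUENCY_KINDS:
            raise ValueError(f"kind must be one of {FREQUENCY_KINDS}, got {self.kind!r}")
        if self.Omega < 1:
            raise ValueError(f"Omega must be >= 1, got {self.Omega}")
        if self.kind == "k_group" and self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.kind == "custom":
            if not self.values:
                raise ValueError("custom frequency spec requires a non-empty 'values' tuple")
            vals = np.asarray(self.values, dtype=float)
            if np.any(vals == 0):
                raise ValueError("custom frequency values must be non-zero")
            object.__setattr__(self, "values", tuple(float(v) for v in vals))

    @property
    def split(self) -> bool:
        """True for distributions that demand an even agent count."""
        return self.kind in ("F2", "F4", "k_group")
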