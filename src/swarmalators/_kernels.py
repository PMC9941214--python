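"""Numba pair-loop kernels for the right-hand side.

The O(N^2) interaction sums are the hot spot of every simulation.  These
kernels avoid per-pair trigonometry by expanding cos/sin of phase
differences into products of per-agent cos/sin, and exploit the i<->j
symmetry of the pair terms.  The frequency-coupling offsets only ever take
the values (0, 0) for same-sign pairs and (pi, pi/2) for opposite-sign
pairs, which reduces to sign flips:

    cos(d - pi)      = -cos(d)
    sin(d - pi/2)    = -cos(d)      (symmetric in i <-> j)

The pure-NumPy implementation in :mod:`swarmalators.model` computes the
same quantities and serves as the fallback when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every simulation
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(fn):
            return fn

        return wrap


@njit(fastmath=True)
def rhs_standard(pos, cth, sth, sgn, A, B, J, K, sigma, eps, freq_coupling, dpos, dphase):
    n = pos.shape[0]
    for i in range(n):
        dpos[i, 0] = 0.0
        dpos[i, 1] = 0.0
        dphase[i] = 0.0
    for i in range(n):
        xi, yi = pos[i, 0], pos[i, 1]
        ci, si = cth[i], sth[i]
        for j in range(i + 1, n):
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            r = (dx * dx + dy * dy) ** 0.5
            if r < eps:
                r = eps
            if sigma - r <= 0.0:
                continue
            cos_d = ci * cth[j] + si * sth[j]
            sin_d = ci * sth[j] - si * cth[j]  # sin(th_j - th_i)
            if freq_coupling and sgn[i] * sgn[j] < 0.0:
                cos_x = -cos_d
                st_ij = -cos_d
                st_ji = -cos_d
            else:
                cos_x = cos_d
                st_ij = sin_d
                st_ji = -sin_d
            w = (A + J * cos_x - B / r) / r
            dpos[i, 0] += w * dx
            dpos[i, 1] += w * dy
            dpos[j, 0] -= w * dx
            dpos[j, 1] -= w * dy
            dphase[i] += st_ij / r
            dphase[j] += st_ji / r
    inv_n = 1.0 / n
    for i in range(n):
        dpos[i, 0] *= inv_n
        dpos[i, 1] *= inv_n
        dphase[i] *= K * inv_n


@njit(fastmath=True)
def rhs_embryonic(pos, cth, sth, A, B, J, K, cos_a, sin_a, eps, dpos, dphase):
    n = pos.shape[0]
    for i in range(n):
        dpos[i, 0] = 0.0
        dpos[i, 1] = 0.0
        dphase[i] = 0.0
    for i in range(n):
        xi, yi = pos[i, 0], pos[i, 1]
        ci, si = cth[i], sth[i]
        for j in range(i + 1, n):
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            r = (dx * dx + dy * dy) ** 0.5
            if r < eps:
                r = eps
            r2 = r * r
            cos_d = ci * cth[j] + si * sth[j]
            sin_d = ci * sth[j] - si * cth[j]
            w = (A + J * cos_d) / r2 - B / (r2 * r2)
            dpos[i, 0] += w * dx
            dpos[i, 1] += w * dy
            dpos[j, 0] -= w * dx
            dpos[j, 1] -= w * dy
            dphase[i] += sin_d * cos_a - cos_d * sin_a
            dphase[j] += -sin_d * cos_a - cos_d * sin_a
    inv_n = 1.0 / n
    for i in range(n):
        dpos[i, 0] *= inv_n
        dpos[i, 1] *= inv_n
        dphase[i] *= K * inv_n
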