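"""Naive scalar-loop reference implementations.

Everything here is written as close to the defining sums as possible —
explicit Python double loops, one pair at a time — and stays independent of
the vectorized/kernel code paths it is used to check.
"""

from __future__ import annotations

import math

import numpy as np


def rhs_loop(state, params):
    """Direct per-pair evaluation of the deterministic derivatives."""
    n = state.n
    dpos = np.zeros((n, 2))
    dth = np.zeros(n)
    for i in range(n):
        vi = state.c[i] * np.array(
            [math.cos(state.phase[i] + math.pi / 2), math.sin(state.phase[i] + math.pi / 2)]
        )
        fsum = np.zeros(2)
        tsum = 0.0
        for j in range(n):
            if j == i:
                continue
            dvec = state.pos[j] - state.pos[i]
            r = max(float(np.linalg.norm(dvec)), params.softening)
            dphase = state.phase[j] - state.phase[i]
            if params.variant == "embryonic":
                fsum += dvec / r**2 * (params.A + params.J * math.cos(dphase))
                fsum -= params.B * dvec / r**4
                tsum += math.sin(dphase - params.alpha)
            else:
                if not math.isinf(params.sigma) and not (params.sigma - r > 0):
                    continue
                qx = qt = 0.0
                if params.freq_coupling:
                    gap = abs(np.sign(state.omega[j]) - np.sign(state.omega[i]))
                    qx = math.pi / 2 * gap
                    qt = math.pi / 4 * gap
                u = dvec / r
                fsum += u * (params.A + params.J * math.cos(dphase - qx))
                fsum -= params.B * u / r
                tsum += math.sin(dphase - qt) / r
        dpos[i] = vi + fsum / n
        dth[i] = state.omega[i] + params.K * tsum / n
    return dpos, dth


def offsets_loop(omega):
    n = len(omega)
    qx = np.zeros((n, n))
    qt = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            gap = abs(omega[j] / abs(omega[j]) - omega[i] / abs(omega[i]))
            qx[i, j] = math.pi / 2 * gap
            qt[i, j] = math.pi / 4 * gap
    return qx, qt


def headings_loop(phase):
    out = np.zeros((len(phase), 2))
    for i, th in enumerate(phase):
        out[i] = [math.cos(th + math.pi / 2), math.sin(th + math.pi / 2)]
    return out


def space_phase_loop(state):
    centroid = state.pos.mean(axis=0)
    zp = 0j
    zm = 0j
    n = 0
    for i in range(state.n):
        rel = state.pos[i] - centroid
        if np.hypot(rel[0], rel[1]) <= 1e-12:
            continue
        phi = math.atan2(rel[1], rel[0])
        zp += np.exp(1j * (phi + state.phase[i]))
        zm += np.exp(1j * (phi - state.phase[i]))
        n += 1
    return abs(zp) / n, abs(zm) / n


def kuramoto_loop(state):
    z = sum(np.exp(1j * th) for th in state.phase) / state.n
    return abs(z)


def beta_loop(state):
    plus = np.array([state.pos[i] for i in range(state.n) if state.omega[i] > 0])
    minus = np.array([state.pos[i] for i in range(state.n) if state.omega[i] < 0])
    return float(np.linalg.norm(plus.mean(axis=0) - minus.mean(axis=0)))


def pair_histogram_loop(states, edges):
    """Ordered-pair distance histogram: fraction per bin / width, raw counts."""
    nbins = len(edges) - 1
    frac = np.zeros(nbins)
    count = np.zeros(nbins)
    for state in states:
        for i in range(state.n):
            for j in range(state.n):
                if i == j:
                    continue
                r = float(np.linalg.norm(state.pos[j] - state.pos[i]))
                for b in range(nbins):
                    if edges[b] <= r < edges[b + 1]:
                        frac[b] += 1.0 / (state.n * (state.n - 1))
                        count[b] += 1
                        break
    return frac / (len(states) * np.diff(edges)), count


def phase_corr_loop(states, edges):
    """Conditional mean of cos(th_i - th_j) per distance bin, pooled."""
    nbins = len(edges) - 1
    total = np.zeros(nbins)
    count = np.zeros(nbins)
    for state in states:
        for i in range(state.n):
            for j in range(state.n):
                if i == j:
                    continue
                r = float(np.linalg.norm(state.pos[j] - state.pos[i]))
                for b in range(nbins):
                    if edges[b] <= r < edges[b + 1]:
                        total[b] += math.cos(state.phase[i] - state.phase[j])
                        count[b] += 1
                        break
    value = np.full(nbins, np.nan)
    value[count > 0] = total[count > 0] / count[count > 0]
    return value, count


def velocity_corr_loop(times, velocities, lags, transient_fraction=0.5):
    """Per-lag mean of v_i(t) . v_i(t - tau) over agents and admissible t."""
    frame_dt = times[1] - times[0]
    t_start = times[0] + transient_fraction * (times[-1] - times[0])
    out = []
    for lag in lags:
        step = int(round(lag / frame_dt))
        acc = []
        for k in range(len(times)):
            if times[k] < t_start or k - step < 0:
                continue
            dots = [float(velocities[k, i] @ velocities[k - step, i]) for i in range(velocities.shape[1])]
            acc.append(np.mean(dots))
        out.append(np.mean(acc) if acc else np.nan)
    return np.array(out)


def support_radius_loop(edges, value, count, threshold):
    vmax = max(v for v, c in zip(value, count) if c > 0 and not math.isnan(v))
    last = None
    for b in range(len(value)):
        if count[b] > 0 and not math.isnan(value[b]) and value[b] > threshold * vmax:
            last = b
    return edges[last + 1]


def count_peaks_loop(values):
    """Strict interior local maxima of an already-smoothed sequence."""
    n = 0
    for k in range(1, len(values) - 1):
        if values[k] > values[k - 1] and values[k] > values[k + 1]:
            n += 1
    return n
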