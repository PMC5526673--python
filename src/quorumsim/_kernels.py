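"""Compiled event loop of the stochastic birth-death process.

The kernel advances the state vector of production degrees event by event:
exponential waiting times at total rate ``sum_k phi(p_k)``, a
fitness-proportional parent drawn by rejection sampling (``phi <= 1``), a
uniform death slot among the other N-1 individuals, and the two offspring
independently responding to the sensed average with probability ``lam``.
Everything is O(1) per event; the running sum of degrees is refreshed every
N events to bound floating-point drift.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# response-family tags (kept in sync with model.py)
KIND_LINEAR = 0
KIND_SINUSOIDAL = 1
KIND_HILL = 2
KIND_PITCHFORK = 3
KIND_TABLE = 4


@njit(cache=True, inline="always")
def _resp(kind, a, b, xs, ys, x):
    if kind == KIND_LINEAR:
        return x
    if kind == KIND_SINUSOIDAL:
        return x + a * np.sin(np.pi * x)
    if kind == KIND_HILL:
        xn = x ** a
        kn = b ** a
        return xn * (1.0 + kn) / (xn + kn)
    if kind == KIND_PITCHFORK:
        u = x - 0.5
        return x + a * u - b * u * u * u
    return np.interp(x, xs, ys)


@njit(cache=True, inline="always")
def _clip01(x):
    if x < 0.0:
        return 0.0
    if x > 1.0:
        return 1.0
    return x


@njit(cache=True)
def simulate(degrees, s, lam, kind, ra, rb, rxs, rys,
             sig_inh, sig_per, sig_res, seed,
             t_end, record_times, stop_on_absorb, death_any, sense_post,
             check_every):
    """Run the process in place until ``t_end`` or absorption.

    Returns (snapshots, n_recorded, absorbed, t_abs, t_final).  Snapshot k
    holds the state at record_times[k] (the state just before the first
    event beyond that time).  If the run absorbs early, remaining record
    slots are filled with the frozen absorbing state.
    """
    np.random.seed(seed)
    N = degrees.shape[0]
    n_rec = record_times.shape[0]
    snaps = np.empty((n_rec, N))
    rec_i = 0
    t = 0.0
    sum_p = 0.0
    for k in range(N):
        sum_p += degrees[k]
    events = 0
    since_check = 0
    absorbed = False
    t_abs = -1.0

    while True:
        # absorption test on the current state (amortized O(1) for large N)
        if stop_on_absorb and since_check == 0:
            p0 = degrees[0]
            alleq = True
            for k in range(1, N):
                if degrees[k] != p0:
                    alleq = False
                    break
            if alleq and (lam == 0.0 or
                          abs(_resp(kind, ra, rb, rxs, rys, p0) - p0) <= 1e-12):
                absorbed = True
                t_abs = t
                break
        since_check += 1
        if since_check >= check_every:
            since_check = 0

        total_rate = N - s * sum_p
        t_next = t + np.random.exponential(1.0 / total_rate)

        while rec_i < n_rec and record_times[rec_i] <= t_next:
            for k in range(N):
                snaps[rec_i, k] = degrees[k]
            rec_i += 1

        if t_next >= t_end:
            t = t_end
            break

        # parent i by rejection: accept with probability phi(p_i) <= 1
        while True:
            i = np.random.randint(N)
            if np.random.random() < 1.0 - s * degrees[i]:
                break
        # death slot j (uniform over the other N-1 individuals by default)
        if death_any:
            j = np.random.randint(N)
        else:
            j = np.random.randint(N - 1)
            if j >= i:
                j += 1

        anc = degrees[i]
        if sense_post and j != i:
            sensed = (sum_p - degrees[j] + anc) / N
        else:
            sensed = sum_p / N

        # both offspring (slots i and j) respond independently
        for slot in (i, j):
            if np.random.random() < lam:
                cue = sensed
                if sig_per > 0.0:
                    cue = _clip01(cue + sig_per * np.random.normal())
                newp = _resp(kind, ra, rb, rxs, rys, cue)
                if sig_res > 0.0:
                    newp = _clip01(newp + sig_res * np.random.normal())
            else:
                newp = anc
                if sig_inh > 0.0:
                    newp = _clip01(newp + sig_inh * np.random.normal())
            sum_p += newp - degrees[slot]
            degrees[slot] = newp

        t = t_next
        events += 1
        if events % N == 0:
            # refresh the running sum to bound floating-point drift
            sum_p = 0.0
            for k in range(N):
                sum_p += degrees[k]

    if absorbed:
        while rec_i < n_rec:
            for k in range(N):
                snaps[rec_i, k] = degrees[k]
            rec_i += 1

    return snaps, rec_i, absorbed, t_abs, t
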