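"""Mean-field dynamics of the production distribution (the autoinducer equation).

In the large-N limit the one-particle production distribution ``rho(p, t)``
obeys

    d_t rho = 2*lam*phibar_t * (delta(p - R(pbar_t)) - rho)
              + (1 - 2*lam) * (phi(p) - phibar_t) * rho ,

where ``pbar_t`` and ``phibar_t = 1 - s*pbar_t`` are the mean production
degree and mean fitness under ``rho``.  The first term is
sense-and-response: mass is injected as a delta peak at the up-regulated
degree ``R(pbar_t)`` at rate ``2*lam*phibar_t`` while the rest of the
distribution decays at the same rate.  The second is the replicator term of
the continuous-strategy selection dynamics.  The equation conserves total
mass.

The integrator represents rho as an adaptive set of weighted atoms — the
natural representation, since the injection term creates moving delta
peaks and the heterogeneous attractor is purely atomic with a gap.  Each
step applies an operator splitting that is exact when the population means
are frozen over the step: an exponential replicator tilt
``w_k <- w_k * exp(-(1-2*lam)*s*p_k*dt)`` (mean terms absorbed by
renormalization) followed by transfer of the mass fraction
``1 - exp(-2*lam*phibar*dt)`` to the atom at ``R(pbar_t)``.  The scheme is
first-order in the coupling through the means but reproduces the two known
closed-form solutions (lam = 0, and lam = 1/2 with linear response) to
machine precision at any step size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.integrate import quad
from scipy.stats import wasserstein_distance

from .model import (
    MERGE_EPS,
    WEIGHT_FLOOR,
    AtomMeasure,
    InitialDistribution,
    ResponseFunction,
)

__all__ = [
    "MeanFieldTrajectory",
    "autoinducer_rhs",
    "integrate",
    "closed_form_lambda0",
    "closed_form_lambda0_mean",
    "closed_form_linear_half",
    "measure_distance",
    "IntegrationError",
]

DEFAULT_DT_MAX = 1e-2
DEFAULT_N_ATOMS = 400
#: per-step cap on the relative weight change (sets the adaptive dt)
MAX_LOG_WEIGHT_STEP = 0.05


class IntegrationError(RuntimeError):
    """Raised when the adaptive step size collapses."""


@dataclass
class MeanFieldTrajectory:
    """Recorded mean-field evolution: measures and their first two moments."""

    times: np.ndarray
    measures: list[AtomMeasure] = field(repr=False)
    means: np.ndarray
    mean_fitnesses: np.ndarray
    variances: np.ndarray

    def final_measure(self) -> AtomMeasure:
        return self.measures[-1]


def autoinducer_rhs(measure: AtomMeasure, s: float, lam: float,
                    R: ResponseFunction):
    """Right-hand side of the autoinducer equation on an atomic measure.

    Returns ``(dw_dt, injection_location, injection_rate)``: per-atom weight
    derivatives ``dw_k/dt = [-2*lam*phibar + (1-2*lam)*(phi(p_k) - phibar)] w_k``
    with ``phi(p) - phibar = -s*(p - pbar)``, plus mass injected at
    ``R(pbar)`` at rate ``2*lam*phibar``.  The derivatives and the injection
    rate sum to zero (mass conservation).
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lam must lie in [0, 1]")
    if abs(measure.total_mass() - 1.0) > 1e-9:
        raise ValueError("measure must be normalized")
    p = measure.locations
    w = measure.weights
    pbar = float(w @ p)
    phibar = 1.0 - s * pbar
    dw = (-2.0 * lam * phibar - (1.0 - 2.0 * lam) * s * (p - pbar)) * w
    injection_rate = 2.0 * lam * phibar
    injection_location = float(R(pbar))
    return dw, injection_location, injection_rate


def _deposit(locs: np.ndarray, w: np.ndarray, target: float, mass: float,
             eps: float):
    """Add mass at ``target``, merging into an existing atom within eps."""
    idx = np.searchsorted(locs, target)
    for k in (idx - 1, idx):
        if 0 <= k < locs.size and abs(locs[k] - target) < eps:
            tot = w[k] + mass
            locs[k] = (locs[k] * w[k] + target * mass) / tot
            w[k] = tot
            return locs, w
    locs = np.insert(locs, idx, target)
    w = np.insert(w, idx, mass)
    return locs, w


def integrate(init: Union[AtomMeasure, InitialDistribution],
              s: float, lam: float,
              R: Optional[ResponseFunction] = None, *,
              t_max: float, dt_max: float = DEFAULT_DT_MAX,
              record_every: float = 1.0, n_atoms: int = DEFAULT_N_ATOMS,
              merge_eps: float = MERGE_EPS, weight_floor: float = WEIGHT_FLOOR,
              stop_residual: Optional[float] = None) -> MeanFieldTrajectory:
    """Integrate the autoinducer equation from an initial distribution.

    ``init`` may be an :class:`AtomMeasure` or an
    :class:`InitialDistribution` (discretized into ``n_atoms`` equal-mass
    atoms at quantile midpoints).  The step size adapts so that no atom's
    log-weight moves by more than 5% per step, capped at ``dt_max``, and
    lands exactly on the recording schedule.  Atoms below ``weight_floor``
    are pruned; total mass is renormalized to 1 every step.

    If ``stop_residual`` is given, integration stops early once the measure
    moves less than ``stop_residual`` (transport distance per unit time)
    between consecutive integer times; the trajectory then ends at that
    time.
    """
    s = float(s)
    lam = float(lam)
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lam must lie in [0, 1]")
    if lam > 0.0 and R is None:
        raise TypeError("a response function R is required when lam > 0")
    if t_max <= 0:
        raise ValueError("t_max must be > 0")

    measure = init.copy() if isinstance(init, AtomMeasure) else init.to_atoms(n_atoms)
    locs = measure.locations.copy()
    w = measure.weights.copy()

    times = [0.0]
    measures = [AtomMeasure(locs.copy(), w.copy(), merge_eps=merge_eps)]
    t = 0.0
    next_record = record_every
    prev_check: Optional[AtomMeasure] = None
    check_t = 1.0

    while t < t_max - 1e-12:
        pbar = float(w @ locs)
        phibar = 1.0 - s * pbar
        tilt = -(1.0 - 2.0 * lam) * s * locs
        decay = 2.0 * lam * phibar
        max_rate = max(np.max(np.abs(tilt + (1.0 - 2.0 * lam) * s * pbar)), decay, 1e-12)
        dt = min(dt_max, MAX_LOG_WEIGHT_STEP / max_rate, t_max - t)
        if next_record <= t_max + 1e-9:
            dt = min(dt, next_record - t)
        if stop_residual is not None:
            dt = min(dt, check_t - t)
        if dt < 1e-10:
            raise IntegrationError(
                f"step size collapsed at t={t:.6g} (dt={dt:.3g}, "
                f"{locs.size} atoms, pbar={pbar:.6g})")

        # exact replicator tilt (frozen means), renormalized
        w = w * np.exp(tilt * dt)
        w /= w.sum()
        # sense-and-response: transfer mass fraction to the injected peak
        if lam > 0.0:
            f = math.exp(-decay * dt)
            w *= f
            locs, w = _deposit(locs, w, float(R(pbar)), 1.0 - f, merge_eps)
        # prune and renormalize
        keep = w > weight_floor
        if not np.all(keep):
            locs, w = locs[keep], w[keep]
        w /= w.sum()
        t += dt
        # snap onto schedule times to keep accumulated float drift out of
        # the step-size control
        if abs(t - next_record) < 1e-9:
            t = next_record
        elif stop_residual is not None and abs(t - check_t) < 1e-9:
            t = check_t

        if stop_residual is not None and t >= check_t - 1e-12:
            cur = AtomMeasure(locs.copy(), w.copy(), merge_eps=merge_eps)
            if prev_check is not None and measure_distance(cur, prev_check) < stop_residual:
                times.append(t)
                measures.append(cur)
                break
            prev_check = cur
            check_t = t + 1.0

        if t >= next_record - 1e-12 and next_record <= t_max + 1e-12:
            times.append(t)
            measures.append(AtomMeasure(locs.copy(), w.copy(), merge_eps=merge_eps))
            next_record += record_every

    times_arr = np.asarray(times)
    means = np.array([m.mean() for m in measures])
    variances = np.array([m.variance() for m in measures])
    return MeanFieldTrajectory(times=times_arr, measures=measures, means=means,
                               mean_fitnesses=1.0 - s * means, variances=variances)


# ---------------------------------------------------------------------------
# closed-form solutions
# ---------------------------------------------------------------------------

def closed_form_lambda0(init: InitialDistribution, s: float, t: float,
                        n_atoms: int = DEFAULT_N_ATOMS) -> AtomMeasure:
    """Exact solution without quorum sensing: rho_0 reweighted by exp(-s t p).

    ``rho(p, t) = rho_0(p) * exp(-s t p) / Z(t)``: pure replicator dynamics
    exponentially favour the lowest production degrees.  Returned as the
    equal-mass atomic discretization of rho_0 reweighted and renormalized
    (exact for an atomic rho_0).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    atoms = init.to_atoms(n_atoms)
    w = atoms.weights * np.exp(-s * t * atoms.locations)
    return AtomMeasure(atoms.locations, w, normalize=True)


def closed_form_lambda0_mean(init: InitialDistribution, s: float, t: float) -> float:
    """Mean of the lam = 0 closed form, by quadrature (or exact atomic sums).

    For continuous rho_0 the moments of rho_0(p) e^{-s t p}/Z are computed
    with adaptive quadrature; for an atomic rho_0 the sums are exact.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if init.family == "atoms":
        m = closed_form_lambda0(init, s, t)
        return m.mean()
    st = s * t
    z = quad(lambda p: init.pdf(p) * math.exp(-st * p), 0.0, 1.0, limit=200)[0]
    num = quad(lambda p: p * init.pdf(p) * math.exp(-st * p), 0.0, 1.0, limit=200)[0]
    return num / z


def closed_form_linear_half(init: InitialDistribution, s: float, t: float,
                            R: Optional[ResponseFunction] = None,
                            lam: float = 0.5,
                            n_atoms: int = DEFAULT_N_ATOMS) -> AtomMeasure:
    """Exact solution for linear response R(x) = x at lam = 1/2.

    ``rho(p, t) = y(t) rho_0(p) + (1 - y(t)) delta(p - pbar_0)`` with
    ``y(t) = exp(-phibar_0 t)``: the initial distribution decays uniformly
    into a delta peak at the (conserved) initial mean.  Raises if called
    with a nonlinear response or lam != 1/2.
    """
    if lam != 0.5:
        raise ValueError("closed form requires lam = 1/2")
    if R is not None:
        grid = np.linspace(0.0, 1.0, 101)
        if np.max(np.abs(np.asarray(R(grid)) - grid)) > 1e-12:
            raise ValueError("closed form requires the linear (identity) response")
    if t < 0:
        raise ValueError("t must be >= 0")
    pbar0 = init.mean()
    phibar0 = 1.0 - s * pbar0
    y = math.exp(-phibar0 * t)
    atoms = init.to_atoms(n_atoms)
    locs = np.append(atoms.locations, pbar0)
    w = np.append(atoms.weights * y, 1.0 - y)
    return AtomMeasure(locs, w, normalize=True)


def measure_distance(a: AtomMeasure, b: AtomMeasure) -> float:
    """First-order transport (Wasserstein-1) distance between two measures.

    On the compact interval [0, 1] this dominates the bounded-Lipschitz
    distance, so it serves as the numerical convergence diagnostic between
    the stochastic empirical measure and the mean-field solution.
    """
    return float(wasserstein_distance(a.locations, b.locations,
                                      a.weights, b.weights))
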