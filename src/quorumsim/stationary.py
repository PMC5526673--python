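"""Stationary states and phase structure of the autoinducer equation.

For selection strength ``s > 0`` and response probability ``lam``, the
balance parameter ``beta = 2*lam/s`` measures sense-and-response against
fitness differences.  The heterogeneous (bimodal) stationary distribution

    rho_inf = y * delta(p) + (1 - y) * delta(p - p_high),
    p_high = R(beta),  y = 1 - beta / R(beta),

exists whenever ``0 < p_high <= 1`` and ``0 < y < 1``; it has mean ``beta``
and variance ``beta * (R(beta) - beta)``.  Existence requires a nonlinear,
up-regulating response (R(beta) > beta) and a small response probability,
``lam < lam_up = s/2``.  As ``lam -> lam_up`` the gap closes and the
variance vanishes continuously; as ``lam -> 0`` the weight of the
non-producing peak jumps discontinuously to ``1 - 1/R'(0)`` (for R(0) = 0
with finite slope R'(0) > 1).

The low peak is fixed at ``p_low = 0`` here, corresponding to initial
distributions whose lowest production degree is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import meanfield
from .model import AtomMeasure, ResponseFunction

__all__ = [
    "StationarySolution",
    "PhaseDiagnosis",
    "StabilityReport",
    "beta",
    "lambda_up",
    "heterogeneous_solution",
    "phase_classify",
    "order_parameter_curve",
    "stability_probe",
]


def beta(s: float, lam: float) -> float:
    """Balance parameter beta = 2*lam/s (also the stationary mean)."""
    if s <= 0:
        raise ValueError("beta is undefined for s = 0 (no fitness differences)")
    return 2.0 * lam / s


def lambda_up(s: float) -> float:
    """Upper threshold lam_up = s/2 of the heterogeneous phase."""
    if s < 0:
        raise ValueError("s must be >= 0")
    return 0.5 * s


@dataclass(frozen=True)
class StationarySolution:
    """The two-atom heterogeneous stationary distribution and its moments."""

    beta: float
    p_high: float
    p_low: float
    y: float
    mean: float
    variance: float
    exists: bool
    violated_conditions: tuple[str, ...] = ()

    def to_measure(self) -> AtomMeasure:
        if not self.exists:
            raise ValueError("no heterogeneous stationary solution at these parameters")
        return AtomMeasure([self.p_low, self.p_high], [self.y, 1.0 - self.y])


@dataclass(frozen=True)
class PhaseDiagnosis:
    """Phase of the stationary distribution at given (R, s, lam)."""

    phase: str  # "heterogeneous" | "homogeneous"
    lambda_up: float
    jump_at_zero: Optional[float] = None
    solution: Optional[StationarySolution] = field(default=None, repr=False)


def heterogeneous_solution(R: ResponseFunction, s: float, lam: float) -> StationarySolution:
    """Evaluate the closed-form bimodal stationary state at (R, s, lam).

    ``exists`` is True iff 0 < p_high <= 1 and 0 < y < 1; otherwise the
    violated conditions are listed.  The boundary lam = lam_up (y = 0) does
    not count as heterogeneous.
    """
    b = beta(s, lam)
    violated: list[str] = []
    if b > 1.0:
        # R is undefined beyond the unit interval; no consistent solution
        return StationarySolution(beta=b, p_high=np.nan, p_low=0.0, y=np.nan,
                                  mean=b, variance=np.nan, exists=False,
                                  violated_conditions=("beta <= 1",))
    p_high = float(R(b))
    if p_high <= 0.0:
        violated.append("p_high > 0")
        y = np.nan
        var = np.nan
    else:
        y = 1.0 - b / p_high
        var = b * (p_high - b)
        if not (0.0 < p_high <= 1.0):
            violated.append("0 < p_high <= 1")
        if not (0.0 < y < 1.0):
            violated.append("0 < y < 1")
    return StationarySolution(beta=b, p_high=p_high, p_low=0.0, y=y,
                              mean=b, variance=var, exists=not violated,
                              violated_conditions=tuple(violated))


def phase_classify(R: ResponseFunction, s: float, lam: float) -> PhaseDiagnosis:
    """Classify (R, s, lam) as heterogeneous or homogeneous.

    Heterogeneous iff the closed-form bimodal solution exists (which implies
    0 < lam < lam_up = s/2 for an up-regulating response).  When R(0) = 0
    with finite slope 1 < R'(0), the lam -> 0 limit of the low-peak weight,
    1 - 1/R'(0), is reported as the size of the discontinuous jump.
    """
    sol = heterogeneous_solution(R, s, lam)
    jump = None
    if abs(float(R(0.0))) <= 1e-12:
        d0 = float(R.derivative(0.0))
        if np.isfinite(d0) and d0 > 1.0:
            jump = 1.0 - 1.0 / d0
    return PhaseDiagnosis(
        phase="heterogeneous" if sol.exists else "homogeneous",
        lambda_up=lambda_up(s),
        jump_at_zero=jump,
        solution=sol,
    )


def order_parameter_curve(R: ResponseFunction, s: float, lam_grid) -> np.ndarray:
    """Stationary variance Var(p)_inf over a grid of response probabilities.

    The variance is beta*(R(beta) - beta) inside the heterogeneous phase and
    0 outside; it vanishes continuously as lam -> lam_up, while the low-peak
    weight (not the variance) jumps at lam -> 0.
    """
    lam_grid = np.asarray(lam_grid, dtype=float)
    if np.any(lam_grid < 0.0) or np.any(lam_grid > 1.0):
        raise ValueError("lam grid must lie within [0, 1]")
    out = np.zeros_like(lam_grid)
    for k, lam in enumerate(lam_grid.ravel()):
        sol = heterogeneous_solution(R, s, float(lam))
        out.ravel()[k] = sol.variance if sol.exists else 0.0
    return out


@dataclass(frozen=True)
class StabilityReport:
    """Numerical response of the stationary state to a small perturbation."""

    times: np.ndarray
    distances: np.ndarray
    initial_distance: float
    final_distance: float
    decayed: bool


def stability_probe(solution: StationarySolution, R: ResponseFunction,
                    s: float, lam: float, *, weight_shift: float = 0.02,
                    location_shift: float = 0.0, t_max: float = 50.0,
                    dt_max: float = meanfield.DEFAULT_DT_MAX) -> StabilityReport:
    """Perturb the two-atom stationary measure and integrate the relaxation.

    Shifts ``weight_shift`` of mass from the high- to the low-producing atom
    (sign reverses the direction) and optionally displaces the atom
    locations by ``location_shift``; the autoinducer equation is then
    integrated and the transport distance to the unperturbed solution
    recorded.  In the existence region the distance is expected to decay.
    """
    if not solution.exists:
        raise ValueError("stability_probe requires an existing heterogeneous solution")
    target = solution.to_measure()
    if abs(weight_shift) >= min(solution.y, 1.0 - solution.y):
        raise ValueError("weight_shift too large for the stationary weights")

    locs = np.clip(target.locations + location_shift, 0.0, 1.0)
    w = target.weights.copy()
    w[0] += weight_shift
    w[1] -= weight_shift
    perturbed = AtomMeasure(locs, w, normalize=True)

    traj = meanfield.integrate(perturbed, s, lam, R, t_max=t_max,
                               dt_max=dt_max, record_every=1.0)
    dists = np.array([meanfield.measure_distance(m, target) for m in traj.measures])
    return StabilityReport(times=traj.times, distances=dists,
                           initial_distance=float(dists[0]),
                           final_distance=float(dists[-1]),
                           decayed=bool(dists[-1] < dists[0]))
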