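"""Scripted, seeded experiment drivers.

Each driver reproduces one of the model's characteristic behaviours at a
configurable (by default desk-scale) size, comparing the stochastic and
mean-field layers where both apply:

``histogram_evolution``   pooled histogram movies of the three regimes
``decay_lambda0``         algebraic ~1/(s t) decay of <p> without response
``absorption_scaling``    exponential growth of the absorption time with N
``phase_diagram``         heterogeneity indicator over the (lam, kappa) plane
``variance_vs_lambda``    simulated order parameter vs the analytic curve
``initial_robustness``    common mean-field attractor across initial states
``noise_robustness``      bimodality under each noise channel
``bifurcation_timescale`` critical slowing down at a response bifurcation

Every driver is a pure function of its arguments plus a seed, so results
are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import linregress

from . import gillespie, meanfield, stationary
from .model import (
    AtomMeasure,
    InitialDistribution,
    LinearResponse,
    ModelParams,
    NoiseSettings,
    PitchforkResponse,
    SinusoidalResponse,
)

__all__ = [
    "ExperimentConfig",
    "ScalingFit",
    "run_experiment",
    "decay_lambda0",
    "histogram_evolution",
    "absorption_scaling",
    "phase_diagram",
    "variance_vs_lambda",
    "initial_robustness",
    "noise_robustness",
    "bifurcation_timescale",
    "fit_loglog_slope",
    "fit_exponential_rate",
]

EXPERIMENT_IDS = (
    "histogram_evolution", "decay_lambda0", "absorption_scaling",
    "phase_diagram", "variance_vs_lambda", "initial_robustness",
    "noise_robustness", "bifurcation_timescale",
)


@dataclass
class ExperimentConfig:
    """Declaration of a named experiment: id, seed and size overrides."""

    id: str
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.id not in EXPERIMENT_IDS:
            raise ValueError(
                f"unknown experiment id {self.id!r}; choose from {EXPERIMENT_IDS}")


def run_experiment(config: ExperimentConfig):
    """Dispatch a named experiment with its overrides applied."""
    driver = globals()[config.id]
    return driver(seed=config.seed, **config.overrides)


# ---------------------------------------------------------------------------
# fitting helpers
# ---------------------------------------------------------------------------

def fit_loglog_slope(times, values, window=(50.0, 500.0)):
    """Least-squares slope of log(value) vs log(time) inside a window."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    sel = (t >= window[0]) & (t <= window[1]) & (v > 0)
    if sel.sum() < 3:
        raise ValueError("need at least 3 positive points inside the fit window")
    res = linregress(np.log(t[sel]), np.log(v[sel]))
    return float(res.slope), float(res.stderr)


def fit_exponential_rate(times, values, floor=1e-12):
    """Decay rate (and R^2) from a log-linear fit of |values| vs time."""
    t = np.asarray(times, dtype=float)
    v = np.abs(np.asarray(values, dtype=float))
    sel = v > floor
    if sel.sum() < 3:
        raise ValueError("need at least 3 points above the floor")
    res = linregress(t[sel], np.log(v[sel]))
    return -float(res.slope), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def decay_lambda0(*, N: int = 10_000, s: float = 0.2, M: int = 10,
                  t_max: float = 500.0, window=(50.0, 500.0), seed: int = 0):
    """Algebraic approach to the non-producing state without quorum sensing.

    With lam = 0 and a quasi-continuous (uniform) initial distribution, the
    replicator dynamics drive <p>(t) ~ 1/(s t) at late times.  The slope is
    fitted on the ensemble mean of <p>(t) over M replicates — in a single
    finite-N run the late-time mean is dominated by demographic drift among
    the few surviving low-production lineages, so only the ensemble average
    exhibits the clean power law.  The exact slope of the closed-form mean
    is returned alongside.
    """
    params = ModelParams(N=N, s=s, lam=0.0, seed=seed)
    init = InitialDistribution("uniform")
    summary = gillespie.ensemble_run(params, LinearResponse(), init,
                                     t_max=t_max, M=M, record_every=2.0,
                                     keep_trajectories=False)
    sim_slope, sim_se = fit_loglog_slope(summary.times, summary.mean_of_means,
                                         window)

    ts = np.geomspace(window[0], window[1], 40)
    exact_means = np.array([meanfield.closed_form_lambda0_mean(init, s, t) for t in ts])
    exact_slope, _ = fit_loglog_slope(ts, exact_means, window)
    return {
        "summary": summary,
        "sim_slope": sim_slope,
        "sim_slope_se": sim_se,
        "exact_slope": exact_slope,
    }


def histogram_evolution(*, N: int = 2000, s: float = 0.2, lam: float = 0.05,
                        kappa: float = 0.2, M: int = 10, t_max: float = 100.0,
                        record_every: float = 5.0, seed: int = 0):
    """Ensemble-pooled histogram evolution at one parameter point."""
    params = ModelParams(N=N, s=s, lam=lam, seed=seed)
    R = SinusoidalResponse(kappa)
    init = InitialDistribution("uniform")
    summary = gillespie.ensemble_run(params, R, init, t_max=t_max, M=M,
                                     record_every=record_every)
    return {"summary": summary, "params": params}


@dataclass
class ScalingFit:
    """Exponential scaling of the absorption time with population size."""

    N_values: np.ndarray
    geometric_means: np.ndarray
    spread_low: np.ndarray   # 2.5th percentile of T_abs per N
    spread_high: np.ndarray  # 97.5th percentile
    gamma: float
    gamma_se: float
    censored_fraction: np.ndarray
    times: list = field(repr=False, default_factory=list)


def absorption_scaling(N_list: Sequence[int] = (50, 100, 200, 400), *,
                       s: float = 0.2, lam: float = 0.05, kappa: float = 0.2,
                       M: int = 50, t_cutoff: float = 1e5,
                       seed: int = 0) -> ScalingFit:
    """Absorption time T_abs vs population size N.

    For each N, M replicates run from a uniform initial distribution until
    a homogeneous absorbing state; the geometric mean of the non-censored
    T_abs is fitted as log T_abs ~ gamma * N.  In the heterogeneous phase
    the escape requires a large demographic fluctuation, so gamma > 0.
    """
    N_list = list(N_list)
    if any(b <= a for a, b in zip(N_list, N_list[1:])):
        raise ValueError("N_list must be strictly ascending")
    if len(N_list) < 3:
        raise ValueError("need at least 3 population sizes for a scaling fit")
    if M < 10:
        raise ValueError("need at least 10 replicates per size")
    R = SinusoidalResponse(kappa)
    init = InitialDistribution("uniform")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(len(N_list) * M, dtype=np.uint32) >> np.uint32(1)

    gmeans, lo, hi, cens, all_times = [], [], [], [], []
    kept_N = []
    k = 0
    for N in N_list:
        times = []
        n_cens = 0
        for _ in range(M):
            params = ModelParams(N=int(N), s=s, lam=lam, seed=int(seeds[k]))
            k += 1
            res = gillespie.absorption_time(params, R, init, t_cutoff=t_cutoff)
            if res.reached:
                times.append(res.t_abs)
            else:
                n_cens += 1
        cens.append(n_cens / M)
        all_times.append(times)
        if not times:
            continue  # all-censored level: excluded from the fit
        kept_N.append(N)
        t = np.asarray(times)
        gmeans.append(float(np.exp(np.mean(np.log(np.maximum(t, 1e-12))))))
        lo.append(float(np.percentile(t, 2.5)))
        hi.append(float(np.percentile(t, 97.5)))
    if len(kept_N) < 3:
        raise ValueError("fewer than 3 non-censored population sizes; cannot fit")
    res = linregress(np.asarray(kept_N, float), np.log(gmeans))
    return ScalingFit(N_values=np.asarray(kept_N), geometric_means=np.asarray(gmeans),
                      spread_low=np.asarray(lo), spread_high=np.asarray(hi),
                      gamma=float(res.slope), gamma_se=float(res.stderr),
                      censored_fraction=np.asarray(cens), times=all_times)


def phase_diagram(lam_grid=None, kappa_grid=None, *, s: float = 0.2,
                  N: int = 1000, M: int = 3, t_max: float = 100.0,
                  seed: int = 0):
    """Heterogeneity indicator over the response-probability x kappa plane.

    For each (lam, kappa) cell, the time-averaged quasi-stationary variance
    (over the second half of the run, averaged over M replicates) indicates
    heterogeneity; the analytic boundary is lam_up = s/2.
    """
    lam_grid = np.asarray([0.01, 0.03, 0.05, 0.08, 0.12, 0.15]
                          if lam_grid is None else lam_grid, float)
    kappa_grid = np.asarray([0.0, 0.1, 0.2, 0.3]
                            if kappa_grid is None else kappa_grid, float)
    init = InitialDistribution("uniform")
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(lam_grid.size * kappa_grid.size * M,
                                   dtype=np.uint32) >> np.uint32(1))
    indicator = np.zeros((lam_grid.size, kappa_grid.size))
    analytic = np.zeros_like(indicator)
    for i, lam in enumerate(lam_grid):
        for j, kappa in enumerate(kappa_grid):
            R = SinusoidalResponse(kappa)
            vals = []
            for _ in range(M):
                params = ModelParams(N=N, s=s, lam=float(lam), seed=int(next(seeds)))
                traj = gillespie.run(params, R, init, t_max=t_max, record_every=2.0)
                sel = traj.times >= t_max / 2
                vals.append(float(traj.variances[sel].mean()))
            indicator[i, j] = float(np.mean(vals))
            analytic[i, j] = stationary.order_parameter_curve(R, s, [lam])[0]
    return {
        "lam_grid": lam_grid,
        "kappa_grid": kappa_grid,
        "indicator": indicator,
        "analytic_variance": analytic,
        "lambda_up": stationary.lambda_up(s),
    }


def variance_vs_lambda(lam_grid=None, *, s: float = 0.2, kappa: float = 0.2,
                       N: int = 2000, t_max: float = 100.0, seed: int = 0):
    """Quasi-stationary variance vs lam against the analytic order parameter."""
    lam_grid = np.asarray(np.linspace(0.01, 0.15, 8)
                          if lam_grid is None else lam_grid, float)
    R = SinusoidalResponse(kappa)
    init = InitialDistribution("uniform")
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(lam_grid.size, dtype=np.uint32) >> np.uint32(1)
    sim_var = np.zeros(lam_grid.size)
    for i, lam in enumerate(lam_grid):
        params = ModelParams(N=N, s=s, lam=float(lam), seed=int(seeds[i]))
        traj = gillespie.run(params, R, init, t_max=t_max, record_every=2.0)
        sel = traj.times >= t_max / 2
        sim_var[i] = float(traj.variances[sel].mean())
    analytic = stationary.order_parameter_curve(R, s, lam_grid)
    return {"lam_grid": lam_grid, "sim_variance": sim_var,
            "analytic_variance": analytic}


def initial_robustness(init_list: Optional[Sequence[InitialDistribution]] = None, *,
                       s: float = 0.2, lam: float = 0.05, kappa: float = 0.2,
                       t_max: float = 1600.0, seed: int = 0):
    """Convergence of the mean-field dynamics to a common attractor.

    Integrates the autoinducer equation from several initial distributions
    (each with mass at 0 and above beta) and reports the transport distance
    of every final measure to the closed-form bimodal stationary state.
    """
    R = SinusoidalResponse(kappa)
    if init_list is None:
        init_list = [
            InitialDistribution("uniform"),
            InitialDistribution("atoms", atoms={0.0: 0.5, 1.0: 0.5}),
            InitialDistribution("truncated_gaussian", mu=0.4, sigma=0.35),
        ]
    if len(init_list) < 1:
        raise ValueError("need at least one initial distribution")
    sol = stationary.heterogeneous_solution(R, s, lam)
    target = sol.to_measure() if sol.exists else None
    finals, dists = [], []
    for init in init_list:
        traj = meanfield.integrate(init, s, lam, R, t_max=t_max, record_every=5.0)
        m = traj.final_measure()
        finals.append(m)
        if target is not None:
            dists.append(meanfield.measure_distance(m, target))
    pairwise = np.array([[meanfield.measure_distance(a, b) for b in finals]
                         for a in finals])
    return {"final_measures": finals, "distances_to_solution": np.asarray(dists),
            "pairwise_distances": pairwise, "solution": sol}


def noise_robustness(sigma_values: Sequence[float] = (0.0, 0.01, 0.03), *,
                     s: float = 0.2, lam: float = 0.05, kappa: float = 0.2,
                     N: int = 2000, t_max: float = 100.0, seed: int = 0):
    """Persistence of bimodality under each noise channel separately.

    For each channel (inheritance, perception, response) and each sigma,
    runs the stochastic process and evaluates the two-subpopulation
    diagnostic on every record in the quasi-stationary window
    [t_max/2, t_max], reporting the bimodal fraction and the median mode
    locations of the low- and high-producing groups.
    """
    R = SinusoidalResponse(kappa)
    init = InitialDistribution("uniform")
    channels = ("sigma_inherit", "sigma_perceive", "sigma_respond")
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(len(channels) * len(sigma_values),
                                   dtype=np.uint32) >> np.uint32(1))
    out = {}
    for channel in channels:
        rows = []
        for sigma in sigma_values:
            if sigma < 0:
                raise ValueError("sigma must be >= 0")
            noise = NoiseSettings(**{channel: float(sigma)})
            params = ModelParams(N=N, s=s, lam=lam, noise=noise,
                                 seed=int(next(seeds)))
            traj = gillespie.run(params, R, init, t_max=t_max, record_every=5.0)
            window = np.nonzero(traj.times >= t_max / 2)[0]
            reports = [gillespie.bimodality(traj.snapshots[k]) for k in window]
            rows.append({
                "sigma": float(sigma),
                "bimodal_fraction": float(np.mean([r.is_bimodal for r in reports])),
                "low_mode": float(np.median([r.low_mode for r in reports])),
                "high_mode": float(np.median([r.high_mode for r in reports])),
                "variance": float(np.mean(traj.variances[window])),
            })
        out[channel] = rows
    return out


def bifurcation_timescale(a_values: Sequence[float] = (-0.4, -0.2, -0.1, -0.04), *,
                          s: float = 0.2, lam: float = 0.5, b: float = 1.0,
                          p0: float = 0.65, t_max: float = 60.0, seed: int = 0):
    """Critical slowing down near a pitchfork bifurcation of the response.

    Uses the cubic-perturbed identity response family (a generic pitchfork
    stand-in) at lam = 1/2, where the mean obeys
    dpbar/dt = phibar * (R(pbar) - pbar) and relaxes to the midpoint fixed
    point at rate ~ phibar * |a|.  Fits the exponential relaxation rate of
    pbar for each bifurcation parameter ``a < 0``; the rate decreases
    toward 0 as a -> 0.
    """
    rows = []
    for a in a_values:
        if a >= 0:
            raise ValueError("driver probes the monostable side: a must be < 0")
        R = PitchforkResponse(a, b)
        init = AtomMeasure.delta(p0)
        traj = meanfield.integrate(init, s, lam, R, t_max=t_max,
                                   record_every=0.5)
        dev = np.abs(traj.means - 0.5)
        sel = dev > 1e-9
        rate, r2 = fit_exponential_rate(traj.times[sel], dev[sel])
        rows.append({"a": float(a), "rate": rate, "r_squared": r2})
    return rows
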