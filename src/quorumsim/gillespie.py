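"""Exact stochastic simulation of the quorum-sensing birth-death process.

Continuous-time Moran-type dynamics: individual ``i`` reproduces at rate
``phi(p_i) = 1 - s p_i``; its offspring replaces a uniformly chosen other
individual, and both offspring independently either adopt ``R(<p>)`` with
probability ``lam`` (sense-and-response through quorum sensing) or inherit
the ancestor's degree.  Time is measured in units where a population of
pure non-producers experiences one reproduction per individual per unit on
average.

The fast path is a compiled kernel (:mod:`quorumsim._kernels`); a
pure-Python single-event step with provenance tracking is provided for
small-scale oracles and direct inspection of the update rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from . import _kernels
from .model import (
    AtomMeasure,
    InitialDistribution,
    ModelParams,
    PopulationState,
    ResponseFunction,
    sample_initial,
)

__all__ = [
    "Trajectory",
    "AbsorptionResult",
    "EnsembleSummary",
    "Observables",
    "gillespie_step",
    "run",
    "detect_absorbing",
    "absorption_time",
    "observables",
    "cluster_split",
    "ensemble_run",
]

#: default histogram bin count over [0, 1]
DEFAULT_BINS = 50
#: default gap (in production-degree units) separating subpopulations
DEFAULT_GAP = 0.05
#: clusters holding less than this fraction of individuals are ignored
MIN_CLUSTER_FRAC = 0.01
#: default absorption cutoff (model time)
DEFAULT_T_CUTOFF = 1e4


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

class Observables(NamedTuple):
    mean: float
    variance: float
    histogram: np.ndarray
    cluster_count: int


def cluster_split(degrees: np.ndarray, gap: float = DEFAULT_GAP,
                  min_frac: float = MIN_CLUSTER_FRAC):
    """Split sorted degrees into gap-separated subpopulations.

    Returns a list of (center, fraction) pairs for every group whose
    consecutive sorted values differ by at most ``gap`` internally and that
    holds at least ``min_frac`` of the population.
    """
    x = np.sort(np.asarray(degrees, dtype=float))
    n = x.size
    breaks = np.nonzero(np.diff(x) > gap)[0]
    bounds = np.concatenate([[0], breaks + 1, [n]])
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        frac = (b - a) / n
        if frac >= min_frac and b > a:
            out.append((float(x[a:b].mean()), float(frac)))
    return out


class BimodalityReport(NamedTuple):
    is_bimodal: bool
    threshold: float
    low_mode: float       # histogram peak location of the low group
    low_mean: float
    low_fraction: float
    high_mode: float
    high_mean: float
    high_fraction: float


def bimodality(degrees, bins: int = 25) -> BimodalityReport:
    """Two-subpopulation diagnostic robust to noise-broadened peaks.

    Splits the sample at the threshold maximizing the between-class variance
    (Otsu's criterion on the degree histogram).  The state counts as bimodal
    when both groups hold at least 5% of the population and the histogram
    density around the threshold is below half the smaller of the two peak
    densities — a genuine valley, even when noise fills the gap between the
    subpopulations with stragglers.
    """
    x = np.asarray(degrees, dtype=float)
    hist, edges = np.histogram(x, bins=bins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = hist.sum()
    best, thr, k_best = -1.0, None, None
    csum = np.cumsum(hist)
    cmean = np.cumsum(hist * centers)
    for k in range(1, bins):
        n0, n1 = csum[k - 1], total - csum[k - 1]
        if n0 == 0 or n1 == 0:
            continue
        m0 = cmean[k - 1] / n0
        m1 = (cmean[-1] - cmean[k - 1]) / n1
        score = n0 * n1 * (m0 - m1) ** 2
        if score > best:
            best, thr, k_best = score, float(edges[k]), k
    if thr is None:
        m = float(x.mean())
        return BimodalityReport(False, m, m, m, 1.0, m, m, 0.0)
    low = x[x < thr]
    high = x[x >= thr]
    f_low = low.size / x.size
    f_high = high.size / x.size
    lo_mode = float(centers[:k_best][np.argmax(hist[:k_best])])
    hi_mode = float(centers[k_best:][np.argmax(hist[k_best:])])
    lo_mean = float(low.mean()) if low.size else float("nan")
    hi_mean = float(high.mean()) if high.size else float("nan")
    if min(f_low, f_high) < 0.05:
        return BimodalityReport(False, thr, lo_mode, lo_mean, f_low,
                                hi_mode, hi_mean, f_high)
    # the valley is the shallowest bin between the two mode bins
    lo_idx = int(np.argmax(hist[:k_best]))
    hi_idx = k_best + int(np.argmax(hist[k_best:]))
    valley = hist[lo_idx:hi_idx + 1].min()
    is_bim = bool(valley < 0.5 * min(hist[lo_idx], hist[hi_idx]))
    return BimodalityReport(is_bim, thr, lo_mode, lo_mean, f_low,
                            hi_mode, hi_mean, f_high)


def observables(state, B: int = DEFAULT_BINS, gap: float = DEFAULT_GAP) -> Observables:
    """Mean, population variance, histogram and cluster count of a state.

    The cluster count is the number of gap-separated groups (sorted degrees
    split wherever consecutive values differ by more than ``gap``), counting
    only groups holding at least 1% of the individuals.
    """
    if B < 2:
        raise ValueError("bin count B must be >= 2")
    if not (0.0 < gap < 1.0):
        raise ValueError("cluster gap must lie in (0, 1)")
    degrees = state.degrees if isinstance(state, PopulationState) else np.asarray(state, float)
    hist, _ = np.histogram(degrees, bins=B, range=(0.0, 1.0))
    clusters = cluster_split(degrees, gap)
    return Observables(
        mean=float(degrees.mean()),
        variance=float(degrees.var()),
        histogram=hist,
        cluster_count=len(clusters),
    )


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-indexed observables of a single stochastic run.

    ``snapshots[k]`` holds the full degree vector at ``times[k]``; the
    scalar observables and histograms are derived from it.  Histogram counts
    sum to N at every record.
    """

    times: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    histograms: np.ndarray
    cluster_counts: np.ndarray
    snapshots: np.ndarray
    bins: int = DEFAULT_BINS
    gap: float = DEFAULT_GAP
    seed: Optional[int] = None

    @property
    def N(self) -> int:
        return self.snapshots.shape[1]

    def final_state(self) -> PopulationState:
        return PopulationState(self.snapshots[-1].copy(), time=float(self.times[-1]))

    def empirical_measure(self, k: int = -1) -> AtomMeasure:
        """Empirical production distribution at record index k."""
        return AtomMeasure.from_samples(self.snapshots[k])


@dataclass
class AbsorptionResult:
    """Outcome of a run-to-absorption experiment.

    ``reached`` is False when the cutoff time was hit first (censored run);
    ``final_degree`` is the common production degree p* at absorption.
    """

    t_abs: float
    final_degree: Optional[float]
    reached: bool


@dataclass
class EnsembleSummary:
    """Pooled statistics of M independent replicate runs."""

    M: int
    seeds: list[int]
    times: np.ndarray
    mean_of_means: np.ndarray
    mean_of_variances: np.ndarray
    pooled_histograms: np.ndarray  # averaged over replicates, per record
    trajectories: Optional[list[Trajectory]] = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# single event (pure-Python mirror of the kernel)
# ---------------------------------------------------------------------------

def gillespie_step(state: PopulationState, params: ModelParams,
                   R: ResponseFunction, rng: np.random.Generator,
                   *, death_any: bool = False, sense_post: bool = False,
                   track=None):
    """Advance the population by exactly one birth-death event.

    Draws the exponential waiting time at total rate ``sum_k phi(p_k)``,
    picks the reproducing individual i with probability ``phi(p_i)/sum phi``,
    a death slot j uniformly among the other N-1 individuals, computes the
    sensed cue ``<p>`` from the pre-division state, and lets both offspring
    (slots i and j) independently adopt ``R(<p>)`` with probability ``lam``
    or the ancestor's degree otherwise.  Noise channels, if configured,
    perturb inheritance, perception and response (clipped to [0, 1]).

    Returns ``(new_state, waiting_time)``.  If ``track`` is a list, every
    response value ``R(cue)`` assigned during the event is appended to it
    (used for provenance checks).
    """
    degrees = state.degrees.copy()
    N = degrees.size
    s, lam, noise = params.s, params.lam, params.noise

    phi = 1.0 - s * degrees
    total = phi.sum()
    wait = rng.exponential(1.0 / total)

    # fitness-proportional parent by rejection (phi <= 1)
    while True:
        i = int(rng.integers(N))
        if rng.random() < phi[i]:
            break
    if death_any:
        j = int(rng.integers(N))
    else:
        j = int(rng.integers(N - 1))
        if j >= i:
            j += 1

    anc = degrees[i]
    if sense_post and j != i:
        sensed = (degrees.sum() - degrees[j] + anc) / N
    else:
        sensed = degrees.mean()

    for slot in (i, j):
        if rng.random() < lam:
            cue = sensed
            if noise.sigma_perceive > 0:
                cue = float(np.clip(cue + noise.sigma_perceive * rng.normal(), 0.0, 1.0))
            newp = float(R(cue))
            if noise.sigma_respond > 0:
                newp = float(np.clip(newp + noise.sigma_respond * rng.normal(), 0.0, 1.0))
            if track is not None:
                track.append(newp)
        else:
            newp = anc
            if noise.sigma_inherit > 0:
                newp = float(np.clip(newp + noise.sigma_inherit * rng.normal(), 0.0, 1.0))
        degrees[slot] = newp

    return PopulationState(degrees, time=state.time + wait), wait


# ---------------------------------------------------------------------------
# full runs (compiled kernel)
# ---------------------------------------------------------------------------

def detect_absorbing(state: PopulationState, R: ResponseFunction, lam: float) -> bool:
    """True iff the state is absorbing for the noise-free dynamics.

    All degrees must be exactly equal; with quorum sensing (lam > 0) the
    common degree must additionally be a fixed point of R (|R(p*) - p*| <=
    1e-12).  Exact float equality is meaningful because the noise-free
    dynamics only ever copy existing values or assign R(<p>).
    """
    degrees = state.degrees
    p0 = degrees[0]
    if not np.all(degrees == p0):
        return False
    if lam == 0.0:
        return True
    return abs(float(R(p0)) - p0) <= 1e-12


def _derive_seeds(master: int, n: int) -> list[int]:
    """Derive n independent 31-bit kernel seeds from a master seed."""
    ss = np.random.SeedSequence(master)
    return [int(x) for x in ss.generate_state(n, dtype=np.uint32) >> np.uint32(1)]


def _kernel_args(params: ModelParams, R: ResponseFunction):
    kind, ra, rb, rxs, rys = R._kernel_spec()
    noise = params.noise
    return (kind, ra, rb, rxs, rys,
            noise.sigma_inherit, noise.sigma_perceive, noise.sigma_respond)


def _initial_state(init, N: int, seed: int) -> PopulationState:
    """Resolve an initial condition: a concrete state or an i.i.d. sample."""
    if isinstance(init, PopulationState):
        if init.N != N:
            raise ValueError(f"initial state has {init.N} individuals, expected N={N}")
        return init.copy()
    return sample_initial(init, N, seed)


def run(params: ModelParams, R: ResponseFunction, init: InitialDistribution,
        t_max: float, record_every: float = 1.0, *,
        bins: int = DEFAULT_BINS, gap: float = DEFAULT_GAP,
        death_any: bool = False, sense_post: bool = False,
        seed: Optional[int] = None) -> Trajectory:
    """Simulate a full trajectory, recording observables on a fixed schedule.

    The initial population is sampled i.i.d. from ``init``; all randomness
    derives from ``params.seed`` (or the ``seed`` override), so runs are
    bit-reproducible.
    """
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    if record_every <= 0:
        raise ValueError("record_every must be > 0")
    master = params.seed if seed is None else seed
    init_seed, kernel_seed = _derive_seeds(master, 2)

    state = _initial_state(init, params.N, init_seed)
    record_times = np.arange(0.0, t_max + 0.5 * record_every, record_every)
    record_times = record_times[record_times <= t_max]

    snaps, n_rec, _, _, _ = _kernels.simulate(
        state.degrees, params.s, params.lam, *_kernel_args(params, R),
        kernel_seed, t_max, record_times,
        False, death_any, sense_post, max(1, params.N))
    snaps = snaps[:n_rec]
    times = record_times[:n_rec]

    means = snaps.mean(axis=1)
    variances = snaps.var(axis=1)
    histograms = np.empty((n_rec, bins), dtype=np.int64)
    cluster_counts = np.empty(n_rec, dtype=np.int64)
    for k in range(n_rec):
        obs = observables(snaps[k], bins, gap)
        histograms[k] = obs.histogram
        cluster_counts[k] = obs.cluster_count

    return Trajectory(times=times, means=means, variances=variances,
                      histograms=histograms, cluster_counts=cluster_counts,
                      snapshots=snaps, bins=bins, gap=gap, seed=master)


def absorption_time(params: ModelParams, R: ResponseFunction,
                    init: InitialDistribution, t_cutoff: float = DEFAULT_T_CUTOFF,
                    *, death_any: bool = False, sense_post: bool = False,
                    seed: Optional[int] = None) -> AbsorptionResult:
    """Run until a homogeneous absorbing state is reached or ``t_cutoff``.

    Runs hitting the cutoff are reported censored (``reached=False``), never
    silently dropped.  For N <= 512 the absorbing condition is checked after
    every event; for larger populations every 64 events (amortized cost).
    """
    if t_cutoff <= 0:
        raise ValueError("t_cutoff must be > 0")
    master = params.seed if seed is None else seed
    init_seed, kernel_seed = _derive_seeds(master, 2)
    state = _initial_state(init, params.N, init_seed)

    if detect_absorbing(state, R, params.lam):
        return AbsorptionResult(t_abs=0.0, final_degree=float(state.degrees[0]),
                                reached=True)

    check_every = 1 if params.N <= 512 else 64
    empty = np.empty(0, dtype=float)
    _, _, absorbed, t_abs, t_final = _kernels.simulate(
        state.degrees, params.s, params.lam, *_kernel_args(params, R),
        kernel_seed, t_cutoff, empty,
        True, death_any, sense_post, check_every)

    if absorbed:
        return AbsorptionResult(t_abs=float(t_abs),
                                final_degree=float(state.degrees[0]), reached=True)
    return AbsorptionResult(t_abs=float(t_final), final_degree=None, reached=False)


def ensemble_run(params: ModelParams, R: ResponseFunction,
                 init: InitialDistribution, t_max: float, M: int,
                 record_every: float = 1.0, *, bins: int = DEFAULT_BINS,
                 gap: float = DEFAULT_GAP, keep_trajectories: bool = True,
                 seed: Optional[int] = None) -> EnsembleSummary:
    """Run M independent replicates and pool their statistics.

    Replicate seeds are derived from the master seed and logged in the
    summary; pooled histograms are averaged over replicates per record time.
    """
    if M < 1:
        raise ValueError("replicate count M must be >= 1")
    master = params.seed if seed is None else seed
    rep_seeds = _derive_seeds(master, M)

    trajs = []
    for m in range(M):
        trajs.append(run(params, R, init, t_max, record_every,
                         bins=bins, gap=gap, seed=rep_seeds[m]))
    times = trajs[0].times
    mean_of_means = np.mean([t.means for t in trajs], axis=0)
    mean_of_variances = np.mean([t.variances for t in trajs], axis=0)
    pooled_histograms = np.mean([t.histograms for t in trajs], axis=0)
    return EnsembleSummary(M=M, seeds=rep_seeds, times=times,
                           mean_of_means=mean_of_means,
                           mean_of_variances=mean_of_variances,
                           pooled_histograms=pooled_histograms,
                           trajectories=trajs if keep_trajectories else None)
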