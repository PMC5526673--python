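"""Tests of the stochastic birth-death simulator against exact small-scale
oracles and large-N limits."""

import math

import numpy as np
import pytest
from scipy import stats

import quorumsim as q
from quorumsim.gillespie import bimodality, cluster_split, observables


# ---------------------------------------------------------------------------
# single events
# ---------------------------------------------------------------------------

def test_step_preserves_uniform_state_without_response(rng):
    """With lam=0, copying can never change a homogeneous population."""
    params = q.ModelParams(N=20, s=0.2, lam=0.0)
    state = q.PopulationState(np.full(20, 0.3))
    for _ in range(30):
        state, _ = q.gillespie_step(state, params, q.LinearResponse(), rng)
        assert np.all(state.degrees == 0.3)


def test_step_fixed_point_state_is_frozen(sinusoidal, rng):
    """At a fixed point of R, response and inheritance both reproduce p*."""
    params = q.ModelParams(N=20, s=0.2, lam=1.0)
    state = q.PopulationState(np.ones(20))  # R(1) = 1
    for _ in range(30):
        state, _ = q.gillespie_step(state, params, sinusoidal, rng)
        assert np.all(state.degrees == 1.0)


def test_step_population_size_and_range(sinusoidal, rng):
    params = q.ModelParams(
        N=30, s=0.2, lam=0.3,
        noise=q.NoiseSettings(sigma_inherit=0.05, sigma_perceive=0.05,
                              sigma_respond=0.05))
    state = q.sample_initial(q.InitialDistribution("uniform"), 30, seed=0)
    for _ in range(200):
        state, wait = q.gillespie_step(state, params, sinusoidal, rng)
        assert wait > 0
        assert state.N == 30
        assert np.all((state.degrees >= 0) & (state.degrees <= 1))


def test_two_individual_first_step_analysis(rng):
    """N=2, degrees (0,1), lam=0: the first event fixes the population.

    The survivor is the non-producer with probability phi(0)/(phi(0)+phi(1))
    = 1/(2-s), and the waiting time is Exp(2-s).
    """
    params = q.ModelParams(N=2, s=0.2, lam=0.0)
    R = q.LinearResponse()
    n = 4000
    nonproducer_wins = 0
    waits = np.empty(n)
    for k in range(n):
        state = q.PopulationState(np.array([0.0, 1.0]))
        new, wait = q.gillespie_step(state, params, R, rng)
        assert new.degrees[0] == new.degrees[1]
        nonproducer_wins += new.degrees[0] == 0.0
        waits[k] = wait
    p_expected = 1 / 1.8
    se = math.sqrt(p_expected * (1 - p_expected) / n)
    assert abs(nonproducer_wins / n - p_expected) < 3 * se
    assert abs(waits.mean() - 1 / 1.8) < 3 * waits.std() / math.sqrt(n)


def test_degree_provenance(sinusoidal, rng):
    """Every degree is an initial value or some R(<p>) assigned en route."""
    params = q.ModelParams(N=25, s=0.2, lam=0.4)
    state = q.sample_initial(q.InitialDistribution("uniform"), 25, seed=3)
    allowed = set(state.degrees.tolist())
    track: list = []
    for _ in range(300):
        state, _ = q.gillespie_step(state, params, sinusoidal, rng, track=track)
    allowed |= set(track)
    assert set(state.degrees.tolist()) <= allowed


# ---------------------------------------------------------------------------
# absorbing states
# ---------------------------------------------------------------------------

def test_detect_absorbing(sinusoidal):
    lam = 0.05
    assert q.detect_absorbing(q.PopulationState(np.zeros(10)), sinusoidal, lam)
    assert not q.detect_absorbing(q.PopulationState(np.full(10, 0.3)), sinusoidal, lam)
    # without sense-and-response any homogeneous state is absorbing
    assert q.detect_absorbing(q.PopulationState(np.full(10, 0.3)), sinusoidal, 0.0)
    assert not q.detect_absorbing(
        q.PopulationState(np.array([0.0, 0.0, 0.1])), sinusoidal, lam)


def test_absorption_time_already_absorbed():
    params = q.ModelParams(N=10, s=0.2, lam=0.0, seed=0)
    init = q.InitialDistribution("atoms", atoms={0.3: 1.0})
    res = q.absorption_time(params, q.LinearResponse(), init)
    assert res.reached and res.t_abs == 0.0 and res.final_degree == 0.3


def test_absorption_two_individuals_exact_law():
    """N=2 absorption times follow Exp(2-s): mean 1/(2-s), KS at alpha=0.01."""
    R = q.LinearResponse()
    state0 = q.PopulationState(np.array([0.0, 1.0]))
    seeds = np.random.SeedSequence(7).generate_state(10_000, dtype=np.uint32) >> np.uint32(1)
    ts = np.empty(seeds.size)
    for k, sd in enumerate(seeds):
        params = q.ModelParams(N=2, s=0.2, lam=0.0, seed=int(sd))
        ts[k] = q.absorption_time(params, R, state0).t_abs
    rate = 2 - 0.2
    assert abs(ts.mean() - 1 / rate) < 3 * ts.std() / math.sqrt(ts.size)
    assert stats.kstest(ts, stats.expon(scale=1 / rate).cdf).pvalue > 0.01


def test_absorption_ends_at_response_fixed_point(sinusoidal):
    params = q.ModelParams(N=50, s=0.2, lam=0.05, seed=5)
    res = q.absorption_time(params, sinusoidal, q.InitialDistribution("uniform"),
                            t_cutoff=1e5)
    assert res.reached
    assert res.final_degree in (0.0, 1.0)  # the fixed points of R


def test_absorption_censoring_reported(sinusoidal):
    params = q.ModelParams(N=200, s=0.2, lam=0.05, seed=1)
    res = q.absorption_time(params, sinusoidal, q.InitialDistribution("uniform"),
                            t_cutoff=1.0)
    assert not res.reached
    assert res.final_degree is None
    assert res.t_abs == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def test_observables_homogeneous():
    obs = observables(np.full(100, 0.4), B=50, gap=0.05)
    assert obs.mean == pytest.approx(0.4)
    assert obs.variance == pytest.approx(0.0, abs=1e-15)
    assert (obs.histogram > 0).sum() == 1
    assert obs.cluster_count == 1


def test_observables_two_point():
    degrees = np.concatenate([np.zeros(50), np.full(50, 0.7)])
    obs = observables(degrees, B=50, gap=0.05)
    assert obs.mean == pytest.approx(0.35)
    assert obs.variance == pytest.approx(0.1225)
    assert (obs.histogram > 0).sum() == 2
    assert obs.cluster_count == 2


def test_observables_stationary_mixture(het_solution):
    """The y=2/7 mixture at (0, 0.7) has the closed-form moments (0.5, 0.1)."""
    degrees = np.concatenate([np.zeros(2000), np.full(5000, 0.7)])
    obs = observables(degrees)
    assert obs.mean == pytest.approx(het_solution.mean, abs=1e-12)
    assert obs.variance == pytest.approx(het_solution.variance, abs=1e-12)


def test_observables_validation():
    with pytest.raises(ValueError):
        observables(np.zeros(10), B=1)
    with pytest.raises(ValueError):
        observables(np.zeros(10), gap=1.5)


def test_cluster_split_ignores_stragglers():
    degrees = np.concatenate([np.zeros(500), np.full(2, 0.4), np.full(500, 0.8)])
    clusters = cluster_split(degrees, gap=0.05)
    assert len(clusters) == 2  # the 0.2% clump is below the 1% mass floor


def test_bimodality_diagnostic():
    rng = np.random.default_rng(0)
    low = rng.normal(0.05, 0.02, 600)
    high = rng.normal(0.7, 0.03, 1400)
    rep = bimodality(np.clip(np.concatenate([low, high]), 0, 1))
    assert rep.is_bimodal
    assert abs(rep.low_mode - 0.05) < 0.05
    assert abs(rep.high_mode - 0.7) < 0.05
    uni = bimodality(rng.normal(0.5, 0.05, 2000).clip(0, 1))
    assert not uni.is_bimodal


# ---------------------------------------------------------------------------
# full trajectories
# ---------------------------------------------------------------------------

def test_run_is_deterministic(sinusoidal, uniform_init):
    params = q.ModelParams(N=300, s=0.2, lam=0.05, seed=9)
    a = q.run(params, sinusoidal, uniform_init, t_max=5.0)
    b = q.run(params, sinusoidal, uniform_init, t_max=5.0)
    assert np.array_equal(a.snapshots, b.snapshots)
    assert np.array_equal(a.times, b.times)


def test_run_invariants(sinusoidal, uniform_init):
    params = q.ModelParams(
        N=200, s=0.2, lam=0.1, seed=2,
        noise=q.NoiseSettings(sigma_inherit=0.02, sigma_perceive=0.02,
                              sigma_respond=0.02))
    traj = q.run(params, sinusoidal, uniform_init, t_max=10.0)
    assert np.all(np.diff(traj.times) > 0)
    assert np.all(traj.histograms.sum(axis=1) == 200)
    assert np.all((traj.snapshots >= 0) & (traj.snapshots <= 1))
    with pytest.raises(ValueError):
        q.run(params, sinusoidal, uniform_init, t_max=-1.0)


def test_two_type_decay_matches_replicator(two_type_init):
    """lam=0 producer fraction follows dx/dt = -s x(1-x) at large N."""
    R = q.LinearResponse()
    finals = []
    for seed in (0, 1, 2, 3):
        params = q.ModelParams(N=10_000, s=0.2, lam=0.0, seed=seed)
        traj = q.run(params, R, two_type_init, t_max=10.0)
        finals.append(float(np.mean(traj.snapshots[-1] == 1.0)))
    x_exact = math.exp(-2.0) / (1 + math.exp(-2.0))  # logistic solution, x0=1/2
    finals = np.asarray(finals)
    se = finals.std(ddof=1) / math.sqrt(finals.size)
    assert abs(finals.mean() - x_exact) < 3 * se + 1e-3


def test_quasi_stationary_bimodal_state(sinusoidal, uniform_init):
    """At s=0.2, lam=0.05, N=1e4 the population splits in two and the
    time-averaged variance tracks the mean-field value beta(R(beta)-beta)=0.1."""
    params = q.ModelParams(N=10_000, s=0.2, lam=0.05, seed=0)
    traj = q.run(params, sinusoidal, uniform_init, t_max=100.0, record_every=2.0)
    window = traj.times >= 50.0
    avg_var = traj.variances[window].mean()
    assert avg_var > 0
    assert abs(avg_var - 0.1) < 0.02  # within 20% of the mean-field value
    clusters = cluster_split(traj.snapshots[-1])
    assert len(clusters) >= 2
    centers = [c for c, _ in clusters]
    assert min(centers) < 0.15 and abs(max(centers) - 0.7) < 0.15


def test_homogeneous_trend_above_threshold(sinusoidal, uniform_init):
    """lam=0.2 > s/2: the population homogenizes (single cluster)."""
    params = q.ModelParams(N=2000, s=0.2, lam=0.2, seed=0)
    traj = q.run(params, sinusoidal, uniform_init, t_max=100.0, record_every=5.0)
    assert traj.cluster_counts[-1] == 1
    assert traj.variances[-1] < 0.01


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def test_ensemble_single_replicate_matches_run(sinusoidal, uniform_init):
    params = q.ModelParams(N=200, s=0.2, lam=0.05, seed=4)
    summary = q.ensemble_run(params, sinusoidal, uniform_init, t_max=5.0, M=1)
    traj = summary.trajectories[0]
    assert np.array_equal(summary.mean_of_means, traj.means)
    assert np.array_equal(summary.pooled_histograms, traj.histograms)


def test_ensemble_reproducible_and_distinct_seeds(sinusoidal, uniform_init):
    params = q.ModelParams(N=100, s=0.2, lam=0.05, seed=4)
    a = q.ensemble_run(params, sinusoidal, uniform_init, t_max=3.0, M=4)
    b = q.ensemble_run(params, sinusoidal, uniform_init, t_max=3.0, M=4)
    assert a.seeds == b.seeds
    assert len(set(a.seeds)) == 4
    assert np.array_equal(a.pooled_histograms, b.pooled_histograms)


def test_ensemble_lambda0_algebraic_decay(uniform_init):
    """Pooled <p>(t) decays with late-time log-log slope near -1."""
    params = q.ModelParams(N=2000, s=0.2, lam=0.0, seed=6)
    summary = q.ensemble_run(params, q.LinearResponse(), uniform_init,
                             t_max=300.0, M=5, record_every=5.0,
                             keep_trajectories=False)
    from quorumsim.experiments import fit_loglog_slope
    slope, _ = fit_loglog_slope(summary.times, summary.mean_of_means,
                                window=(50.0, 300.0))
    assert -1.2 < slope < -0.8
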