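"""Tests of the autoinducer-equation integrator against its closed forms."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import quorumsim as q
from quorumsim.meanfield import (
    IntegrationError,
    autoinducer_rhs,
    closed_form_lambda0,
    closed_form_lambda0_mean,
    closed_form_linear_half,
    integrate,
    measure_distance,
)


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def test_rhs_single_atom_stationary_without_response():
    m = q.AtomMeasure.delta(0.3)
    dw, _, rate = autoinducer_rhs(m, s=0.2, lam=0.0, R=q.LinearResponse())
    assert dw == pytest.approx([0.0], abs=1e-15)
    assert rate == 0.0


def test_rhs_two_atom_replicator():
    """Atoms {0: 1/2, 1: 1/2} at s=0.2: dw(0)/dt=+0.05, dw(1)/dt=-0.05."""
    m = q.AtomMeasure([0.0, 1.0], [0.5, 0.5])
    dw, _, rate = autoinducer_rhs(m, s=0.2, lam=0.0, R=q.LinearResponse())
    assert dw[0] == pytest.approx(0.05, abs=1e-15)
    assert dw[1] == pytest.approx(-0.05, abs=1e-15)
    assert rate == 0.0


def test_rhs_injection_at_fixed_point_balances(sinusoidal):
    """A single atom at p* = R(p*) receives exactly what it loses."""
    m = q.AtomMeasure.delta(1.0)
    dw, loc, rate = autoinducer_rhs(m, s=0.2, lam=0.3, R=sinusoidal)
    assert loc == pytest.approx(1.0, abs=1e-12)
    assert dw.sum() + rate == pytest.approx(0.0, abs=1e-14)
    assert dw[0] == pytest.approx(-rate, abs=1e-14)


@pytest.mark.parametrize("lam", [0.0, 0.05, 0.3, 0.5, 1.0])
def test_rhs_conserves_mass(lam, sinusoidal, rng):
    locs = np.sort(rng.random(20))
    w = rng.random(20)
    m = q.AtomMeasure(locs, w, normalize=True)
    dw, _, rate = autoinducer_rhs(m, s=0.2, lam=lam, R=sinusoidal)
    assert dw.sum() + rate == pytest.approx(0.0, abs=1e-12)


def test_rhs_rejects_unnormalized(sinusoidal):
    m = q.AtomMeasure.delta(0.5)
    m.weights = m.weights * 0.5  # break the invariant behind the API
    with pytest.raises(ValueError):
        autoinducer_rhs(m, 0.2, 0.1, sinusoidal)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def test_lambda0_closed_form_t0_is_initial(uniform_init):
    m = closed_form_lambda0(uniform_init, s=0.2, t=0.0)
    assert measure_distance(m, uniform_init.to_atoms(400)) < 1e-12


def test_lambda0_closed_form_mean_quadrature_oracle(uniform_init):
    """Independent quadrature of rho0 e^{-stp} fixes the t=10 mean at 0.3435."""
    st = 2.0
    z = quad(lambda p: math.exp(-st * p), 0, 1)[0]
    expected = quad(lambda p: p * math.exp(-st * p), 0, 1)[0] / z
    assert expected == pytest.approx(0.3435, abs=5e-5)
    assert closed_form_lambda0_mean(uniform_init, 0.2, 10.0) == pytest.approx(
        expected, abs=1e-10)
    m = closed_form_lambda0(uniform_init, 0.2, 10.0)
    assert m.mean() == pytest.approx(expected, abs=1e-5)


def test_lambda0_single_atom_stationary():
    dist = q.InitialDistribution("atoms", atoms={0.3: 1.0})
    for t in (0.0, 5.0, 50.0):
        m = closed_form_lambda0(dist, 0.2, t)
        assert m.n_atoms == 1 and m.locations[0] == 0.3


def test_linear_half_closed_form(uniform_init):
    m0 = closed_form_linear_half(uniform_init, 0.2, 0.0)
    assert measure_distance(m0, uniform_init.to_atoms(400)) < 1e-12
    m5 = closed_form_linear_half(uniform_init, 0.2, 5.0)
    y = math.exp(-0.9 * 5)
    # mass at the initial mean 0.5 carries weight 1 - y
    k = np.argmin(np.abs(m5.locations - 0.5))
    assert m5.weights[k] == pytest.approx(1 - y, abs=1e-9)
    far = closed_form_linear_half(uniform_init, 0.2, 200.0)
    assert measure_distance(far, q.AtomMeasure.delta(0.5)) < 1e-12


def test_linear_half_contract_errors(uniform_init, sinusoidal):
    with pytest.raises(ValueError):
        closed_form_linear_half(uniform_init, 0.2, 1.0, lam=0.3)
    with pytest.raises(ValueError):
        closed_form_linear_half(uniform_init, 0.2, 1.0, R=sinusoidal)


# ---------------------------------------------------------------------------
# integrator vs closed forms
# ---------------------------------------------------------------------------

def test_integrator_matches_lambda0_closed_form(uniform_init):
    traj = integrate(uniform_init, 0.2, 0.0, None, t_max=50.0, record_every=5.0)
    for t, m in zip(traj.times, traj.measures):
        ref = closed_form_lambda0(uniform_init, 0.2, float(t))
        assert measure_distance(m, ref) < 1e-3
    assert traj.means[2] == pytest.approx(
        closed_form_lambda0_mean(uniform_init, 0.2, 10.0), abs=1e-3)


def test_integrator_matches_linear_half_closed_form(uniform_init):
    traj = integrate(uniform_init, 0.2, 0.5, q.LinearResponse(),
                     t_max=10.0, record_every=1.0)
    for t, m in zip(traj.times, traj.measures):
        ref = closed_form_linear_half(uniform_init, 0.2, float(t))
        assert measure_distance(m, ref) < 1e-3


def test_two_atom_reduction_reproduces_logistic():
    """lam=0 producer weight follows dx/dt = -s x(1-x) to high accuracy."""
    init = q.AtomMeasure([0.0, 1.0], [0.5, 0.5])
    traj = integrate(init, 0.2, 0.0, None, t_max=10.0, dt_max=1e-3,
                     record_every=1.0)
    for t, m in zip(traj.times, traj.measures):
        x = m.weights[-1] if m.locations[-1] == 1.0 else 0.0
        e = math.exp(-0.2 * t)
        x_exact = 0.5 * e / (0.5 + 0.5 * e)
        assert abs(x - x_exact) < 1e-6


def test_mass_conserved_at_every_record(sinusoidal, uniform_init):
    traj = integrate(uniform_init, 0.2, 0.05, sinusoidal, t_max=30.0)
    for m in traj.measures:
        assert abs(m.total_mass() - 1.0) < 1e-9


def test_heterogeneous_attractor_matches_bimodal_solution(
        sinusoidal, uniform_init, het_solution):
    """Long-time integration lands on the two-atom stationary measure."""
    traj = integrate(uniform_init, 0.2, 0.05, sinusoidal, t_max=1600.0,
                     record_every=100.0)
    final = traj.final_measure()
    assert measure_distance(final, het_solution.to_measure()) < 5e-3
    assert final.mean() == pytest.approx(het_solution.mean, abs=5e-3)
    assert final.variance() == pytest.approx(het_solution.variance, abs=5e-3)


def test_homogeneous_attractor_above_threshold(sinusoidal, uniform_init):
    """lam > s/2: variance vanishes and the state sits at a fixed point."""
    traj = integrate(uniform_init, 0.2, 0.2, sinusoidal, t_max=200.0,
                     stop_residual=1e-6)
    final = traj.final_measure()
    assert final.variance() < 1e-6
    pbar = final.mean()
    assert abs(float(sinusoidal(pbar)) - pbar) < 1e-3


def test_stationary_measure_barely_moves(sinusoidal, het_solution):
    m0 = het_solution.to_measure()
    traj = integrate(m0, 0.2, 0.05, sinusoidal, t_max=10.0)
    assert measure_distance(traj.final_measure(), m0) < 1e-3


def test_integrate_validation(uniform_init, sinusoidal):
    with pytest.raises(ValueError):
        integrate(uniform_init, 0.2, 0.05, sinusoidal, t_max=0.0)
    with pytest.raises(TypeError):
        integrate(uniform_init, 0.2, 0.05, None, t_max=1.0)


# ---------------------------------------------------------------------------
# transport distance
# ---------------------------------------------------------------------------

def test_distance_examples():
    d = q.AtomMeasure.delta
    assert measure_distance(d(0.2), d(0.2)) == 0.0
    assert measure_distance(d(0.0), d(1.0)) == pytest.approx(1.0)
    grid = q.AtomMeasure(np.linspace(0.005, 0.995, 100), np.full(100, 0.01))
    assert measure_distance(grid, d(0.5)) == pytest.approx(0.25, abs=5e-3)


def test_distance_metric_properties(rng):
    ms = []
    for _ in range(3):
        locs = np.sort(rng.random(8))
        ms.append(q.AtomMeasure(locs, rng.random(8), normalize=True))
    a, b, c = ms
    assert measure_distance(a, b) == pytest.approx(measure_distance(b, a), abs=1e-14)
    assert measure_distance(a, c) <= (measure_distance(a, b)
                                      + measure_distance(b, c) + 1e-12)
    assert measure_distance(a, a) == 0.0


# ---------------------------------------------------------------------------
# stochastic process converges to the mean-field solution
# ---------------------------------------------------------------------------

def test_empirical_measure_approaches_meanfield(sinusoidal, uniform_init):
    """W1 distance between the N-particle empirical measure and the
    mean-field solution at t=20 decreases with N."""
    mf = integrate(uniform_init, 0.2, 0.05, sinusoidal, t_max=20.0)
    target = mf.final_measure()
    avg = {}
    for N in (100, 1000, 10_000):
        ds = []
        for seed in (0, 1, 2):
            params = q.ModelParams(N=N, s=0.2, lam=0.05, seed=seed)
            traj = q.run(params, sinusoidal, uniform_init, t_max=20.0,
                         record_every=10.0)
            ds.append(measure_distance(traj.empirical_measure(), target))
        avg[N] = np.mean(ds)
    assert avg[1000] < avg[100]
    assert avg[10_000] < avg[1000]
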