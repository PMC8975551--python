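"""Promoter chain: state space, generator, master equation, SSA, MS2 kernel."""

from __future__ import annotations

from math import comb, log

import numpy as np
import pytest

from bicoidms2.promoter_model import (
    OFF,
    ON,
    BcdGradient,
    PromoterArchitecture,
    SignalKernel,
    activation_rate,
    binding_rate,
    build_generator,
    enumerate_states,
    gillespie_simulate,
    initiation_survival,
    ms2_signal_from_events,
    p_on_from_probabilities,
    predicted_kymograph,
    predicted_steady_profile,
    propagate,
    steady_state_distribution,
    steady_state_p_on,
    steady_state_spot_probability,
)
from conftest import make_model


# ---------------------------------------------------------------------------
# State space
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_sites, expected", [(6, 14), (0, 2), (9, 20)])
def test_state_count_is_two_n_plus_two(n_sites, expected):
    arch = PromoterArchitecture(n_sites=n_sites, k_threshold=0)
    space = enumerate_states(arch)
    assert len(space) == expected


def test_state_index_is_bijective():
    space = enumerate_states(PromoterArchitecture(n_sites=5, k_threshold=2))
    assert len(space.index) == len(space.states)
    for r, s in enumerate(space.states):
        assert space.index[s] == r


def test_negative_sites_rejected():
    with pytest.raises(ValueError):
        PromoterArchitecture(n_sites=-1, k_threshold=0)


def test_threshold_outside_array_rejected():
    with pytest.raises(ValueError):
        PromoterArchitecture(n_sites=3, k_threshold=4)


# ---------------------------------------------------------------------------
# Elementary rates
# ---------------------------------------------------------------------------

def test_binding_rate_counts_free_sites():
    m6 = make_model(6, 3)
    c = 0.8
    r = m6.rates.kb * c
    assert binding_rate(0, m6.architecture, m6.rates, c) == pytest.approx(6 * r)
    assert binding_rate(5, m6.architecture, m6.rates, c) == pytest.approx(1 * r)
    assert binding_rate(6, m6.architecture, m6.rates, c) == 0.0
    m9 = make_model(9, 3)
    assert binding_rate(3, m9.architecture, m9.rates, c) == pytest.approx(
        6 * m9.rates.kb * c)


def test_activation_rate_threshold_and_binomial_scaling():
    m = make_model(6, 3)
    assert activation_rate(2, m.architecture, m.rates) == 0.0
    assert activation_rate(3, m.architecture, m.rates) == pytest.approx(
        m.rates.k_on_base)
    assert activation_rate(6, m.architecture, m.rates) == pytest.approx(
        comb(6, 3) * m.rates.k_on_base)


def test_activation_weights_nondecreasing():
    arch = PromoterArchitecture(n_sites=9, k_threshold=3)
    w = [arch.activation_weight(i) for i in range(10)]
    assert w[:3] == [0.0, 0.0, 0.0]
    assert w[3] == 1.0
    assert all(b >= a for a, b in zip(w, w[1:]))


def test_linear_activation_scaling_option():
    m = make_model(6, 3, scaling="linear")
    assert activation_rate(6, m.architecture, m.rates) == pytest.approx(
        2.0 * m.rates.k_on_base)


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def test_generator_rows_sum_to_zero_for_random_rates():
    rng = np.random.default_rng(11)
    for _ in range(5):
        n = int(rng.integers(1, 7))
        m = make_model(n, int(rng.integers(0, n + 1)),
                       kb=rng.uniform(0.01, 1), ku=rng.uniform(0.01, 1),
                       k_on_base=rng.uniform(0.01, 1),
                       k_off_promoter=rng.uniform(0.01, 1))
        q = build_generator(m.architecture, m.rates, float(rng.uniform(0, 2)))
        assert q.shape == (2 * n + 2, 2 * n + 2)
        np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)
        off_diag = q - np.diag(q.diagonal())
        assert (off_diag >= 0).all()


def test_zero_concentration_has_no_binding_transitions():
    m = make_model(4, 2)
    q = build_generator(m.architecture, m.rates, 0.0)
    space = enumerate_states(m.architecture)
    for r, (i, a) in enumerate(space.states):
        if i < 4:
            assert q[r, space.index[(i + 1, a)]] == 0.0


def test_rate_length_mismatch_rejected():
    from bicoidms2.promoter_model import KineticRates, PromoterModel
    with pytest.raises(ValueError):
        PromoterModel(PromoterArchitecture(n_sites=4, k_threshold=2),
                      KineticRates(kb=0.1, k_off_site=(0.1, 0.1),
                                   k_on_base=0.1, k_off_promoter=0.1,
                                   rnap_rate=0.1))


# ---------------------------------------------------------------------------
# Master equation
# ---------------------------------------------------------------------------

def test_propagate_conserves_probability():
    rng = np.random.default_rng(3)
    m = make_model(4, 2)
    q = build_generator(m.architecture, m.rates, 0.7)
    p0 = rng.dirichlet(np.ones(q.shape[0]))
    probs = propagate(q, p0, np.linspace(0.0, 800.0, 41))
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
    assert (probs >= 0).all()


def test_propagate_all_rates_zero_is_constant():
    m = make_model(2, 2, kb=0.0, ku=0.0, k_on_base=0.0, k_off_promoter=0.0)
    q = build_generator(m.architecture, m.rates, 1.0)
    space = enumerate_states(m.architecture)
    p0 = np.zeros(len(space))
    p0[space.index[(0, OFF)]] = 1.0
    probs = propagate(q, p0, [0.0, 100.0, 500.0])
    np.testing.assert_allclose(probs, np.tile(p0, (3, 1)), atol=1e-12)


def test_occupancy_equilibrium_is_binomial():
    # With the promoter switch disabled and aggregate unbinding i*ku, the
    # occupancy is an independent-sites birth-death chain whose equilibrium
    # is Binomial(N, kb*c / (kb*c + ku)).
    n, kb, ku, c = 4, 0.08, 0.03, 0.9
    m = make_model(n, n, kb=kb, ku=ku, k_on_base=0.0)
    q = build_generator(m.architecture, m.rates, c)
    space = enumerate_states(m.architecture)
    p0 = np.zeros(len(space))
    p0[space.index[(0, OFF)]] = 1.0
    probs = propagate(q, p0, [0.0, 5000.0])
    occupancy = np.zeros(n + 1)
    for r, (i, _) in enumerate(space.states):
        occupancy[i] += probs[-1, r]
    theta = kb * c / (kb * c + ku)
    expected = np.array([comb(n, i) * theta ** i * (1 - theta) ** (n - i)
                         for i in range(n + 1)])
    np.testing.assert_allclose(occupancy, expected, atol=1e-7)


def test_long_time_propagation_matches_null_space():
    m = make_model(3, 2)
    q = build_generator(m.architecture, m.rates, 0.6)
    space = enumerate_states(m.architecture)
    p0 = np.zeros(len(space))
    p0[space.index[(0, OFF)]] = 1.0
    final = propagate(q, p0, [0.0, 2e4])[-1]
    pi = steady_state_distribution(q)
    np.testing.assert_allclose(final, pi, atol=1e-6)


def test_bad_initial_vector_rejected():
    m = make_model(2, 1)
    q = build_generator(m.architecture, m.rates, 1.0)
    with pytest.raises(ValueError):
        propagate(q, np.ones(q.shape[0]), [0.0, 1.0])


# ---------------------------------------------------------------------------
# Steady state
# ---------------------------------------------------------------------------

def test_saturating_concentration_pins_full_occupancy():
    # At saturating Bicoid the chain lives at occupancy N and the
    # ON-probability reduces to the two-state closed form.
    m = make_model(4, 2)
    c = 1e6
    k_on_n = m.rates.k_on_base * m.architecture.activation_weight(4)
    expected = k_on_n / (k_on_n + m.rates.k_off_promoter)
    assert steady_state_p_on(m, c) == pytest.approx(expected, abs=1e-6)


def test_zero_concentration_never_activates():
    # with c = 0 all mass drains to the empty-OFF state, which is the
    # unique stationary point
    m = make_model(3, 2)
    p_on = steady_state_p_on(m, 0.0)
    assert p_on == pytest.approx(0.0, abs=1e-12)


def test_stationary_distribution_matches_gillespie_occupancy():
    m = make_model(3, 1)
    c = 0.8
    q = build_generator(m.architecture, m.rates, c)
    pi = steady_state_distribution(q)
    space = enumerate_states(m.architecture)
    rng = np.random.default_rng(17)
    n_runs, t_probe = 500, 1500.0
    counts = np.zeros(len(space))
    for _ in range(n_runs):
        traj = gillespie_simulate(m.architecture, m.rates, c, t_probe + 1.0, rng)
        k = int(np.searchsorted(traj.switch_times, t_probe, side="right"))
        counts[space.index[traj.states[k]]] += 1
    freq = counts / n_runs
    se = np.sqrt(np.maximum(pi * (1 - pi), 1e-12) / n_runs)
    assert np.all(np.abs(freq - pi) <= 3 * se + 1e-9)


# ---------------------------------------------------------------------------
# Gillespie
# ---------------------------------------------------------------------------

def test_no_activation_means_no_initiations():
    m = make_model(3, 2, k_on_base=0.0)
    traj = gillespie_simulate(m.architecture, m.rates, 1.0, 800.0, seed=5)
    assert traj.initiation_times.size == 0
    assert all(a == OFF for _, a in traj.states)


def test_trajectory_events_ordered_and_initiations_inside_on_dwells():
    m = make_model(3, 1)
    traj = gillespie_simulate(m.architecture, m.rates, 1.0, 800.0, seed=7)
    assert np.all(np.diff(traj.switch_times) > 0)
    intervals = traj.on_intervals()
    for t in traj.initiation_times:
        assert any(a <= t <= b for a, b in intervals)


def test_wald_identity_initiations_vs_on_time():
    # E[#initiations] = rnap_rate * E[total ON time]
    m = make_model(3, 1, rnap_rate=0.15)
    rng = np.random.default_rng(23)
    tot_init, tot_on = 0.0, 0.0
    for _ in range(300):
        traj = gillespie_simulate(m.architecture, m.rates, 0.8, 600.0, rng)
        tot_init += traj.initiation_times.size
        tot_on += traj.total_on_time()
    expected = m.rates.rnap_rate * tot_on
    assert abs(tot_init - expected) <= 4 * np.sqrt(expected)


def test_gillespie_seed_reproducibility():
    m = make_model(3, 1)
    a = gillespie_simulate(m.architecture, m.rates, 0.8, 500.0, seed=42)
    b = gillespie_simulate(m.architecture, m.rates, 0.8, 500.0, seed=42)
    np.testing.assert_array_equal(a.switch_times, b.switch_times)
    np.testing.assert_array_equal(a.initiation_times, b.initiation_times)


# ---------------------------------------------------------------------------
# MS2 signal kernel
# ---------------------------------------------------------------------------

def _trajectory_with_inits(inits, duration=600.0):
    from bicoidms2.promoter_model import Trajectory
    return Trajectory(switch_times=np.empty(0), states=((0, ON),),
                      initiation_times=np.asarray(inits, float),
                      duration=duration)


def test_no_initiations_gives_zero_trace(kernel):
    traj = _trajectory_with_inits([])
    times = np.arange(0.0, 600.0, 10.0)
    np.testing.assert_array_equal(ms2_signal_from_events(traj, kernel, times),
                                  np.zeros_like(times))


def test_single_initiation_is_a_trapezoid(kernel):
    traj = _trajectory_with_inits([100.0])
    times = np.array([90.0, 100.0, 130.0, 160.0, 250.0, 280.0, 281.0])
    sig = ms2_signal_from_events(traj, kernel, times)
    # ramp over loop_ramp_time=60 s, plateau 1.0, drop after elongation 180 s
    np.testing.assert_allclose(sig, [0.0, 0.0, 0.5, 1.0, 1.0, 1.0, 0.0],
                               atol=1e-12)


def test_overlapping_initiations_match_per_event_summation(kernel):
    rng = np.random.default_rng(9)
    inits = np.sort(rng.uniform(0.0, 500.0, 40))
    traj = _trajectory_with_inits(inits)
    times = np.arange(0.0, 600.0, 7.0)
    sig = ms2_signal_from_events(traj, kernel, times)
    brute = np.zeros_like(times)
    for t0 in inits:
        for j, t in enumerate(times):
            dt = t - t0
            if 0 <= dt <= kernel.elongation_time:
                brute[j] += min(1.0, dt / kernel.loop_ramp_time)
    np.testing.assert_allclose(sig, brute, atol=1e-10)


def test_kernel_validation():
    with pytest.raises(ValueError):
        SignalKernel(loop_ramp_time=200.0, elongation_time=180.0)
    with pytest.raises(ValueError):
        SignalKernel(detection_threshold=-0.1)


# ---------------------------------------------------------------------------
# Exact spot probability (Feynman-Kac) vs mean field
# ---------------------------------------------------------------------------

def test_exact_spot_probability_below_poisson_mean_field(kernel):
    # Burst clumping makes the true visibility probability smaller than the
    # Poisson mean-field formula (Jensen's inequality).
    m = make_model(4, 2, rnap_rate=0.1)
    exact = steady_state_spot_probability(m, 0.8, kernel)
    poisson = steady_state_spot_probability(m, 0.8, kernel, method="poisson")
    assert 0.0 < exact <= poisson <= 1.0


def test_initiation_survival_decays_with_duration():
    m = make_model(3, 1)
    s = [initiation_survival(m, 0.8, d) for d in (50.0, 200.0, 800.0)]
    assert 1.0 > s[0] > s[1] > s[2] >= 0.0


# ---------------------------------------------------------------------------
# Spatial predictions
# ---------------------------------------------------------------------------

def test_kymograph_shape_monotone_and_bounded(gradient, kernel):
    m = make_model(5, 3)
    x = np.arange(10.0, 80.0, 5.0)
    t = np.array([120.0, 400.0, 800.0])
    surf = predicted_kymograph(m, gradient, x, t, kernel)
    assert surf.shape == (len(t), len(x))
    assert surf.min() >= 0.0 and surf.max() <= 1.0
    # spatial monotone decrease at the last time point
    assert np.all(np.diff(surf[-1]) <= 1e-9)


def test_anterior_plateau_approaches_saturating_closed_form(kernel):
    m = make_model(4, 2, kb=50.0)  # saturating anterior concentration
    grad = BcdGradient(c0=1.0, lambda_decay=15.0)
    k_on_n = m.rates.k_on_base * m.architecture.activation_weight(4)
    p_on_sat = k_on_n / (k_on_n + m.rates.k_off_promoter)
    surf = predicted_kymograph(m, grad, [2.0], [3000.0], kernel)
    expected = 1.0 - np.exp(-m.rates.rnap_rate * kernel.elongation_time * p_on_sat)
    assert surf[0, 0] == pytest.approx(expected, abs=1e-3)


def test_more_binding_sites_moves_boundary_posterior(gradient, kernel):
    shared = dict(kb=0.07, ku=0.005, k_on_base=0.0021, k_off_promoter=0.05,
                  rnap_rate=0.018)
    x = np.arange(10.0, 90.0, 1.0)
    prof6 = predicted_steady_profile(make_model(6, 3, **shared), gradient, x, kernel)
    prof9 = predicted_steady_profile(make_model(9, 3, **shared), gradient, x, kernel)
    half6 = np.interp(0.5 * prof6[0], prof6[::-1], x[::-1])
    half9 = np.interp(0.5 * prof9[0], prof9[::-1], x[::-1])
    assert half9 > half6 + 1.0


def test_halved_amplitude_translates_kymograph(gradient, kernel):
    # surfaces sampled on x and on x - lambda*ln2 with halved dosage agree
    m = make_model(5, 3, kb=0.3)
    shift = gradient.lambda_decay * log(2.0)
    x = np.arange(20.0, 60.0, 5.0)
    t = np.array([200.0, 700.0])
    full = predicted_kymograph(m, gradient, x, t, kernel)
    halved = predicted_kymograph(m, gradient.with_dosage(0.5), x - shift + 1e-12,
                                 t, kernel)
    np.testing.assert_allclose(full, halved, atol=1e-9)
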