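"""Generative choice model: DV distribution, decision function, mixtures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wmdrift.model import (
    ModelParams,
    decision_function,
    dv_distribution,
    memory_lapse_prob,
    memory_std,
    p_different,
    p_different_many,
    simulate_responses,
)
from wmdrift.task import generate_trials


def test_memory_std_diffusion_scaling():
    assert memory_std(5.0, 0.0) == 0.0
    assert memory_std(5.0, 1.0) == 5.0
    assert memory_std(5.0, 9.0) == pytest.approx(15.0)
    with pytest.raises(ValueError):
        memory_std(5.0, -1.0)


def test_dv_distribution_half_normal_at_zero_delta():
    g = dv_distribution(0.0, 3.0)
    expected = 2.0 * np.exp(-0.5 * (g.x / 3.0) ** 2) / np.sqrt(2 * np.pi) / 3.0 * g.dx
    assert np.allclose(g.masses, expected)


@pytest.mark.parametrize(
    "delta,sigma", [(0.0, 1.0), (0.0, 4.2856), (13.846, 4.2856), (90.0, 30.0), (166.15, 40.0), (180.0, 55.0)]
)
def test_dv_mass_conservation(delta, sigma):
    g = dv_distribution(delta, sigma)
    assert g.masses.sum() == pytest.approx(1.0, abs=1e-3)
    assert np.all(g.masses >= 0)


def test_dv_grid_mean_matches_monte_carlo(rng):
    delta, sigma = 13.85, 4.2856
    g = dv_distribution(delta, sigma)
    grid_mean = float(np.sum(g.x * g.masses))
    draws = np.abs(rng.normal(delta, sigma, 10**6))
    mc_mean = draws.mean()
    mc_se = draws.std() / 1000.0
    assert abs(grid_mean - mc_mean) < 3 * mc_se


def test_decision_function_inflection_and_asymptotes():
    smooth = ModelParams(1.0, 11.137, theta=0.1, sigma_dec=2.0)
    assert decision_function(11.137, smooth) == pytest.approx(0.5)
    assert decision_function(1e6, smooth) == pytest.approx(0.9)
    step = ModelParams(1.0, 11.137, theta=0.02, sigma_dec=0.0)
    assert decision_function(0.0, step) == 0.02
    assert decision_function(11.137, step) == 0.5
    assert decision_function(20.0, step) == 0.98
    hard = ModelParams(1.0, 5.0)
    assert decision_function(6.0, hard) == 1.0


def test_memory_lapse_hazard():
    assert memory_lapse_prob(0.0, 9.0) == 0.0
    assert memory_lapse_prob(0.0049, 9.0) == pytest.approx(0.04314, abs=5e-5)
    probs = [memory_lapse_prob(0.1, t) for t in (0, 1, 3, 9)]
    assert np.all(np.diff(probs) > 0)


def test_p_different_threshold_beyond_support():
    p = ModelParams(sigma_mem=4.2856, delta_thresh=180.0)
    assert p_different(p, 1.0, 0.0) == pytest.approx(0.0, abs=1e-6)


def test_p_different_certain_memory_lapse_guesses():
    p = ModelParams(sigma_mem=4.2856, delta_thresh=11.137, lam=1e6)
    for d in (0.0, 13.85, 90.0):
        assert p_different(p, 3.0, d) == pytest.approx(0.5, abs=1e-6)


@pytest.mark.parametrize("method", ["grid", "auto"])
def test_p_different_matches_monte_carlo_traces(method, representative, rng):
    """Forward probabilities match a trace-level simulator (step variant)."""
    params = representative.replace(sigma_dec=0.0, lam=0.0)
    n = 10**6
    for T, delta in [(1.0, 0.0), (3.0, 13.846), (9.0, 27.7), (3.0, 96.9)]:
        x = np.abs(rng.normal(delta, params.sigma_mem * np.sqrt(T), n))
        beyond = x > params.delta_thresh
        p_mc = params.theta * (1 - beyond.mean()) + (1 - params.theta) * beyond.mean()
        se = np.sqrt(p_mc * (1 - p_mc) / n)
        assert p_different(params, T, delta, method) == pytest.approx(
            p_mc, abs=max(3 * se, 1e-3)
        )


def test_p_different_monotone_in_delta_and_delay():
    hard = ModelParams(sigma_mem=4.2856, delta_thresh=11.137)
    deltas = np.arange(0.0, 170.0, 13.846)
    probs = [p_different(hard, 3.0, d, "auto") for d in deltas]
    assert np.all(np.diff(probs) >= -1e-12)
    # false-alarm tendency at the matched location rises with delay
    p_match = [p_different(hard, T, 0.0, "auto") for T in (1.0, 3.0, 9.0)]
    assert np.all(np.diff(p_match) > 0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    sigma_mem=st.floats(0.1, 40.0),
    delta_thresh=st.floats(0.1, 150.0),
    theta=st.floats(0.0, 0.5),
    lam=st.floats(0.0, 0.8),
    sigma_dec=st.floats(0.0, 30.0),
    T=st.sampled_from([1.0, 3.0, 9.0]),
    delta=st.floats(0.0, 180.0),
)
def test_p_different_bounded_and_fast_path_consistent(
    sigma_mem, delta_thresh, theta, lam, sigma_dec, T, delta
):
    params = ModelParams(sigma_mem, delta_thresh, theta, lam, sigma_dec)
    p_auto = p_different(params, T, delta, "auto")
    assert 0.0 <= p_auto <= 1.0
    # the reference grid quantizes the threshold to dx-wide bins, so the two
    # paths can differ by up to the decision-variable mass in the bin that
    # straddles the threshold (largest when sigma_T is small and the
    # threshold sits near the density peak)
    sigma_T = sigma_mem * np.sqrt(T)
    peak = np.exp(-0.5 * ((delta_thresh - delta) / sigma_T) ** 2)
    peak += np.exp(-0.5 * ((delta_thresh + delta) / sigma_T) ** 2)
    straddle = peak / np.sqrt(2 * np.pi) / sigma_T * 0.05
    assert p_auto == pytest.approx(
        p_different(params, T, delta, "grid"), abs=2e-3 + straddle
    )


def test_p_different_many_matches_scalar(representative):
    pm = np.array(
        [
            [4.2856, 11.137, 0.0203, 0.0, 0.0],
            [4.2856, 11.137, 0.0203, 0.0049, 3.0802],
            [0.5, 30.0, 0.4, 0.2, 0.01],
        ]
    )
    T = np.array([1.0, 3.0, 9.0, 9.0])
    delta = np.array([0.0, 13.846, 27.7, 166.15])
    out = p_different_many(pm, T, delta)
    for i in range(pm.shape[0]):
        for j in range(len(T)):
            assert out[i, j] == pytest.approx(
                p_different(ModelParams(*pm[i]), T[j], delta[j], "auto"), abs=1e-12
            )


def test_simulate_responses_deterministic_and_binomially_calibrated(representative):
    params = representative.replace(sigma_dec=0.0)
    trials = generate_trials(1, rng_seed=4)
    a = simulate_responses(params, trials, rng_seed=9)
    b = simulate_responses(params, trials, rng_seed=9)
    assert (a.response == b.response).all()
    # empirical p(different) per cell matches the forward model
    big = simulate_responses(
        params, trials * 200, rng_seed=10
    )  # ~12600 trials reusing cell structure
    for (T, d), cell in big.groupby(["delay_s", "delta_deg"]):
        p_hat = cell.response.mean()
        p_mod = p_different(params, T, d, "auto")
        se = np.sqrt(max(p_mod * (1 - p_mod), 1e-6) / len(cell))
        assert abs(p_hat - p_mod) < 4 * se + 1e-9


def test_param_validation():
    with pytest.raises(ValueError):
        ModelParams(-1.0, 10.0)
    with pytest.raises(ValueError):
        ModelParams(1.0, 10.0, theta=0.6)
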