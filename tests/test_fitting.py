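"""Cross-entropy objective, swarm fitting, BIC and recovery machinery."""

import numpy as np
import pandas as pd
import pytest

from wmdrift.fitting import (
    MODEL_VARIANTS,
    bic,
    compare_models,
    cross_entropy,
    fit_variant,
    fwhm_normal,
    recovery_study,
)
from wmdrift.model import ModelParams, p_different, simulate_responses
from wmdrift.pso import PSOConfig, minimize_pso
from wmdrift.task import generate_trials


@pytest.fixture(scope="module")
def small_dataset(representative):
    params = representative.replace(lam=0.0, sigma_dec=0.0)
    trials = generate_trials(3, rng_seed=21)
    return params, simulate_responses(params, trials, rng_seed=22)


def test_variant_table_matches_design():
    frees = {v.id: set(v.free_params) for v in MODEL_VARIANTS.values()}
    for v in MODEL_VARIANTS.values():
        assert {"sigma_mem", "delta_thresh"} <= frees[v.id]
    assert [MODEL_VARIANTS[i].n_free for i in range(1, 7)] == [2, 3, 3, 3, 4, 5]
    assert frees[2] == {"sigma_mem", "delta_thresh", "theta"}
    assert frees[3] == {"sigma_mem", "delta_thresh", "lam"}
    assert frees[4] == {"sigma_mem", "delta_thresh", "sigma_dec"}
    assert frees[6] == set(
        ("sigma_mem", "delta_thresh", "theta", "lam", "sigma_dec")
    )


def test_cross_entropy_limits(small_dataset):
    _, responses = small_dataset
    n = len(responses)
    # a guessing model predicts 0.5 everywhere: CE = n ln 2
    guess = ModelParams(sigma_mem=1.0, delta_thresh=1.0, lam=1e9)
    assert cross_entropy(responses, guess) == pytest.approx(n * np.log(2), rel=1e-9)
    with pytest.raises(ValueError):
        cross_entropy(responses.iloc[:0], guess)


def test_cross_entropy_matches_per_trial_loop_oracle(small_dataset):
    params, responses = small_dataset
    probe = ModelParams(sigma_mem=5.0, delta_thresh=9.0, theta=0.05)
    oracle = 0.0
    for row in responses.itertuples():
        p = np.clip(
            p_different(probe, row.delay_s, row.delta_deg, "auto"), 1e-12, 1 - 1e-12
        )
        oracle -= row.response * np.log(p) + (1 - row.response) * np.log(1 - p)
    assert cross_entropy(responses, probe) == pytest.approx(oracle, abs=1e-10)


def test_cross_entropy_minimal_near_generating_params(small_dataset):
    """Likelihood principle: perturbed parameters never beat the truth by much."""
    params, responses = small_dataset
    ce_true = cross_entropy(responses, params)
    rng = np.random.default_rng(3)
    worse = 0
    for _ in range(20):
        pert = params.replace(
            sigma_mem=params.sigma_mem * rng.uniform(1.5, 3),
            delta_thresh=params.delta_thresh * rng.uniform(1.5, 3),
        )
        worse += cross_entropy(responses, pert) > ce_true
    assert worse >= 18


def test_bic_formula_and_identity():
    assert bic(0.0, 0, 10) == 0.0
    assert bic(100.0, 3, 189) == pytest.approx(215.7253, abs=1e-3)
    assert bic(50.0, 3, 189) - bic(50.0, 2, 189) == pytest.approx(np.log(189))
    with pytest.raises(ValueError):
        bic(1.0, 1, 0)


def test_fit_variant_recovers_and_is_deterministic(small_dataset, scaled_pso):
    _, responses = small_dataset
    fit1 = fit_variant(responses, 2, scaled_pso, rng_seed=5)
    fit2 = fit_variant(responses, 2, scaled_pso, rng_seed=5)
    assert fit1.params == fit2.params and fit1.ce == fit2.ce
    # BIC identity holds bit-exactly
    assert fit1.bic == 2.0 * fit1.ce + fit1.n_free * np.log(fit1.n_trials)
    # generating values were sigma_mem=4.2856, delta=11.137: loose recovery
    assert fit1.params.sigma_mem == pytest.approx(4.2856, abs=2.0)
    assert fit1.params.delta_thresh == pytest.approx(11.137, abs=3.0)


def test_pso_finds_quadratic_minimum():
    fun = lambda x: ((x - np.array([1.0, -2.0])) ** 2).sum(axis=1)
    res = minimize_pso(
        fun, np.array([[-10, 10], [-10, 10]]), PSOConfig(n_particles=20, max_iter=200),
        seed=0,
    )
    assert np.allclose(res.x, [1.0, -2.0], atol=1e-4)


def test_recovery_study_centers_and_flags(representative, scaled_pso):
    gen = ModelParams(sigma_mem=4.2856, delta_thresh=11.137, theta=0.0203)
    r = recovery_study(
        2, gen, n_datasets=12, n_trials=189, rng_seed=8, optimizer_config=scaled_pso
    )
    assert r.recovered.shape == (12, 3)
    assert r.fwhm["sigma_mem"] == pytest.approx(
        fwhm_normal(r.recovered.sigma_mem.to_numpy())
    )
    assert abs(r.recovered.sigma_mem.mean() - 4.2856) < max(
        r.fwhm["sigma_mem"], 1.5
    )
    tiny = recovery_study(
        1, None, n_datasets=2, n_trials=63, rng_seed=8, optimizer_config=scaled_pso
    )
    assert tiny.low_confidence


def test_compare_models_single_variant_trivially_wins(small_dataset, scaled_pso):
    _, responses = small_dataset
    table, winner = compare_models(
        {0: responses, 1: responses}, variants=[3], optimizer_config=scaled_pso
    )
    assert winner == 3


def test_fitted_noise_and_threshold_correlate_when_generated_correlated(scaled_pso):
    """Subjects with higher generating noise+threshold refit higher on both."""
    rng = np.random.default_rng(14)
    sig_fit, thr_fit, sig_gen = [], [], []
    for s in range(12):
        scale = rng.uniform(0.6, 1.8)
        gen = ModelParams(
            sigma_mem=4.2856 * scale, delta_thresh=11.137 * scale, theta=0.02
        )
        trials = generate_trials(3, rng_seed=100 + s)
        resp = simulate_responses(gen, trials, rng_seed=200 + s)
        fit = fit_variant(resp, 2, scaled_pso, rng_seed=300 + s)
        sig_fit.append(fit.params.sigma_mem)
        thr_fit.append(fit.params.delta_thresh)
        sig_gen.append(gen.sigma_mem)
    assert np.corrcoef(sig_fit, thr_fit)[0, 1] > 0
    assert np.corrcoef(sig_gen, sig_fit)[0, 1] > 0.5
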