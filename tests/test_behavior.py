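"""Exclusion rules, error-rate summaries and signal-detection metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from wmdrift.behavior import (
    error_rates,
    exclude_subjects,
    exclude_trials,
    sdt_metrics,
)
from wmdrift.model import ModelParams, simulate_responses
from wmdrift.task import generate_trials


def _rt_frame(rts, subject=0):
    return pd.DataFrame(
        {
            "subject": subject,
            "rt_s": rts,
            "response": 0,
            "correct": 1,
            "category": "match",
            "delay_s": 1.0,
        }
    )


def test_exclude_trials_rt_rules():
    kept, log = exclude_trials(_rt_frame([1.0] * 20))
    assert len(kept) == 20 and len(log) == 0

    kept, log = exclude_trials(_rt_frame([0.1] + [1.0] * 19))
    assert len(kept) == 19
    assert log.rule.tolist() == ["rt_floor"]


def test_exclude_trials_sd_outlier_constructed():
    # base RTs with known mean/SD, one 4.5-SD outlier and one 3.5-SD point
    rng = np.random.default_rng(0)
    base = rng.normal(1.0, 0.1, 200)
    base = (base - base.mean()) / base.std() * 0.1 + 1.0  # exact moments
    rts = np.concatenate([base, [1.0 + 0.45 * 1.02], [1.0 + 0.35]])
    # outlier inflates SD slightly; compute expected cut from the full set
    kept, log = exclude_trials(_rt_frame(rts))
    m, s = np.mean(rts), np.std(rts, ddof=1)
    assert (rts > m + 4 * s).sum() == 1
    assert len(kept) == len(rts) - 1
    assert set(log.rule) == {"rt_outlier"}


def test_exclude_trials_idempotent():
    rts = np.concatenate([np.full(50, 1.0), [0.05, 3.5]])
    once, _ = exclude_trials(_rt_frame(rts))
    twice, log2 = exclude_trials(once)
    assert len(twice) == len(once) and len(log2) == 0


def test_exclude_trials_missing_rt_passes():
    frame = _rt_frame([1.0] * 5)
    frame.loc[2, "rt_s"] = np.nan
    kept, _ = exclude_trials(frame)
    assert len(kept) == 5


def test_exclude_subjects_strict_below_threshold():
    kept, excluded = exclude_subjects({"a": 0.59, "b": 0.60, "c": 0.80})
    assert excluded == ["a"] and kept == ["b", "c"]


def test_always_different_agent_kept_at_two_thirds():
    trials = generate_trials(3, rng_seed=1)
    resp = simulate_responses(
        ModelParams(sigma_mem=1.0, delta_thresh=0.0), trials, rng_seed=2
    )
    acc = resp.correct.mean()
    assert acc == pytest.approx(2 / 3, abs=1e-9)
    kept, _ = exclude_subjects({0: acc})
    assert kept == [0]


def test_error_rates_perfect_and_guessing_agents():
    trials = generate_trials(2, rng_seed=3)
    perfect = simulate_responses(
        ModelParams(sigma_mem=1e-6, delta_thresh=13.846 / 2), trials, rng_seed=4
    )
    out = error_rates(perfect)
    assert np.allclose(out.error_rate, 0.0)
    guess = simulate_responses(
        ModelParams(sigma_mem=1.0, delta_thresh=1.0, lam=1e9), trials * 40,
        rng_seed=5,
    )
    out = error_rates(guess, by=("category",))
    assert np.allclose(out.error_rate, 0.5, atol=0.05)


def test_near_false_alarms_rise_with_delay(representative):
    params = representative.replace(sigma_dec=0.0, lam=0.0)
    trials = generate_trials(60, rng_seed=6)
    resp = simulate_responses(params, trials, rng_seed=7)
    near = error_rates(resp[resp.category == "near"], by=("delay_s",))
    rates = near.sort_values("delay_s").error_rate.to_numpy()
    assert rates[0] < rates[1] < rates[2]


def test_sdt_chance_and_worked_values():
    def frame(h_same, n_match, fa_same_near, n_near, fa_same_far, n_far):
        rows = (
            [("match", 0)] * h_same
            + [("match", 1)] * (n_match - h_same)
            + [("near", 0)] * fa_same_near
            + [("near", 1)] * (n_near - fa_same_near)
            + [("far", 0)] * fa_same_far
            + [("far", 1)] * (n_far - fa_same_far)
        )
        return pd.DataFrame(rows, columns=["category", "response"])

    # H = FA -> d' = 0
    m = sdt_metrics(frame(10, 20, 5, 10, 5, 10))
    assert m.d_prime == pytest.approx(0.0, abs=1e-12)

    # H=0.8, FA=0.2 on both nonmatch classes
    m = sdt_metrics(frame(16, 20, 4, 20, 4, 20))
    assert m.d_prime == pytest.approx(2 * 0.8416, abs=1e-3)
    assert m.criterion == pytest.approx(0.0, abs=1e-12)
    conv = sdt_metrics(frame(16, 20, 4, 20, 4, 20), criterion_convention="conventional")
    assert conv.criterion == pytest.approx(0.0, abs=1e-12)

    # extreme-rate correction: near FA 0.4, far FA 0 (N=20) -> corrected 1/40
    m = sdt_metrics(frame(16, 20, 8, 20, 0, 20))
    assert m.fa_rate == pytest.approx((0.4 + 1 / 40) / 2)


def test_d_prime_decreases_with_memory_noise():
    trials = generate_trials(20, rng_seed=8)
    d_primes = []
    for i, sm in enumerate([2.0, 5.0, 10.0]):
        resp = simulate_responses(
            ModelParams(sigma_mem=sm, delta_thresh=11.137), trials, rng_seed=9 + i
        )
        d_primes.append(sdt_metrics(resp).d_prime)
    assert d_primes[0] > d_primes[1] > d_primes[2]


def test_sdt_requires_both_classes():
    df = pd.DataFrame({"category": ["match"] * 5, "response": [0] * 5})
    with pytest.raises(ValueError):
        sdt_metrics(df)
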