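"""Synthetic-data generators with recorded ground truth.

Every input the pipeline consumes can be generated here: behavioral cohorts
(per-subject generative parameters drawn from truncated normals, trials from
the task design, responses from the choice model), neuropsychological
batteries (a single dominant shared factor plus independent noise, mapped
onto realistic test scales), and TGM ensembles with stable or dynamic coding
structure.  All generators are seed-deterministic and return their ground
truth alongside the data, so downstream modules can be tested by recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .fitting import DEFAULT_BOUNDS, PARAM_NAMES
from .model import ModelParams, simulate_responses
from .task import DEFAULT_CONFIG, TaskConfig, generate_trials, trials_to_frame
from .tgm import TGMatrix

__all__ = [
    "GroupSpec",
    "Cohort",
    "gen_cohort",
    "gen_battery",
    "gen_tgm",
    "DEFAULT_LOADINGS",
]


@dataclass(frozen=True)
class GroupSpec:
    """Distribution of generative parameters for one subject group.

    ``param_means``/``param_sds`` give truncated-normal location and scale
    per model parameter (sd 0 = shared value); parameters not listed are
    fixed at zero.  ``block_count_probs`` gives the probabilities of a
    subject completing 1, 2 or 3 blocks of 63 trials (data collection was
    not always complete); the default favors the full three blocks.
    """

    name: str
    n_subjects: int
    param_means: dict[str, float]
    param_sds: dict[str, float] = field(default_factory=dict)
    block_count_probs: tuple[float, float, float] = (0.1, 0.2, 0.7)

    def __post_init__(self) -> None:
        unknown = set(self.param_means) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        if abs(sum(self.block_count_probs) - 1.0) > 1e-9:
            raise ValueError("block_count_probs must sum to 1")


@dataclass
class Cohort:
    subjects: pd.DataFrame  # group, subject, n_blocks, true parameter columns
    responses: pd.DataFrame  # trial table with response/correct columns


def _draw_param(
    rng: np.random.Generator, name: str, mean: float, sd: float
) -> float:
    lo, hi = DEFAULT_BOUNDS[name]
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def gen_cohort(
    group_specs: list[GroupSpec],
    rng_seed: int = 0,
    config: TaskConfig = DEFAULT_CONFIG,
) -> Cohort:
    """Simulate a multi-group behavioral cohort with known ground truth."""
    rng = np.random.default_rng(rng_seed)
    subject_rows = []
    response_frames = []
    sid = 0
    for spec in group_specs:
        for _ in range(spec.n_subjects):
            values = {
                name: _draw_param(
                    rng, name, spec.param_means[name], spec.param_sds.get(name, 0.0)
                )
                for name in spec.param_means
            }
            params = ModelParams(
                **{name: values.get(name, 0.0) for name in PARAM_NAMES}
            )
            n_blocks = int(rng.choice([1, 2, 3], p=spec.block_count_probs))
            trials = generate_trials(n_blocks, config, rng_seed=rng)
            responses = simulate_responses(params, trials, rng_seed=rng, subject=sid)
            responses["group"] = spec.name
            response_frames.append(responses)
            subject_rows.append(
                {
                    "group": spec.name,
                    "subject": sid,
                    "n_blocks": n_blocks,
                    **{f"true_{k}": getattr(params, k) for k in PARAM_NAMES},
                }
            )
            sid += 1
    return Cohort(
        subjects=pd.DataFrame(subject_rows),
        responses=pd.concat(response_frames, ignore_index=True),
    )


# Unit loadings on all ten tests: one dominant shared factor.
DEFAULT_LOADINGS = np.ones(10)

# (column, offset, scale, low, high) mapping of latent traits onto realistic
# test scales; the TMT columns are mapped with inverted sign so that higher
# raw values mean slower, i.e. worse, performance.
_SCALE_MAP = [
    ("semantic_fluency", 20.0, 5.0, 0.0, 40.0),
    ("phonemic_fluency", 14.0, 4.0, 0.0, 30.0),
    ("bnt", 13.5, 1.5, 0.0, 15.0),
    ("wordlist_learning", 20.0, 4.0, 0.0, 30.0),
    ("wordlist_recall", 7.0, 2.0, 0.0, 10.0),
    ("praxis", 10.0, 1.0, 0.0, 11.0),
    ("praxis_recall", 9.0, 2.0, 0.0, 11.0),
]


def gen_battery(
    n_subjects: int,
    factor_loadings: np.ndarray = DEFAULT_LOADINGS,
    noise_sd: float = 1.0,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a neuropsych battery from a one-factor model.

    Latent trait_ij = loading_j × factor_i + ε_ij (factor ~ N(0,1), noise
    ~ N(0, noise_sd²)), mapped onto each test's scale.  Recognition is
    produced as integer hits/correct rejects out of 10; the TMT columns
    carry the inverted convention (larger = worse).  Returns the battery
    table and the generating factor (the ground truth).
    """
    factor_loadings = np.asarray(factor_loadings, dtype=float)
    if len(factor_loadings) != 10:
        raise ValueError("need one loading per PCA-eligible test")
    rng = np.random.default_rng(rng_seed)
    factor = rng.standard_normal(n_subjects)
    latent = factor[:, None] * factor_loadings[None, :] + noise_sd * rng.standard_normal(
        (n_subjects, 10)
    )
    df = pd.DataFrame(index=range(n_subjects))
    for j, (col, off, scale, lo, hi) in enumerate(_SCALE_MAP):
        df[col] = np.clip(off + scale * latent[:, j], lo, hi)
    # recognition: latent trait 7 split into hits and correct rejects
    rec = latent[:, 7]
    df["recognition_hits"] = np.clip(
        np.round(9.0 + 1.2 * rec + 0.5 * rng.standard_normal(n_subjects)), 0, 10
    )
    df["recognition_correct_rejects"] = np.clip(
        np.round(9.0 + 1.2 * rec + 0.5 * rng.standard_normal(n_subjects)), 0, 10
    )
    # TMT: seconds, log-normal-ish, higher = slower = worse
    df["tmt_a_s"] = 40.0 * np.exp(-0.3 * latent[:, 8])
    df["tmt_b_s"] = 100.0 * np.exp(-0.3 * latent[:, 9])
    df["mmse"] = np.clip(np.round(28.0 + 1.2 * factor), 0, 30)
    return df, factor


def _temporal_profile(t: np.ndarray) -> np.ndarray:
    """Smooth rise-and-sustain precision profile over the epoch."""
    return 1.0 / (1.0 + np.exp(-(t - 0.15) / 0.05))


def gen_tgm(
    n_subjects: int,
    code: str = "stable",
    snr: float = 3.0,
    rng_seed: int = 0,
    n_times: int = 41,
    dt: float = 0.05,
    t0: float = 0.0,
    peak: float = 0.3,
    dynamic_width: float = 0.15,
) -> tuple[list[TGMatrix], dict]:
    """Simulate per-subject TGMs with stable or dynamic coding structure.

    ``stable``: rank-one signal peak·u(x)u(y) — cross-time precision matches
    within-time precision.  ``dynamic``: the same signal attenuated by a
    Gaussian band exp(−(x−y)²/(2·width²)) — off-diagonal precision is
    suppressed beyond ``dynamic_width`` seconds.  Additive i.i.d. Gaussian
    noise with SD peak/snr.  Returns the matrices and a ground-truth dict
    (noiseless signal, code type).
    """
    if code not in ("stable", "dynamic", "noise"):
        raise ValueError(f"unknown code spec {code!r}")
    rng = np.random.default_rng(rng_seed)
    t = t0 + dt * np.arange(n_times)
    u = _temporal_profile(t)
    signal = peak * np.outer(u, u)
    if code == "dynamic":
        band = np.exp(-((t[:, None] - t[None, :]) ** 2) / (2.0 * dynamic_width**2))
        signal = signal * band
    elif code == "noise":
        signal = np.zeros_like(signal)
    noise_sd = peak / snr
    mats = [
        TGMatrix(values=signal + noise_sd * rng.standard_normal(signal.shape), times=t)
        for _ in range(n_subjects)
    ]
    return mats, {"code": code, "signal": signal, "times": t, "noise_sd": noise_sd}
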