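"""Delayed match-to-sample task geometry and trial-sequence generation.

The task presents a sample at one of 12 locations on the lower-hemifield
polar-angle arc, followed after a variable delay by a test stimulus that is
either at the same location ("match"), one grid step away ("near" nonmatch)
or two or more grid steps away ("far" nonmatch).  The 12 sample locations are
strictly inside [0, 180] degrees so that even the extreme samples can be
flanked by a near test on both sides, which yields a 14-point test grid that
includes the endpoints 0 and 180.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "TrialSpec",
    "DEFAULT_CONFIG",
    "sample_locations",
    "test_locations",
    "far_delta_support",
    "generate_block",
    "generate_trials",
    "trials_to_frame",
    "frame_to_trials",
]

TRIAL_COLUMNS = [
    "subject",
    "block",
    "trial",
    "sample_angle_deg",
    "test_angle_deg",
    "delta_deg",
    "delay_s",
    "category",
]


@dataclass(frozen=True)
class TaskConfig:
    """Geometry and composition of the delayed match-to-sample task.

    ``spacing`` is the grid step 180/13 ≈ 13.846°; a block of ``block_size``
    trials contains ``category_counts`` (match, near, far) trials.  The
    printed category mix of 33/33/34% cannot be realized as integers in a
    63-trial block; 21/21/21 is used, which matches the printed 33% for match
    and near trials exactly and keeps blocks deterministic in composition.
    """

    n_sample_locations: int = 12
    angle_min: float = 0.0
    angle_max: float = 180.0
    delays: tuple[float, ...] = (1.0, 3.0, 9.0)
    block_size: int = 63
    category_counts: tuple[int, int, int] = (21, 21, 21)  # match, near, far

    @property
    def spacing(self) -> float:
        """Grid step in degrees: (angle_max - angle_min) / 13 for 12 samples."""
        return (self.angle_max - self.angle_min) / (self.n_sample_locations + 1)

    @property
    def category_mix(self) -> tuple[float, float, float]:
        total = sum(self.category_counts)
        return tuple(c / total for c in self.category_counts)

    def __post_init__(self) -> None:
        if self.n_sample_locations < 1:
            raise ValueError("need at least one sample location")
        if not self.angle_max > self.angle_min:
            raise ValueError("angle_max must exceed angle_min")
        if sum(self.category_counts) != self.block_size:
            raise ValueError("category_counts must sum to block_size")
        if len(self.delays) < 1:
            raise ValueError("need at least one delay")


DEFAULT_CONFIG = TaskConfig()


@dataclass(frozen=True)
class TrialSpec:
    """One task trial: geometry (degrees of polar angle), delay and category."""

    sample_angle: float
    test_angle: float
    delta: float
    delay: float
    category: str  # {"match", "near", "far"}
    block_index: int = 0
    trial_index: int = 0


def sample_locations(config: TaskConfig = DEFAULT_CONFIG) -> np.ndarray:
    """The 12 equiprobable sample locations, strictly inside the arc."""
    s = config.spacing
    return config.angle_min + s * np.arange(1, config.n_sample_locations + 1)


def test_locations(config: TaskConfig = DEFAULT_CONFIG) -> np.ndarray:
    """The 14 possible test locations, spanning the arc endpoints."""
    s = config.spacing
    return config.angle_min + s * np.arange(0, config.n_sample_locations + 2)


def _grid_index(angle: float, config: TaskConfig) -> int:
    """Index of ``angle`` on the sample grid (1..12); raises if off grid."""
    s = config.spacing
    k = (angle - config.angle_min) / s
    ki = int(round(k))
    if abs(k - ki) > 1e-9 or not (1 <= ki <= config.n_sample_locations):
        raise ValueError(f"angle {angle!r} is not on the sample grid")
    return ki


def far_delta_support(
    sample_angle: float, config: TaskConfig = DEFAULT_CONFIG
) -> dict[float, list[int]]:
    """Admissible far sample-test distances for a given sample location.

    Returns a mapping from distance Δ = k × spacing (k ≥ 2) to the list of
    sides (-1 left toward 0°, +1 right toward 180°) on which a test at that
    distance lies on the 14-point test grid.
    """
    i = _grid_index(sample_angle, config)
    n = config.n_sample_locations
    s = config.spacing
    support: dict[float, list[int]] = {}
    for k in range(2, n + 2):
        sides = []
        if i - k >= 0:
            sides.append(-1)
        if i + k <= n + 1:
            sides.append(+1)
        if sides:
            support[k * s] = sides
    return support


def generate_block(
    config: TaskConfig = DEFAULT_CONFIG,
    rng_seed: int | np.random.Generator = 0,
    block_index: int = 0,
) -> list[TrialSpec]:
    """Generate one randomly interleaved block of 63 trials.

    Composition is fixed at the per-block category counts; delays and sample
    locations are drawn i.i.d. equiprobably; near trials flank the sample on
    a uniformly chosen side; far distances are uniform over the admissible
    spacing multiples for the drawn sample location, with the side then
    uniform among sides where that distance is realizable.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    samples = sample_locations(config)
    s = config.spacing
    trials: list[TrialSpec] = []
    categories = (
        ["match"] * config.category_counts[0]
        + ["near"] * config.category_counts[1]
        + ["far"] * config.category_counts[2]
    )
    for category in categories:
        sample = float(rng.choice(samples))
        delay = float(rng.choice(config.delays))
        if category == "match":
            test, delta = sample, 0.0
        elif category == "near":
            side = rng.choice([-1, 1])
            test, delta = sample + side * s, s
        else:
            support = far_delta_support(sample, config)
            delta = float(rng.choice(sorted(support)))
            side = rng.choice(support[delta])
            test = sample + side * delta
        trials.append(
            TrialSpec(
                sample_angle=sample,
                test_angle=float(test),
                delta=float(delta),
                delay=delay,
                category=category,
                block_index=block_index,
            )
        )
    order = rng.permutation(len(trials))
    return [
        TrialSpec(
            sample_angle=trials[j].sample_angle,
            test_angle=trials[j].test_angle,
            delta=trials[j].delta,
            delay=trials[j].delay,
            category=trials[j].category,
            block_index=block_index,
            trial_index=i,
        )
        for i, j in enumerate(order)
    ]


def generate_trials(
    n_blocks: int,
    config: TaskConfig = DEFAULT_CONFIG,
    rng_seed: int | np.random.Generator = 0,
) -> list[TrialSpec]:
    """Concatenate ``n_blocks`` independently generated blocks."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    trials: list[TrialSpec] = []
    for b in range(n_blocks):
        trials.extend(generate_block(config, rng, block_index=b))
    return trials


def trials_to_frame(trials: list[TrialSpec], subject: int | str = 0) -> pd.DataFrame:
    """Tabulate trials with the canonical CSV column layout."""
    return pd.DataFrame(
        {
            "subject": subject,
            "block": [t.block_index for t in trials],
            "trial": [t.trial_index for t in trials],
            "sample_angle_deg": [t.sample_angle for t in trials],
            "test_angle_deg": [t.test_angle for t in trials],
            "delta_deg": [t.delta for t in trials],
            "delay_s": [t.delay for t in trials],
            "category": [t.category for t in trials],
        }
    )


def frame_to_trials(frame: pd.DataFrame) -> list[TrialSpec]:
    return [
        TrialSpec(
            sample_angle=row.sample_angle_deg,
            test_angle=row.test_angle_deg,
            delta=row.delta_deg,
            delay=row.delay_s,
            category=row.category,
            block_index=int(row.block),
            trial_index=int(row.trial),
        )
        for row in frame.itertuples()
    ]
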