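"""Trial/subject exclusion rules, error-rate summaries and SDT metrics.

Conventions follow the task analysis: a hit is a "same" response on a match
trial; a false alarm is a "same" response on a nonmatch trial, computed
separately for near and far nonmatch trials and then averaged.  Sensitivity
is d' = z(H) − z(FA).  The criterion is reported as z(H) + z(FA) (the
convention used alongside this model); the conventional definition
−(z(H)+z(FA))/2 is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SDTMetrics",
    "exclude_trials",
    "exclude_subjects",
    "error_rates",
    "sdt_metrics",
]


@dataclass(frozen=True)
class SDTMetrics:
    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion: float


def exclude_trials(
    responses: pd.DataFrame,
    rt_floor: float = 0.2,
    sd_multiple: float = 4.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply per-subject trial exclusion rules.

    Removes trials flagged as invalid-button presses (``valid_button``
    column, if present), trials with response time ≤ ``rt_floor`` seconds,
    and trials whose response time exceeds the subject's mean by
    ``sd_multiple`` standard deviations.  The mean/SD are computed over each
    subject's valid-button trials in a single pass (i.e. before the floor
    cut).  Trials without a response time pass the RT filters.

    Returns the filtered table and an exclusion log recording the rule
    responsible for each removal.
    """
    df = responses.copy()
    if "subject" not in df.columns:
        df["subject"] = 0
    rt = df["rt_s"] if "rt_s" in df.columns else pd.Series(np.nan, index=df.index)

    reasons = pd.Series(pd.NA, index=df.index, dtype="object")
    if "valid_button" in df.columns:
        bad_button = ~df["valid_button"].astype(bool)
        reasons[bad_button] = "invalid_button"
    else:
        bad_button = pd.Series(False, index=df.index)

    valid_rt = rt.where(~bad_button)
    stats = valid_rt.groupby(df["subject"]).agg(["mean", "std"])
    mean = df["subject"].map(stats["mean"])
    sd = df["subject"].map(stats["std"])

    too_fast = (~bad_button) & (rt <= rt_floor)
    reasons[too_fast & reasons.isna()] = "rt_floor"
    too_slow = (~bad_button) & (rt > mean + sd_multiple * sd)
    reasons[too_slow & reasons.isna()] = "rt_outlier"

    removed = reasons.notna()
    log = pd.DataFrame(
        {
            "subject": df.loc[removed, "subject"],
            "index": df.index[removed],
            "rule": reasons[removed],
            "rt_s": rt[removed],
        }
    ).reset_index(drop=True)
    return df.loc[~removed].copy(), log


def exclude_subjects(
    subject_accuracy: pd.Series | dict, threshold: float = 0.6
) -> tuple[list, list]:
    """Split subjects into kept/excluded by overall task accuracy.

    Exclusion is strict: accuracy *below* the threshold is excluded, the
    boundary value is kept.  (The threshold sits below the 2/3 accuracy a
    subject would reach by always responding "different".)
    """
    acc = pd.Series(subject_accuracy)
    kept = acc.index[acc >= threshold].tolist()
    excluded = acc.index[acc < threshold].tolist()
    return kept, excluded


def error_rates(
    responses: pd.DataFrame, by: tuple[str, ...] = ("delay_s", "category")
) -> pd.DataFrame:
    """Error rates per grouping cell, with SEM across subjects if grouped.

    The error on a match trial is a miss ("different" response); on a
    nonmatch trial it is a false alarm ("same" response).  Empty cells yield
    NaN with a warning.
    """
    if len(responses) == 0:
        raise ValueError("response set is empty")
    df = responses.copy()
    df["error"] = 1 - df["correct"]
    if "subject" in df.columns and df["subject"].nunique() > 1:
        per_subject = (
            df.groupby(["subject", *by], observed=True)["error"].mean().reset_index()
        )
        out = (
            per_subject.groupby(list(by), observed=True)["error"]
            .agg(error_rate="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)))
            .reset_index()
        )
    else:
        out = (
            df.groupby(list(by), observed=True)["error"]
            .agg(error_rate="mean", n="count")
            .reset_index()
        )
    if out["error_rate"].isna().any():
        import warnings

        warnings.warn("empty cells produced NaN error rates")
    return out


def _corrected_rate(k: int, n: int) -> float:
    """Proportion with the 1/(2N) extreme-rate correction."""
    if n == 0:
        raise ValueError("empty trial class")
    rate = k / n
    if rate == 0.0:
        return 1.0 / (2 * n)
    if rate == 1.0:
        return 1.0 - 1.0 / (2 * n)
    return rate


def sdt_metrics(
    responses: pd.DataFrame, criterion_convention: str = "as_printed"
) -> SDTMetrics:
    """Signal-detection sensitivity and criterion for one subject's trials.

    H is the corrected fraction of "same" responses on match trials; FA is
    the mean of the separately corrected near- and far-nonmatch "same"
    fractions.  ``criterion_convention`` selects ``"as_printed"``
    (c = z(H) + z(FA)) or ``"conventional"`` (c = −(z(H)+z(FA))/2).
    """
    match = responses[responses.category == "match"]
    near = responses[responses.category == "near"]
    far = responses[responses.category == "far"]
    if len(match) == 0 or (len(near) + len(far)) == 0:
        raise ValueError("need at least one match and one nonmatch trial")
    same = lambda df: int((df.response == 0).sum())

    H = _corrected_rate(same(match), len(match))
    fa_parts = [
        _corrected_rate(same(df), len(df)) for df in (near, far) if len(df) > 0
    ]
    FA = float(np.mean(fa_parts))
    zH, zFA = norm.ppf(H), norm.ppf(FA)
    if criterion_convention == "as_printed":
        c = zH + zFA
    elif criterion_convention == "conventional":
        c = -0.5 * (zH + zFA)
    else:
        raise ValueError(f"unknown criterion convention {criterion_convention!r}")
    return SDTMetrics(hit_rate=H, fa_rate=FA, d_prime=float(zH - zFA), criterion=float(c))
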