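"""Neuropsychological composite scores for a CERAD-Plus-style battery.

Ten PCA-eligible subtests per subject (MMSE, when present, is kept out of
the PCA): semantic and phonemic fluency, Boston Naming Test, word-list
learning/recall/recognition, constructional praxis and its recall, and
trail-making tests A and B.  Recognition performance enters the battery as
the discriminability score (percent), computed from hits and correct
rejects out of 10 each.  A single summary of cognitive integrity — the PC1
score — is the projection of each subject's z-scored test vector on the
first principal component of the across-subject covariance matrix; the TMT
z-scores are sign-flipped first so higher always means better.  The CERAD
total score is the classical six-test sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PCA_TESTS",
    "CognitiveScores",
    "discriminability",
    "zscore_battery",
    "pc1_scores",
    "cerad_total",
]

# PCA-eligible columns in canonical order; TMT columns are the sign-flipped ones.
PCA_TESTS = (
    "semantic_fluency",
    "phonemic_fluency",
    "bnt",
    "wordlist_learning",
    "wordlist_recall",
    "recognition_discriminability",
    "praxis",
    "praxis_recall",
    "tmt_a_s",
    "tmt_b_s",
)
FLIPPED_TESTS = ("tmt_a_s", "tmt_b_s")


@dataclass
class CognitiveScores:
    pc1_score: pd.Series
    variance_explained: float
    loadings: pd.Series
    cerad_total: pd.Series | None = None


def discriminability(hits: float, correct_rejects: float) -> float:
    """Recognition discriminability, percent: (1 − ((10−H)+(10−CR))/20)·100."""
    hits = np.asarray(hits, dtype=float)
    correct_rejects = np.asarray(correct_rejects, dtype=float)
    if np.any((hits < 0) | (hits > 10)) or np.any(
        (correct_rejects < 0) | (correct_rejects > 10)
    ):
        raise ValueError("hits and correct rejects must lie in [0, 10]")
    out = (1.0 - ((10.0 - hits) + (10.0 - correct_rejects)) / 20.0) * 100.0
    return out if out.ndim else float(out)


def _with_discriminability(battery: pd.DataFrame) -> pd.DataFrame:
    df = battery.copy()
    if "recognition_discriminability" not in df.columns:
        df["recognition_discriminability"] = discriminability(
            df["recognition_hits"].to_numpy(),
            df["recognition_correct_rejects"].to_numpy(),
        )
    return df


def zscore_battery(battery: pd.DataFrame) -> pd.DataFrame:
    """Across-subject z-scores of the ten PCA tests, TMT signs flipped.

    Subjects with any missing test are dropped (and reported via warning),
    mirroring the exclusion of incomplete batteries.  A zero-variance test
    column is an error.
    """
    df = _with_discriminability(battery)
    missing_cols = [c for c in PCA_TESTS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"battery lacks test columns: {missing_cols}")
    data = df[list(PCA_TESTS)]
    incomplete = data.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"dropping {int(incomplete.sum())} subject(s) with incomplete batteries"
        )
        data = data.loc[~incomplete]
    if len(data) < 3:
        raise ValueError("need at least three complete subjects")
    sd = data.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(
            f"zero-variance test column(s): {list(sd.index[sd == 0])}"
        )
    z = (data - data.mean()) / sd
    for col in FLIPPED_TESTS:
        z[col] = -z[col]
    return z


def pc1_scores(z_matrix: pd.DataFrame) -> CognitiveScores:
    """First-principal-component summary of the z-scored battery.

    SVD of the across-subject covariance matrix; PC1 loadings are oriented
    so their sum is positive (the SVD sign being arbitrary) and the PC1
    score is each subject's projection on them.
    """
    n, p = z_matrix.shape
    if n <= p:
        warnings.warn("fewer subjects than tests: PC1 may be unstable")
    cov = np.cov(z_matrix.to_numpy(), rowvar=False, ddof=1)
    u, s, _ = np.linalg.svd(cov)
    if s[0] <= 0 or np.linalg.matrix_rank(cov) < p:
        warnings.warn("rank-deficient covariance matrix")
    loadings = u[:, 0]
    if loadings.sum() < 0:
        loadings = -loadings
    scores = z_matrix.to_numpy() @ loadings
    return CognitiveScores(
        pc1_score=pd.Series(scores, index=z_matrix.index, name="pc1_score"),
        variance_explained=float(s[0] / s.sum()),
        loadings=pd.Series(loadings, index=z_matrix.columns, name="pc1_loading"),
    )


def cerad_total(battery: pd.DataFrame) -> pd.Series:
    """Six-test CERAD total score.

    Semantic fluency capped at 24 points, plus BNT, word-list learning,
    word-list recall, recognition (true positives − false positives, i.e.
    hits − (10 − correct rejects)) and constructional praxis.
    """
    required = [
        "semantic_fluency",
        "bnt",
        "wordlist_learning",
        "wordlist_recall",
        "recognition_hits",
        "recognition_correct_rejects",
        "praxis",
    ]
    missing = [c for c in required if c not in battery.columns]
    if missing:
        raise ValueError(f"battery lacks components: {missing}")
    total = (
        battery["semantic_fluency"].clip(upper=24)
        + battery["bnt"]
        + battery["wordlist_learning"]
        + battery["wordlist_recall"]
        + (battery["recognition_hits"] - (10 - battery["recognition_correct_rejects"]))
        + battery["praxis"]
    )
    return total.rename("cerad_total")
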