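"""Scalar temporal-generalization metrics and the dynamic-coding test.

A temporal generalization matrix (TGM) A holds the decoding precision for a
decoder trained at time x and tested at time y.  Strong off-diagonal
precision indicates a stable neural code; a "dynamic" code shows cross-time
precision significantly below *both* corresponding within-time precisions
(A[x,x] and A[y,y]), assessed by across-subject sign-flip permutation tests
with joint Benjamini–Hochberg FDR correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

__all__ = [
    "TGMatrix",
    "offdiag_sum",
    "wide_offdiag_sum",
    "dynamic_coding_test",
    "read_tgm",
    "write_tgm",
]

DEFAULT_WINDOW = (0.5, 1.5)  # delay-period window, seconds
_TOL = 1e-9


@dataclass(frozen=True)
class TGMatrix:
    """Square decoding-precision matrix with a uniform time axis (seconds)."""

    values: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        t = np.asarray(self.times, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("TGM must be square")
        if len(t) != v.shape[0]:
            raise ValueError("time axis length must match matrix size")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time axis must be strictly increasing")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "times", t)

    def window_indices(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        if lo < self.times[0] - _TOL or hi > self.times[-1] + _TOL:
            raise ValueError("window outside the time axis")
        return np.flatnonzero((self.times >= lo - _TOL) & (self.times <= hi + _TOL))


def offdiag_sum(A: TGMatrix, window: tuple[float, float] = DEFAULT_WINDOW) -> float:
    """Sum of all off-diagonal elements over the window × window block."""
    idx = A.window_indices(window)
    block = A.values[np.ix_(idx, idx)]
    return float(block.sum() - np.trace(block))


def wide_offdiag_sum(
    A: TGMatrix,
    window: tuple[float, float] = DEFAULT_WINDOW,
    min_shift: float = 0.5,
) -> float:
    """Sum over window pairs whose train/test times differ by ≥ min_shift.

    The wider shift removes above-chance generalization attributable solely
    to temporal smoothing of the underlying estimates.  An empty qualifying
    set is flagged with a warning and returns 0.
    """
    idx = A.window_indices(window)
    t = A.times[idx]
    mask = np.abs(t[:, None] - t[None, :]) >= min_shift - _TOL
    if not mask.any():
        warnings.warn("min_shift exceeds the window span: empty sum")
        return 0.0
    return float(A.values[np.ix_(idx, idx)][mask].sum())


def _sign_perm_pvalues(
    diffs: np.ndarray, n_perm: int, rng: np.random.Generator, exhaustive_limit: int
) -> np.ndarray:
    """Two-sided sign-flip permutation p-values, columnwise.

    ``diffs`` has shape (n_subjects, n_tests).  Enumerates all 2^n sign
    patterns when feasible; otherwise Monte-Carlo with the identity pattern
    included (so p ≥ 1/n_perm and the test is valid).
    """
    n = diffs.shape[0]
    obs = np.abs(diffs.mean(axis=0))
    if 2**n <= exhaustive_limit:
        signs = np.array(list(itertools.product((-1.0, 1.0), repeat=n)))
    else:
        signs = rng.choice((-1.0, 1.0), size=(n_perm - 1, n))
        signs = np.vstack([np.ones((1, n)), signs])
    null = np.abs(signs @ diffs) / n
    return (null >= obs[None, :] - _TOL).mean(axis=0)


def dynamic_coding_test(
    A_per_subject: list[TGMatrix],
    window: tuple[float, float] | None = None,
    n_perm: int = 10000,
    alpha: float = 0.05,
    rng_seed: int | None = 0,
    exhaustive_limit: int = 4096,
) -> pd.DataFrame:
    """Test every cross-time element for dynamic coding across subjects.

    For each (x, y), x ≠ y, two paired differences are tested with
    two-sided sign-flip permutation tests across subjects:
    A[x,y] − A[x,x] and A[x,y] − A[y,y].  Both families of p-values are
    Benjamini–Hochberg-corrected jointly; an element is flagged dynamic iff
    both adjusted p-values fall below ``alpha`` (and both differences are
    negative, i.e. cross-time precision is *reduced*).

    Returns a long-format table with one row per cross-time element.
    """
    if len(A_per_subject) < 2:
        raise ValueError("need at least two subjects")
    times = A_per_subject[0].times
    for A in A_per_subject[1:]:
        if len(A.times) != len(times) or np.any(np.abs(A.times - times) > _TOL):
            raise ValueError("subjects have mismatched time axes")
    if window is None:
        idx = np.arange(len(times))
    else:
        idx = A_per_subject[0].window_indices(window)
    stack = np.stack([A.values[np.ix_(idx, idx)] for A in A_per_subject])
    t = times[idx]
    m = len(idx)
    rows, cols = np.where(~np.eye(m, dtype=bool))
    diag = np.einsum("sii->si", stack)
    d_train = stack[:, rows, cols] - diag[:, rows]  # A[x,y] − A[x,x]
    d_test = stack[:, rows, cols] - diag[:, cols]  # A[x,y] − A[y,y]

    rng = np.random.default_rng(rng_seed)
    p_train = _sign_perm_pvalues(d_train, n_perm, rng, exhaustive_limit)
    p_test = _sign_perm_pvalues(d_test, n_perm, rng, exhaustive_limit)
    q = false_discovery_control(np.concatenate([p_train, p_test]), method="bh")
    q_train, q_test = q[: len(p_train)], q[len(p_train):]
    reduced = (d_train.mean(axis=0) < 0) & (d_test.mean(axis=0) < 0)
    return pd.DataFrame(
        {
            "train_time": t[rows],
            "test_time": t[cols],
            "p_vs_train": p_train,
            "p_vs_test": p_test,
            "q_vs_train": q_train,
            "q_vs_test": q_test,
            "dynamic": (q_train < alpha) & (q_test < alpha) & reduced,
        }
    )


def write_tgm(A: TGMatrix, path) -> None:
    """Write a TGM as a delimited grid with a one-line time-axis header."""
    with open(path, "w") as fh:
        fh.write("# times_s\t" + "\t".join(f"{t:.6g}" for t in A.times) + "\n")
        np.savetxt(fh, A.values, delimiter="\t", fmt="%.8g")


def read_tgm(path) -> TGMatrix:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# times_s"):
            raise ValueError("missing time-axis header")
        times = np.array([float(v) for v in header.split("\t")[1:]])
        values = np.loadtxt(fh, delimiter="\t")
    return TGMatrix(values=values, times=times)
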