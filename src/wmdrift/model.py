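"""Generative model of delayed match-to-sample choices.

A remembered location diffuses during the delay (Wiener process with
diffusion coefficient ``sigma_mem``), so the across-trial standard deviation
of the memory trace after a delay of T seconds is sigma_mem * sqrt(T).  At
test, the decision variable x is the absolute distance between the memory
trace and the test stimulus; across trials it follows a normal distribution
centred on the true sample-test distance Δ and folded around zero.  A
logistic decision function with inflection point ``delta_thresh`` (the
decision threshold δ), slope ``sigma_dec`` and symmetric lapse asymptotes
``theta`` maps x onto the probability of a "different" report; with
sigma_dec = 0 the decision function degenerates to a deterministic step
threshold.  A memory-lapse hazard ``lam`` additionally lets the trace vanish
entirely at rate λ per second, in which case the subject guesses (p = 0.5).

Responses are coded "different" = 1, "same" = 0 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr

from .task import TrialSpec, trials_to_frame

__all__ = [
    "ModelParams",
    "DVGrid",
    "REPRESENTATIVE_PARAMS",
    "memory_std",
    "dv_distribution",
    "decision_function",
    "memory_lapse_prob",
    "p_different",
    "p_different_many",
    "simulate_responses",
]

# Representative across-subject parameter values used for the parameter
# recovery simulations (each taken from the fit of the least complex model
# variant that contains the parameter).
REPRESENTATIVE_PARAMS = {
    "sigma_mem": 4.2856,
    "delta_thresh": 11.1370,
    "theta": 0.0203,
    "lam": 0.0049,
    "sigma_dec": 3.0802,
}

GRID_X_MAX = 360.0  # generous upper bound for the decision variable, degrees
GRID_DX = 0.05  # grid resolution, degrees


@dataclass(frozen=True)
class ModelParams:
    """The five generative parameters.

    sigma_mem : memory diffusion coefficient, degrees * s**-0.5
    delta_thresh : decision threshold δ, degrees
    theta : time-independent lapse probability (asymptotes θ and 1-θ)
    lam : memory-lapse hazard rate, s**-1
    sigma_dec : decision-function slope (decision noise), degrees
    """

    sigma_mem: float
    delta_thresh: float
    theta: float = 0.0
    lam: float = 0.0
    sigma_dec: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_mem < 0:
            raise ValueError("sigma_mem must be >= 0")
        if self.delta_thresh < 0:
            raise ValueError("delta_thresh must be >= 0")
        if not 0 <= self.theta <= 0.5:
            raise ValueError("theta must lie in [0, 0.5]")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.sigma_dec < 0:
            raise ValueError("sigma_dec must be >= 0")

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DVGrid:
    """Discretized decision-variable distribution (probability mass per bin)."""

    x: np.ndarray
    dx: float
    masses: np.ndarray


def memory_std(sigma_mem: float, t: float) -> float:
    """Across-trial SD of the memory trace after t seconds of diffusion."""
    if t < 0:
        raise ValueError("elapsed time must be >= 0")
    return sigma_mem * np.sqrt(t)


def _phi(z: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)


def dv_distribution(
    delta: float,
    sigma_T: float,
    x_max: float = GRID_X_MAX,
    dx: float = GRID_DX,
) -> DVGrid:
    """Folded-normal distribution of the decision variable on a fixed grid.

    The bin mass at x is [φ((x−Δ)/σ_T) + φ((x+Δ)/σ_T)] × dx/σ_T evaluated at
    bin midpoints on [0, x_max]; no renormalization is applied (an invariant
    test bounds the truncation loss).  Midpoint placement conserves total
    mass without double-counting the fold point at zero.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if sigma_T <= 0:
        raise ValueError("sigma_T must be > 0 (degenerate case handled by caller)")
    n = int(round(x_max / dx))
    x = (np.arange(n) + 0.5) * dx
    masses = (_phi((x - delta) / sigma_T) + _phi((x + delta) / sigma_T)) * dx / sigma_T
    return DVGrid(x=x, dx=dx, masses=masses)


def decision_function(x, params: ModelParams):
    """Probability of a "different" report given decision variable x.

    Logistic with inflection δ (where the value is exactly 0.5), slope
    sigma_dec and asymptotes θ / 1−θ; a hard step threshold when
    sigma_dec = 0, returning 0.5 at the tie x = δ.
    """
    x = np.asarray(x, dtype=float)
    th, d, sd = params.theta, params.delta_thresh, params.sigma_dec
    if sd > 0:
        out = th + (1.0 - 2.0 * th) * expit((x - d) / sd)
    else:
        out = np.where(x > d, 1.0 - th, np.where(x < d, th, 0.5))
    return out if out.ndim else float(out)


def memory_lapse_prob(lam: float, t: float) -> float:
    """Probability that the memory trace has vanished by time t (hazard λ)."""
    if lam < 0 or t < 0:
        raise ValueError("lam and t must be >= 0")
    return 1.0 - np.exp(-lam * t)


def _core_p_different_grid(params: ModelParams, sigma_T: float, delta: float) -> float:
    if sigma_T == 0.0:
        return float(decision_function(delta, params))
    grid = dv_distribution(delta, sigma_T)
    return float(np.sum(decision_function(grid.x, params) * grid.masses))


def _core_p_different_closed(params: ModelParams, sigma_T: float, delta: float) -> float:
    """Exact step-threshold evaluation (sigma_dec = 0) via the folded CDF."""
    th, d = params.theta, params.delta_thresh
    if sigma_T == 0.0:
        return float(decision_function(delta, params))
    # folded CDF of m ~ N(Δ, σ_T²), truncated at the grid bound as in the
    # reference numerics
    fold_cdf = lambda x: ndtr((x - delta) / sigma_T) - ndtr((-x - delta) / sigma_T)
    below = fold_cdf(min(d, GRID_X_MAX))
    above = fold_cdf(GRID_X_MAX) - below
    return th * below + (1.0 - th) * above


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(129)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(np.pi)

# Nodes for the logistic-correction integral, in units of sigma_dec.  The
# correction kernel expit(u) - step(u) decays like e^{-|u|}, so |u| <= 12
# captures all but ~5e-6 of it; du = 0.05 resolves the kernel (scale 1) and
# the folded density (width sigma_T/sigma_dec >= 1 on this branch, which is
# only taken when sigma_dec <= sigma_T).
_CORR_DU = 0.05
_CORR_HALF = _CORR_DU * np.arange(1, 241)
# exactly symmetric nodes with an exact zero, where the kernel vanishes
_CORR_U = np.concatenate([-_CORR_HALF[::-1], [0.0], _CORR_HALF])
_CORR_KERNEL = expit(_CORR_U) - (_CORR_U > 0) - 0.5 * (_CORR_U == 0)


def _smooth_core_many(
    delta: np.ndarray,
    sigma_T: np.ndarray,
    dthr: np.ndarray,
    theta: np.ndarray,
    sigma_dec: np.ndarray,
) -> np.ndarray:
    """E over the folded-normal DV of the logistic decision function.

    Vectorized over flat arrays (sigma_T > 0, sigma_dec > 0 elementwise);
    the decision variable is truncated at the grid bound (x <= 360), as in
    the reference numerics.  Two regimes: when sigma_dec <= sigma_T, the
    step-threshold folded-CDF term is exact and the remaining logistic
    correction (concentrated around the threshold on the decision-noise
    scale) is integrated with nodes at 0.05·sigma_dec, which also resolves
    the folded density; for slopes wider than the memory spread,
    Gauss–Hermite in the memory trace is used instead (there the integrand
    varies on the slower decision-noise scale and the fold kink at zero is
    weak).
    """
    out = np.empty_like(sigma_T)
    gh = sigma_dec > sigma_T
    if np.any(gh):
        m = np.abs(
            delta[gh, None] + np.sqrt(2.0) * sigma_T[gh, None] * _GH_NODES
        )
        df = theta[gh, None] + (1.0 - 2.0 * theta[gh, None]) * expit(
            (m - dthr[gh, None]) / sigma_dec[gh, None]
        )
        out[gh] = np.where(m <= GRID_X_MAX, df, 0.0) @ _GH_WEIGHTS
    ns = ~gh
    if np.any(ns):
        dd, sT, dt, th, sd = (a[ns] for a in (delta, sigma_T, dthr, theta, sigma_dec))
        fold_cdf = lambda x: ndtr((x - dd) / sT) - ndtr((-x - dd) / sT)
        below = fold_cdf(np.minimum(dt, GRID_X_MAX))
        above = fold_cdf(np.full_like(dd, GRID_X_MAX)) - below
        x = dt[:, None] + sd[:, None] * _CORR_U[None, :]
        # fractional bin coverage of the [0, 360] support at the boundaries
        h = (sd * _CORR_DU)[:, None]
        cover = np.clip(
            (np.minimum(x + 0.5 * h, GRID_X_MAX) - np.maximum(x - 0.5 * h, 0.0)) / h,
            0.0,
            1.0,
        )
        pdf = cover * (
            _phi((x - dd[:, None]) / sT[:, None]) + _phi((x + dd[:, None]) / sT[:, None])
        ) / sT[:, None]
        corr = _CORR_DU * sd * (pdf @ _CORR_KERNEL)
        out[ns] = th * below + (1.0 - th) * above + (1.0 - 2.0 * th) * corr
    return out


def _core_p_different_quad(params: ModelParams, sigma_T: float, delta: float) -> float:
    """Quadrature evaluation of E[DF(|m|)] for the smooth decision function."""
    if sigma_T == 0.0:
        return float(decision_function(delta, params))
    return float(
        _smooth_core_many(
            np.array([delta]),
            np.array([sigma_T]),
            np.array([params.delta_thresh]),
            np.array([params.theta]),
            np.array([params.sigma_dec]),
        )[0]
    )


def p_different(
    params: ModelParams, T: float, delta: float, method: str = "grid"
) -> float:
    """Probability of a "different" response after delay T at distance Δ.

    The choice probability is a mixture of guessing (memory lapse, weight
    θ_mem,T = 1 − e^{−λT}) and the integral of the decision function over the
    folded-normal decision-variable distribution.

    ``method="grid"`` uses the reference dx=0.05 numerical grid;
    ``method="auto"`` uses an exact closed form when sigma_dec = 0 and
    Gauss–Hermite quadrature otherwise (equivalent to the grid well below
    fitting tolerances, but much faster).
    """
    if T < 0:
        raise ValueError("delay must be >= 0")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    sigma_T = memory_std(params.sigma_mem, T)
    if method == "grid":
        core = _core_p_different_grid(params, sigma_T, delta)
    elif method == "auto":
        if params.sigma_dec == 0.0:
            core = _core_p_different_closed(params, sigma_T, delta)
        else:
            core = _core_p_different_quad(params, sigma_T, delta)
    else:
        raise ValueError(f"unknown method {method!r}")
    theta_mem = memory_lapse_prob(params.lam, T)
    return float(theta_mem * 0.5 + (1.0 - theta_mem) * core)


def p_different_many(
    param_matrix: np.ndarray, T: np.ndarray, delta: np.ndarray
) -> np.ndarray:
    """Vectorized choice probabilities for many parameter vectors at once.

    ``param_matrix`` has shape (P, 5) with columns ordered as
    (sigma_mem, delta_thresh, theta, lam, sigma_dec); ``T`` and ``delta`` are
    length-C condition vectors.  Returns an array of shape (P, C).  Uses the
    closed form for rows with sigma_dec = 0 and Gauss–Hermite quadrature for
    the rest; this is the evaluation path used inside the optimizer.
    """
    pm = np.atleast_2d(np.asarray(param_matrix, dtype=float))
    T = np.asarray(T, dtype=float)
    delta = np.asarray(delta, dtype=float)
    sig, d, th, lam, sd = (pm[:, j][:, None] for j in range(5))
    sigma_T = sig * np.sqrt(T)[None, :]
    delta_b = np.broadcast_to(delta[None, :], sigma_T.shape)

    core = np.empty_like(sigma_T)
    step = (pm[:, 4] == 0.0)
    if np.any(step):
        sT = sigma_T[step]
        dd = delta_b[step]
        dt = d[step]
        tht = th[step]
        with np.errstate(divide="ignore", invalid="ignore"):
            fold_cdf = lambda x: ndtr((x - dd) / sT) - ndtr((-x - dd) / sT)
            below = fold_cdf(np.minimum(dt, GRID_X_MAX))
            above = fold_cdf(np.full_like(dd, GRID_X_MAX)) - below
        # σ_T = 0: point mass at Δ — step threshold with 0.5 at the tie
        degen = sT == 0.0
        if np.any(degen):
            below = np.where(
                degen, np.where(dd < dt, 1.0, np.where(dd > dt, 0.0, 0.5)), below
            )
            above = np.where(degen, 1.0 - below, above)
        core[step] = tht * below + (1.0 - tht) * above
    if np.any(~step):
        smooth = ~step
        sT = sigma_T[smooth]
        dd = delta_b[smooth]
        dt = np.broadcast_to(d, sigma_T.shape)[smooth]
        tht = np.broadcast_to(th, sigma_T.shape)[smooth]
        sdt = np.broadcast_to(sd, sigma_T.shape)[smooth]
        vals = np.empty_like(sT)
        degen = sT == 0.0
        if np.any(degen):
            vals[degen] = tht[degen] + (1.0 - 2.0 * tht[degen]) * expit(
                (dd[degen] - dt[degen]) / sdt[degen]
            )
        if np.any(~degen):
            vals[~degen] = _smooth_core_many(
                dd[~degen], sT[~degen], dt[~degen], tht[~degen], sdt[~degen]
            )
        core[smooth] = vals
    theta_mem = 1.0 - np.exp(-lam * T[None, :])
    return theta_mem * 0.5 + (1.0 - theta_mem) * core


def simulate_responses(
    params: ModelParams,
    trials: list[TrialSpec] | pd.DataFrame,
    rng_seed: int | np.random.Generator = 0,
    subject: int | str = 0,
) -> pd.DataFrame:
    """Simulate same/different reports for a list of trials.

    Returns the trial table with ``response`` (1 = "different"), ``correct``
    and an empty ``rt_s`` column (the model is response-time free).
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    frame = (
        trials.copy()
        if isinstance(trials, pd.DataFrame)
        else trials_to_frame(trials, subject=subject)
    )
    cells = frame[["delay_s", "delta_deg"]].drop_duplicates()
    probs = {
        (t, dl): p_different(params, t, dl, method="auto")
        for t, dl in zip(cells.delay_s, cells.delta_deg)
    }
    p = np.array([probs[(t, dl)] for t, dl in zip(frame.delay_s, frame.delta_deg)])
    response = (rng.random(len(frame)) < p).astype(int)
    is_match = (frame.category == "match").to_numpy()
    frame["response"] = response
    frame["correct"] = np.where(is_match, response == 0, response == 1).astype(int)
    frame["rt_s"] = np.nan
    return frame
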