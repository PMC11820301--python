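"""Detrended fluctuation analysis (DFA).

DFA quantifies long-range correlation in a (possibly nonstationary) series
q(t).  The series is mean-centred and integrated into a profile y(m); the
profile is cut into non-overlapping windows of length n, a polynomial trend
is removed per window, and the root-mean-square of the detrended residual
gives the fluctuation F(n).  A power law F(n) ~ n^alpha identifies the
scaling exponent alpha as the slope of log F against log n:

    alpha < 0.5   anticorrelated
    alpha = 0.5   white noise
    0.5 < alpha < 1   long-range correlated (LRC)
    alpha >= 1    nonstationary

The default analysis grid is window lengths 50..500 in steps of 10 with
first-order (linear) detrending.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .signal_model import InvalidInputError


class Regime(str, Enum):
    ANTICORRELATED = "anticorrelated"
    WHITE_NOISE = "white_noise"
    LRC = "lrc"
    NONSTATIONARY = "nonstationary"


class DegenerateSignalError(ValueError):
    """The fluctuation vanished somewhere on the grid (constant input)."""


@dataclass
class DFAConfig:
    n_min: int = 50
    n_max: int = 500
    n_step: int = 10
    detrend_degree: int = 1
    #: also partition the profile from the tail and pool both passes, so the
    #: discarded remainder contributes; off by default (single forward pass)
    reverse_pass: bool = False

    def __post_init__(self) -> None:
        if not (2 < self.n_min < self.n_max):
            raise InvalidInputError("need 2 < n_min < n_max")
        if self.n_step < 1 or self.detrend_degree < 0:
            raise InvalidInputError("n_step >= 1 and detrend_degree >= 0 required")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.n_min, self.n_max + 1, self.n_step)


@dataclass
class DFAResult:
    n_grid: np.ndarray
    F: np.ndarray
    alpha: float
    intercept: float
    r_squared: float
    regime: Regime

    def __post_init__(self) -> None:
        self.n_grid = np.asarray(self.n_grid, dtype=int)
        self.F = np.asarray(self.F, dtype=float)
        if self.F.size != self.n_grid.size:
            raise InvalidInputError("F and n_grid must have matching lengths")


def profile(q: Sequence[float]) -> np.ndarray:
    """Integrated, mean-centred series: y(m) = sum_{k<=m} (q_k - mean(q))."""
    q = np.asarray(q, dtype=float)
    if q.size < 2:
        raise InvalidInputError("need at least 2 samples")
    return np.cumsum(q - q.mean())


def _window_sq_residuals(y: np.ndarray, n: int, degree: int) -> np.ndarray:
    k = y.size // n
    Y = y[: k * n].reshape(k, n).T  # (n, k): windows as columns
    x = np.arange(n, dtype=float)
    X = np.vander(x, degree + 1, increasing=True)  # shared design matrix
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return np.ravel(resid**2)


def fluctuation(y: Sequence[float], n: int, degree: int = 1, reverse_pass: bool = False) -> float:
    """RMS of the window-detrended profile for one window length n.

    The profile is cut into floor(len/n) non-overlapping windows starting at
    index 0 (tail remainder discarded); an ordinary-least-squares polynomial
    of the given degree is removed per window; the RMS over all retained
    samples is returned.  With ``reverse_pass`` the profile is additionally
    partitioned from the tail and the squared residuals of both passes are
    pooled, so the remainder samples also contribute.
    """
    y = np.asarray(y, dtype=float)
    if n > y.size:
        raise InvalidInputError(f"window {n} exceeds series length {y.size}")
    sq = _window_sq_residuals(y, n, degree)
    if reverse_pass:
        sq = np.concatenate([sq, _window_sq_residuals(y[::-1], n, degree)])
    return float(np.sqrt(np.mean(sq)))


def _fluctuations_on_grid(y: np.ndarray, cfg: DFAConfig) -> np.ndarray:
    return np.array(
        [fluctuation(y, int(n), cfg.detrend_degree, cfg.reverse_pass) for n in cfg.grid]
    )


def classify_alpha(alpha: float) -> Regime:
    """Map a scaling exponent onto its correlation regime."""
    if not np.isfinite(alpha):
        raise InvalidInputError("alpha must be finite")
    if alpha >= 1.0:
        return Regime.NONSTATIONARY
    if alpha == 0.5:
        return Regime.WHITE_NOISE
    if alpha < 0.5:
        return Regime.ANTICORRELATED
    return Regime.LRC


def dfa_alpha(q: Sequence[float], cfg: DFAConfig | None = None) -> DFAResult:
    """Scaling exponent of q over the configured window grid.

    alpha and the intercept come from an unweighted least-squares fit of
    ln F(n) on ln n over every grid point; the series must be at least twice
    n_max long so the largest window still yields two windows.
    """
    cfg = cfg or DFAConfig()
    q = np.asarray(q, dtype=float)
    if q.size < 2 * cfg.n_max:
        raise InvalidInputError(
            f"series length {q.size} < 2 * n_max = {2 * cfg.n_max}"
        )
    y = profile(q)
    F = _fluctuations_on_grid(y, cfg)
    if np.any(F <= 0):
        raise DegenerateSignalError("zero fluctuation on the grid (constant signal?)")
    ln_n = np.log(cfg.grid.astype(float))
    ln_F = np.log(F)
    A = np.vstack([ln_n, np.ones_like(ln_n)]).T
    (alpha, intercept), res, *_ = np.linalg.lstsq(A, ln_F, rcond=None)
    ss_tot = float(np.sum((ln_F - ln_F.mean()) ** 2))
    ss_res = float(np.sum((ln_F - A @ np.array([alpha, intercept])) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DFAResult(
        n_grid=cfg.grid,
        F=F,
        alpha=float(alpha),
        intercept=float(intercept),
        r_squared=r2,
        regime=classify_alpha(float(alpha)),
    )
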