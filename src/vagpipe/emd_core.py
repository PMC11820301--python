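"""Classical empirical mode decomposition (EMD).

The decomposition writes the input x(t) as a sum of intrinsic mode
functions (IMFs) plus a residual,

    x(t) = sum_j c_j(t) + r(t),

where each IMF is produced by *sifting*: cubic-spline envelopes are fitted
through the local maxima and minima, and their mean is subtracted until the
candidate satisfies the two IMF conditions (extrema and zero-crossing counts
differ by at most one; the envelope mean is negligibly small) or a
Cauchy-type SD stopping criterion fires.

The numerical kernels (extrema scan, natural cubic spline with mirrored
boundary extrema, envelope mean) are numba-compiled: EEMD calls them
hundreds of times per recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .signal_model import InvalidInputError, Recording


class NotSiftableError(ValueError):
    """Signal has too few extrema (or is constant) to be decomposed."""


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _local_extrema(x):
    """Strict interior extrema; a flat plateau reports its midpoint once."""
    n = x.shape[0]
    maxi = np.empty(n, np.int64)
    mini = np.empty(n, np.int64)
    nmax = 0
    nmin = 0
    i = 1
    while i < n - 1:
        if x[i] == x[i - 1]:
            i += 1
            continue
        j = i
        while j + 1 < n and x[j + 1] == x[j]:
            j += 1
        if j >= n - 1:
            break
        if x[i] > x[i - 1] and x[j] > x[j + 1]:
            maxi[nmax] = (i + j) // 2
            nmax += 1
        elif x[i] < x[i - 1] and x[j] < x[j + 1]:
            mini[nmin] = (i + j) // 2
            nmin += 1
        i = j + 1
    return maxi[:nmax], mini[:nmin]


@njit(cache=True)
def _zero_crossings(x):
    """Strict sign changes; a run of exact zeros counts as one crossing."""
    n = x.shape[0]
    count = 0
    prev = 0.0
    i = 0
    while i < n:
        if x[i] == 0.0:
            count += 1
            while i < n and x[i] == 0.0:
                i += 1
            if i < n:
                prev = x[i]
            i += 1
            continue
        if prev != 0.0 and ((x[i] > 0.0) != (prev > 0.0)):
            count += 1
        prev = x[i]
        i += 1
    return count


@njit(cache=True)
def _natural_spline_eval(xk, yk, xq):
    """Natural cubic spline through (xk, yk), evaluated at sorted xq."""
    m = xk.shape[0]
    out = np.empty(xq.shape[0])
    if m == 1:
        out[:] = yk[0]
        return out
    if m == 2:
        slope = (yk[1] - yk[0]) / (xk[1] - xk[0])
        for q in range(xq.shape[0]):
            out[q] = yk[0] + slope * (xq[q] - xk[0])
        return out
    h = np.empty(m - 1)
    for i in range(m - 1):
        h[i] = xk[i + 1] - xk[i]
    # Thomas algorithm for interior second derivatives, natural BC
    M = np.zeros(m)
    a = np.empty(m - 2)
    b = np.empty(m - 2)
    c = np.empty(m - 2)
    d = np.empty(m - 2)
    for i in range(1, m - 1):
        a[i - 1] = h[i - 1]
        b[i - 1] = 2.0 * (h[i - 1] + h[i])
        c[i - 1] = h[i]
        d[i - 1] = 6.0 * ((yk[i + 1] - yk[i]) / h[i] - (yk[i] - yk[i - 1]) / h[i - 1])
    for i in range(1, m - 2):
        w = a[i] / b[i - 1]
        b[i] -= w * c[i - 1]
        d[i] -= w * d[i - 1]
    if m > 2:
        M[m - 2] = d[m - 3] / b[m - 3]
        for i in range(m - 4, -1, -1):
            M[i + 1] = (d[i] - c[i] * M[i + 2]) / b[i]
    seg = 0
    for q in range(xq.shape[0]):
        xv = xq[q]
        while seg < m - 2 and xv > xk[seg + 1]:
            seg += 1
        hi = h[seg]
        t0 = xk[seg + 1] - xv
        t1 = xv - xk[seg]
        out[q] = (
            M[seg] * t0 * t0 * t0 / (6.0 * hi)
            + M[seg + 1] * t1 * t1 * t1 / (6.0 * hi)
            + (yk[seg] / hi - M[seg] * hi / 6.0) * t0
            + (yk[seg + 1] / hi - M[seg + 1] * hi / 6.0) * t1
        )
    return out


@njit(cache=True)
def _mirror_knots(idx, vals, n, n_mirror):
    """Extend extrema beyond both ends by mirroring up to n_mirror of them."""
    k = idx.shape[0]
    nl = min(n_mirror, k)
    nr = min(n_mirror, k)
    xk = np.empty(k + nl + nr)
    yk = np.empty(k + nl + nr)
    for j in range(nl):
        xk[nl - 1 - j] = -float(idx[j])
        yk[nl - 1 - j] = vals[j]
    for j in range(k):
        xk[nl + j] = float(idx[j])
        yk[nl + j] = vals[j]
    for j in range(nr):
        xk[nl + k + j] = 2.0 * (n - 1) - float(idx[k - 1 - j])
        yk[nl + k + j] = vals[k - 1 - j]
    # drop duplicated abscissae (extremum exactly at an end)
    keep = np.empty(xk.shape[0], np.bool_)
    keep[0] = True
    for j in range(1, xk.shape[0]):
        keep[j] = xk[j] > xk[j - 1]
    return xk[keep], yk[keep]


@njit(cache=True)
def _envelopes_kernel(x, maxi, mini, n_mirror):
    n = x.shape[0]
    xq = np.arange(n).astype(np.float64)
    xk_u, yk_u = _mirror_knots(maxi, x[maxi], n, n_mirror)
    xk_l, yk_l = _mirror_knots(mini, x[mini], n, n_mirror)
    upper = _natural_spline_eval(xk_u, yk_u, xq)
    lower = _natural_spline_eval(xk_l, yk_l, xq)
    return upper, lower


@njit(cache=True)
def _sift_one(x, max_iters, sd_threshold, tol_mean, n_mirror):
    """Extract one IMF from x; returns (imf, ok)."""
    h = x.copy()
    ok = False
    for _ in range(max_iters):
        maxi, mini = _local_extrema(h)
        if maxi.shape[0] < 1 or mini.shape[0] < 1:
            return h, False
        upper, lower = _envelopes_kernel(h, maxi, mini, n_mirror)
        mean = 0.5 * (upper + lower)
        # IMF test on the current candidate
        n_ext = maxi.shape[0] + mini.shape[0]
        n_zc = _zero_crossings(h)
        sd_h = h.std()
        if sd_h > 0.0 and abs(n_ext - n_zc) <= 1 and np.abs(mean).max() <= tol_mean * sd_h:
            ok = True
            break
        h_new = h - mean
        num = 0.0
        den = 0.0
        for i in range(h.shape[0]):
            diff = h[i] - h_new[i]
            num += diff * diff
            den += h[i] * h[i]
        h = h_new
        if den > 0.0 and num / den < sd_threshold:
            ok = True
            break
    return h, ok


@njit(cache=True)
def _is_monotone(x):
    up = True
    down = True
    for i in range(1, x.shape[0]):
        if x[i] > x[i - 1]:
            down = False
        elif x[i] < x[i - 1]:
            up = False
    return up or down


@njit(cache=True)
def _emd_kernel(x, max_imfs, max_iters, sd_threshold, tol_mean, n_mirror):
    n = x.shape[0]
    imfs = np.empty((max_imfs, n))
    residual = x.copy()
    count = 0
    for _ in range(max_imfs):
        maxi, mini = _local_extrema(residual)
        if maxi.shape[0] + mini.shape[0] < 3 or _is_monotone(residual):
            break
        imf, ok = _sift_one(residual, max_iters, sd_threshold, tol_mean, n_mirror)
        if not ok:
            break
        imfs[count] = imf
        residual = residual - imf
        count += 1
    return imfs[:count], residual


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def default_max_imfs(length: int) -> int:
    """Dyadic bound on the number of extractable modes."""
    return max(1, int(np.floor(np.log2(length))) - 1)


@dataclass
class SiftConfig:
    """Sifting controls.

    ``sd_threshold`` is the Cauchy-type stop (sum of squared sift-to-sift
    change over the candidate's energy); ``tol_mean`` bounds the residual
    envelope mean relative to the candidate's standard deviation;
    ``envelope_extension`` is the number of extrema mirrored past each end
    before spline fitting.
    """

    max_imfs: int | None = None
    max_sift_iters: int = 50
    sd_threshold: float = 0.2
    tol_mean: float = 0.05
    envelope_extension: int = 2

    def __post_init__(self) -> None:
        if self.max_imfs is not None and self.max_imfs < 1:
            raise InvalidInputError("max_imfs must be >= 1")
        if self.max_sift_iters < 1 or self.sd_threshold <= 0:
            raise InvalidInputError("max_sift_iters >= 1 and sd_threshold > 0 required")

    def resolve_max_imfs(self, length: int) -> int:
        return self.max_imfs if self.max_imfs is not None else default_max_imfs(length)


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus residual for one recording."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    source_length: int

    def __post_init__(self) -> None:
        self.imfs = [np.asarray(c, dtype=float) for c in self.imfs]
        self.residual = np.asarray(self.residual, dtype=float)
        for c in self.imfs:
            if c.size != self.source_length:
                raise InvalidInputError("every IMF must match the source length")
        if self.residual.size != self.source_length:
            raise InvalidInputError("residual must match the source length")

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """Element-wise sum of all IMFs plus the residual."""
        total = self.residual.copy()
        for c in self.imfs:
            total += c
        return total

    def as_matrix(self) -> np.ndarray:
        """IMFs stacked as rows, residual last: shape (n_imfs + 1, length)."""
        return np.vstack(self.imfs + [self.residual]) if self.imfs else self.residual[None, :]


def find_extrema(samples: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima (plateau midpoints once)."""
    x = np.ascontiguousarray(samples, dtype=float)
    if x.size < 3:
        raise InvalidInputError("need at least 3 samples to find extrema")
    return _local_extrema(x)


def count_zero_crossings(samples: Sequence[float]) -> int:
    """Strict sign changes; runs of exact zeros count once."""
    return int(_zero_crossings(np.ascontiguousarray(samples, dtype=float)))


def envelopes(
    samples: Sequence[float],
    maxima: np.ndarray,
    minima: np.ndarray,
    extension: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper/lower natural-cubic-spline envelopes and their mean.

    Extrema are mirrored past both ends (``extension`` per end) before the
    spline fit so the envelopes do not swing freely at the boundaries.
    """
    x = np.ascontiguousarray(samples, dtype=float)
    maxima = np.asarray(maxima, dtype=np.int64)
    minima = np.asarray(minima, dtype=np.int64)
    if maxima.size < 1 or minima.size < 1:
        raise NotSiftableError("need at least one maximum and one minimum")
    upper, lower = _envelopes_kernel(x, maxima, minima, extension)
    return upper, lower, 0.5 * (upper + lower)


def is_imf(candidate: Sequence[float], tol_mean: float = 0.05) -> bool:
    """Check the two IMF conditions.

    True iff the extrema and zero-crossing counts differ by at most one and
    the local-envelope mean is everywhere below ``tol_mean`` times the
    candidate's standard deviation.
    """
    x = np.ascontiguousarray(candidate, dtype=float)
    if x.size < 3:
        raise InvalidInputError("candidate too short")
    try:
        maxima, minima = find_extrema(x)
        _, _, mean = envelopes(x, maxima, minima)
    except NotSiftableError:
        return False
    sd = x.std()
    if sd == 0:
        return False
    n_ext = maxima.size + minima.size
    n_zc = count_zero_crossings(x)
    return abs(n_ext - n_zc) <= 1 and float(np.abs(mean).max()) <= tol_mean * sd


def emd(recording: Recording | Sequence[float], cfg: SiftConfig | None = None) -> IMFSet:
    """Full decomposition into IMFs plus a residual.

    Accepts a :class:`Recording` or a bare sample sequence.  Extraction
    stops when the residual is monotone, has fewer than 3 extrema, or the
    mode budget is exhausted; the completeness identity
    ``x == sum(imfs) + residual`` holds to machine precision by
    construction.
    """
    cfg = cfg or SiftConfig()
    x = np.ascontiguousarray(
        recording.samples if isinstance(recording, Recording) else recording, dtype=float
    )
    if x.size < 3:
        raise InvalidInputError("signal too short to decompose")
    if np.ptp(x) == 0:
        raise NotSiftableError("constant signal cannot be decomposed")
    max_imfs = cfg.resolve_max_imfs(x.size)
    imfs, residual = _emd_kernel(
        x, max_imfs, cfg.max_sift_iters, cfg.sd_threshold, cfg.tol_mean, cfg.envelope_extension
    )
    return IMFSet(imfs=[imfs[j] for j in range(imfs.shape[0])], residual=residual, source_length=x.size)
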