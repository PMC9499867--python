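"""Robust locally weighted regression (rlowess) with a count-based span.

Local linear fits over the ``span_points`` nearest neighbours of each
observation with tricube distance weights, followed by robust re-weighting
iterations: residuals are scaled by six times their median absolute value
and down-weighted with the bisquare function; residuals at or beyond that
scale get weight zero.  This mirrors the classic robust LOWESS smoother
whose span is an observation count rather than a fraction.

Because the abscissae are sorted, each neighbourhood is a contiguous
window located by a two-pointer sweep; the hot path is a compiled kernel
(numba) so that thousand-replicate bootstrap smoothing stays cheap, with
an equivalent vectorized numpy implementation as fallback.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dep in practice
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

#: robust re-weighting passes after the initial fit
ROBUST_ITERATIONS = 5


@njit(cache=True)
def _rlowess_kernel(x, y, span, robust_iterations):  # pragma: no cover - jit
    n = x.size
    lo = np.empty(n, np.int64)
    hi = np.empty(n, np.int64)  # inclusive
    dmax = np.empty(n, np.float64)
    a = 0
    for i in range(n):
        if a < i - span + 1:
            a = i - span + 1
        amax = i if i < n - span else n - span
        while a < amax and (x[i] - x[a]) > (x[a + span] - x[i]):
            a += 1
        lo[i] = a
        hi[i] = a + span - 1
        left = x[i] - x[a]
        right = x[a + span - 1] - x[i]
        dmax[i] = left if left > right else right
        if dmax[i] <= 0.0:
            # > span exact ties: the neighbourhood is the whole tie run
            while lo[i] > 0 and x[lo[i] - 1] == x[i]:
                lo[i] -= 1
            while hi[i] < n - 1 and x[hi[i] + 1] == x[i]:
                hi[i] += 1

    width = 0
    for i in range(n):
        w = hi[i] - lo[i] + 1
        if w > width:
            width = w
    tri = np.zeros((n, width), np.float64)
    for i in range(n):
        if dmax[i] <= 0.0:
            for k in range(hi[i] - lo[i] + 1):
                tri[i, k] = 1.0 if x[lo[i] + k] == x[i] else 0.0
        else:
            for k in range(hi[i] - lo[i] + 1):
                u = abs(x[lo[i] + k] - x[i]) / dmax[i]
                if u < 1.0:
                    w = 1.0 - u * u * u
                    tri[i, k] = w * w * w

    rw = np.ones(n, np.float64)
    fitted = np.empty(n, np.float64)
    resid = np.empty(n, np.float64)
    for it in range(robust_iterations + 1):
        for i in range(n):
            s0 = 0.0
            s1 = 0.0
            s2 = 0.0
            t0 = 0.0
            t1 = 0.0
            base = lo[i]
            for k in range(hi[i] - base + 1):
                j = base + k
                w = tri[i, k] * rw[j]
                if w > 0.0:
                    dx = x[j] - x[i]
                    s0 += w
                    s1 += w * dx
                    s2 += w * dx * dx
                    t0 += w * y[j]
                    t1 += w * dx * y[j]
            denom = s0 * s2 - s1 * s1
            scale = s0 * s2 if s0 * s2 > s1 * s1 else s1 * s1
            if denom > 1e-12 * (scale if scale > 1e-300 else 1e-300):
                fitted[i] = (s2 * t0 - s1 * t1) / denom
            elif s0 > 0.0:
                fitted[i] = t0 / s0
            else:
                fitted[i] = 0.0
        if it == robust_iterations:
            break
        for i in range(n):
            resid[i] = abs(y[i] - fitted[i])
        s = 6.0 * np.median(resid)
        ymax = 0.0
        for i in range(n):
            if abs(y[i]) > ymax:
                ymax = abs(y[i])
        if s <= 1e-9 * ymax or s <= 0.0:
            break  # residuals at rounding level: the fit interpolates
        for i in range(n):
            r = (y[i] - fitted[i]) / s
            if r < 1.0 and r > -1.0:
                t = 1.0 - r * r
                rw[i] = t * t
            else:
                rw[i] = 0.0
    return fitted


def _rlowess_numpy(x, y, span_points, robust_iterations):
    """Vectorized reference implementation (used when numba is absent)."""
    n = x.size
    d = np.abs(x[:, None] - x[None, :])
    dmax = np.partition(d, span_points - 1, axis=1)[:, span_points - 1]
    degenerate = dmax <= 0
    u = d / np.where(degenerate, 1.0, dmax)[:, None]
    tri = np.clip(1.0 - u ** 3, 0.0, None) ** 3
    if degenerate.any():
        tri[degenerate] = (d[degenerate] == 0.0).astype(float)

    dx = x[None, :] - x[:, None]  # signed, per-point-centred abscissae
    robust_w = np.ones(n)
    fitted = y.astype(float, copy=True)
    for it in range(robust_iterations + 1):
        W = tri * robust_w
        S0 = W.sum(axis=1)
        S1c = (W * dx).sum(axis=1)
        S2c = (W * dx * dx).sum(axis=1)
        T0 = W @ y
        T1c = (W * dx) @ y
        denom = S0 * S2c - S1c * S1c
        scale = np.maximum(S0 * S2c, S1c * S1c)
        ok = denom > 1e-12 * np.maximum(scale, 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            linear = (S2c * T0 - S1c * T1c) / np.where(ok, denom, 1.0)
            mean = T0 / np.where(S0 > 0, S0, 1.0)
        fitted = np.where(ok, linear, np.where(S0 > 0, mean, 0.0))
        if it == robust_iterations:
            break
        resid = y - fitted
        s = 6.0 * np.median(np.abs(resid))
        if s <= 1e-9 * np.max(np.abs(y)) or s <= 0:
            break  # residuals at rounding level: the fit interpolates
        r = resid / s
        robust_w = np.where(np.abs(r) < 1.0, (1.0 - r * r) ** 2, 0.0)
    return fitted


def rlowess_smooth(x, y, span_points: int,
                   robust_iterations: int = ROBUST_ITERATIONS) -> np.ndarray:
    """Smooth ``y`` over sorted ``x`` and return the fitted values.

    Parameters
    ----------
    x : array-like
        Sorted (nondecreasing) predictor values; ties allowed.
    y : array-like
        Responses, same length as ``x``.
    span_points : int
        Number of nearest observations in each local fit (>= 3).
    robust_iterations : int
        Bisquare re-weighting passes after the initial tricube fit.

    Notes
    -----
    Boundary neighbourhoods are asymmetric (no reflection).  Where a
    weighted neighbourhood is degenerate in ``x`` (all mass on one
    abscissa) the fit falls back to the weighted mean.
    """
    x = np.ascontiguousarray(x, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if span_points < 3:
        raise ValueError("span_points must be >= 3")
    if span_points > n:
        raise ValueError(
            f"span_points={span_points} exceeds n={n}: clamp the span to n "
            "or resample the data before smoothing")
    if np.any(np.diff(x) < 0):
        raise ValueError("x must be sorted ascending")
    if _HAVE_NUMBA:
        return _rlowess_kernel(x, y, span_points, robust_iterations)
    return _rlowess_numpy(x, y, span_points, robust_iterations)
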