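"""Two-pass (offline) DFA, DCCA and the detrended cross-correlation coefficient.

These are the classical whole-signal implementations: integrate the series,
split the profile into windows of size ``s``, remove a least-squares linear
trend from every window, and average the residual (co)variance across
windows.  They serve both as reference analyses in their own right and as the
ground truth against which the one-pass streaming engines are validated.

Two window layouts are provided: the sliding variant averages over all
``N - s + 1`` overlapping windows, while the blocked variant uses the
``floor(N/s)`` consecutive non-overlapping windows that the streaming
algorithm also visits.

Normalization note: the residual covariance in a window can be divided by
``s`` or by ``s - 1``.  Both conventions appear in the literature; the
default here is ``1/s``, which is what the one-pass formulas implement, so
that offline and online results are directly comparable.  Pass
``norm="s-1"`` for the unbiased-covariance flavour.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .scales import ScaleSet

__all__ = [
    "integrate",
    "ols_trend",
    "window_detrended_cov",
    "dcca_sliding",
    "dcca_blocked",
    "dfa_blocked",
    "dccc",
    "fit_exponent",
    "cross_scaling_exponent",
]


def _check_series(x, name: str = "series") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"{name} must be 1-D, got shape {x.shape}")
    if x.size < 2:
        raise ValueError(f"{name} must have at least 2 samples, got {x.size}")
    bad = np.flatnonzero(~np.isfinite(x))
    if bad.size:
        raise ValueError(f"non-finite value in {name} at index {bad[0]}")
    return x


def integrate(x) -> np.ndarray:
    """Cumulative sum (the 'profile') of a series.

    DFA/DCCA operate on the integrated signal ``X(t) = sum_{i<=t} x(i)``.
    """
    return np.cumsum(_check_series(x))


def _norm_value(s: int, norm: str) -> float:
    if norm == "s":
        return float(s)
    if norm == "s-1":
        return float(s - 1)
    raise ValueError(f"norm must be 's' or 's-1', got {norm!r}")


def ols_trend(segment) -> tuple[float, float]:
    """Ordinary least-squares linear trend of a window.

    The regressor is the relative (1-based) within-window index
    ``i = 1..s``.  Returns ``(m, b)`` minimizing
    ``sum_i (segment[i] - m*i - b)**2``.
    """
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 1 or seg.size < 2:
        raise ValueError(f"window must be 1-D with length >= 2, got shape {seg.shape}")
    s = seg.size
    i = np.arange(1.0, s + 1.0)
    A = np.column_stack([i, np.ones(s)])
    (m, b), *_ = np.linalg.lstsq(A, seg, rcond=None)
    return float(m), float(b)


def window_detrended_cov(Xseg, Yseg, norm: str = "s") -> float:
    """Detrended covariance of one pair of integrated-profile windows.

    Each window is independently detrended by its own OLS line; the residual
    cross products are summed and divided by ``s`` (or ``s - 1``).
    """
    Xseg = np.asarray(Xseg, dtype=float)
    Yseg = np.asarray(Yseg, dtype=float)
    if Xseg.shape != Yseg.shape:
        raise ValueError(f"window length mismatch: {Xseg.shape} vs {Yseg.shape}")
    s = Xseg.size
    if s < 3:
        raise ValueError(f"window length must be >= 3, got {s}")
    i = np.arange(1.0, s + 1.0)
    mx, bx = ols_trend(Xseg)
    my, by = ols_trend(Yseg)
    rx = Xseg - (mx * i + bx)
    ry = Yseg - (my * i + by)
    return float(np.dot(rx, ry) / _norm_value(s, norm))


def _windowed_detrended_products(Xw: np.ndarray, Yw: np.ndarray) -> np.ndarray:
    """Residual-product sums per window for stacked windows (n_win, s)."""
    s = Xw.shape[1]
    i = np.arange(1.0, s + 1.0)
    # polyfit over multiple right-hand sides: one column per window
    cx = np.polyfit(i, Xw.T, 1)  # (2, n_win): slope, intercept
    cy = np.polyfit(i, Yw.T, 1)
    rx = Xw - (np.outer(cx[0], i) + cx[1][:, None])
    ry = Yw - (np.outer(cy[0], i) + cy[1][:, None])
    return np.einsum("ws,ws->w", rx, ry)


def dcca_sliding(x, y, s: int, norm: str = "s") -> float:
    """Sliding-window detrended covariance ``F2(s)``.

    Averages the per-window detrended covariance over all ``N - s + 1``
    overlapping windows of the integrated profiles.  With ``y is x`` this is
    the (squared) sliding-window DFA fluctuation function.
    """
    X = integrate(x)
    Y = X if y is x else integrate(y)
    N = X.size
    s = int(s)
    if not 3 <= s <= N:
        raise ValueError(f"scale s={s} must satisfy 3 <= s <= N={N}")
    Xw = np.lib.stride_tricks.sliding_window_view(X, s)
    Yw = np.lib.stride_tricks.sliding_window_view(Y, s)
    prods = _windowed_detrended_products(np.ascontiguousarray(Xw), np.ascontiguousarray(Yw))
    return float(prods.mean() / _norm_value(s, norm))


def _blocked_f2(X: np.ndarray, Y: np.ndarray, s: int, norm: str) -> float:
    n_win = X.size // s
    Xw = X[: n_win * s].reshape(n_win, s)
    Yw = Y[: n_win * s].reshape(n_win, s)
    prods = _windowed_detrended_products(Xw, Yw)
    return float(prods.mean() / _norm_value(s, norm))


def _scales_tuple(scales) -> tuple[int, ...]:
    if isinstance(scales, ScaleSet):
        return scales.scales
    return tuple(int(s) for s in scales)


def dcca_blocked(x, y, scales, norm: str = "s") -> np.ndarray:
    """Non-overlapping-window detrended covariance ``F2(s)`` per scale.

    The profile is cut into ``floor(N/s)`` consecutive windows at each scale;
    this is the layout the streaming engine reproduces, so with ``W = N`` the
    online estimate matches this function at machine precision.
    """
    X = integrate(x)
    Y = X if y is x else integrate(y)
    ss = _scales_tuple(scales)
    if ss[-1] > X.size:
        raise ValueError(f"s_max={ss[-1]} exceeds series length {X.size}")
    return np.array([_blocked_f2(X, Y, s, norm) for s in ss])


def dfa_blocked(x, scales, norm: str = "s") -> np.ndarray:
    """Squared DFA fluctuation function ``F2_DFA(s)`` (non-overlapping windows)."""
    return dcca_blocked(x, x, scales, norm=norm)


def dccc(x, y, scales, norm: str = "s") -> np.ndarray:
    """Detrended cross-correlation coefficient ``rho(s)`` per scale.

    ``rho(s) = F2_xy(s) / (F_x(s) * F_y(s))`` — the detrended analogue of
    Pearson's r for nonstationary series, bounded in [-1, 1].
    """
    f2xy = dcca_blocked(x, y, scales, norm=norm)
    f2x = dfa_blocked(x, scales, norm=norm)
    f2y = dfa_blocked(y, scales, norm=norm)
    denom2 = f2x * f2y
    if np.any(denom2 <= 0.0):
        bad = _scales_tuple(scales)[int(np.argmax(denom2 <= 0.0))]
        raise ValueError(
            f"undefined coefficient: zero DFA fluctuation at scale {bad} "
            "(constant or perfectly linear series?)"
        )
    return f2xy / np.sqrt(denom2)


def fit_exponent(scales, F) -> float:
    """Scaling exponent: OLS slope of ``log F(s)`` against ``log s``.

    ``F`` must be the fluctuation function itself (not its square) and
    strictly positive at every scale.
    """
    ss = np.asarray(_scales_tuple(scales), dtype=float)
    F = np.asarray(F, dtype=float)
    if ss.shape != F.shape:
        raise ValueError(f"scales and F length mismatch: {ss.shape} vs {F.shape}")
    nonpos = np.flatnonzero(F <= 0.0)
    if nonpos.size:
        raise ValueError(
            f"non-positive fluctuation value at scale {int(ss[nonpos[0]])}; "
            "cannot log-transform"
        )
    return float(stats.linregress(np.log(ss), np.log(F)).slope)


def cross_scaling_exponent(x, y, scales, norm: str = "s") -> float:
    """Bivariate scaling exponent lambda fitted offline.

    Fits ``sqrt(|F2_xy(s)|)`` on a log-log plot.  The detrended covariance
    may be negative at some scales, in which case the absolute value is used
    (with a warning) — this modification is only possible offline, which is
    why the streaming engines expose rho and alpha but not lambda.
    """
    f2 = dcca_blocked(x, y, scales, norm=norm)
    if np.any(f2 <= 0.0):
        warnings.warn(
            "non-positive detrended covariance encountered; fitting |F2|^(1/2)",
            RuntimeWarning,
            stacklevel=2,
        )
    return fit_exponent(scales, np.sqrt(np.abs(f2)))
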