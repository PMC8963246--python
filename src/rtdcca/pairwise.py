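"""Streaming (one-pass) DCCA/DFA estimator for a pair of signals.

The engine consumes a stream datapoint-by-datapoint.  For every analysis
scale ``s`` it keeps a handful of running sums over the current window of
the integrated profiles (``sx, sy, sxi, syi, sxy`` plus the squared sums
needed for the univariate DFA path).  When a window at scale ``s`` fills,
the window's detrended covariance is produced in closed form from those
sums alone — no window buffer is ever stored — and the sums reset.

Per-window values are aggregated in blocks of ``s_max`` samples; a circular
buffer of ``W/s_max`` block aggregates realizes the moving analysis window:
the first estimate appears once ``W`` samples have been consumed and a new
one every ``s_max`` samples thereafter, with the oldest block dropped each
time.  State size depends only on the scale configuration, never on stream
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import f2_cross, trend_coeffs
from .scales import ScaleSet

__all__ = [
    "HelperVars",
    "WindowEvent",
    "ScalingEstimate",
    "PairwiseDCCA",
    "trend_from_helpers",
    "f2_from_helpers",
    "f2_dfa_from_helpers",
]


@dataclass
class HelperVars:
    """One scale's running window sums for a signal pair.

    ``sx, sy`` sum the integrated profiles over the current window;
    ``sxi, syi`` weight them by the relative (1-based) within-window index;
    ``sxy`` is the cross-product sum; ``sx2, sy2`` the squared sums used by
    the univariate (DFA) reduction.  ``count`` is the window fill level.
    """

    s: int
    sx: float = 0.0
    sy: float = 0.0
    sxi: float = 0.0
    syi: float = 0.0
    sxy: float = 0.0
    sx2: float = 0.0
    sy2: float = 0.0
    count: int = 0

    def accumulate(self, X: float, Y: float) -> None:
        """Feed one sample of the *integrated* profiles."""
        if self.count >= self.s:
            raise ValueError(f"window at scale {self.s} already full")
        i = float(self.count + 1)
        self.sx += X
        self.sy += Y
        self.sxi += i * X
        self.syi += i * Y
        self.sxy += X * Y
        self.sx2 += X * X
        self.sy2 += Y * Y
        self.count += 1

    @classmethod
    def from_profiles(cls, Xseg, Yseg) -> "HelperVars":
        """Build filled helpers from explicit integrated-profile windows."""
        Xseg = np.asarray(Xseg, dtype=float)
        Yseg = np.asarray(Yseg, dtype=float)
        if Xseg.shape != Yseg.shape or Xseg.ndim != 1:
            raise ValueError("need two equal-length 1-D windows")
        h = cls(s=Xseg.size)
        for Xv, Yv in zip(Xseg, Yseg):
            h.accumulate(float(Xv), float(Yv))
        return h


def _require_full(h: HelperVars) -> None:
    if h.count != h.s:
        raise ValueError(f"window at scale {h.s} not full ({h.count}/{h.s})")


def trend_from_helpers(h: HelperVars, which: str = "x") -> tuple[float, float]:
    """OLS trend (m, b) of the current window, from the sums alone."""
    _require_full(h)
    if h.s < 2:
        raise ValueError("degenerate window: s must be >= 2")
    if which == "x":
        return trend_coeffs(h.sx, h.sxi, float(h.s))
    if which == "y":
        return trend_coeffs(h.sy, h.syi, float(h.s))
    raise ValueError("which must be 'x' or 'y'")


def f2_from_helpers(h: HelperVars) -> float:
    """One-pass detrended covariance of the filled window (1/s norm)."""
    _require_full(h)
    s = float(h.s)
    mx, bx = trend_coeffs(h.sx, h.sxi, s)
    my, by = trend_coeffs(h.sy, h.syi, s)
    return f2_cross(h.sxy, h.sx, h.sy, h.sxi, h.syi, mx, bx, my, by, s)


def f2_dfa_from_helpers(h: HelperVars, which: str = "y") -> float:
    """One-pass mean squared OLS residual (DFA window value, >= 0)."""
    _require_full(h)
    s = float(h.s)
    if which == "x":
        m, b = trend_coeffs(h.sx, h.sxi, s)
        return f2_cross(h.sx2, h.sx, h.sx, h.sxi, h.sxi, m, b, m, b, s)
    if which == "y":
        m, b = trend_coeffs(h.sy, h.syi, s)
        return f2_cross(h.sy2, h.sy, h.sy, h.syi, h.syi, m, b, m, b, s)
    raise ValueError("which must be 'x' or 'y'")


@dataclass(frozen=True)
class WindowEvent:
    """A window completion: scale, absolute sample count, and f2 values."""

    scale: int
    t: int
    f2_cross: float
    f2_x: float
    f2_y: float


@dataclass(frozen=True)
class ScalingEstimate:
    """Per-scale scaling-function estimate emitted by the streaming engine."""

    t: int
    scales: tuple[int, ...]
    f2_cross: np.ndarray
    f2_x: np.ndarray
    f2_y: np.ndarray
    rho: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        denom2 = self.f2_x * self.f2_y
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(denom2 > 0.0, self.f2_cross / np.sqrt(denom2), np.nan)
        object.__setattr__(self, "rho", rho)


class PairwiseDCCA:
    """One-pass DCCA/DFA/DCCC engine for a two-channel stream.

    Parameters
    ----------
    scales
        A :class:`~rtdcca.scales.ScaleSet` with an analysis window ``W``.

    Notes
    -----
    ``push`` ingests a single ``(x_t, y_t)`` sample and returns the window
    completions it triggered; ``push_many`` ingests a chunk and returns the
    estimates emitted along the way.  Feeding the same stream in any chunk
    partition yields bit-identical state and estimates, because every sample
    passes through the same scalar update sequence.
    """

    def __init__(self, scales: ScaleSet):
        if scales.W is None:
            raise ValueError("streaming analysis requires a ScaleSet with W set")
        self.scales = scales
        self._s = scales.as_array()
        n_s = scales.n_s
        self._H = np.zeros((7, n_s))
        self._fill = np.zeros(n_s, dtype=np.int64)
        self._block = np.zeros((3, n_s))
        self._ring = np.zeros((scales.n_blocks, 3, n_s))
        self._fstate = np.zeros(2)
        self._istate = np.zeros(3, dtype=np.int64)
        # W/s terms are averaged per scale per emission; fixed at init
        self._nwin = (scales.W // self._s).astype(np.float64)
        self._latest: ScalingEstimate | None = None

    # -- properties ------------------------------------------------------
    @property
    def t(self) -> int:
        """Total samples consumed."""
        return int(self._istate[0])

    @property
    def window_index(self) -> int:
        """Largest currently fillable scale rank within the running block."""
        t = self.t
        if t == 0:
            return 0
        rel = (t - 1) % self.scales.s_max + 1
        return int(np.count_nonzero(self._s <= rel))

    # -- streaming -------------------------------------------------------
    def _advance(self, x: np.ndarray, y: np.ndarray):
        n = x.size
        n_s = self.scales.n_s
        cap_ev = int(np.sum(n // self._s)) + n_s
        cap_em = n // self.scales.s_max + 1
        ev_scale = np.empty(cap_ev, dtype=np.int64)
        ev_t = np.empty(cap_ev, dtype=np.int64)
        ev_f2 = np.empty((cap_ev, 3))
        emit_t = np.empty(cap_em, dtype=np.int64)
        emit_f2 = np.empty((cap_em, 3, n_s))
        n_ev, n_emit = _kernels.pairwise_advance(
            x, y, self._s, self._H, self._fill, self._block, self._ring,
            self._fstate, self._istate,
            ev_scale, ev_t, ev_f2, emit_t, emit_f2,
        )
        estimates = [
            ScalingEstimate(
                t=int(emit_t[e]),
                scales=self.scales.scales,
                f2_cross=emit_f2[e, 0] / self._nwin,
                f2_x=emit_f2[e, 1] / self._nwin,
                f2_y=emit_f2[e, 2] / self._nwin,
            )
            for e in range(n_emit)
        ]
        if estimates:
            self._latest = estimates[-1]
        events = [
            WindowEvent(
                scale=int(self._s[ev_scale[e]]),
                t=int(ev_t[e]),
                f2_cross=float(ev_f2[e, 0]),
                f2_x=float(ev_f2[e, 1]),
                f2_y=float(ev_f2[e, 2]),
            )
            for e in range(n_ev)
        ]
        return events, estimates

    @staticmethod
    def _as_chunk(x, name: str, t0: int) -> np.ndarray:
        arr = np.ascontiguousarray(x, dtype=np.float64).ravel()
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise ValueError(f"non-finite {name} sample at stream index {t0 + int(bad[0])}")
        return arr

    def push(self, x_t: float, y_t: float) -> list[WindowEvent]:
        """Ingest one sample pair; return window completions it caused."""
        t0 = self.t
        x = self._as_chunk([x_t], "x", t0)
        y = self._as_chunk([y_t], "y", t0)
        events, _ = self._advance(x, y)
        return events

    def push_many(self, x, y) -> list[ScalingEstimate]:
        """Ingest a chunk of samples; return estimates emitted during it."""
        t0 = self.t
        x = self._as_chunk(x, "x", t0)
        y = self._as_chunk(y, "y", t0)
        if x.size != y.size:
            raise ValueError(f"chunk length mismatch: {x.size} vs {y.size}")
        _, estimates = self._advance(x, y)
        return estimates

    def current_estimate(self) -> ScalingEstimate | None:
        """Latest estimate, or None during the W-sample warm-up."""
        return self._latest


def init_pair(scales: ScaleSet) -> PairwiseDCCA:
    """Construct a fresh pairwise streaming engine (all accumulators zero)."""
    return PairwiseDCCA(scales)
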