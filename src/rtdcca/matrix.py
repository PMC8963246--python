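"""Streaming DCCA in matrix form: all channel pairs of a K-channel stream.

Rather than running K(K-1)/2 pairwise engines, the helper sums collapse to
per-scale channel vectors (``sx``, ``sxi``) and one accumulated outer-product
matrix per scale.  Trend fitting happens for all channels simultaneously and
each filled window yields a symmetric K x K detrended-covariance matrix whose
diagonal holds the univariate DFA values of every channel — so the detrended
cross-correlation coefficient and the per-channel DFA exponent alpha come out
of the same pass.  Memory grows as K^2 while the per-sample operation count
stays flat in the number of *pairs*, which is what makes this form win over
sequential pairwise processing for larger channel counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .offline import fit_exponent
from .scales import ScaleSet

__all__ = ["MatrixWindowEvent", "MatrixEstimate", "MatrixDCCA", "dccc_and_alpha", "init_matrix"]


@dataclass(frozen=True)
class MatrixWindowEvent:
    """A window completion at one scale: the K x K f2 matrix it produced."""

    scale: int
    t: int
    f2: np.ndarray  # (K, K), symmetric, diagonal >= 0


@dataclass(frozen=True)
class MatrixEstimate:
    """Per-emission multichannel estimate.

    ``f2[i, j, s_idx]`` is the detrended covariance of channels i and j at
    the scale with index ``s_idx`` (diagonal: DFA).  ``rho`` is the
    detrended cross-correlation coefficient array and ``alpha`` the
    per-channel DFA scaling exponent.  Channels whose DFA function is not
    strictly positive at every scale get NaN rho/alpha entries; the other
    channels are unaffected.
    """

    t: int
    scales: tuple[int, ...]
    f2: np.ndarray  # (K, K, n_s)
    rho: np.ndarray = field(init=False)
    alpha: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        rho, alpha = _rho_alpha(self.f2, self.scales)
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "alpha", alpha)


def _rho_alpha(f2: np.ndarray, scales) -> tuple[np.ndarray, np.ndarray]:
    K = f2.shape[0]
    diag = np.array([f2[i, i, :] for i in range(K)])  # (K, n_s)
    ok = np.all(diag > 0.0, axis=1)  # per-channel validity
    # same arithmetic as the pairwise path: divide by sqrt of the product,
    # so rho(i, i, s) == 1 exactly and both engines agree bitwise
    denom2 = diag[:, None, :] * diag[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom2 > 0.0, f2 / np.sqrt(denom2), np.nan)
    rho[~ok, :, :] = np.nan
    rho[:, ~ok, :] = np.nan
    alpha = np.full(K, np.nan)
    for i in range(K):
        if ok[i]:
            alpha[i] = fit_exponent(scales, np.sqrt(diag[i]))
    return rho, alpha


def dccc_and_alpha(f2: np.ndarray, scales, t: int = 0) -> MatrixEstimate:
    """Convert an accumulated F2(i, j, s) array into rho and alpha.

    ``rho(i,j,s) = F2(i,j,s) / sqrt(F2(i,i,s) F2(j,j,s))``; ``alpha(i)`` is
    the log-log OLS slope of the channel's DFA fluctuation function.
    """
    f2 = np.asarray(f2, dtype=float)
    if f2.ndim != 3 or f2.shape[0] != f2.shape[1]:
        raise ValueError(f"expected (K, K, n_s) array, got shape {f2.shape}")
    ss = scales.scales if isinstance(scales, ScaleSet) else tuple(int(s) for s in scales)
    if f2.shape[2] != len(ss):
        raise ValueError(f"scale axis {f2.shape[2]} does not match {len(ss)} scales")
    return MatrixEstimate(t=t, scales=ss, f2=f2)


class MatrixDCCA:
    """One-pass multichannel DCCA engine (K >= 1 channels).

    With K=1 this degenerates to a univariate DFA tracker; with K=2 it
    reproduces the pairwise engine's numbers exactly.
    """

    def __init__(self, K: int, scales: ScaleSet):
        K = int(K)
        if K < 1:
            raise ValueError(f"channel count must be >= 1, got {K}")
        if scales.W is None:
            raise ValueError("streaming analysis requires a ScaleSet with W set")
        self.K = K
        self.scales = scales
        self._s = scales.as_array()
        n_s = scales.n_s
        self._Xbar = np.zeros(K)
        self._sx = np.zeros((n_s, K))
        self._sxi = np.zeros((n_s, K))
        self._sx2 = np.zeros((n_s, K, K))
        self._fill = np.zeros(n_s, dtype=np.int64)
        self._block = np.zeros((n_s, K, K))
        self._ring = np.zeros((scales.n_blocks, n_s, K, K))
        self._istate = np.zeros(3, dtype=np.int64)
        self._mbuf = np.empty(K)
        self._bbuf = np.empty(K)
        self._nwin = (scales.W // self._s).astype(np.float64)
        self._latest: MatrixEstimate | None = None

    @property
    def t(self) -> int:
        return int(self._istate[0])

    @property
    def window_index(self) -> int:
        t = self.t
        if t == 0:
            return 0
        rel = (t - 1) % self.scales.s_max + 1
        return int(np.count_nonzero(self._s <= rel))

    def _advance(self, xs: np.ndarray):
        n, K = xs.shape
        n_s = self.scales.n_s
        cap_ev = int(np.sum(n // self._s)) + n_s
        cap_em = n // self.scales.s_max + 1
        ev_scale = np.empty(cap_ev, dtype=np.int64)
        ev_t = np.empty(cap_ev, dtype=np.int64)
        ev_f2 = np.empty((cap_ev, K, K))
        emit_t = np.empty(cap_em, dtype=np.int64)
        emit_f2 = np.empty((cap_em, n_s, K, K))
        n_ev, n_emit = _kernels.matrix_advance(
            xs, self._s, self._Xbar, self._sx, self._sxi, self._sx2,
            self._fill, self._block, self._ring, self._istate,
            self._mbuf, self._bbuf,
            ev_scale, ev_t, ev_f2, emit_t, emit_f2,
        )
        estimates = []
        for e in range(n_emit):
            # (n_s, K, K) ring totals -> (K, K, n_s) averaged array
            f2 = np.transpose(emit_f2[e], (1, 2, 0)) / self._nwin
            estimates.append(
                MatrixEstimate(t=int(emit_t[e]), scales=self.scales.scales, f2=f2)
            )
        if estimates:
            self._latest = estimates[-1]
        events = [
            MatrixWindowEvent(
                scale=int(self._s[ev_scale[e]]),
                t=int(ev_t[e]),
                f2=ev_f2[e].copy(),
            )
            for e in range(n_ev)
        ]
        return events, estimates

    def _as_chunk(self, xs) -> np.ndarray:
        arr = np.ascontiguousarray(xs, dtype=np.float64)
        if arr.ndim == 1:
            arr = arr.reshape(1, -1)
        if arr.ndim != 2 or arr.shape[1] != self.K:
            raise ValueError(
                f"expected samples with {self.K} channels, got shape {arr.shape}"
            )
        bad = np.argwhere(~np.isfinite(arr))
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"non-finite sample at stream index {self.t + int(r)}, channel {int(c)}"
            )
        return arr

    def push_vector(self, x_t) -> list[MatrixWindowEvent]:
        """Ingest one K-vector sample; return completed-window events."""
        xs = self._as_chunk(x_t)
        if xs.shape[0] != 1:
            raise ValueError("push_vector takes a single sample; use push_many")
        events, _ = self._advance(xs)
        return events

    def push_many(self, xs) -> list[MatrixEstimate]:
        """Ingest an (n, K) chunk; return estimates emitted during it."""
        xs = self._as_chunk(xs)
        _, estimates = self._advance(xs)
        return estimates

    def current_estimate(self) -> MatrixEstimate | None:
        return self._latest


def init_matrix(K: int, scales: ScaleSet) -> MatrixDCCA:
    """Construct a fresh multichannel streaming engine."""
    return MatrixDCCA(K, scales)
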