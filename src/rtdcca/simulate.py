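"""Synthetic long-memory test signals.

An ARFIMA(0, d, 0) process with memory parameter ``d in (0, 0.5)`` obeys the
AR(infinity) recursion ``x_t = sum_n a_n(d) x_{t-n} + eps_t`` with weights
``a_n(d) = d * Gamma(n - d) / (Gamma(1 - d) Gamma(n + 1))`` and i.i.d.
standard-normal innovations; its DFA exponent is ``alpha = 0.5 + d``.

A *mixed-correlated* ARFIMA pair builds each of two series as a weighted sum
of two independent ARFIMA components and induces long-range
cross-correlation by correlating the innovations of one component of each
series (by default ``rho_23 = 0.9``), giving a bivariate exponent
``lambda = (d2 + d3 + 1) / 2``.

Contamination helpers add white noise at a prescribed signal-to-noise ratio
or raised-cosine ("Hanning") spike artifacts mimicking transient
physiological disturbances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.special import gammaln

__all__ = [
    "arfima_weights",
    "simulate_arfima",
    "McArfimaParams",
    "DEFAULT_MC_ARFIMA",
    "simulate_mc_arfima",
    "add_white_noise",
    "SpikeSpec",
    "add_spikes",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def arfima_weights(d: float, n_max: int) -> np.ndarray:
    """AR weights ``a_n(d)`` for n = 1..n_max, via log-gamma for stability."""
    if not 0.0 <= d < 0.5:
        raise ValueError(f"memory parameter d must be in [0, 0.5), got {d}")
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    if d == 0.0:
        return np.zeros(n_max)
    n = np.arange(1, n_max + 1, dtype=float)
    return d * np.exp(gammaln(n - d) - gammaln(1.0 - d) - gammaln(n + 1.0))


def _default_trunc(N: int, n_trunc: int | None) -> int:
    # weights decay as n**(d-1); 1000 lags keep the neglected tail negligible
    return min(N, 1000) if n_trunc is None else int(n_trunc)


def _arfima_filter(d: float, eps: np.ndarray, n_trunc: int) -> np.ndarray:
    """Run the truncated AR recursion as an IIR filter over innovations."""
    if d == 0.0:
        return eps
    a = np.empty(n_trunc + 1)
    a[0] = 1.0
    a[1:] = -arfima_weights(d, n_trunc)
    return signal.lfilter([1.0], a, eps)


def simulate_arfima(
    d: float,
    N: int,
    seed,
    n_trunc: int | None = None,
    burn_in: int | None = None,
    sigma: float = 1.0,
) -> np.ndarray:
    """One ARFIMA(0, d, 0) realization of length N.

    The infinite AR sum is truncated at ``n_trunc`` lags (default
    ``min(N, 1000)``) and an equally long burn-in segment is discarded so
    the retained samples are past start-up transients.  ``d = 0`` gives
    plain i.i.d. Gaussian noise (alpha = 0.5).
    """
    if N < 64:
        raise ValueError(f"N must be >= 64, got {N}")
    n_trunc = _default_trunc(N, n_trunc)
    burn = n_trunc if burn_in is None else int(burn_in)
    eps = _rng(seed).standard_normal(N + burn) * sigma
    return _arfima_filter(d, eps, n_trunc)[burn:]


@dataclass(frozen=True)
class McArfimaParams:
    """Parameters of the four-component mixed-correlated ARFIMA pair.

    ``x = w1*c1 + w2*c2`` and ``y = w3*c3 + w4*c4`` with component ``ci``
    an ARFIMA(0, d_i, 0) process.  Innovations are drawn each step as a
    correlated 4-vector with covariance ``sigma2`` on the diagonal and
    ``rho[i, j]`` off it.  Defaults emphasize long-term cross persistence:
    the heavily weighted components 2 and 3 share rho_23 = 0.9.
    """

    weights: tuple[float, float, float, float] = (0.2, 1.0, 1.0, 0.2)
    d: tuple[float, float, float, float] = (0.4, 0.3, 0.3, 0.4)
    sigma2: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    rho: np.ndarray | None = field(default=None)
    n_trunc: int | None = None
    burn_in: int | None = None
    allow_d_zero: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        lo = 0.0 if self.allow_d_zero else np.nextafter(0.0, 1.0)
        for di in self.d:
            if not lo <= di < 0.5:
                raise ValueError(f"memory parameter {di} outside (0, 0.5)")
        rho = np.eye(4) if self.rho is None else np.asarray(self.rho, dtype=float)
        if self.rho is None:
            rho[1, 2] = rho[2, 1] = 0.9
        if rho.shape != (4, 4) or not np.allclose(rho, rho.T):
            raise ValueError("rho must be a symmetric 4x4 matrix")
        object.__setattr__(self, "rho", rho)
        if np.linalg.eigvalsh(self.covariance()).min() < -1e-10:
            raise ValueError("innovation covariance is not positive semi-definite")

    def covariance(self) -> np.ndarray:
        """4x4 innovation covariance: sigma2 on the diagonal, rho_ij off it."""
        cov = self.rho.copy()
        np.fill_diagonal(cov, self.sigma2)
        return cov

    def with_memory(self, d2: float, d3: float, d1: float | None = None,
                    d4: float | None = None) -> "McArfimaParams":
        d = list(self.d)
        d[1], d[2] = d2, d3
        if d1 is not None:
            d[0] = d1
        if d4 is not None:
            d[3] = d4
        return replace(self, d=tuple(d))


DEFAULT_MC_ARFIMA = McArfimaParams()


def simulate_mc_arfima(
    params: McArfimaParams, N: int, seed
) -> tuple[np.ndarray, np.ndarray]:
    """One mc-ARFIMA pair (x, y) of length N."""
    if N < 64:
        raise ValueError(f"N must be >= 64, got {N}")
    n_trunc = _default_trunc(N, params.n_trunc)
    burn = n_trunc if params.burn_in is None else int(params.burn_in)
    cov = params.covariance()
    L = np.linalg.cholesky(cov + 1e-14 * np.eye(4))
    eps = _rng(seed).standard_normal((N + burn, 4)) @ L.T
    comps = np.stack(
        [_arfima_filter(params.d[i], eps[:, i], n_trunc)[burn:] for i in range(4)]
    )
    w = params.weights
    x = w[0] * comps[0] + w[1] * comps[1]
    y = w[2] * comps[2] + w[3] * comps[3]
    return x, y


def add_white_noise(x, snr: float, seed) -> np.ndarray:
    """Add Gaussian noise with variance var(x)/snr.

    SNR is the ratio of signal variance to noise variance, so snr=1 doubles
    the variance and snr -> infinity leaves the series untouched.
    """
    x = np.asarray(x, dtype=float)
    if snr <= 0.0:
        raise ValueError(f"snr must be positive, got {snr}")
    v = float(np.var(x))
    if v == 0.0:
        raise ValueError("SNR is undefined for a constant series")
    return x + _rng(seed).standard_normal(x.size) * np.sqrt(v / snr)


@dataclass(frozen=True)
class SpikeSpec:
    """Hanning-spike contamination settings.

    ``kind``: 'A' contaminates x only; 'B' puts independently placed spikes
    in both series; 'C' puts identically placed spikes in both.  Spike peak
    height is ``amplitude`` times the host series' variance (set
    ``amplitude_units='sd'`` to scale by the standard deviation instead).
    """

    count: int = 10
    width: int = 20
    amplitude: float = 4.0
    kind: str = "A"
    amplitude_units: str = "variance"

    def __post_init__(self) -> None:
        if self.kind not in ("A", "B", "C"):
            raise ValueError(f"spike kind must be 'A', 'B' or 'C', got {self.kind!r}")
        if self.amplitude_units not in ("variance", "sd"):
            raise ValueError("amplitude_units must be 'variance' or 'sd'")
        if self.count < 0 or self.width < 4:
            raise ValueError("need count >= 0 and width >= 4")


def _spike_positions(rng: np.random.Generator, N: int, count: int, width: int) -> np.ndarray:
    """Uniformly random non-overlapping spike start positions.

    Gap construction: draw ``count`` starts in the slack interval left after
    reserving one spike width each, sort, and fan them out by ``i * width``.
    Every non-overlapping configuration is reachable and the draw never
    needs rejection, even when the spikes nearly tile the series.
    """
    if count * width > N:
        raise ValueError(
            f"cannot place {count} non-overlapping spikes of width {width} in {N} samples"
        )
    slack = N - count * width
    starts = np.sort(rng.integers(0, slack + 1, size=count))
    return starts + np.arange(count) * width


def _bump(width: int) -> np.ndarray:
    w = np.hanning(width)
    return w / w.max()  # peak exactly 1 regardless of width parity


def _spike_train(N: int, positions: np.ndarray, width: int, peak: float) -> np.ndarray:
    out = np.zeros(N)
    bump = _bump(width) * peak
    for p in positions:
        out[p : p + width] += bump
    return out


def _peak(x: np.ndarray, spec: SpikeSpec) -> float:
    v = float(np.var(x))
    scale = v if spec.amplitude_units == "variance" else np.sqrt(v)
    return spec.amplitude * scale


def add_spikes(x, y, spec: SpikeSpec, seed) -> tuple[np.ndarray, np.ndarray]:
    """Contaminate a pair with non-overlapping Hanning spikes.

    Returns new arrays; inputs are untouched.  Type A spikes x only, Type B
    uses independent placements in each series, Type C reuses the same
    placements (and bump shape) in both, scaled by each host's variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    rng = _rng(seed)
    N = x.size
    pos_x = _spike_positions(rng, N, spec.count, spec.width)
    xc = x + _spike_train(N, pos_x, spec.width, _peak(x, spec))
    if spec.kind == "A":
        return xc, y.copy()
    if spec.kind == "B":
        pos_y = _spike_positions(rng, N, spec.count, spec.width)
    else:  # C: synchronized artifacts
        pos_y = pos_x
    yc = y + _spike_train(N, pos_y, spec.width, _peak(y, spec))
    return xc, yc
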