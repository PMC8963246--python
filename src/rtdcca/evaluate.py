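"""In-silico evaluation experiments for the streaming estimators.

Three experiment families:

* precision — mean squared error (over scales) between the detrended
  cross-correlation coefficient obtained offline and online on the same
  mc-ARFIMA pairs, over a (d2, d3) parameter grid;
* robustness — the same MSE, but between clean and contaminated versions of
  identical pairs (additive white noise at a given SNR, or Hanning spike
  artifacts of type A/B/C);
* runtime — wall-clock scaling of the engines with signal length and with
  channel count (only ratios and growth trends are meaningful; absolute
  seconds are hardware-dependent).

All experiments are pure functions of (configuration, seed).
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MatrixDCCA
from .offline import dccc
from .pairwise import PairwiseDCCA
from .scales import ScaleSet, preset_for_length
from .simulate import (
    DEFAULT_MC_ARFIMA,
    McArfimaParams,
    SpikeSpec,
    add_spikes,
    add_white_noise,
    simulate_mc_arfima,
)

__all__ = [
    "GRID_D_VALUES",
    "EvaluationGrid",
    "mse_scales",
    "online_dccc",
    "precision_experiment",
    "noise_experiment",
    "runtime_benchmark",
]

#: Memory-parameter axis of the evaluation grids: 0.05 to 0.45 in 0.05 steps.
GRID_D_VALUES: np.ndarray = np.round(np.arange(1, 10) * 0.05, 2)


def mse_scales(rho_a, rho_b) -> float:
    """Mean squared difference between two per-scale coefficient vectors."""
    a = np.asarray(rho_a, dtype=float)
    b = np.asarray(rho_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"per-scale vectors must match in length: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


@dataclass(frozen=True)
class EvaluationGrid:
    """A complete (d2, d3) grid of per-cell MSE values for one condition."""

    condition: str
    d2_values: np.ndarray
    d3_values: np.ndarray
    mse: np.ndarray  # shape (len(d2_values), len(d3_values))
    replicates: int
    seed: int | None

    def __post_init__(self) -> None:
        expected = (len(self.d2_values), len(self.d3_values))
        if self.mse.shape != expected:
            raise ValueError(f"grid shape {self.mse.shape} != {expected}")
        if not np.all(np.isfinite(self.mse)) or np.any(self.mse < 0.0):
            raise ValueError("grid incomplete or invalid (MSE must be finite and >= 0)")

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (d2, d3) cell."""
        d2, d3 = np.meshgrid(self.d2_values, self.d3_values, indexing="ij")
        return pd.DataFrame(
            {
                "d2": d2.ravel(),
                "d3": d3.ravel(),
                "condition": self.condition,
                "mse": self.mse.ravel(),
            }
        )

    def max_mse(self, where=None) -> float:
        """Largest cell MSE, optionally restricted by ``where(d2, d3) -> bool``."""
        if where is None:
            return float(self.mse.max())
        d2, d3 = np.meshgrid(self.d2_values, self.d3_values, indexing="ij")
        mask = np.vectorize(where)(d2, d3)
        return float(self.mse[mask].max())


def online_dccc(x, y, scales: ScaleSet, engine: str = "pairwise") -> np.ndarray:
    """rho(s) from one streaming pass over a whole pair (W must equal N)."""
    x = np.asarray(x, dtype=float)
    if scales.W != x.size:
        raise ValueError(f"whole-signal streaming needs W == N (W={scales.W}, N={x.size})")
    if engine == "pairwise":
        eng = PairwiseDCCA(scales)
        estimates = eng.push_many(x, y)
        return estimates[-1].rho
    if engine == "matrix":
        meng = MatrixDCCA(2, scales)
        mestimates = meng.push_many(np.column_stack([x, y]))
        return mestimates[-1].rho[0, 1, :]
    raise ValueError(f"engine must be 'pairwise' or 'matrix', got {engine!r}")


def _cell_seeds(seed, n_cells: int, replicates: int) -> list[list[np.random.SeedSequence]]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_cells)
    return [child.spawn(replicates) for child in children]


def precision_experiment(
    N: int = 2**10,
    scales: ScaleSet | None = None,
    replicates: int = 10,
    seed: int | None = 0,
    engine: str = "pairwise",
) -> EvaluationGrid:
    """Offline-vs-online DCCC agreement over the (d2, d3) grid.

    Pairs are generated with d1 = d4 = 0.45 (strong univariate persistence)
    while d2, d3 sweep the grid; the analysis window W equals the signal
    length, so one streaming pass ends exactly at the single offline
    estimate it must reproduce.
    """
    scales = preset_for_length(N) if scales is None else scales.with_window(N)
    base = DEFAULT_MC_ARFIMA.with_memory(0.3, 0.3, d1=0.45, d4=0.45)
    nd = len(GRID_D_VALUES)
    seeds = _cell_seeds(seed, nd * nd, replicates)
    mse = np.empty((nd, nd))
    for a, d2 in enumerate(GRID_D_VALUES):
        for b, d3 in enumerate(GRID_D_VALUES):
            params = base.with_memory(d2, d3)
            cell = seeds[a * nd + b]
            errs = []
            for rep in range(replicates):
                rng = np.random.default_rng(cell[rep])
                x, y = simulate_mc_arfima(params, N, rng)
                rho_off = dccc(x, y, scales)
                rho_on = online_dccc(x, y, scales, engine=engine)
                errs.append(mse_scales(rho_off, rho_on))
            mse[a, b] = np.mean(errs)
    return EvaluationGrid(
        condition=f"offline-vs-online[{engine}]",
        d2_values=GRID_D_VALUES.copy(),
        d3_values=GRID_D_VALUES.copy(),
        mse=mse,
        replicates=replicates,
        seed=seed,
    )


def _contaminate(x, y, kind: str, level, rng) -> tuple[np.ndarray, np.ndarray]:
    if kind == "white":
        # noise enters the first series only, mirroring the Type A spike
        # scenario; contaminating both channels roughly quadruples the MSE
        snr = 10.0 if level is None else float(level)
        return add_white_noise(x, snr, rng), y.copy()
    if kind in ("spikeA", "spikeB", "spikeC"):
        amp = 4.0 if level is None else float(level)
        spec = SpikeSpec(kind=kind[-1], amplitude=amp)
        return add_spikes(x, y, spec, rng)
    raise ValueError(f"kind must be white/spikeA/spikeB/spikeC, got {kind!r}")


def noise_experiment(
    kind: str,
    level: float | None = None,
    N: int = 2**12,
    replicates: int = 10,
    seed: int | None = 0,
    scales: ScaleSet | None = None,
    params: McArfimaParams = DEFAULT_MC_ARFIMA,
    engine: str = "pairwise",
) -> EvaluationGrid:
    """Clean-vs-contaminated DCCC error over the (d2, d3) grid.

    ``level`` is the SNR for white noise and the spike amplitude factor for
    spike kinds (default 4 x variance).  Each replicate simulates one
    mc-ARFIMA pair, contaminates a copy, and measures the MSE over scales
    between the two streaming rho estimates.
    """
    scales = preset_for_length(N) if scales is None else scales.with_window(N)
    nd = len(GRID_D_VALUES)
    seeds = _cell_seeds(seed, nd * nd, replicates)
    mse = np.empty((nd, nd))
    for a, d2 in enumerate(GRID_D_VALUES):
        for b, d3 in enumerate(GRID_D_VALUES):
            cell_params = params.with_memory(d2, d3)
            cell = seeds[a * nd + b]
            errs = []
            for rep in range(replicates):
                rng = np.random.default_rng(cell[rep])
                x, y = simulate_mc_arfima(cell_params, N, rng)
                xc, yc = _contaminate(x, y, kind, level, rng)
                rho_clean = online_dccc(x, y, scales, engine=engine)
                rho_cont = online_dccc(xc, yc, scales, engine=engine)
                errs.append(mse_scales(rho_clean, rho_cont))
            mse[a, b] = np.mean(errs)
    label = kind if level is None else f"{kind}[{level:g}]"
    return EvaluationGrid(
        condition=label,
        d2_values=GRID_D_VALUES.copy(),
        d3_values=GRID_D_VALUES.copy(),
        mse=mse,
        replicates=replicates,
        seed=seed,
    )


def _time_call(fn, replicates: int) -> float:
    times = []
    for _ in range(replicates):
        t0 = time.perf_counter()
        fn()
        times.append(time.perf_counter() - t0)
    return float(np.median(times))


def runtime_benchmark(
    lengths=(2**10, 2**11, 2**12, 2**13, 2**14),
    channel_counts=(2, 3, 4, 5, 6),
    channel_N: int = 2**10,
    replicates: int = 3,
    seed: int | None = 0,
) -> dict[str, pd.DataFrame]:
    """Median wall-clock times: offline-vs-online over N, pairwise-vs-matrix over K.

    Returns raw per-configuration medians; interpret ratios and growth
    trends only.  Online streaming cost is expected to be linear in N; the
    sequential pairwise pipeline over K channels does K(K-1)/2 passes
    (quadratic), whereas the matrix engine's per-sample cost grows far more
    slowly in the tested range.
    """
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root)

    rows = []
    for N in lengths:
        scales = preset_for_length(N)
        x, y = simulate_mc_arfima(DEFAULT_MC_ARFIMA, N, rng)
        PairwiseDCCA(scales).push_many(x, y)  # warm any jit compilation
        t_online = _time_call(lambda: PairwiseDCCA(scales).push_many(x, y), replicates)
        t_offline = _time_call(lambda: dccc(x, y, scales), replicates)
        rows.append({"N": N, "offline_s": t_offline, "online_s": t_online})
    length_df = pd.DataFrame(rows)

    rows = []
    scales = preset_for_length(channel_N)
    for K in channel_counts:
        chans = np.column_stack(
            [simulate_mc_arfima(DEFAULT_MC_ARFIMA, channel_N, rng)[0] for _ in range(K)]
        )
        MatrixDCCA(K, scales).push_many(chans)  # warm

        def run_pairwise():
            for i in range(K):
                for j in range(i + 1, K):
                    PairwiseDCCA(scales).push_many(chans[:, i], chans[:, j])

        t_pair = _time_call(run_pairwise, replicates)
        t_mat = _time_call(lambda: MatrixDCCA(K, scales).push_many(chans), replicates)
        rows.append({"K": K, "pairwise_s": t_pair, "matrix_s": t_mat})
    channel_df = pd.DataFrame(rows)

    return {"length_scaling": length_df, "channel_scaling": channel_df}
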