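"""Delimited-text input, estimate output, and provenance sidecars.

Input is one column per channel, one row per sample (CSV/TSV; header row
auto-detected).  Estimates round-trip losslessly: JSON floats are written
with Python's shortest-round-trip repr and the CSV writer uses full
precision.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import MatrixEstimate
from .pairwise import ScalingEstimate

__all__ = [
    "read_multichannel",
    "write_estimates",
    "read_pairwise_estimates",
    "read_matrix_estimates",
    "write_sidecar",
]


def read_multichannel(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a delimited numeric table: one column per channel.

    ``dialect`` is a delimiter character; by default it is sniffed.  A
    header row is detected by attempting numeric conversion of the first
    row.  Missing, non-numeric, or ragged cells are rejected with their
    location reported.
    """
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty file")
    sep = dialect
    if sep is None:
        try:
            sep = csv.Sniffer().sniff(first, delimiters=",;\t ").delimiter
        except csv.Error:
            sep = ","
    tokens = [tok for tok in first.strip().split(sep) if tok != ""]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = 0 if not all(_numeric(t) for t in tokens) else None
    df = pd.read_csv(path, sep=sep, header=header, skipinitialspace=True)
    if header is None:
        df.columns = [f"ch{i + 1}" for i in range(df.shape[1])]
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))
        if bad.size:
            raise ValueError(
                f"{path}: missing or non-numeric value at row {int(bad[0])}, "
                f"column {col!r}"
            )
        df[col] = vals.astype(float)
    if len(df) < 2:
        raise ValueError(f"{path}: need at least 2 samples per channel")
    return df


# -- pairwise estimates ---------------------------------------------------

def _pairwise_records(est: ScalingEstimate):
    for k, s in enumerate(est.scales):
        yield {
            "t": est.t,
            "scale": int(s),
            "f2_cross": float(est.f2_cross[k]),
            "f2_x": float(est.f2_x[k]),
            "f2_y": float(est.f2_y[k]),
            "rho": float(est.rho[k]),
        }


_PAIR_FIELDS = ["t", "scale", "f2_cross", "f2_x", "f2_y", "rho"]


def _write_pairwise_csv(estimates, fh) -> None:
    w = csv.DictWriter(fh, fieldnames=_PAIR_FIELDS)
    w.writeheader()
    for est in estimates:
        for rec in _pairwise_records(est):
            w.writerow({k: repr(v) if isinstance(v, float) else v for k, v in rec.items()})


def _write_pairwise_jsonl(estimates, fh) -> None:
    for est in estimates:
        fh.write(
            json.dumps(
                {
                    "t": est.t,
                    "scales": [int(s) for s in est.scales],
                    "f2_cross": est.f2_cross.tolist(),
                    "f2_x": est.f2_x.tolist(),
                    "f2_y": est.f2_y.tolist(),
                    "rho": est.rho.tolist(),
                }
            )
            + "\n"
        )


def read_pairwise_estimates(path, fmt: str = "csv") -> list[ScalingEstimate]:
    path = Path(path)
    out: list[ScalingEstimate] = []
    if fmt == "jsonl":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(
                ScalingEstimate(
                    t=obj["t"],
                    scales=tuple(obj["scales"]),
                    f2_cross=np.array(obj["f2_cross"]),
                    f2_x=np.array(obj["f2_x"]),
                    f2_y=np.array(obj["f2_y"]),
                )
            )
        return out
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        return out
    for t, grp in df.groupby("t", sort=True):
        out.append(
            ScalingEstimate(
                t=int(t),
                scales=tuple(int(s) for s in grp["scale"]),
                f2_cross=grp["f2_cross"].to_numpy(),
                f2_x=grp["f2_x"].to_numpy(),
                f2_y=grp["f2_y"].to_numpy(),
            )
        )
    return out


# -- matrix estimates -----------------------------------------------------

def _triu_pairs(K: int):
    return [(i, j) for i in range(K) for j in range(i, K)]


def _write_matrix_csv(estimates, fh) -> None:
    """Wide format: rho upper triangle (incl. diagonal) per scale, the DFA
    diagonal per scale, and alpha per channel."""
    writer = csv.writer(fh)
    header_done = False
    for est in estimates:
        K = est.f2.shape[0]
        pairs = _triu_pairs(K)
        if not header_done:
            cols = ["t"]
            cols += [f"rho_{i + 1}_{j + 1}_s{s}" for s in est.scales for (i, j) in pairs]
            cols += [f"f2_{i + 1}_{i + 1}_s{s}" for s in est.scales for i in range(K)]
            cols += [f"alpha_{i + 1}" for i in range(K)]
            writer.writerow(cols)
            header_done = True
        row: list = [est.t]
        for k in range(len(est.scales)):
            row += [repr(float(est.rho[i, j, k])) for (i, j) in pairs]
        for k in range(len(est.scales)):
            row += [repr(float(est.f2[i, i, k])) for i in range(K)]
        row += [repr(float(a)) for a in est.alpha]
        writer.writerow(row)
    if not header_done:
        writer.writerow(["t"])


def _write_matrix_jsonl(estimates, fh) -> None:
    for est in estimates:
        K = est.f2.shape[0]
        pairs = _triu_pairs(K)
        fh.write(
            json.dumps(
                {
                    "t": est.t,
                    "K": K,
                    "scales": [int(s) for s in est.scales],
                    "pairs": pairs,
                    "f2_triu": [[float(est.f2[i, j, k]) for (i, j) in pairs]
                                for k in range(len(est.scales))],
                    "alpha": est.alpha.tolist(),
                }
            )
            + "\n"
        )


def read_matrix_estimates(path) -> list[MatrixEstimate]:
    """Read back JSONL matrix estimates (f2 reconstructed by symmetry)."""
    out: list[MatrixEstimate] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        K = obj["K"]
        n_s = len(obj["scales"])
        f2 = np.empty((K, K, n_s))
        for k in range(n_s):
            for (i, j), v in zip(obj["pairs"], obj["f2_triu"][k]):
                f2[i, j, k] = v
                f2[j, i, k] = v
        out.append(MatrixEstimate(t=obj["t"], scales=tuple(obj["scales"]), f2=f2))
    return out


def write_estimates(estimates, path, fmt: str = "csv") -> None:
    """Write a stream of pairwise or matrix estimates to csv or jsonl."""
    if fmt not in ("csv", "jsonl"):
        raise ValueError(f"format must be 'csv' or 'jsonl', got {fmt!r}")
    estimates = list(estimates)
    is_matrix = bool(estimates) and isinstance(estimates[0], MatrixEstimate)
    with Path(path).open("w", newline="") as fh:
        if fmt == "csv":
            (_write_matrix_csv if is_matrix else _write_pairwise_csv)(estimates, fh)
        else:
            (_write_matrix_jsonl if is_matrix else _write_pairwise_jsonl)(estimates, fh)


def write_sidecar(path, config: dict) -> Path:
    """Drop a machine-readable provenance file next to an output file."""
    from . import __version__

    side = Path(str(path) + ".meta.json")
    payload = {"rtdcca_version": __version__, "config": config}
    side.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return side
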