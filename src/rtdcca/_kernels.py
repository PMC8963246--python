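"""One-pass accumulation kernels shared by the pairwise and matrix engines.

Everything here is written as flat loops over numpy buffers so that the same
source compiles under numba when it is available and runs unchanged in pure
Python when it is not.  The two engines call the *same* scalar helpers
(`trend_coeffs`, `f2_cross`), with identical operand ordering, which is what
makes the matrix engine's off-diagonal entries agree bit-for-bit with the
sequential pairwise engine.

State layout (pairwise):
    H[0..6, j]   per-scale running sums over the current window at scale j:
                 sx, sy, sxi, syi, sxy, sx2, sy2
    fill[j]      samples accumulated in the current window at scale j
    block[r, j]  r in {0: cross, 1: auto-x, 2: auto-y}; sum of completed
                 per-window f2 values within the current s_max block
    ring[b,r,j]  per-block f2 sums for the last W/s_max blocks (circular)

The matrix engine collapses sx/sxi to (n_s, K) arrays and the second-order
sum to a (n_s, K, K) array of accumulated outer products.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def trend_coeffs(sx: float, sxi: float, s: float) -> tuple[float, float]:
    """Slope and intercept of the OLS line through a filled window.

    Closed form in the window sums alone: with the relative index i = 1..s,
        m = -6(-2*sxi + (s+1)*sx) / (s(s^2-1)),   b = sx/s - m(s+1)/2.
    """
    m = -6.0 * (-2.0 * sxi + (s + 1.0) * sx) / (s * (s * s - 1.0))
    b = sx / s - m * (s + 1.0) / 2.0
    return m, b


@njit(cache=False)
def f2_cross(
    sab: float,
    sa: float,
    sb: float,
    sai: float,
    sbi: float,
    ma: float,
    ba: float,
    mb: float,
    bb: float,
    s: float,
) -> float:
    """Detrended covariance of one window from the one-pass sums.

    Expands sum (A_i - ma*i - ba)(B_i - mb*i - bb) / s using
    sum i = s(s+1)/2 and sum i^2 = s(s+1)(2s+1)/6.  With A == B this is the
    (non-negative) DFA form.  The term grouping is fixed once here; both
    engines route every window through this function.
    """
    t1 = ma * sbi + mb * sai
    t2 = ba * sb + bb * sa
    core = (sab - t1 - t2) / s
    c2 = (s + 1.0) * (2.0 * s + 1.0) / 6.0
    c1 = (s + 1.0) / 2.0
    return core + c2 * (ma * mb) + c1 * (ma * bb + mb * ba) + ba * bb


@njit(cache=False)
def pairwise_advance(
    x,
    y,
    scales,
    H,
    fill,
    block,
    ring,
    fstate,
    istate,
    ev_scale,
    ev_t,
    ev_f2,
    emit_t,
    emit_f2,
):
    """Consume a chunk of samples; record window events and ring emissions.

    Returns (n_events, n_emits).  Estimates are emitted as *sums* of f2 over
    the full ring; the Python wrapper divides by W/s per scale.
    """
    n = x.shape[0]
    n_s = scales.shape[0]
    n_blocks = ring.shape[0]
    X = fstate[0]
    Y = fstate[1]
    t = istate[0]
    ring_pos = istate[1]
    ring_count = istate[2]
    n_ev = 0
    n_emit = 0
    for k in range(n):
        X = X + x[k]
        Y = Y + y[k]
        t += 1
        for j in range(n_s):
            fi = float(fill[j] + 1)
            H[0, j] += X
            H[1, j] += Y
            H[2, j] += fi * X
            H[3, j] += fi * Y
            H[4, j] += X * Y
            H[5, j] += X * X
            H[6, j] += Y * Y
            fill[j] += 1
            if fill[j] == scales[j]:
                s = float(scales[j])
                mx, bx = trend_coeffs(H[0, j], H[2, j], s)
                my, by = trend_coeffs(H[1, j], H[3, j], s)
                fxy = f2_cross(H[4, j], H[0, j], H[1, j], H[2, j], H[3, j], mx, bx, my, by, s)
                fxx = f2_cross(H[5, j], H[0, j], H[0, j], H[2, j], H[2, j], mx, bx, mx, bx, s)
                fyy = f2_cross(H[6, j], H[1, j], H[1, j], H[3, j], H[3, j], my, by, my, by, s)
                block[0, j] += fxy
                block[1, j] += fxx
                block[2, j] += fyy
                ev_scale[n_ev] = j
                ev_t[n_ev] = t
                ev_f2[n_ev, 0] = fxy
                ev_f2[n_ev, 1] = fxx
                ev_f2[n_ev, 2] = fyy
                n_ev += 1
                for r in range(7):
                    H[r, j] = 0.0
                fill[j] = 0
                if j == n_s - 1:
                    # largest scale filled: the s_max block is complete
                    for r in range(3):
                        for q in range(n_s):
                            ring[ring_pos, r, q] = block[r, q]
                            block[r, q] = 0.0
                    ring_pos = (ring_pos + 1) % n_blocks
                    if ring_count < n_blocks:
                        ring_count += 1
                    if ring_count == n_blocks:
                        for r in range(3):
                            for q in range(n_s):
                                tot = 0.0
                                for blk in range(n_blocks):
                                    tot += ring[blk, r, q]
                                emit_f2[n_emit, r, q] = tot
                        emit_t[n_emit] = t
                        n_emit += 1
    fstate[0] = X
    fstate[1] = Y
    istate[0] = t
    istate[1] = ring_pos
    istate[2] = ring_count
    return n_ev, n_emit


@njit(cache=False)
def matrix_advance(
    xs,
    scales,
    Xbar,
    sx,
    sxi,
    sx2,
    fill,
    block,
    ring,
    istate,
    mbuf,
    bbuf,
    ev_scale,
    ev_t,
    ev_f2,
    emit_t,
    emit_f2,
):
    """Multichannel version of :func:`pairwise_advance`.

    ``xs`` is (n, K).  Per-scale helpers are sx, sxi: (n_s, K) and the
    outer-product sum sx2: (n_s, K, K).  Events and emissions carry full
    K x K f2 matrices per scale (diagonal = DFA).
    """
    n = xs.shape[0]
    K = xs.shape[1]
    n_s = scales.shape[0]
    n_blocks = ring.shape[0]
    t = istate[0]
    ring_pos = istate[1]
    ring_count = istate[2]
    n_ev = 0
    n_emit = 0
    for k in range(n):
        for a in range(K):
            Xbar[a] = Xbar[a] + xs[k, a]
        t += 1
        for j in range(n_s):
            fi = float(fill[j] + 1)
            for a in range(K):
                Xa = Xbar[a]
                sx[j, a] += Xa
                sxi[j, a] += fi * Xa
                for b in range(K):
                    sx2[j, a, b] += Xa * Xbar[b]
            fill[j] += 1
            if fill[j] == scales[j]:
                s = float(scales[j])
                for a in range(K):
                    m, bcoef = trend_coeffs(sx[j, a], sxi[j, a], s)
                    mbuf[a] = m
                    bbuf[a] = bcoef
                for a in range(K):
                    for b in range(K):
                        f2 = f2_cross(
                            sx2[j, a, b],
                            sx[j, a],
                            sx[j, b],
                            sxi[j, a],
                            sxi[j, b],
                            mbuf[a],
                            bbuf[a],
                            mbuf[b],
                            bbuf[b],
                            s,
                        )
                        block[j, a, b] += f2
                        ev_f2[n_ev, a, b] = f2
                ev_scale[n_ev] = j
                ev_t[n_ev] = t
                n_ev += 1
                for a in range(K):
                    sx[j, a] = 0.0
                    sxi[j, a] = 0.0
                    for b in range(K):
                        sx2[j, a, b] = 0.0
                fill[j] = 0
                if j == n_s - 1:
                    for q in range(n_s):
                        for a in range(K):
                            for b in range(K):
                                ring[ring_pos, q, a, b] = block[q, a, b]
                                block[q, a, b] = 0.0
                    ring_pos = (ring_pos + 1) % n_blocks
                    if ring_count < n_blocks:
                        ring_count += 1
                    if ring_count == n_blocks:
                        for q in range(n_s):
                            for a in range(K):
                                for b in range(K):
                                    tot = 0.0
                                    for blk in range(n_blocks):
                                        tot += ring[blk, q, a, b]
                                    emit_f2[n_emit, q, a, b] = tot
                        emit_t[n_emit] = t
                        n_emit += 1
    istate[0] = t
    istate[1] = ring_pos
    istate[2] = ring_count
    return n_ev, n_emit
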