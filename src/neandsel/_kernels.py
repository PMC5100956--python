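"""Numba kernels for the grid-search hot path.

A fit evaluates ~850 (s, mu) grid cells over a few million flattened window
entries.  Scanning the entry arrays once per cell is memory-bound, so the
grid kernel instead walks the windows once: for each SNP it materializes the
per-s retention factors and per-mu nearest-exon weights for its handful of
window entries in small L1-resident buffers, and accumulates all grid cells'
block sums from there.

The retention factor is evaluated as ``f = (b*A*E + r) / (b + r)`` with
``b = s*(1-r)``, ``A = (1-s)^t`` (a per-s scalar) and ``E = (1-r)^t`` (a
per-entry array precomputed by the engine); ``A = 0`` selects the
equilibrium (t = infinity) form.  Window entries live in float32; all
accumulation is in float64.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ML_CAP = 1.0 - 1e-12  # keeps 1 - mu*l positive


@njit(cache=True, fastmath=True)
def g_per_snp(r, l, e, omr, ptr, s, a_s, mu):
    """Per-SNP g at a single (s, mu); mirrors the grid kernel bit-for-bit."""
    n = ptr.size - 1
    g = np.empty(n)
    for i in range(n):
        lo, hi = ptr[i], ptr[i + 1]
        acc = 0.0
        cum = 1.0
        for k in range(lo, hi):
            rk = np.float64(r[k])
            b = s * np.float64(omr[k])
            denom = b + rk
            if denom > 0.0:
                f = np.float32((b * a_s * np.float64(e[k]) + rk) / denom)
            else:
                f = np.float32(1.0)
            ml = mu * np.float64(l[k])
            if ml > _ML_CAP:
                ml = _ML_CAP
            w = np.float32(ml * cum)
            cum *= 1.0 - ml
            acc += np.float64(f * w)
        g[i] = acc + cum
    return g


@njit(cache=True, fastmath=True)
def grid_block_sums(r, l, e, omr, ptr, p_n, block_of_snp, n_blocks,
                    s_values, a_values, mu_values, k_max):
    """Per-block sum(p_n*g) and sum(g^2) for every (s, mu) grid cell.

    Returns ``num`` and ``den`` of shape (S, U, n_blocks).
    """
    S = s_values.size
    U = mu_values.size
    n = ptr.size - 1
    num = np.zeros((S, U, n_blocks))
    den = np.zeros((S, U, n_blocks))
    fbuf = np.empty((S, k_max), dtype=np.float32)
    wbuf = np.empty((U, k_max), dtype=np.float32)
    res = np.empty(U)
    for i in range(n):
        lo, hi = ptr[i], ptr[i + 1]
        kk = hi - lo
        for si in range(S):
            s = s_values[si]
            a_s = a_values[si]
            for k in range(kk):
                rk = np.float64(r[lo + k])
                b = s * np.float64(omr[lo + k])
                denom = b + rk
                if denom > 0.0:
                    fbuf[si, k] = (b * a_s * np.float64(e[lo + k]) + rk) / denom
                else:
                    fbuf[si, k] = 1.0
        for ui in range(U):
            mu = mu_values[ui]
            cum = 1.0
            for k in range(kk):
                ml = mu * np.float64(l[lo + k])
                if ml > _ML_CAP:
                    ml = _ML_CAP
                wbuf[ui, k] = ml * cum
                cum *= 1.0 - ml
            res[ui] = cum
        p = p_n[i]
        blk = block_of_snp[i]
        for si in range(S):
            for ui in range(U):
                acc = 0.0
                for k in range(kk):
                    acc += np.float64(fbuf[si, k] * wbuf[ui, k])
                g = acc + res[ui]
                num[si, ui, blk] += p * g
                den[si, ui, blk] += g * g
    return num, den
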