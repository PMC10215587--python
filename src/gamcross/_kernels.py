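"""Single-site Gibbs sweep kernels.

The location sweep is inherently sequential (each scalar draw
conditions on the current value of every other effect), so the inner
loops are compiled with numba.  Residuals ``e`` and the prior
bookkeeping matrix ``Q = G^-1 U V^-1`` are updated in place after every
accepted draw; the Python driver owns the RNG and passes pre-drawn
standard normals so the whole chain is reproducible from one seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def sweep_scalar(e, w, vals, free, prior_prec, indptr, recs, z):
    """One Gauss-Seidel pass over a concatenated bank of scalar effects.

    For level k with incidence records R_k, the full conditional is
    N(( sum w e* + prior terms) / c, 1/c) with c = sum_R w + prior
    precision, where e* is the residual with the level's own
    contribution restored.  Levels with ``free`` false (identifiability
    constraints, empty levels) are skipped.
    """
    for k in range(vals.shape[0]):
        if not free[k]:
            continue
        sw = 0.0
        swe = 0.0
        for t in range(indptr[k], indptr[k + 1]):
            r = recs[t]
            sw += w[r]
            swe += w[r] * e[r]
        prec = sw + prior_prec[k]
        if prec <= 0.0:
            continue
        mean = (swe + sw * vals[k]) / prec
        new = mean + z[k] / math.sqrt(prec)
        d = new - vals[k]
        for t in range(indptr[k], indptr[k + 1]):
            e[recs[t]] -= d
        vals[k] = new


@njit(cache=True)
def sweep_gametic(e, w, U, Ginv, Q, Vinv, active_role, indptr, recs, z):
    """One pass over the bivariate gametic effects of one origin.

    ``U`` is (n_gametes x 2): column 0 the paternal-role value, column 1
    the maternal-role value.  The prior on vec(U) is N(0, V (x) G), so
    the single-site prior precision of U[i, r] is Vinv[r, r] *
    Ginv[i, i] and the conditional prior mean couples every other
    (gamete, role) through Q = Ginv @ U @ Vinv, which is updated
    incrementally.  Only the role in ``active_role[i]`` touches data.
    """
    n = U.shape[0]
    for i in range(n):
        for r in range(2):
            pp = Vinv[r, r] * Ginv[i, i]
            cross = Q[i, r] - pp * U[i, r]
            sw = 0.0
            swe = 0.0
            if r == active_role[i]:
                for t in range(indptr[i], indptr[i + 1]):
                    rec = recs[t]
                    sw += w[rec]
                    swe += w[rec] * e[rec]
            prec = sw + pp
            mean = (swe + sw * U[i, r] - cross) / prec
            new = mean + z[2 * i + r] / math.sqrt(prec)
            d = new - U[i, r]
            if r == active_role[i]:
                for t in range(indptr[i], indptr[i + 1]):
                    e[recs[t]] -= d
            c0 = d * Vinv[r, 0]
            c1 = d * Vinv[r, 1]
            for j in range(n):
                g = Ginv[j, i]
                Q[j, 0] += g * c0
                Q[j, 1] += g * c1
            U[i, r] = new


def build_csr(levels: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Record lists per level in CSR form (indptr, record indices)."""
    order = np.argsort(levels, kind="stable")
    counts = np.bincount(levels, minlength=n_levels)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return indptr, order.astype(np.int64)
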