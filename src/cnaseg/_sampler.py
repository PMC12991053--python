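"""Compiled Gibbs sweep for the product-partition changepoint model.

The sampler performs a systematic left-to-right scan over the changepoint
indicators U_1..U_{n-1} (0-based; the final indicator is fixed to 1).  At each
position the conditional odds of a changepoint are a ratio of beta-type
integrals in the block count b and the within-/between-block sums of squares
(W, B) under the two indicator settings; see :mod:`cnaseg._special`.

Sums of squares are evaluated from prefix sums, which makes each position an
O(1) update plus an amortized O(1) scan for the next changepoint.  W and B are
recomputed from scratch at the start of every sweep so floating-point drift
cannot accumulate across the chain.

Uniform variates are pre-generated by the caller from a single seeded
``numpy.random.Generator`` and consumed one row per sweep, so a fixed seed
yields a bitwise-identical chain and the public single-sweep API shares this
exact kernel.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._special import log_w_integral

__all__ = ["gibbs_sweep_", "run_chain_", "shrinkage_weight_"]


@njit(cache=True)
def _seg_stats(S1, S2, s, e, g):
    """Within-SS and between-SS contribution of bins s..e (inclusive)."""
    k = e - s + 1
    su = S1[e + 1] - S1[s]
    ss = S2[e + 1] - S2[s]
    m = su / k
    w = ss - su * m
    if w < 0.0:
        w = 0.0
    dm = m - g
    return w, k * dm * dm


@njit(cache=True)
def gibbs_sweep_(U, S1, S2, g, tss, w0, log_prior, u_row, tol):
    """One systematic scan updating U in place.

    Returns (b, W, B) of the partition after the sweep.  ``log_prior[b]`` is
    log int_0^{p0} p^b (1-p)^(n-b-1) dp; ``u_row`` holds n-1 uniforms.
    """
    n = U.shape[0]
    b = 0
    W = 0.0
    B = 0.0
    s = 0
    for j in range(n):
        if U[j] == 1:
            wj, bj = _seg_stats(S1, S2, s, j, g)
            W += wj
            B += bj
            b += 1
            s = j + 1
    l = -1
    r = 0
    while U[r] == 0:
        r += 1
    for i in range(n - 1):
        if i == r:
            r = i + 1
            while U[r] == 0:
                r += 1
        wl, bl = _seg_stats(S1, S2, l + 1, i, g)
        wr, br = _seg_stats(S1, S2, i + 1, r, g)
        wm, bm = _seg_stats(S1, S2, l + 1, r, g)
        if U[i] == 1:
            Wb = W - wl - wr
            Bb = B - bl - br
            b1 = b
        else:
            Wb = W - wm
            Bb = B - bm
            b1 = b + 1
        b0 = b1 - 1
        W1 = Wb + wl + wr
        B1 = Bb + bl + br
        W0 = Wb + wm
        B0 = Bb + bm
        if W1 < 0.0:
            W1 = 0.0
        if W0 < 0.0:
            W0 = 0.0
        if B1 < 0.0:
            B1 = 0.0
        if B0 < 0.0:
            B0 = 0.0
        lo = log_prior[b1] - log_prior[b0]
        if tss > tol:
            lw1 = log_w_integral(n, float(b1), W1, B1, w0, tol)
            lw0 = log_w_integral(n, float(b0), W0, B0, w0, tol)
            inf1 = math.isinf(lw1)
            inf0 = math.isinf(lw0)
            if inf1 and inf0:
                # both divergent: the W -> 0 limit of the ratio vanishes,
                # so a redundant cut inside a constant stretch is rejected
                lo = -np.inf
            elif inf1:
                lo = np.inf
            elif math.isnan(lw1) or math.isnan(lw0):
                pass  # flat-likelihood limit: prior odds only
            else:
                lo += lw1 - lw0
        if lo >= 0.0:
            p = 1.0 / (1.0 + math.exp(-lo))
        else:
            e = math.exp(lo)
            p = e / (1.0 + e)
        new = 1 if u_row[i] < p else 0
        if new != U[i]:
            U[i] = new
            if new == 1:
                W = W1
                B = B1
                b = b1
            else:
                W = W0
                B = B0
                b = b0
        if U[i] == 1:
            l = i
    return b, W, B


@njit(cache=True)
def shrinkage_weight_(n, b, W, B, w0, tss, tol):
    """Posterior mean of the signal-to-noise parameter w given a partition.

    E[w | rho, X] = I_w(b+2, W, B) / I_w(b, W, B); the w -> 0 limit applies
    when the denominator diverges (zero within-block variation), and the
    flat-likelihood limit (constant data) contributes no shrinkage either
    because every block mean equals the grand mean.
    """
    if tss <= tol:
        return 0.0
    lwd = log_w_integral(n, float(b), W, B, w0, tol)
    lwn = log_w_integral(n, float(b + 2), W, B, w0, tol)
    if math.isinf(lwd):
        return 0.0
    if math.isnan(lwd) or math.isnan(lwn):
        return 0.0
    w_hat = math.exp(lwn - lwd)
    if w_hat > w0:
        w_hat = w0
    if w_hat < 0.0:
        w_hat = 0.0
    return w_hat


@njit(cache=True)
def _fill_cond_means(U, S1, S2, g, w_hat, out):
    n = U.shape[0]
    s = 0
    for j in range(n):
        if U[j] == 1:
            k = j - s + 1
            m = (S1[j + 1] - S1[s]) / k
            v = (1.0 - w_hat) * m + w_hat * g
            for t in range(s, j + 1):
                out[t] = v
            s = j + 1


@njit(cache=True)
def run_chain_(S1, S2, g, tss, w0, log_prior, uniforms, burnin, thin, tol,
               counts, means):
    """Run burnin + m*thin sweeps from the all-zero initialization.

    Every ``thin``-th post-burnin partition is retained: its indicators are
    accumulated into ``counts`` and its conditional posterior means written to
    the next row of ``means``.  Returns the number of retained iterations.
    """
    n = S1.shape[0] - 1
    U = np.zeros(n, dtype=np.int8)
    U[n - 1] = 1
    m = means.shape[0]
    total = uniforms.shape[0]
    kept = 0
    for s in range(total):
        b, W, B = gibbs_sweep_(U, S1, S2, g, tss, w0, log_prior,
                               uniforms[s], tol)
        if s >= burnin and (s - burnin) % thin == 0 and kept < m:
            for j in range(n):
                counts[j] += U[j]
            w_hat = shrinkage_weight_(n, b, W, B, w0, tss, tol)
            _fill_cond_means(U, S1, S2, g, w_hat, means[kept])
            kept += 1
    return kept
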