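"""Log-space special functions used by the changepoint sampler.

The per-position Gibbs odds of the product-partition changepoint model are
ratios of one-dimensional integrals,

    I_p(b)       = int_0^{p0} p^b (1-p)^(n-b-1) dp
    I_w(b, W, B) = int_0^{w0} w^(b/2) / (W + B w)^((n-1)/2) dw ,

where ``b`` counts blocks, ``W``/``B`` are within-/between-block sums of
squares and ``n`` is the number of bins.  Both reduce to (incomplete) beta
integrals; for long profiles the raw integrands under/overflow double
precision, so everything here is evaluated in log space.  A regularized
incomplete beta (Lentz continued fraction) is implemented directly because
these kernels run inside numba-compiled code, where scipy.special is not
available, and because the log of the CF form never underflows.

Substituting t = B w / (W + B w) in I_w gives, with a = b/2 + 1 and
c = (n-1)/2 - a = (n - b - 3)/2,

    I_w = B^(-a) W^(a - (n-1)/2) * B_t0(a, c),     t0 = B w0 / (W + B w0),

and after cancelling the complete-beta factors,

    log I_w = a log w0 - ((n-1)/2) log(W + B w0) - log a + log CF(a, c, t0).

For c <= 0 (only reachable for very short profiles or near-saturated
partitions) the incomplete beta has a non-positive shape parameter and the
integral is evaluated by Gauss-Legendre quadrature in log-substituted
coordinates instead.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["log_betainc", "log_w_integral", "betaln_"]

# 64-point Gauss-Legendre rule, used for the c <= 0 fallback quadrature.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)

_EPS = 3.0e-16
_FPMIN = 1.0e-300


@njit(cache=True)
def betaln_(a: float, b: float) -> float:
    return math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)


@njit(cache=True)
def _betacf(a: float, b: float, x: float) -> float:
    """Continued fraction for the incomplete beta (modified Lentz)."""
    qab = a + b
    qap = a + 1.0
    qam = a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < _FPMIN:
        d = _FPMIN
    d = 1.0 / d
    h = d
    for m in range(1, 300):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < _FPMIN:
            d = _FPMIN
        c = 1.0 + aa / c
        if abs(c) < _FPMIN:
            c = _FPMIN
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < _FPMIN:
            d = _FPMIN
        c = 1.0 + aa / c
        if abs(c) < _FPMIN:
            c = _FPMIN
        d = 1.0 / d
        de = d * c
        h *= de
        if abs(de - 1.0) < _EPS:
            break
    return h


@njit(cache=True)
def log_betainc(a: float, b: float, x: float) -> float:
    """log of the regularized incomplete beta I_x(a, b), a, b > 0."""
    if x <= 0.0:
        return -np.inf
    if x >= 1.0:
        return 0.0
    if x < (a + 1.0) / (a + b + 2.0):
        return (
            a * math.log(x)
            + b * math.log1p(-x)
            - math.log(a)
            - betaln_(a, b)
            + math.log(_betacf(a, b, x))
        )
    # complement is the numerically small side
    j = math.exp(
        b * math.log1p(-x)
        + a * math.log(x)
        - math.log(b)
        - betaln_(b, a)
        + math.log(_betacf(b, a, 1.0 - x))
    )
    if j >= 1.0:
        j = 1.0 - 1e-16
    return math.log1p(-j)


@njit(cache=True)
def _log_incbeta_nonpos_c(a: float, c: float, t0: float, nodes, weights) -> float:
    """log of B_t0(a, c) = int_0^{t0} t^(a-1) (1-t)^(c-1) dt for c <= 0, t0 < 1.

    Substituting u = 1 - t and then u = e^z turns the integral into
    int_{log u0}^0 (1 - e^z)^(a-1) e^(z c) dz with u0 = 1 - t0, which is
    smooth on a log scale; evaluated by Gauss-Legendre with a log-sum-exp.
    """
    u0 = 1.0 - t0
    if u0 <= 0.0:
        return np.inf  # divergent endpoint
    zlo = math.log(u0)
    half = -0.5 * zlo
    mid = 0.5 * zlo
    m = -np.inf
    vals = np.empty(nodes.shape[0])
    for k in range(nodes.shape[0]):
        z = mid + half * nodes[k]
        one_minus_u = -math.expm1(z)
        if one_minus_u <= 0.0:
            vals[k] = -np.inf
            continue
        v = c * z + (a - 1.0) * math.log(one_minus_u)
        vals[k] = v
        if v > m:
            m = v
    if not np.isfinite(m):
        return -np.inf
    s = 0.0
    for k in range(nodes.shape[0]):
        s += weights[k] * math.exp(vals[k] - m)
    return m + math.log(s * half)


@njit(cache=True)
def log_w_integral(
    n: int, b: float, W: float, B: float, w0: float, tol: float
) -> float:
    """log of int_0^{w0} w^(b/2) (W + B w)^(-(n-1)/2) dw.

    ``b`` is the block-count parameter (the conditional odds use the block
    counts under each indicator setting; the posterior shrinkage weight uses
    b + 2).  Sums of squares below ``tol`` are treated as exactly zero, which
    selects the analytic limit branch; +inf is returned when the integral
    diverges (zero within-block variation with few blocks), and the caller
    resolves ratios of divergent integrals as the W -> 0 limit.
    """
    a = 0.5 * b + 1.0
    c = 0.5 * (n - 1.0) - a  # = (n - b - 3) / 2
    if W <= tol and B <= tol:
        return np.nan  # constant data; caller falls back to prior odds
    if W <= tol:
        if c >= 0.0:
            return np.inf
        d = -c  # (b - n + 3) / 2 > 0
        return -0.5 * (n - 1.0) * math.log(B) + d * math.log(w0) - math.log(d)
    if B <= tol:
        return a * math.log(w0) - math.log(a) - 0.5 * (n - 1.0) * math.log(W)
    t0 = B * w0 / (W + B * w0)
    if c > 0.0:
        if t0 < (a + 1.0) / (a + c + 2.0):
            return (
                a * math.log(w0)
                - 0.5 * (n - 1.0) * math.log(W + B * w0)
                - math.log(a)
                + math.log(_betacf(a, c, t0))
            )
        j = math.exp(
            c * math.log1p(-t0)
            + a * math.log(t0)
            - math.log(c)
            - betaln_(c, a)
            + math.log(_betacf(c, a, 1.0 - t0))
        )
        if j >= 1.0:
            j = 1.0 - 1e-16
        return (
            -a * math.log(B)
            - c * math.log(W)
            + betaln_(a, c)
            + math.log1p(-j)
        )
    # c <= 0: non-positive shape parameter, fall back to quadrature
    log_bx = _log_incbeta_nonpos_c(a, c, t0, _GL_NODES, _GL_WEIGHTS)
    return -a * math.log(B) - c * math.log(W) + log_bx
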