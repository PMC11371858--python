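"""Deterministic multivariate-normal rectangle probabilities.

Liability-threshold models need P(a < X < b) for a zero-mean Gaussian
vector X in up to four dimensions (two traits x two twins).  Dimension 1
is a difference of normal CDFs; dimension 2 uses Owen's T function, which
is accurate to ~1e-14.  Dimensions 3-4 use a sequential-conditioning
(separation-of-variables) transform of the first d-2 variables, with the
trailing bivariate rectangle integrated exactly through Owen's T; the
remaining smooth 1- or 2-dimensional integral is evaluated by a fixed
tensor Gauss-Legendre rule.  Everything is deterministic with a fixed
node count, so likelihoods are bit-reproducible across runs.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import ndtr, ndtri, owens_t

__all__ = ["mvn_rectangle", "mvn_rectangle_batch", "bvn_cdf"]

# Gauss-Legendre rules on (0, 1), cached per node count.
_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}

_P_CLIP = 1e-15  # keep ndtri arguments strictly inside (0, 1)
DEFAULT_N_NODES = 16


def _gl_rule(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre on (0,1) composed with a quintic smoothstep.

    The conditioning substitution can have unbounded endpoint
    derivatives when rectangle bounds are infinite; the smoothstep
    t -> t^3(10 - 15t + 6t^2) flattens the integrand at both endpoints
    and restores rapid convergence.
    """
    if n not in _GL_CACHE:
        x, w = leggauss(n)
        t = 0.5 * (x + 1.0)
        w = 0.5 * w
        xs = t * t * t * (10.0 - 15.0 * t + 6.0 * t * t)
        ws = w * 30.0 * t * t * (1.0 - t) ** 2
        _GL_CACHE[n] = (xs, ws)
    return _GL_CACHE[n]


def bvn_cdf(h, k, rho):
    """Standard bivariate normal CDF P(X <= h, Y <= k) at correlation rho.

    Vectorized over ``h`` and ``k``; computed from Owen's T function.
    Infinite arguments are handled; |rho| may be 1.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    scalar = h.ndim == 0 and k.ndim == 0
    h, k = np.broadcast_arrays(np.atleast_1d(h), np.atleast_1d(k))
    h = h.astype(float).copy()
    k = k.astype(float).copy()
    rho = float(rho)

    out = np.empty(h.shape, dtype=float)

    neg_inf = np.isneginf(h) | np.isneginf(k)
    h_inf = np.isposinf(h)
    k_inf = np.isposinf(k)
    out[neg_inf] = 0.0
    both_inf = h_inf & k_inf
    out[both_inf] = 1.0
    m = h_inf & ~k_inf & ~neg_inf
    out[m] = ndtr(k[m])
    m = k_inf & ~h_inf & ~neg_inf
    out[m] = ndtr(h[m])

    core = ~(neg_inf | h_inf | k_inf)
    if not np.any(core):
        return float(out[0]) if scalar else out

    hh, kk = h[core], k[core]
    if rho >= 1.0 - 1e-12:
        val = ndtr(np.minimum(hh, kk))
    elif rho <= -1.0 + 1e-12:
        val = np.maximum(0.0, ndtr(hh) + ndtr(kk) - 1.0)
    elif rho == 0.0:
        val = ndtr(hh) * ndtr(kk)
    else:
        # nudge exact zeros off the removable singularity of the T-terms
        hh = np.where(hh == 0.0, 1e-14, hh)
        kk = np.where(kk == 0.0, 1e-14, kk)
        denom = np.sqrt(1.0 - rho * rho)
        a_h = (kk - rho * hh) / (hh * denom)
        a_k = (hh - rho * kk) / (kk * denom)
        delta = np.where(hh * kk < 0.0, 0.5, 0.0)
        val = (
            0.5 * (ndtr(hh) + ndtr(kk))
            - owens_t(hh, a_h)
            - owens_t(kk, a_k)
            - delta
        )
        val = np.clip(val, 0.0, 1.0)
    out[core] = val
    return float(out[0]) if scalar else out


def _rect1(lower, upper, var):
    s = np.sqrt(var)
    return ndtr(upper / s) - ndtr(lower / s)


def _rect2(lower, upper, cov):
    s0 = np.sqrt(cov[0, 0])
    s1 = np.sqrt(cov[1, 1])
    rho = cov[0, 1] / (s0 * s1)
    a0, a1 = lower[:, 0] / s0, lower[:, 1] / s1
    b0, b1 = upper[:, 0] / s0, upper[:, 1] / s1
    return (
        bvn_cdf(b0, b1, rho)
        - bvn_cdf(a0, b1, rho)
        - bvn_cdf(b0, a1, rho)
        + bvn_cdf(a0, a1, rho)
    )


def _cholesky(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        eigmin = float(np.linalg.eigvalsh(cov).min())
        raise ValueError(
            f"covariance matrix is not positive definite "
            f"(smallest eigenvalue {eigmin:.3e})"
        ) from None


def _rect_cond_quad(lower, upper, cov, n_nodes):
    """Rectangles in d=3 or 4 by conditioning quadrature.

    The first d-2 variables are transformed to the unit cube by the
    Genz sequential-conditioning substitution; conditional on them, the
    last two variables form a bivariate normal whose rectangle
    probability is exact (Owen's T).  The remaining integrand is smooth,
    so a tensor Gauss-Legendre rule converges rapidly.
    """
    d = cov.shape[0]
    L = _cholesky(cov)
    x, wt = _gl_rule(n_nodes)
    if d == 3:
        u = x[None, :]            # (1, N)
        weights = wt
    else:
        u1, u2 = np.meshgrid(x, x, indexing="ij")
        u = np.stack([u1.ravel(), u2.ravel()])  # (2, N)
        weights = np.outer(wt, wt).ravel()
    nq = d - 2

    p = ndtr(lower[:, 0] / L[0, 0])[:, None]  # (B, 1)
    q = ndtr(upper[:, 0] / L[0, 0])[:, None]
    f = q - p
    ys = []
    for i in range(nq):
        z = p + u[i][None, :] * (q - p)
        y = ndtri(np.clip(z, _P_CLIP, 1.0 - _P_CLIP))
        ys.append(y)
        if i + 1 < nq:
            mu = sum(L[i + 1, k] * ys[k] for k in range(i + 1))
            p = ndtr((lower[:, i + 1, None] - mu) / L[i + 1, i + 1])
            q = ndtr((upper[:, i + 1, None] - mu) / L[i + 1, i + 1])
            f = f * (q - p)

    # conditional mean of the last two variables given y_0..y_{nq-1}
    mu_a = sum(L[nq, k] * ys[k] for k in range(nq))
    mu_b = sum(L[nq + 1, k] * ys[k] for k in range(nq))
    # residual covariance of the trailing 2x2 block
    lr = L[nq:, nq:]
    s_a = lr[0, 0]
    s_b = float(np.hypot(lr[1, 0], lr[1, 1]))
    rho = lr[1, 0] * lr[0, 0] / (s_a * s_b)

    def std(bound, mu, s):
        with np.errstate(invalid="ignore"):
            return (bound[:, None] - mu) / s

    la, ua = std(lower[:, nq], mu_a, s_a), std(upper[:, nq], mu_a, s_a)
    lb, ub = std(lower[:, nq + 1], mu_b, s_b), std(upper[:, nq + 1], mu_b, s_b)
    rect = (bvn_cdf(ua, ub, rho) - bvn_cdf(la, ub, rho)
            - bvn_cdf(ua, lb, rho) + bvn_cdf(la, lb, rho))
    return (f * rect) @ weights


def mvn_rectangle_batch(lower, upper, cov, n_nodes: int = DEFAULT_N_NODES):
    """Probabilities of axis-aligned rectangles under N(0, cov).

    Parameters
    ----------
    lower, upper : array (B, d)
        Rectangle bounds; entries may be ``-inf`` / ``+inf``.
    cov : array (d, d)
        Positive-definite covariance matrix shared by the batch.
    n_nodes : int
        Gauss-Legendre nodes per conditioning dimension for d >= 3
        (ignored for d <= 2, which are closed-form).
    """
    lower = np.atleast_2d(np.asarray(lower, dtype=float))
    upper = np.atleast_2d(np.asarray(upper, dtype=float))
    cov = np.asarray(cov, dtype=float)
    d = cov.shape[0]
    if lower.shape[1] != d or upper.shape[1] != d:
        raise ValueError("bounds do not match covariance dimension")
    if d == 1:
        return _rect1(lower[:, 0], upper[:, 0], cov[0, 0])
    if d == 2:
        _cholesky(cov)  # positive-definiteness check
        return np.clip(_rect2(lower, upper, cov), 0.0, 1.0)
    return np.clip(_rect_cond_quad(lower, upper, cov, n_nodes), 0.0, 1.0)


def mvn_rectangle(lower, upper, cov, n_nodes: int = DEFAULT_N_NODES) -> float:
    """Probability of one rectangle under N(0, cov); see batch version."""
    lower = np.asarray(lower, dtype=float)[None, :]
    upper = np.asarray(upper, dtype=float)[None, :]
    return float(mvn_rectangle_batch(lower, upper, cov, n_nodes)[0])
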