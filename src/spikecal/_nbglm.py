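"""Vectorised negative-binomial likelihood machinery.

Parameterisation throughout: NB(mu, a) has mean mu and variance
mu + mu^2/a (shape/dispersion parameter a > 0); the Poisson limit is
a -> infinity.  Everything here is batched over transcripts (rows) so that
genome-scale fits and parametric bootstraps stay cheap.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

_MU_FLOOR = 1e-12


def nb_logpmf(y, mu, a):
    """Log pmf of NB(mu, a) at counts y (broadcasting; ``a`` may vary per
    column, e.g. condition-specific shapes)."""
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), _MU_FLOOR)
    return (
        gammaln(y + a)
        - gammaln(a)
        - gammaln(y + 1.0)
        + a * np.log(a / (a + mu))
        + y * np.log(mu / (a + mu))
    )


def nb_ml_mean(y, c, a, n_iter: int = 60):
    """ML of mu for Y_j ~ NB(mu * c_j, a), batched over rows of ``y``.

    ``y`` has shape (..., r), ``c`` shape (r,); ``a`` is a scalar or a
    per-column vector.  Returns the ML mu with the same leading shape.
    Fisher scoring on log mu; all-zero rows get mu=0.
    """
    y = np.asarray(y, dtype=float)
    c = np.asarray(c, dtype=float)
    a = np.asarray(a, dtype=float)
    tot = y.sum(axis=-1)
    mu = tot / c.sum()  # moment start; exact ML when c is constant
    pos = mu > 0
    if not np.any(pos):
        return np.zeros_like(mu)
    eta = np.log(np.where(pos, mu, 1.0))
    for _ in range(n_iter):
        m = np.exp(eta)[..., None] * c  # fitted means, (..., r)
        # dL/dmu = sum_j c_j a (y-m)/(m(a+m)); on the log-mu scale times mu:
        score = (a * (y - m) / (m + a)).sum(axis=-1)
        info = (a * m / (m + a)).sum(axis=-1)  # Fisher info wrt log mu
        step = np.where(info > 0, score / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -4.0, 4.0)
        eta = eta + np.where(pos, step, 0.0)
        if np.max(np.abs(step)) < 1e-12:
            break
    return np.where(pos, np.exp(eta), 0.0)


def nb_glm_fit(y, x, offset_log, a, n_iter: int = 80, tol: float = 1e-10):
    """Batched NB regression with log link and known shape.

    Model: Y_bj ~ NB(exp((x @ beta_b)_j + offset_log_j), a) for each batch
    row b.  ``y``: (n, r); ``x``: (r, p); ``offset_log``: (r,); ``a``
    scalar or per-column.  Returns (beta (n, p), loglik (n,)).  Fisher
    scoring with step clipping.
    """
    a = np.asarray(a, dtype=float)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    x = np.asarray(x, dtype=float)
    offset_log = np.asarray(offset_log, dtype=float)
    n, r = y.shape
    p = x.shape[1]
    # initial beta from least squares on log((y + 0.5)/exp(offset))
    z0 = np.log((y + 0.5)) - offset_log
    beta = z0 @ np.linalg.pinv(x).T
    eye = 1e-8 * np.eye(p)
    for _ in range(n_iter):
        eta = beta @ x.T + offset_log  # (n, r)
        eta = np.clip(eta, -40.0, 40.0)
        m = np.exp(eta)
        resid = a * (y - m) / (m + a)  # (n, r)
        score = resid @ x  # (n, p)
        w = a * m / (m + a)  # Fisher weights, (n, r)
        info = np.einsum("nr,rp,rq->npq", w, x, x) + eye
        step = np.linalg.solve(info, score[..., None])[..., 0]
        norm = np.linalg.norm(step, axis=1, keepdims=True)
        step = np.where(norm > 5.0, step * (5.0 / norm), step)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(beta @ x.T + offset_log, -40.0, 40.0)
    ll = nb_logpmf(y, np.exp(eta), a).sum(axis=1)
    return beta, ll
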