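"""Independent brute-force oracles used to check the fast implementations.

Everything here is written from the model definition alone — explicit
covariance matrices, determinants and generic numerical optimization — and
shares no code path with the package's whitened/profiled updates.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def mvn_logpdf_direct(y, mean, cov) -> float:
    """Multivariate normal log-density via explicit inverse and determinant."""
    y = np.asarray(y, dtype=float)
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    r = y - mean
    sign, logdet = np.linalg.slogdet(cov)
    assert sign > 0
    return float(
        -0.5 * (len(y) * np.log(2 * np.pi) + logdet + r @ np.linalg.inv(cov) @ r)
    )


def random_intercept_cov(n_i: int, d: float, sigma2: float) -> np.ndarray:
    """sigma^2 (d J + I) built explicitly."""
    return sigma2 * (d * np.ones((n_i, n_i)) + np.eye(n_i))


def lmm_neg_loglik(theta, y_list, X_list):
    """Exact negative marginal log-likelihood; theta = (beta, log d, log sigma2)."""
    p = X_list[0].shape[1]
    beta = theta[:p]
    d = np.exp(theta[p])
    sigma2 = np.exp(theta[p + 1])
    nll = 0.0
    for y, X in zip(y_list, X_list):
        V = random_intercept_cov(len(y), d, sigma2)
        nll -= mvn_logpdf_direct(y, X @ beta, V)
    return nll


def lmm_ml_bruteforce(y_list, X_list):
    """Generic-optimizer ML fit of the random-intercept LMM.

    Returns (beta, d, sigma2, loglik).  L-BFGS from an OLS start, then a
    Nelder-Mead polish, on the unconstrained (beta, log d, log sigma2) scale.
    """
    Xs = np.vstack(X_list)
    ys = np.concatenate(y_list)
    beta0, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta0
    s2 = max(float(np.var(resid)), 1e-6)
    theta0 = np.concatenate([beta0, [np.log(0.5), np.log(s2)]])
    res = optimize.minimize(
        lmm_neg_loglik,
        theta0,
        args=(y_list, X_list),
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    res = optimize.minimize(
        lmm_neg_loglik,
        res.x,
        args=(y_list, X_list),
        method="Nelder-Mead",
        options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
    )
    p = X_list[0].shape[1]
    return res.x[:p], float(np.exp(res.x[p])), float(np.exp(res.x[p + 1])), -res.fun
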