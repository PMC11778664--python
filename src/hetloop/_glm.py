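"""Batched Newton-Raphson logistic regression.

A minimal IRLS fitter used for the per-SNP association scans (thousands of
tiny regressions that share the same response) and the forward covariate
selection.  It fits the standard binomial GLM with a logit link; an optional
ridge penalty (excluding the intercept) stabilizes separated or degenerate
fits.  Wald standard errors come from the (penalized) Fisher information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

_MU_EPS = 1e-10
_BETA_CAP = 30.0  # |linear predictor coefficient| beyond which we call separation


@dataclass
class LogisticFit:
    beta: np.ndarray  # (S, p)
    se: np.ndarray  # (S, p)
    loglik_: np.ndarray  # (S,)
    converged: np.ndarray  # (S,) bool
    separated: np.ndarray  # (S,) bool

    @property
    def loglik(self) -> float:
        return float(self.loglik_[0])


def fit_logistic_batch(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 60,
    tol: float = 1e-8,
) -> LogisticFit:
    """Fit ``S`` logistic regressions sharing the response ``y``.

    ``X`` has shape (S, n, p); the first column of each design is assumed to
    be the intercept and is never penalized.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    S, n, p = X.shape
    y = np.asarray(y, dtype=float)
    beta = np.zeros((S, p))
    pen = np.zeros(p)
    pen[1:] = ridge
    converged = np.zeros(S, dtype=bool)
    for _ in range(max_iter):
        eta = np.einsum("snp,sp->sn", X, beta)
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), _MU_EPS, None)
        grad = np.einsum("snp,sn->sp", X, y[None, :] - mu) - pen * beta
        H = np.einsum("sni,sn,snj->sij", X, w, X)
        H += np.diag(pen)[None, :, :]
        try:
            delta = np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(
                H.reshape(-1, p, p)[0], grad[0], rcond=None
            )[0][None, :]
            if S > 1:  # degenerate batch: fall back per problem
                delta = np.stack(
                    [np.linalg.lstsq(H[s], grad[s], rcond=None)[0] for s in range(S)]
                )
        # damp very large steps to keep Newton stable under near-separation
        step_norm = np.abs(delta).max(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(step_norm > 5.0, 5.0 / step_norm, 1.0)
        beta = beta + delta * scale
        converged = np.abs(delta).max(axis=1) < tol
        if converged.all():
            break
    eta = np.einsum("snp,sp->sn", X, beta)
    mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
    loglik = (y[None, :] * np.log(mu) + (1 - y[None, :]) * np.log(1 - mu)).sum(axis=1)
    w = np.clip(mu * (1.0 - mu), _MU_EPS, None)
    H = np.einsum("sni,sn,snj->sij", X, w, X) + np.diag(pen)[None, :, :]
    se = np.full((S, p), np.nan)
    ok = np.ones(S, dtype=bool)
    try:
        cov = np.linalg.inv(H)
        diag = np.einsum("sii->si", cov)
        good = diag > 0
        se[good] = np.sqrt(diag[good])
    except np.linalg.LinAlgError:
        ok[:] = False
    separated = (np.abs(beta).max(axis=1) > _BETA_CAP) | ~converged | ~ok
    return LogisticFit(
        beta=beta, se=se, loglik_=loglik, converged=converged, separated=separated
    )


def fit_logistic(
    X: np.ndarray, y: np.ndarray, ridge: float = 0.0
) -> LogisticFit:
    """Fit a single logistic regression (design shape (n, p))."""
    fit = fit_logistic_batch(np.asarray(X)[None], y, ridge=ridge)
    return LogisticFit(
        beta=fit.beta[0],
        se=fit.se[0],
        loglik_=fit.loglik_,
        converged=fit.converged,
        separated=fit.separated,
    )
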