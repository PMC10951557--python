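"""Variance-weighted random-effects meta-regression.

The model for per-species effect sizes ``y_i`` with known sampling
variances ``v_i`` and moderator row ``x_i`` is

    y_i = x_i' beta + u_i + e_i,   u_i ~ N(0, tau2),  e_i ~ N(0, v_i)

Coefficients are estimated by generalised least squares with weights
``1 / (v_i + tau2)``; the between-species variance ``tau2`` is estimated
by restricted maximum likelihood (REML, the default), ordinary maximum
likelihood (ML), or fixed at zero (FE).  Inference is Wald-normal.

ML log-likelihoods are always reported alongside the fit so that
information criteria can be compared across models with different
fixed-effect structures (REML likelihoods are not comparable there).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = ["MetaRegressionFit", "fit_meta_regression", "intercept_diagnostic"]

_METHODS = ("REML", "ML", "FE")
_TOL = 1e-10
_MAX_ITER = 100


@dataclass
class MetaRegressionFit:
    """Result of one weighted meta-regression fit."""

    beta: np.ndarray            # coefficients, intercept first
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    tau2: float                 # between-species variance (0 for FE)
    pseudo_r2: float            # % reduction in tau2 vs intercept-only, in [0, 100]
    loglik: float               # log-likelihood under the requested method
    loglik_ml: float            # ML log-likelihood (for AICc comparability)
    k: int                      # number of species
    p_dim: int                  # number of coefficients
    method: str = "REML"
    converged: bool = True
    names: tuple[str, ...] = field(default_factory=tuple)

    def coefficient_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"estimate": self.beta, "se": self.se, "z": self.z, "p": self.p},
            index=list(self.names) or [f"b{i}" for i in range(self.p_dim)],
        )


def _design(X, k: int, add_intercept: bool, names):
    if X is None:
        Xm = np.ones((k, 1))
        cols = ("intercept",)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        if names is None:
            names = [f"x{j + 1}" for j in range(Xm.shape[1])]
        if add_intercept:
            Xm = np.column_stack([np.ones(Xm.shape[0]), Xm])
            cols = ("intercept", *names)
        else:
            cols = tuple(names)
    return Xm, cols


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = sorted(names[j] for j in piv[rank:]) if diag.size else list(names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _gls(y, v, X, tau2):
    """Profile beta out at a given tau2; returns beta, resid, A = X'WX, w."""
    w = 1.0 / (v + tau2)
    Xw = X * w[:, None]
    A = X.T @ Xw
    beta = np.linalg.solve(A, Xw.T @ y)
    r = y - X @ beta
    return beta, r, A, w

def _ll_ml(y, v, X, tau2):
    _, r, _, w = _gls(y, v, X, tau2)
    k = y.size
    return -0.5 * (k * np.log(2 * np.pi) - np.sum(np.log(w)) + np.sum(w * r * r))


def _ll_reml(y, v, X, tau2):
    _, r, A, w = _gls(y, v, X, tau2)
    k, p = X.shape
    sign, logdet = np.linalg.slogdet(A)
    return -0.5 * (
        (k - p) * np.log(2 * np.pi) - np.sum(np.log(w)) + logdet + np.sum(w * r * r)
    )


def _fisher_scoring(y, v, X, restricted: bool):
    """tau2 by Fisher scoring on the (restricted) profile likelihood.

    Returns (tau2, converged).  Falls back to bounded 1-D optimisation when
    scoring fails to settle; the better of the two objective values wins.
    """
    k, p = X.shape
    tau2 = max(np.var(y, ddof=1) - float(np.mean(v)), 0.0) if k > 1 else 0.0
    converged = False
    for _ in range(_MAX_ITER):
        _, r, A, w = _gls(y, v, X, tau2)
        w2r2 = np.sum(w * w * r * r)
        if restricted:
            Ainv = np.linalg.inv(A)
            B = X.T @ (X * (w**2)[:, None])
            C = X.T @ (X * (w**3)[:, None])
            tr_p = np.sum(w) - np.trace(Ainv @ B)
            score = -0.5 * tr_p + 0.5 * w2r2
            AB = Ainv @ B
            tr_pp = np.sum(w**2) - 2.0 * np.trace(Ainv @ C) + np.trace(AB @ AB)
            info = 0.5 * tr_pp
        else:
            score = -0.5 * np.sum(w) + 0.5 * w2r2
            info = 0.5 * np.sum(w**2)
        if info <= 0 or not np.isfinite(score):
            break
        new = tau2 + score / info
        if new < 0.0:
            new = 0.0
        if abs(new - tau2) < _TOL * (1.0 + tau2):
            tau2 = new
            converged = True
            break
        tau2 = new

    ll = _ll_reml if restricted else _ll_ml
    if not converged:
        hi = max(10.0 * np.var(y, ddof=1) if k > 1 else 1.0, 10.0 * float(np.mean(v)), 1.0)
        res = optimize.minimize_scalar(
            lambda t: -ll(y, v, X, t), bounds=(0.0, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        if not np.isfinite(tau2) or ll(y, v, X, float(res.x)) > ll(y, v, X, tau2):
            tau2 = float(res.x)
        converged = bool(res.success)
    return float(tau2), converged


def fit_meta_regression(
    yi,
    vi,
    X=None,
    method: str = "REML",
    add_intercept: bool = True,
    moderator_names: Sequence[str] | None = None,
    compute_pseudo_r2: bool = True,
) -> MetaRegressionFit:
    """Fit ``yi = X beta + u + e`` with weights ``1/(vi + tau2)``.

    Parameters
    ----------
    yi, vi
        Effect sizes and their sampling variances (``vi > 0``).
    X
        Moderator matrix (k x m) *without* intercept; ``None`` for an
        intercept-only model.  An intercept column is prepended unless
        ``add_intercept`` is false.
    method
        ``"REML"`` (default), ``"ML"``, or ``"FE"`` (tau2 fixed at 0).
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}, got {method!r}")
    y = np.asarray(yi, dtype=float)
    v = np.asarray(vi, dtype=float)
    if y.shape != v.shape or y.ndim != 1:
        raise ValueError("yi and vi must be 1-D arrays of equal length")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(v)):
        raise ValueError("yi and vi must be finite")
    if np.any(v <= 0):
        raise ValueError("all sampling variances vi must be > 0")
    k = y.size
    Xm, names = _design(X, k, add_intercept, moderator_names)
    p = Xm.shape[1]
    if k < p:
        raise ValueError(f"k={k} species cannot support p={p} coefficients")
    _check_rank(Xm, names)

    converged = True
    if method == "FE":
        tau2 = 0.0
    elif method == "ML":
        tau2, converged = _fisher_scoring(y, v, Xm, restricted=False)
    else:
        tau2, converged = _fisher_scoring(y, v, Xm, restricted=True)

    beta, _, A, _ = _gls(y, v, Xm, tau2)
    se = np.sqrt(np.diag(np.linalg.inv(A)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    loglik = (_ll_reml if method == "REML" else _ll_ml)(y, v, Xm, tau2)
    if method == "ML":
        loglik_ml = loglik
    else:
        tau2_ml = 0.0 if method == "FE" else _fisher_scoring(y, v, Xm, restricted=False)[0]
        if method == "FE":
            loglik = _ll_ml(y, v, Xm, 0.0)
            tau2_ml = 0.0
        loglik_ml = _ll_ml(y, v, Xm, tau2_ml)

    pseudo_r2 = 0.0
    if compute_pseudo_r2 and p > 1 and method != "FE":
        null_fit = fit_meta_regression(
            y, v, None, method=method, compute_pseudo_r2=False
        )
        if null_fit.tau2 > 0:
            pseudo_r2 = 100.0 * max(0.0, (null_fit.tau2 - tau2) / null_fit.tau2)

    return MetaRegressionFit(
        beta=beta, se=se, z=z, p=pvals, tau2=tau2, pseudo_r2=pseudo_r2,
        loglik=float(loglik), loglik_ml=float(loglik_ml), k=k, p_dim=p,
        method=method, converged=converged, names=names,
    )


def intercept_diagnostic(fit: MetaRegressionFit, alpha: float = 0.05):
    """Two-sided Wald test of the intercept; flags departure from zero.

    A non-significant intercept is the framework's check that uniform
    storage/maternal bias is not contaminating the climate signal: such a
    bias shifts the regression's elevation but never its slope.
    """
    if not fit.names or fit.names[0] != "intercept":
        raise ValueError("fit has no intercept term")
    p = float(fit.p[0])
    return p < alpha, p
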