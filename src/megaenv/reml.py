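"""Restricted maximum likelihood for linear mixed models with crossed
random effects.

The model is y = X b + sum_k Z_k u_k + e with u_k ~ N(0, s2_k I) and
e ~ N(0, s2_e I); all random-effect blocks may be crossed (genotype,
genotype-by-trial, rows, columns, ...).  The observation count in a
multi-environment trial series is a few thousand at most, so everything
is dense: with K_k = Z_k Z_k' precomputed once per design,

    V(theta) = s2_e I + sum_k s2_k K_k

and each likelihood evaluation is one Cholesky factorization of V.

Optimization is average-information (AI) REML: Fisher-scoring with the
average of the observed and expected information, started from a crude
equal-split of the total variance, with step halving on the REML
log-likelihood and variance components clamped at a small non-negative
bound (a component at the bound is reported as boundary).  If AI fails to
converge a bounded Nelder-Mead on log-variances takes over.

The engine exposes exactly what downstream genetics needs: variance
components, BLUPs u_hat_k = s2_k Z_k' P y, the prediction-error variance
(PEV) matrix of any block, GLS fixed effects with Satterthwaite-type
degrees of freedom, and the REML log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .errors import ConvergenceError, ParameterError

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class REMLResult:
    """Fitted mixed model: components, likelihood and cached solves."""

    components: dict[str, float]          # includes "residual"
    loglik: float
    converged: bool
    n_iter: int
    boundary: dict[str, bool]
    beta: np.ndarray
    beta_cov: np.ndarray
    fixed_names: list[str]
    # internals for BLUP / PEV extraction
    _y: np.ndarray = field(repr=False, default=None)
    _X: np.ndarray = field(repr=False, default=None)
    _Z: dict[str, np.ndarray] = field(repr=False, default=None)
    _P: np.ndarray = field(repr=False, default=None)
    _Py: np.ndarray = field(repr=False, default=None)
    _Vinv: np.ndarray = field(repr=False, default=None)
    _ai_cov: np.ndarray = field(repr=False, default=None)
    _order: list[str] = field(repr=False, default=None)

    def blup(self, name: str) -> np.ndarray:
        """BLUP of random-effect block ``name``: u_hat = s2 Z' P y."""
        return self.components[name] * (self._Z[name].T @ self._Py)

    def pev(self, name: str) -> np.ndarray:
        """Prediction-error variance Var(u_hat - u) = s2 I - s2^2 Z' P Z."""
        s2 = self.components[name]
        Z = self._Z[name]
        ZtP = Z.T @ self._P
        return s2 * np.eye(Z.shape[1]) - s2 * s2 * (ZtP @ Z)

    def fixed_effects(self) -> pd.DataFrame:
        """GLS estimates with Satterthwaite-type df and t-test p-values.

        The df of coefficient j is 2 (c'Sc)^2 / Var(c'Sc) where S is the
        coefficient covariance and the variance is a delta-method
        propagation of the AI covariance of the variance components;
        p-values from other df approximations may differ in the third
        decimal.
        """
        rows = []
        grads = self._beta_cov_gradients()
        for j, name in enumerate(self.fixed_names):
            var_b = self.beta_cov[j, j]
            se = np.sqrt(var_b)
            g = grads[:, j]
            denom = float(g @ self._ai_cov @ g)
            df = 2.0 * var_b**2 / denom if denom > 0 else np.inf
            tval = self.beta[j] / se if se > 0 else np.nan
            p = 2.0 * stats.t.sf(abs(tval), df) if np.isfinite(tval) else np.nan
            rows.append((name, self.beta[j], se, df, tval, p))
        return pd.DataFrame(rows, columns=["term", "estimate", "se", "df",
                                           "t", "p"])

    def _beta_cov_gradients(self) -> np.ndarray:
        """d Var(b_j) / d theta_k for every component k and coefficient j."""
        X, Vinv = self._X, self._Vinv
        W = Vinv @ X
        C = self.beta_cov
        out = np.empty((len(self._order), X.shape[1]))
        for k, name in enumerate(self._order):
            if name == "residual":
                M = W.T @ W
            else:
                ZtW = self._Z[name].T @ W
                M = ZtW.T @ ZtW
            D = C @ M @ C  # -dC/dtheta_k has this magnitude; sign squares out
            out[k] = np.diag(D)
        return out


def _design_matrix(labels) -> tuple[np.ndarray, list]:
    """Dense 0/1 incidence matrix for a factor, with its level order."""
    labels = pd.Series(labels)
    levels = sorted(labels.unique())
    idx = {lv: i for i, lv in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), [idx[lv] for lv in labels]] = 1.0
    return Z, levels


class _Workspace:
    """Per-theta REML quantities; one Cholesky per evaluation."""

    def __init__(self, y, X, Z, order):
        self.y, self.X = y, X
        self.Z = Z
        self.order = order
        self.n, self.p = X.shape
        self.K = {k: Z[k] @ Z[k].T for k in Z}

    def build_v(self, theta):
        V = theta[-1] * np.eye(self.n)
        for k, name in enumerate(self.order[:-1]):
            V += theta[k] * self.K[name]
        return V

    def loglik(self, theta) -> float:
        try:
            c, low = linalg.cho_factor(self.build_v(theta), lower=True)
        except linalg.LinAlgError:
            return -np.inf
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        Vi_X = linalg.cho_solve((c, low), self.X)
        Vi_y = linalg.cho_solve((c, low), self.y)
        XtViX = self.X.T @ Vi_X
        sign, logdet_c = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(XtViX, self.X.T @ Vi_y)
        Py = Vi_y - Vi_X @ beta
        return -0.5 * (logdet_v + logdet_c + self.y @ Py
                       + (self.n - self.p) * _LOG2PI)

    def full(self, theta):
        """log-likelihood, score vector, AI matrix and cached solves."""
        V = self.build_v(theta)
        c, low = linalg.cho_factor(V, lower=True)
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        Vinv = linalg.cho_solve((c, low), np.eye(self.n))
        W = Vinv @ self.X
        XtViX = self.X.T @ W
        sign, logdet_c = np.linalg.slogdet(XtViX)
        C = np.linalg.inv(XtViX)
        beta = C @ (self.X.T @ (Vinv @ self.y))
        P = Vinv - W @ C @ W.T
        Py = P @ self.y
        ll = -0.5 * (logdet_v + logdet_c + self.y @ Py
                     + (self.n - self.p) * _LOG2PI)
        m = len(self.order)
        score = np.empty(m)
        F = np.empty((self.n, m))
        for k, name in enumerate(self.order):
            if name == "residual":
                Fk = Py
                trPK = np.trace(P)
            else:
                Fk = self.K[name] @ Py
                trPK = float(np.sum(P * self.K[name]))
            F[:, k] = Fk
            score[k] = -0.5 * (trPK - Py @ Fk)
        AI = 0.5 * (F.T @ P @ F)
        return ll, score, AI, beta, C, P, Py, Vinv


def reml_fit(y, X, random_effects: dict[str, np.ndarray],
             fixed_names: list[str] | None = None, max_iter: int = 60,
             tol: float = 1e-8, bound_frac: float = 1e-8,
             start: dict[str, float] | None = None) -> REMLResult:
    """Fit the mixed model by AI-REML.

    Parameters
    ----------
    y, X : response vector and fixed-effect design matrix.
    random_effects : mapping name -> dense incidence matrix Z_k.
    start : optional starting variance components (by name, plus
        "residual"); defaults to an equal split of the OLS residual
        variance.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if y.ndim != 1 or X.shape[0] != len(y):
        raise ParameterError("y and X have incompatible shapes")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        X = X[:, _independent_columns(X)]
    order = list(random_effects) + ["residual"]
    ws = _Workspace(y, X, dict(random_effects), order)
    m = len(order)

    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    s2_total = max(float(resid @ resid) / max(len(y) - X.shape[1], 1), 1e-12)
    lb = bound_frac * s2_total
    if start is not None:
        theta = np.array([max(start.get(k, s2_total / m), lb) for k in order])
    else:
        theta = np.full(m, s2_total / m)

    ll, score, AI, beta, C, P, Py, Vinv = ws.full(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        free = (theta > lb * 1.5) | (score > 0)
        if not free.any():
            converged = True
            break
        step = np.zeros(m)
        try:
            sub = AI[np.ix_(free, free)]
            step[free] = np.linalg.solve(
                sub + 1e-10 * np.eye(free.sum()) * np.trace(sub), score[free])
        except np.linalg.LinAlgError:
            step[free] = score[free] / np.maximum(np.diag(AI)[free], 1e-12)
        new_ll = -np.inf
        for _ in range(30):  # step halving
            cand = np.maximum(theta + step, lb)
            new_ll = ws.loglik(cand)
            if new_ll >= ll - 1e-12:
                break
            step *= 0.5
        if not np.isfinite(new_ll):
            break
        delta = new_ll - ll
        theta = np.maximum(theta + step, lb)
        ll, score, AI, beta, C, P, Py, Vinv = ws.full(theta)
        ll = max(ll, new_ll)
        at_bound = theta <= lb * 1.5
        scaled = np.abs(score * theta)  # gradient on the log-variance scale
        grad_ok = np.all(scaled[~at_bound] < 1e-4 * (1 + abs(ll))) \
            if (~at_bound).any() else True
        if abs(delta) < tol and grad_ok:
            converged = True
            break

    if not converged:
        # derivative-free fallback on log-variances
        def neg(logth):
            return -ws.loglik(np.exp(logth))

        res = optimize.minimize(neg, np.log(np.maximum(theta, lb)),
                                method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-10,
                                         "maxiter": 4000})
        cand = np.maximum(np.exp(res.x), lb)
        if ws.loglik(cand) >= ll:
            theta = cand
            ll, score, AI, beta, C, P, Py, Vinv = ws.full(theta)
            converged = res.success
    scaled = np.abs(score * theta)
    if not converged and np.max(scaled) > 1e-2 * (1 + abs(ll)):
        raise ConvergenceError(
            f"REML did not converge after {it} iterations: "
            f"loglik={ll:.6f}, max|scaled score|={np.max(scaled):.3g}")

    comp = {name: (0.0 if theta[k] <= lb * 1.5 else float(theta[k]))
            for k, name in enumerate(order)}
    boundary = {name: theta[k] <= lb * 1.5 for k, name in enumerate(order)}
    try:
        ai_cov = np.linalg.inv(AI + 1e-12 * np.eye(m) * max(np.trace(AI), 1))
    except np.linalg.LinAlgError:
        ai_cov = np.full((m, m), np.nan)
    names = fixed_names or [f"b{j}" for j in range(X.shape[1])]
    converged = converged or np.max(scaled) <= 1e-2 * (1 + abs(ll))
    return REMLResult(components=comp, loglik=float(ll), converged=bool(converged),
                      n_iter=it, boundary=boundary, beta=beta, beta_cov=C,
                      fixed_names=list(names)[:X.shape[1]],
                      _y=y, _X=X, _Z=dict(random_effects), _P=P, _Py=Py,
                      _Vinv=Vinv, _ai_cov=ai_cov, _order=order)


def _independent_columns(X: np.ndarray) -> list[int]:
    """Greedy pivot of linearly independent columns (for rank-deficient X)."""
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    rank = int(np.sum(np.abs(np.diag(R)) > 1e-10 * abs(R[0, 0])))
    return sorted(piv[:rank])
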