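"""REML variance-component estimation and GBLUP prediction.

The model is

    y = X beta + sum_i g_i + e,   g_i ~ N(0, K_i sigma2_i),   e ~ N(0, I sigma2_e),

with X an intercept by default. Restricted maximum likelihood is maximised
by average-information (AI) updates warm-started with a few EM steps; EM is
used as a fallback whenever an AI step would leave the parameter space or
decrease the restricted likelihood. A pure EM path with Aitken acceleration
is available via ``method="em"``. Single-kernel fits use a spectral
decomposition of K so each iteration is O(n); multi-kernel fits use dense
solves.

Prediction solves the mixed-model equations with training records only but
relationship matrices over all individuals, at the training-estimated
variance components:

    g_hat_i = sigma2_i * K_i[., train] @ V_train^{-1} (y_train - X_train beta_hat).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

_LOG2PI = np.log(2.0 * np.pi)


class RemlError(ValueError):
    pass


@dataclass
class FitResult:
    """Variance components, fixed effects and fit diagnostics."""

    variances: dict[str, float]          # per random term, plus "residual"
    beta: np.ndarray                     # fixed-effect solutions (intercept first)
    loglik: float
    n_iter: int
    converged: bool
    term_names: tuple[str, ...] = ()
    gebv: pd.DataFrame | None = None

    @property
    def mu(self) -> float:
        return float(self.beta[0])

    @property
    def residual_variance(self) -> float:
        return self.variances["residual"]

    def genetic_variances(self) -> list[float]:
        return [self.variances[t] for t in self.term_names]


def _as_matrices(relationship_matrices) -> list[np.ndarray]:
    from .kinship import RelationshipMatrix

    out = []
    for K in relationship_matrices:
        arr = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise RemlError("relationship matrices must be square")
        if not np.allclose(arr, arr.T, atol=1e-8):
            raise RemlError("relationship matrices must be symmetric")
        out.append(np.asarray(arr, dtype=np.float64))
    return out


def _design(y: np.ndarray, X: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64).ravel()
    if X is None:
        X = np.ones((len(y), 1))
    else:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[:, None]
    if X.shape[0] != len(y):
        raise RemlError("covariate rows do not match phenotype length")
    return y, X


def restricted_loglik(y, relationship_matrices, variance_components, X=None) -> float:
    """Exact restricted log-likelihood at the given variance components.

    ``variance_components`` lists one variance per kernel followed by the
    residual variance. Includes the -((n - p)/2) log(2 pi) constant so toy
    cases match closed forms.
    """
    Ks = _as_matrices(relationship_matrices)
    y, X = _design(y, X)
    theta = np.asarray(variance_components, dtype=np.float64)
    if len(theta) != len(Ks) + 1:
        raise RemlError("need one variance per kernel plus a residual variance")
    if np.any(theta < 0) or not np.any(theta > 0):
        raise RemlError("variance components must be >= 0 and not all zero")
    n, p = X.shape
    V = theta[-1] * np.eye(n)
    for s2, K in zip(theta[:-1], Ks):
        V += s2 * K
    try:
        c = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise RemlError("total covariance matrix is singular") from exc
    logdet_v = 2.0 * np.sum(np.log(np.diag(c[0])))
    Vinv_X = cho_solve(c, X)
    XtVinvX = X.T @ Vinv_X
    sign, logdet_x = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise RemlError("X'V^{-1}X is singular")
    beta = np.linalg.solve(XtVinvX, Vinv_X.T @ y)
    resid = y - X @ beta
    quad = float(resid @ cho_solve(c, resid))
    return -0.5 * (logdet_v + logdet_x + quad + (n - p) * _LOG2PI)


def _dense_stats(theta, Ks, y, X):
    """Per-iteration REML quantities for the dense multi-kernel path."""
    n, p = X.shape
    V = theta[-1] * np.eye(n)
    for s2, K in zip(theta[:-1], Ks):
        V += s2 * K
    c = cho_factor(V, lower=True)
    Vinv = cho_solve(c, np.eye(n))
    Vinv_X = Vinv @ X
    XtVinvX = X.T @ Vinv_X
    XtVinvX_inv = np.linalg.inv(XtVinvX)
    beta = XtVinvX_inv @ (Vinv_X.T @ y)
    P = Vinv - Vinv_X @ XtVinvX_inv @ Vinv_X.T
    Py = P @ y
    logdet_v = 2.0 * np.sum(np.log(np.diag(c[0])))
    sign, logdet_x = np.linalg.slogdet(XtVinvX)
    ll = -0.5 * (logdet_v + logdet_x + float(y @ Py) + (n - p) * _LOG2PI)

    traces, quads, ws = [], [], []
    for K in Ks:
        traces.append(float(np.sum(P * K)))
        w = K @ Py
        quads.append(float(Py @ w))
        ws.append(w)
    traces.append(float(np.trace(P)))
    quads.append(float(Py @ Py))
    ws.append(Py)

    k1 = len(theta)
    AI = np.empty((k1, k1))
    Pw = [P @ w for w in ws]
    for i in range(k1):
        for j in range(i, k1):
            AI[i, j] = AI[j, i] = 0.5 * float(ws[i] @ Pw[j])
    return ll, beta, np.array(traces), np.array(quads), AI


class _SpectralWork:
    """Single-kernel REML in the eigenbasis of K: V is diagonal, O(n) per step."""

    def __init__(self, K: np.ndarray, y: np.ndarray, X: np.ndarray):
        lam, U = np.linalg.eigh(K)
        self.lam = np.maximum(lam, 0.0)
        self.U = U
        self.yt = U.T @ y
        self.Xt = U.T @ X
        self.n, self.p = X.shape

    def stats(self, theta):
        lam, yt, Xt = self.lam, self.yt, self.Xt
        d = 1.0 / (theta[0] * lam + theta[1])
        DX = d[:, None] * Xt
        XtDX = Xt.T @ DX
        XtDX_inv = np.linalg.inv(XtDX)
        Dy = d * yt
        beta = XtDX_inv @ (Xt.T @ Dy)

        def apply_P(v):
            Dv = d * v
            return Dv - DX @ (XtDX_inv @ (Xt.T @ Dv))

        Py = apply_P(yt)
        logdet_v = float(np.sum(np.log(theta[0] * lam + theta[1])))
        sign, logdet_x = np.linalg.slogdet(XtDX)
        ll = -0.5 * (logdet_v + logdet_x + float(yt @ Py) + (self.n - self.p) * _LOG2PI)

        tr_PK = float(np.sum(d * lam)) - float(np.trace(XtDX_inv @ (DX.T * lam) @ DX))
        tr_P = float(np.sum(d)) - float(np.trace(XtDX_inv @ (DX.T @ DX)))
        w_g = lam * Py
        quads = np.array([float(Py @ w_g), float(Py @ Py)])
        traces = np.array([tr_PK, tr_P])
        ws = [w_g, Py]
        AI = np.empty((2, 2))
        Pw = [apply_P(w) for w in ws]
        for i in range(2):
            for j in range(i, 2):
                AI[i, j] = AI[j, i] = 0.5 * float(ws[i] @ Pw[j])
        return ll, beta, traces, quads, AI


def reml_fit(
    y,
    relationship_matrices,
    max_iter: int = 200,
    tol: float = 1e-6,
    init=None,
    X=None,
    method: str = "ai",
    term_names: tuple[str, ...] | None = None,
    n_em_warmup: int = 3,
) -> FitResult:
    """Fit the variance components of a multi-kernel GBLUP model by REML.

    Returns estimates for every kernel and the residual, the GLS fixed
    effects at the optimum, the restricted log-likelihood, and convergence
    state (non-convergence is flagged, not fatal). Components are bounded
    below at 1e-8 * var(y).
    """
    Ks = _as_matrices(relationship_matrices)
    y, Xd = _design(y, X)
    n = len(y)
    if n < 2:
        raise RemlError("need at least 2 records")
    for K in Ks:
        if K.shape[0] != n:
            raise RemlError("relationship matrix size does not match phenotypes")
    vary = float(np.var(y, ddof=1))
    if vary == 0:
        raise RemlError("phenotype has zero variance")
    if method not in ("ai", "em"):
        raise RemlError(f"unknown REML method {method!r}")

    k = len(Ks)
    names = tuple(term_names) if term_names else tuple(f"g{i + 1}" for i in range(k))
    if len(names) != k:
        raise RemlError("term_names length does not match number of kernels")
    lb = 1e-8 * vary
    theta = (np.full(k + 1, vary / (k + 1))
             if init is None else np.asarray(init, dtype=np.float64).copy())
    if len(theta) != k + 1 or np.any(theta < 0):
        raise RemlError("init must give a non-negative variance per kernel plus residual")
    theta = np.maximum(theta, lb)

    spectral = _SpectralWork(Ks[0], y, Xd) if k == 1 else None
    stats = spectral.stats if spectral is not None else (lambda t: _dense_stats(t, Ks, y, Xd))

    converged = False
    prev_ll = -np.inf
    beta = np.zeros(Xd.shape[1])
    ll = -np.inf
    history: list[np.ndarray] = []
    it = 0
    for it in range(1, max_iter + 1):
        ll, beta, traces, quads, AI = stats(theta)
        # multiplicative EM-type fixed point: contracts geometrically toward
        # a zero boundary where the additive EM step (theta^2-scaled) stalls
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(traces > 0, quads / traces, 1.0)
        em_step = np.maximum(theta * ratio, lb)

        new = None
        score = 0.5 * (quads - traces)
        # components pinned at the lower bound with negative score stay put
        pinned = (theta <= 2 * lb) & (score < 0)
        if method == "ai" and it > n_em_warmup and ll >= prev_ll - 1e-8:
            free = ~pinned
            try:
                delta = np.zeros(k + 1)
                if free.any():
                    AIf = AI[np.ix_(free, free)] + 1e-10 * np.eye(int(free.sum()))
                    delta[free] = np.linalg.solve(AIf, score[free])
                cand = np.maximum(theta + delta, lb)
                cand[pinned] = lb
                if np.all(np.isfinite(cand)) and np.max(np.abs(delta)) < 1e3 * vary:
                    new = cand
            except np.linalg.LinAlgError:
                new = None
        if new is None:
            new = em_step
            new[pinned] = lb
            if method == "em":
                # Aitken extrapolation on the EM sequence every fourth step
                history.append(new.copy())
                if len(history) >= 3 and it % 4 == 0:
                    t1, t2, t3 = history[-3], history[-2], history[-1]
                    d1, d2 = t2 - t1, t3 - t2
                    denom = d2 - d1
                    safe = np.abs(denom) > 1e-12
                    acc = t3.copy()
                    acc[safe] = t3[safe] - d2[safe] ** 2 / denom[safe]
                    if np.all(acc >= 0):
                        try:
                            if restricted_loglik(y, Ks, np.maximum(acc, lb), Xd) > ll:
                                new = np.maximum(acc, lb)
                        except RemlError:
                            pass

        rel_change = np.max(np.abs(new - theta) / np.maximum(theta, lb))
        prev_ll = ll
        theta = new
        if rel_change < tol:
            converged = True
            break

    ll, beta, *_ = stats(theta)
    variances = {name: float(v) for name, v in zip(names, theta[:-1])}
    variances["residual"] = float(theta[-1])
    return FitResult(variances=variances, beta=beta, loglik=float(ll),
                     n_iter=it, converged=converged, term_names=names)


def predict_gebv(
    fit: FitResult,
    full_relationship_matrices,
    training_idx: np.ndarray,
    validation_idx: np.ndarray,
    y_training: np.ndarray,
    ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """GEBV for validation individuals from a training-only fit.

    ``full_relationship_matrices`` cover training and validation
    individuals; ``training_idx``/``validation_idx`` index rows of those
    matrices and must be disjoint. Returns one column per random term plus
    their sum ("total"), for the validation individuals.
    """
    Ks = _as_matrices(full_relationship_matrices)
    t = np.asarray(training_idx)
    v = np.asarray(validation_idx)
    if np.intersect1d(t, v).size:
        raise RemlError("training and validation sets overlap")
    if len(fit.term_names) != len(Ks):
        raise RemlError("number of matrices does not match fitted terms")
    sigmas = [fit.variances[name] for name in fit.term_names]
    if any(s < 0 for s in sigmas) or fit.residual_variance < 0:
        raise RemlError("variance components must be non-negative")
    yt = np.asarray(y_training, dtype=np.float64).ravel()
    if len(yt) != len(t):
        raise RemlError("y_training length does not match training index")

    n_t = len(t)
    V = fit.residual_variance * np.eye(n_t)
    for s2, K in zip(sigmas, Ks):
        V += s2 * K[np.ix_(t, t)]
    c = cho_factor(V, lower=True)
    w = cho_solve(c, yt - fit.mu)

    data: dict[str, np.ndarray] = {}
    total = np.zeros(len(v))
    for name, s2, K in zip(fit.term_names, sigmas, Ks):
        g = s2 * (K[np.ix_(v, t)] @ w)
        data[name] = g
        total += g
    data["total"] = total
    index = np.asarray(ids)[v] if ids is not None else v
    return pd.DataFrame(data, index=index)
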