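"""Restricted maximum likelihood for mixed models with dense animal-effect
covariances.

The model is y = X b + sum_i u_i + e with u_i ~ N(0, K_i sigma2_i) and
e ~ N(0, I sigma2_e), where each K_i is a dense n x n relationship matrix
(G, T or T_c).  Variance components are estimated by average-information
REML with EM fallback steps and a nonnegativity floor; BLUPs and fixed
effects are read off the mixed-model equations at the optimum.

A single-random-term fast path diagonalizes K once and evaluates every
iteration in O(n p^2), which makes repeated fits (cross-validation folds,
grid searches, null simulations) cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

LOG2PI = float(np.log(2.0 * np.pi))


def _as_matrix(K):
    from .relmat import RelationshipMatrix

    if isinstance(K, RelationshipMatrix):
        return K.values
    return np.asarray(K, dtype=float)


def reml_loglik(y, X, terms, sigma2_e: float) -> float:
    """REML log-likelihood of y ~ N(Xb, V), V = sum K_i s2_i + I s2_e.

    Includes the -(n-p)/2 log(2 pi) constant so values are comparable
    across models fitted to the same (y, X).

    Parameters
    ----------
    terms : list of (K, sigma2) pairs; K may be a RelationshipMatrix or array.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n, p = X.shape
    V = sigma2_e * np.eye(n)
    for K, s2 in terms:
        V = V + s2 * _as_matrix(K)
    try:
        L = scipy.linalg.cholesky(V, lower=True)
    except scipy.linalg.LinAlgError as err:
        raise ValueError("V is not positive definite") from err
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    ViX = scipy.linalg.cho_solve((L, True), X)
    Viy = scipy.linalg.cho_solve((L, True), y)
    XtViX = X.T @ ViX
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise ValueError("X'V^-1X not positive definite (X rank deficient?)")
    beta = scipy.linalg.solve(XtViX, X.T @ Viy, assume_a="pos")
    Py = Viy - ViX @ beta
    yPy = float(y @ Py)
    return -0.5 * (logdetV + logdetXtViX + yPy + (n - p) * LOG2PI)


@dataclass
class REMLFit:
    """Raw output of the REML optimizer (wrapped by models.BLUPResults)."""

    sigma2: np.ndarray          # variance components, residual last
    labels: list                # term labels, 'residual' last
    loglik: float
    beta: np.ndarray
    blups: dict                 # label -> (n,) BLUP vector
    se_sigma2: np.ndarray       # SEs from the inverse AI matrix
    ai_matrix: np.ndarray
    converged: bool
    n_iter: int
    trace: list = field(default_factory=list)
    boundary: np.ndarray = None  # mask of components pinned at the floor


class _DenseOps:
    """Per-iteration REML quantities with explicit V inversion."""

    def __init__(self, y, X, Ks):
        self.y = np.asarray(y, dtype=float)
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            self.X = self.X.T
        self.Ks = [np.asarray(K, dtype=float) for K in Ks]
        self.n, self.p = self.X.shape

    def quantities(self, theta):
        n, p, X, y = self.n, self.p, self.X, self.y
        V = theta[-1] * np.eye(n)
        for K, s2 in zip(self.Ks, theta[:-1]):
            V = V + s2 * K
        L = scipy.linalg.cholesky(V, lower=True)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
        Vi = scipy.linalg.cho_solve((L, True), np.eye(n))
        ViX = Vi @ X
        XtViX = X.T @ ViX
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        B = scipy.linalg.solve(XtViX, ViX.T, assume_a="pos")
        P = Vi - ViX @ B
        Py = P @ y
        yPy = float(y @ Py)
        loglik = -0.5 * (logdetV + logdetXtViX + yPy + (n - p) * LOG2PI)
        # score_i = -0.5 [tr(P K_i) - y'P K_i P y];   K for residual is I
        mats = self.Ks + [None]
        q = len(mats)
        trPK = np.empty(q)
        yPKPy = np.empty(q)
        Kv = []
        for i, K in enumerate(mats):
            if K is None:
                trPK[i] = float(np.trace(P))
                v = Py.copy()
            else:
                trPK[i] = float(np.sum(P * K))  # both symmetric
                v = K @ Py
            Kv.append(v)
            yPKPy[i] = float(Py @ v)
        score = -0.5 * (trPK - yPKPy)
        AI = np.empty((q, q))
        Pv = [P @ v for v in Kv]
        for i in range(q):
            for j in range(i, q):
                AI[i, j] = AI[j, i] = 0.5 * float(Kv[i] @ Pv[j])
        return loglik, score, AI, Py, trPK, yPKPy

    def loglik_only(self, theta):
        return reml_loglik(self.y, self.X, list(zip(self.Ks, theta[:-1])), theta[-1])

    def blups(self, theta, Py):
        return {i: theta[i] * (self.Ks[i] @ Py) for i in range(len(self.Ks))}

    def beta(self, theta):
        n = self.n
        V = theta[-1] * np.eye(n)
        for K, s2 in zip(self.Ks, theta[:-1]):
            V = V + s2 * K
        L = scipy.linalg.cholesky(V, lower=True)
        ViX = scipy.linalg.cho_solve((L, True), self.X)
        Viy = scipy.linalg.cho_solve((L, True), self.y)
        return scipy.linalg.solve(self.X.T @ ViX, self.X.T @ Viy, assume_a="pos")


class _EigenOps:
    """Single-K fast path: rotate by the eigenvectors of K so V is diagonal."""

    def __init__(self, y, X, K):
        y = np.asarray(y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != y.shape[0]:
            X = X.T
        d, U = scipy.linalg.eigh(np.asarray(K, dtype=float))
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.yt = U.T @ y
        self.Xt = U.T @ X
        self.n, self.p = X.shape

    def quantities(self, theta):
        s2k, s2e = theta
        n, p = self.n, self.p
        vdiag = s2k * self.d + s2e
        if np.any(vdiag <= 0):
            raise scipy.linalg.LinAlgError("V not PD")
        vi = 1.0 / vdiag
        ViX = self.Xt * vi[:, None]
        XtViX = self.Xt.T @ ViX
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        Bi = scipy.linalg.solve(XtViX, ViX.T, assume_a="pos")  # (p, n)
        Py = vi * self.yt - ViX @ (Bi @ self.yt)
        yPy = float(self.yt @ Py)
        logdetV = float(np.sum(np.log(vdiag)))
        loglik = -0.5 * (logdetV + logdetXtViX + yPy + (n - p) * LOG2PI)
        diagP = vi - np.einsum("ij,ji->i", ViX, Bi)

        def Pdot(v):
            return vi * v - ViX @ (Bi @ v)

        trPK = np.array([float(diagP @ self.d), float(diagP.sum())])
        Kv = [self.d * Py, Py.copy()]
        yPKPy = np.array([float(Py @ Kv[0]), float(Py @ Kv[1])])
        score = -0.5 * (trPK - yPKPy)
        Pv = [Pdot(v) for v in Kv]
        AI = np.empty((2, 2))
        for i in range(2):
            for j in range(i, 2):
                AI[i, j] = AI[j, i] = 0.5 * float(Kv[i] @ Pv[j])
        return loglik, score, AI, Py, trPK, yPKPy

    def loglik_only(self, theta):
        s2k, s2e = theta
        vdiag = s2k * self.d + s2e
        if np.any(vdiag <= 0):
            raise scipy.linalg.LinAlgError("V not PD")
        vi = 1.0 / vdiag
        ViX = self.Xt * vi[:, None]
        XtViX = self.Xt.T @ ViX
        _, logdetXtViX = np.linalg.slogdet(XtViX)
        beta = scipy.linalg.solve(XtViX, ViX.T @ self.yt, assume_a="pos")
        Py = vi * self.yt - ViX @ beta
        yPy = float(self.yt @ Py)
        return -0.5 * (float(np.sum(np.log(vdiag))) + logdetXtViX + yPy
                       + (self.n - self.p) * LOG2PI)

    def blups(self, theta, Py):
        # back-rotate: u = s2k K P y = s2k U D U' (U Py_rot)
        return {0: theta[0] * (self.U @ (self.d * Py))}

    def beta(self, theta):
        s2k, s2e = theta
        vi = 1.0 / (s2k * self.d + s2e)
        ViX = self.Xt * vi[:, None]
        return scipy.linalg.solve(self.Xt.T @ ViX, ViX.T @ self.yt, assume_a="pos")


def ai_reml(y, X, Ks, labels=None, start=None, max_iter: int = 200,
            tol_loglik: float = 1e-8, tol_param: float = 1e-6,
            use_eigen: bool = None) -> REMLFit:
    """Estimate variance components by average-information REML.

    AI updates with step halving; an EM step is taken whenever the damped AI
    step still fails to improve the log-likelihood.  Components are floored
    at 1e-8 * Var(y) (nonnegativity constraint); components that finish on
    the floor are flagged as boundary estimates.
    """
    y = np.asarray(y, dtype=float)
    Ks = [_as_matrix(K) for K in Ks]
    if labels is None:
        labels = [f"K{i}" for i in range(len(Ks))]
    labels = list(labels) + ["residual"]
    if use_eigen is None:
        use_eigen = len(Ks) == 1
    ops = _EigenOps(y, X, Ks[0]) if (use_eigen and len(Ks) == 1) else _DenseOps(y, X, Ks)

    vary = float(np.var(y, ddof=1))
    floor = 1e-8 * vary
    q = len(Ks) + 1
    if start is None:
        theta = np.full(q, vary / q)
    else:
        theta = np.asarray(start, dtype=float).copy()
    theta = np.maximum(theta, floor)

    loglik, score, AI, Py, trPK, yPKPy = ops.quantities(theta)
    trace = [(theta.copy(), loglik)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # AI step with step halving
        try:
            delta = np.linalg.solve(AI, score)
            if not np.all(np.isfinite(delta)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            delta = np.linalg.pinv(AI) @ score
        accepted = False
        stepsize = 1.0
        for _ in range(12):
            cand = np.maximum(theta + stepsize * delta, floor)
            try:
                cand_ll = ops.loglik_only(cand)
            except scipy.linalg.LinAlgError:
                cand_ll = -np.inf
            if np.isfinite(cand_ll) and cand_ll >= loglik - 1e-12:
                accepted = True
                break
            stepsize /= 2.0
        if not accepted:
            # EM fallback: guaranteed-ascent style update
            n = ops.n
            cand = theta + theta**2 * (yPKPy - trPK) / n
            cand = np.maximum(cand, floor)
            try:
                cand_ll = ops.loglik_only(cand)
            except scipy.linalg.LinAlgError:
                cand_ll, cand = loglik, theta
        dll = cand_ll - loglik
        dpar = np.max(np.abs(cand - theta) / np.maximum(np.abs(theta), floor))
        theta = cand
        loglik, score, AI, Py, trPK, yPKPy = ops.quantities(theta)
        trace.append((theta.copy(), loglik))
        if abs(dll) < tol_loglik and dpar < tol_param:
            converged = True
            break

    boundary = theta <= floor * (1 + 1e-9)
    try:
        se = np.sqrt(np.diag(np.linalg.inv(AI)))
    except np.linalg.LinAlgError:
        se = np.sqrt(np.diag(np.linalg.pinv(AI)))
    blup_map = ops.blups(theta, Py)
    blups = {labels[i]: blup_map[i] for i in blup_map}
    beta = ops.beta(theta)
    return REMLFit(sigma2=theta, labels=labels, loglik=float(loglik), beta=beta,
                   blups=blups, se_sigma2=se, ai_matrix=AI, converged=converged,
                   n_iter=it, trace=trace, boundary=boundary)
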