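"""Bivariate TBLUP: transcriptomic correlations between two traits.

The stacked model y = (y1, y2) has covariance Sigma_t (x) T + Sigma_e (x) I
with 2x2 trait covariance matrices for the transcriptomic animal effect and
the residual.  Diagonalizing T once turns the REML log-likelihood into a
product over n independent 2x2 blocks, so each evaluation is O(n p^2) and
direct numerical maximization over the Cholesky factors of Sigma_t and
Sigma_e (PSD guaranteed) is cheap.  The transcriptomic correlation
r_t = Sigma_t[1,2] / sqrt(Sigma_t[1,1] Sigma_t[2,2]) is tested against
zero with a likelihood-ratio test (refit with Sigma_t diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.stats

from .relmat import RelationshipMatrix
from .reml import LOG2PI, ai_reml

_LOGD_FLOOR = -8.0  # floor on log Cholesky diagonals (|r| reachable to ~1 - 1e-7)


@dataclass
class BivariateResults:
    sigma_t: np.ndarray          # 2x2 transcriptomic covariance
    sigma_e: np.ndarray          # 2x2 residual covariance
    llf: float
    converged: bool
    se_r_t: float = None
    model: object = field(repr=False, default=None)
    params: np.ndarray = field(repr=False, default=None)

    @property
    def r_t(self) -> float:
        s = self.sigma_t
        return float(s[0, 1] / np.sqrt(s[0, 0] * s[1, 1]))

    @property
    def r_e(self) -> float:
        s = self.sigma_e
        return float(s[0, 1] / np.sqrt(s[0, 0] * s[1, 1]))

    def summary(self) -> str:
        lines = [
            "Bivariate TBLUP REML fit",
            "=" * 40,
            f"logL (REML): {self.llf:.4f}   converged: {self.converged}",
            f"r_t = {self.r_t:+.3f}" + (f" (SE {self.se_r_t:.3f})" if self.se_r_t else ""),
            f"r_e = {self.r_e:+.3f}",
            f"sigma2_t: {self.sigma_t[0,0]:.4f}, {self.sigma_t[1,1]:.4f}",
            f"sigma2_e: {self.sigma_e[0,0]:.4f}, {self.sigma_e[1,1]:.4f}",
        ]
        return "\n".join(lines)


def _chol_from_params(theta):
    """(log d1, off, log d2) -> lower-triangular 2x2 Cholesky factor."""
    return np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])


class BivariateTBLUP:
    """Two traits, one transcriptomic relationship matrix, shared fixed design."""

    def __init__(self, y1, y2, X, T, fix_re: bool = False):
        y1 = np.asarray(y1, dtype=float)
        y2 = np.asarray(y2, dtype=float)
        if y1.shape != y2.shape:
            raise ValueError("traits must be measured on the same animals")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != y1.shape[0]:
            X = X.T
        Tv = T.values if isinstance(T, RelationshipMatrix) else np.asarray(T, dtype=float)
        d, U = scipy.linalg.eigh(Tv)
        self.d = np.clip(d, 0.0, None)
        self.y1r = U.T @ y1
        self.y2r = U.T @ y2
        self.Xr = U.T @ X
        self.n, self.p = X.shape
        self.fix_re = fix_re
        self._y1, self._y2, self._X, self._T = y1, y2, X, Tv

    # -- REML log-likelihood over n independent 2x2 blocks ---------------
    def loglik(self, sigma_t: np.ndarray, sigma_e: np.ndarray) -> float:
        d, A = self.d, self.Xr
        v11 = sigma_t[0, 0] * d + sigma_e[0, 0]
        v12 = sigma_t[0, 1] * d + sigma_e[0, 1]
        v22 = sigma_t[1, 1] * d + sigma_e[1, 1]
        det = v11 * v22 - v12**2
        if np.any(det <= 0) or np.any(v11 <= 0):
            return -np.inf
        logdetV = float(np.sum(np.log(det)))
        i11, i12, i22 = v22 / det, -v12 / det, v11 / det
        # X'V^-1X in 2x2 blocks of size p
        B11 = A.T @ (i11[:, None] * A)
        B12 = A.T @ (i12[:, None] * A)
        B22 = A.T @ (i22[:, None] * A)
        XtViX = np.block([[B11, B12], [B12, B22]])
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf
        b1 = A.T @ (i11 * self.y1r + i12 * self.y2r)
        b2 = A.T @ (i12 * self.y1r + i22 * self.y2r)
        XtViy = np.concatenate([b1, b2])
        try:
            c = np.linalg.cholesky(XtViX)
            beta = scipy.linalg.cho_solve((c, True), XtViy)
        except np.linalg.LinAlgError:
            return -np.inf
        yViy = float(np.sum(i11 * self.y1r**2 + 2 * i12 * self.y1r * self.y2r
                            + i22 * self.y2r**2))
        yPy = yViy - float(XtViy @ beta)
        N, p2 = 2 * self.n, 2 * self.p
        return -0.5 * (logdetV + logdetXtViX + yPy + (N - p2) * LOG2PI)

    def _nll(self, theta, diag_t: bool):
        st, se = self._unpack(theta, diag_t)
        ll = self.loglik(st, se)
        return -ll if np.isfinite(ll) else 1e12

    def _unpack(self, theta, diag_t: bool):
        if diag_t:
            st = _chol_from_params(np.array([theta[0], 0.0, theta[1]]))
            rest = theta[2:]
        else:
            st = _chol_from_params(theta[:3])
            rest = theta[3:]
        if self.fix_re:
            sec = _chol_from_params(np.array([rest[0], 0.0, rest[1]]))
        else:
            sec = _chol_from_params(rest[:3])
        return st @ st.T, sec @ sec.T

    def _starts(self, diag_t: bool):
        u1 = ai_reml(self._y1, self._X, [self._T], labels=["t"])
        u2 = ai_reml(self._y2, self._X, [self._T], labels=["t"])
        s2t = np.maximum([u1.sigma2[0], u2.sigma2[0]], 1e-6)
        s2e = np.maximum([u1.sigma2[1], u2.sigma2[1]], 1e-6)
        starts = []
        for r in ((0.0,) if diag_t else (0.0, 0.8, -0.8)):
            lt = [0.5 * np.log(s2t[0]),
                  r * np.sqrt(s2t[1]),
                  0.5 * np.log(max(s2t[1] * (1 - r**2), 1e-8))]
            le = [0.5 * np.log(s2e[0]), 0.0, 0.5 * np.log(s2e[1])]
            if diag_t:
                lt = [lt[0], lt[2]]
            if self.fix_re:
                le = [le[0], le[2]]
            starts.append(np.array(lt + le))
        return starts

    def _bounds(self, diag_t: bool):
        """Log Cholesky diagonals bounded in [-15, 10]; off-diagonals free."""
        n_t = 2 if diag_t else 3
        n_e = 2 if self.fix_re else 3
        b = []
        for block, sz in (("t", n_t), ("e", n_e)):
            if sz == 2:
                b += [(_LOGD_FLOOR, 10.0)] * 2
            else:
                b += [(_LOGD_FLOOR, 10.0), (-1e3, 1e3), (_LOGD_FLOOR, 10.0)]
        return b

    def fit(self, diag_t: bool = False, compute_se: bool = True) -> BivariateResults:
        """Maximize the bivariate REML log-likelihood (Nelder-Mead polish
        after L-BFGS-B), multi-starting from the univariate fits."""
        best = None
        for x0 in self._starts(diag_t):
            bounds = self._bounds(diag_t)
            res = scipy.optimize.minimize(self._nll, x0, args=(diag_t,),
                                          method="L-BFGS-B", bounds=bounds,
                                          options={"maxiter": 500, "ftol": 1e-13})
            res2 = scipy.optimize.minimize(self._nll, res.x, args=(diag_t,),
                                           method="Nelder-Mead", bounds=bounds,
                                           options={"maxiter": 4000,
                                                    "fatol": 1e-10, "xatol": 1e-9})
            cand = res2 if res2.fun < res.fun else res
            if best is None or cand.fun < best.fun:
                best = cand
        st, se_mat = self._unpack(best.x, diag_t)
        out = BivariateResults(sigma_t=st, sigma_e=se_mat, llf=-best.fun,
                               converged=bool(np.isfinite(best.fun)),
                               model=self, params=best.x)
        if compute_se and not diag_t:
            out.se_r_t = self._se_r_t(best.x, diag_t)
        return out

    def _se_r_t(self, theta, diag_t: bool) -> float:
        """Delta-method SE of r_t from the observed information matrix."""
        q = len(theta)
        h = 1e-4
        H = np.zeros((q, q))
        f0 = self._nll(theta, diag_t)
        for i in range(q):
            for j in range(i, q):
                ei = np.zeros(q); ei[i] = h
                ej = np.zeros(q); ej[j] = h
                fpp = self._nll(theta + ei + ej, diag_t)
                fpm = self._nll(theta + ei - ej, diag_t)
                fmp = self._nll(theta - ei + ej, diag_t)
                fmm = self._nll(theta - ei - ej, diag_t)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
        grad = np.zeros(q)
        for i in range(q):
            ei = np.zeros(q); ei[i] = h
            rp = self._r_of(theta + ei, diag_t)
            rm = self._r_of(theta - ei, diag_t)
            grad[i] = (rp - rm) / (2 * h)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        var = float(grad @ cov @ grad)
        return float(np.sqrt(var)) if var > 0 else np.nan

    def _r_of(self, theta, diag_t):
        st, _ = self._unpack(theta, diag_t)
        return float(st[0, 1] / np.sqrt(st[0, 0] * st[1, 1]))


def correlation_lrt(full: BivariateResults, model: BivariateTBLUP = None):
    """LRT of H0: r_t = 0 via a refit with Sigma_t constrained diagonal.

    D = 2 [logL(full) - logL(diag)]; p from chi-square with 1 df.
    """
    model = model or full.model
    reduced = model.fit(diag_t=True, compute_se=False)
    D = 2.0 * (full.llf - reduced.llf)
    if D < -1e-6:
        raise ValueError(f"negative LRT statistic D={D:.3g}")
    D = max(D, 0.0)
    p = float(scipy.stats.chi2.sf(D, 1)) if D > 0 else 1.0
    return D, p
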