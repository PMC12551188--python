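"""Back-solving individual transcript effects from TBLUP animal effects.

The TBLUP animal effect t-hat aggregates k transcript-level effects; the
per-transcript effects are recovered as u-hat = (1/k) W' T^-1 t-hat, with
sampling variance built from the prediction error variance (PEV) of t-hat
via the inverse mixed-model-equation block C^tt.  Each standardized effect
RNA_j = u_j / sqrt(Var(u_j)) is tested against a standard normal, with
both a nominal 0.05 and a Bonferroni threshold reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.stats

from .relmat import RelationshipMatrix, DEFAULT_RIDGE


@dataclass
class TranscriptEffectResult:
    u_hat: np.ndarray
    var_u: np.ndarray
    rna_stat: np.ndarray = field(init=False)
    p_values: np.ndarray = field(init=False)
    bonferroni_alpha: float = None
    transcript_ids: list = None
    ridge: float = None

    def __post_init__(self):
        u, v = self.u_hat, self.var_u
        stat = np.zeros_like(u)
        pos = v > 0
        stat[pos] = u[pos] / np.sqrt(v[pos])
        p = 2.0 * scipy.stats.norm.sf(np.abs(stat))
        zero_var = ~pos
        if np.any(zero_var & (u != 0)):
            warnings.warn("zero Var(u) with nonzero effect: p set to 0", stacklevel=2)
            p[zero_var & (u != 0)] = 0.0
        p[zero_var & (u == 0)] = 1.0
        self.rna_stat = stat
        self.p_values = p

    def to_frame(self):
        import pandas as pd

        ids = self.transcript_ids or [f"tx{j}" for j in range(len(self.u_hat))]
        return pd.DataFrame({
            "transcript_id": ids, "u_hat": self.u_hat, "var_u": self.var_u,
            "rna_stat": self.rna_stat, "p_value": self.p_values,
            "neg_log10_p": -np.log10(np.maximum(self.p_values, 1e-300)),
        })

    def plot(self, ax=None, title=None):
        """Manhattan-style plot: -log10(p) per transcript with the nominal
        0.05 line and the Bonferroni-corrected line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        neglog = -np.log10(np.maximum(self.p_values, 1e-300))
        ax.scatter(np.arange(len(neglog)), neglog, s=12, color="0.3")
        ax.axhline(-np.log10(0.05), color="salmon", lw=1, label="p = 0.05")
        if self.bonferroni_alpha:
            ax.axhline(-np.log10(self.bonferroni_alpha), color="darkred", lw=1,
                       label="Bonferroni 0.05")
        ax.set_xlabel("transcript")
        ax.set_ylabel(r"$-\log_{10}(p)$")
        if title:
            ax.set_title(title)
        ax.legend(frameon=False, fontsize=8)
        return ax


def _tinv(T, ridge: float):
    Tm = T.ridged(ridge) if isinstance(T, RelationshipMatrix) else (
        np.asarray(T, dtype=float)
        + ridge * float(np.mean(np.diag(T))) * np.eye(np.asarray(T).shape[0]))
    return np.linalg.inv(Tm)


def backsolve_effects(W, T, t_hat, k: int = None, ridge: float = DEFAULT_RIDGE) -> np.ndarray:
    """u-hat = (1/k) W' T^-1 t-hat.

    When T is exactly invertible (k >= n) the consistency identity
    W u-hat = t-hat holds; for k < n, T is singular and a small relative
    ridge stabilizes the inverse.
    """
    W = np.asarray(W, dtype=float)
    t_hat = np.asarray(t_hat, dtype=float)
    if t_hat.shape[0] != W.shape[0]:
        raise ValueError("t_hat length must equal the number of animals")
    if k is None:
        k = W.shape[1]
    Ti = _tinv(T, ridge)
    return (W.T @ (Ti @ t_hat)) / k


def ctt_matrix(X, T, sigma2_e: float, sigma2_t: float,
               ridge: float = DEFAULT_RIDGE) -> np.ndarray:
    """PEV block of the mixed-model equations for the animal effect:

    C^tt = sigma2_e (I - X (X'X)^-1 X' + T^-1 lambda)^-1, lambda = sigma2_e/sigma2_t.

    Valid when every animal has one record (the incidence matrix of t is
    the identity).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Tv = T.values if isinstance(T, RelationshipMatrix) else np.asarray(T, dtype=float)
    n = Tv.shape[0]
    if X.shape[0] != n:
        X = X.T
    if X.shape[0] != n:
        raise ValueError("X rows must equal the number of animals")
    if sigma2_t <= 0 or sigma2_e <= 0:
        raise ValueError("variances must be positive")
    lam = sigma2_e / sigma2_t
    XtX = X.T @ X
    P_X = X @ scipy.linalg.solve(XtX, X.T, assume_a="pos")
    Ti = _tinv(T, ridge)
    inner = np.eye(n) - P_X + Ti * lam
    cond = np.linalg.cond(inner)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"C^tt inner matrix numerically singular (condition number {cond:.3g})")
    Ctt = sigma2_e * np.linalg.inv(inner)
    return (Ctt + Ctt.T) / 2.0


def effect_variance(W, T, Ctt, sigma2_t: float, k: int = None,
                    ridge: float = DEFAULT_RIDGE) -> np.ndarray:
    """diag of Var(u-hat) = (1/k^2) W' T^-1 (T sigma2_t - C^tt) T^-1 W.

    T sigma2_t - C^tt is Var(t-hat); negative diagonal entries beyond
    numerical noise signal an inconsistent PEV and raise; tiny negatives
    are clipped to zero.
    """
    W = np.asarray(W, dtype=float)
    if k is None:
        k = W.shape[1]
    Ti = _tinv(T, ridge)
    Tv = T.values if isinstance(T, RelationshipMatrix) else np.asarray(T, dtype=float)
    M = Tv * sigma2_t - np.asarray(Ctt, dtype=float)
    TiW = Ti @ W
    var_u = np.einsum("ij,jl,li->i", TiW.T, M, TiW) / k**2
    scale = max(float(np.max(np.abs(var_u))), 1.0)
    if np.any(var_u < -1e-10 * scale):
        raise ValueError("negative Var(u): PEV larger than prior variance "
                         "(check sigma2_t / sigma2_e or the ridge)")
    return np.clip(var_u, 0.0, None)


def rna_test(u_hat, var_u, n_tests: int = None, transcript_ids=None,
             ridge: float = None) -> TranscriptEffectResult:
    """Two-sided normal test of each standardized transcript effect.

    Reports p_j = 2 (1 - Phi(|RNA_j|)) plus the Bonferroni threshold
    0.05 / n_tests alongside the nominal 0.05 level.
    """
    u_hat = np.asarray(u_hat, dtype=float)
    var_u = np.asarray(var_u, dtype=float)
    if np.any(var_u < 0):
        raise ValueError("var_u must be nonnegative")
    if n_tests is None:
        n_tests = len(u_hat)
    return TranscriptEffectResult(u_hat=u_hat, var_u=var_u,
                                  bonferroni_alpha=0.05 / n_tests,
                                  transcript_ids=transcript_ids, ridge=ridge)


def transcript_effect_pipeline(W, T, tblup_results, k: int = None,
                               transcript_ids=None,
                               ridge: float = DEFAULT_RIDGE) -> TranscriptEffectResult:
    """Back-solve and test transcript effects from a fitted TBLUP model."""
    t_hat = tblup_results.blups["t"]
    s2t = tblup_results.variance_components["t"]
    s2e = tblup_results.sigma2_e
    u = backsolve_effects(W, T, t_hat, k=k, ridge=ridge)
    Ctt = ctt_matrix(tblup_results.model.X, T, s2e, s2t, ridge=ridge)
    v = effect_variance(W, T, Ctt, s2t, k=k, ridge=ridge)
    return rna_test(u, v, transcript_ids=transcript_ids, ridge=ridge)
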