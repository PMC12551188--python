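"""Box-Cox transformation, standardization and transcript pre-correction.

Skewed traits are power-transformed with a trait-specific Box-Cox lambda
chosen by maximum likelihood on a grid, then centered and scaled.
Transcript abundances get the same treatment per column, followed by a
least-squares pre-correction for technical fixed effects (test day, plate,
sex, housekeeping-gene covariates), leaving residual columns orthogonal to
the covariates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.special
import scipy.stats

from .data import TranscriptData

logger = logging.getLogger(__name__)


@dataclass
class BoxCoxResult:
    """Grid-search ML estimate of the Box-Cox exponent.

    `profile` holds (lambda, log-likelihood) pairs over the coarse grid;
    `lambda_hat` comes from a refinement pass around the best grid point.
    """

    lambda_hat: float
    profile: np.ndarray  # (n_grid, 2): lambda, loglik
    transformed: np.ndarray


def boxcox(y, lam: float) -> np.ndarray:
    """Two-branch power transform: (y^lam - 1)/lam, or log(y) when lam = 0."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        bad = np.flatnonzero(y <= 0)
        raise ValueError(f"Box-Cox requires positive values; offending indices: {bad.tolist()}")
    return scipy.special.boxcox(y, lam)


def _profile_loglik(y: np.ndarray, lams: np.ndarray) -> np.ndarray:
    return np.array([scipy.stats.boxcox_llf(l, y) for l in lams])


def boxcox_mle(y, lo: float = -4.0, hi: float = 6.0, step: float = 0.001) -> BoxCoxResult:
    """Choose lambda by grid search over the normal-theory profile likelihood.

    The profile log-likelihood includes the Jacobian term (lam - 1) * sum(log y).
    A coarse pass at `step` x 10 is followed by a refinement at `step` around
    the coarse optimum.  Ties are broken toward the grid value nearest 1.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("Box-Cox requires strictly positive data")
    if np.ptp(y) == 0:
        raise ValueError("Box-Cox profile undefined for constant data")
    coarse = np.arange(lo, hi + step * 10 / 2, step * 10)
    ll = _profile_loglik(y, coarse)
    best = _argmax_near_one(coarse, ll)
    a, b = coarse[best] - step * 10, coarse[best] + step * 10
    fine = np.arange(a, b + step / 2, step)
    llf = _profile_loglik(y, fine)
    bestf = _argmax_near_one(fine, llf)
    lam = float(fine[bestf])
    return BoxCoxResult(lam, np.column_stack([coarse, ll]), boxcox(y, lam))


def _argmax_near_one(grid: np.ndarray, ll: np.ndarray) -> int:
    top = ll.max()
    cand = np.flatnonzero(ll >= top - 1e-12)
    return int(cand[np.argmin(np.abs(grid[cand] - 1.0))])


def standardize(v) -> np.ndarray:
    """Center to mean 0 and scale to SD 1 (sample SD, denominator n - 1)."""
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def precorrect_transcripts(raw, covariates, transcript_ids=None, animal_ids=None,
                           apply_boxcox: bool = True) -> TranscriptData:
    """Transform, standardize and pre-correct transcript abundances.

    Per column: Box-Cox (ML lambda) -> standardize -> replace by OLS
    residuals on the covariates -> re-center.  Covariates must include an
    intercept column; aliased (rank-deficient) covariate columns are dropped
    with a warning.  Residual columns are orthogonal to every covariate.
    """
    raw = np.asarray(raw, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.shape[0] != raw.shape[0]:
        raise ValueError("covariate rows must align with transcript rows")
    if not np.any(np.all(C == C[0], axis=0) & (C[0] != 0)):
        # accept any column spanning the intercept: check 1 in column space
        ones = np.ones(C.shape[0])
        resid = ones - C @ np.linalg.lstsq(C, ones, rcond=None)[0]
        if np.linalg.norm(resid) > 1e-8 * np.sqrt(C.shape[0]):
            raise ValueError("covariates must include an intercept column")
    C = _drop_aliased(C)
    n, k = raw.shape
    cols = []
    for j in range(k):
        col = raw[:, j]
        if apply_boxcox:
            col = boxcox_mle(col, step=0.01).transformed
        col = standardize(col)
        beta, *_ = np.linalg.lstsq(C, col, rcond=None)
        col = col - C @ beta
        cols.append(col - col.mean())
    W = np.column_stack(cols)
    if transcript_ids is None:
        transcript_ids = [f"tx{j}" for j in range(k)]
    if animal_ids is None:
        animal_ids = list(range(n))
    return TranscriptData(raw=raw, W=W, animal_ids=list(animal_ids),
                          transcript_ids=list(transcript_ids))


def _drop_aliased(C: np.ndarray) -> np.ndarray:
    """Drop linearly dependent covariate columns (QR with column pivoting)."""
    q, r, piv = scipy.linalg.qr(C, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(C.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < C.shape[1]:
        dropped = sorted(piv[rank:])
        logger.warning("dropping aliased covariate columns: %s", dropped)
        warnings.warn(f"dropping aliased covariate columns: {dropped}", stacklevel=2)
        keep = sorted(piv[:rank])
        return C[:, keep]
    return C
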