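"""BLUP model family: GBLUP, TBLUP, GTBLUP, GTCBLUP and GTCBLUPi.

Each model class is constructed from data (phenotype vector, fixed-effect
design, relationship matrices or raw genotype/transcript matrices) and
`fit()` returns a :class:`BLUPResults` carrying REML variance components
with standard errors, fixed-effect estimates, BLUP animal effects, the
REML log-likelihood and AIC, plus a `summary()` table.

GTCBLUPi is the grid-search variant: the heritability of transcript-level
effects h2_t determines the conditioning ridge lambda = m_tilde (1/h2_t - 1);
the grid value maximizing the REML log-likelihood of the conditioned model
is selected.  GTCBLUP instead derives lambda from the trait's own GBLUP
heritability, lambda = m (1/h2 - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.stats

from .data import GenotypeData
from .relmat import (
    RelationshipMatrix,
    vanraden_g,
    transcript_t,
    conditioned_t,
    lambda_from_h2,
    choose_route,
    condition_w_direct,
    condition_w_woodbury,
)
from .reml import ai_reml, reml_loglik, REMLFit


@dataclass
class VarianceProportions:
    """Variance-component contributions as fractions of phenotypic variance.

    Each component's contribution is sigma2_i * mean(diag(K_i)) — the
    mean-diagonal scaling matters for conditioned transcript matrices whose
    diagonal is shrunk below 1 — and the residual contributes sigma2_e.
    """

    proportions: dict
    scaled_by_mean_diag: bool = True

    @property
    def h2(self) -> float:
        return self.proportions.get("g", 0.0)

    @property
    def t2(self) -> float:
        return self.proportions.get("t", self.proportions.get("t_c", 0.0))

    @property
    def e2(self) -> float:
        return self.proportions["residual"]


class BLUPResults:
    """Fitted mixed model: variance components, BLUPs, logL, AIC."""

    def __init__(self, model, fit: REMLFit):
        self.model = model
        self._fit = fit
        self.converged = fit.converged
        self.n_iter = fit.n_iter
        self.llf = fit.loglik
        self.params = fit.beta
        self.blups = fit.blups
        self.variance_components = dict(zip(fit.labels, fit.sigma2))
        self.std_errors = dict(zip(fit.labels, fit.se_sigma2))
        self.boundary = dict(zip(fit.labels, fit.boundary))

    @property
    def sigma2_e(self) -> float:
        return self.variance_components["residual"]

    @property
    def n_varparams(self) -> int:
        return len(self.variance_components)

    @property
    def aic(self) -> float:
        """AIC = -2 logL_REML + 2 x (number of variance parameters).

        Fixed effects are excluded from the count: compared models share X.
        """
        return -2.0 * self.llf + 2.0 * self.n_varparams

    def variance_proportions(self) -> VarianceProportions:
        total = self.sigma2_e
        contrib = {}
        for label, K in self.model.random_terms:
            c = self.variance_components[label] * float(np.mean(np.diag(_values(K))))
            contrib[label] = c
            total += c
        props = {lab: c / total for lab, c in contrib.items()}
        props["residual"] = self.sigma2_e / total
        return VarianceProportions(props)

    def lrt(self, reduced: "BLUPResults"):
        return lrt(self, reduced)

    def summary(self) -> str:
        name = self.model.model_name
        lines = [
            f"{name} REML fit",
            "=" * 46,
            f"n obs: {len(self.model.y):>6d}   converged: {self.converged}  "
            f"iter: {self.n_iter}",
            f"logL (REML): {self.llf:.4f}   AIC: {self.aic:.4f}",
            "-" * 46,
            f"{'component':<12}{'sigma2':>12}{'SE':>12}{'prop':>9}",
        ]
        props = self.variance_proportions().proportions
        for lab in self.variance_components:
            flag = "*" if self.boundary.get(lab) else " "
            lines.append(
                f"{lab:<12}{self.variance_components[lab]:>12.5f}"
                f"{self.std_errors[lab]:>12.5f}{props.get(lab, float('nan')):>8.3f}{flag}"
            )
        lines.append("-" * 46)
        lines.append("* component estimated on the zero boundary")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model.model_name,
            "variance_components": {k: float(v) for k, v in self.variance_components.items()},
            "std_errors": {k: float(v) for k, v in self.std_errors.items()},
            "loglik_reml": float(self.llf),
            "aic": float(self.aic),
            "beta": np.asarray(self.params).tolist(),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }


def _values(K):
    return K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, dtype=float)


class _MixedBLUP:
    """Shared machinery: a trait, a fixed design, ordered dense random terms."""

    model_name = "BLUP"

    def __init__(self, y, X, random_terms):
        self.y = np.asarray(y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != self.y.shape[0]:
            X = X.T
        self.X = X
        self.random_terms = [(lab, K) for lab, K in random_terms]
        for lab, K in self.random_terms:
            if _values(K).shape[0] != len(self.y):
                raise ValueError(f"relationship matrix {lab!r} does not match y")

    def fit(self, start=None, max_iter: int = 200) -> BLUPResults:
        labels = [lab for lab, _ in self.random_terms]
        Ks = [_values(K) for _, K in self.random_terms]
        res = ai_reml(self.y, self.X, Ks, labels=labels, start=start, max_iter=max_iter)
        return BLUPResults(self, res)

    def loglik(self, sigma2: dict) -> float:
        terms = [(_values(K), sigma2[lab]) for lab, K in self.random_terms]
        return reml_loglik(self.y, self.X, terms, sigma2["residual"])


class GBLUP(_MixedBLUP):
    """Additive genomic BLUP: y = Xb + g + e, g ~ N(0, G sigma2_g)."""

    model_name = "GBLUP"

    def __init__(self, y, X, G):
        super().__init__(y, X, [("g", G)])

    @classmethod
    def from_genotypes(cls, y, X, geno: GenotypeData) -> "GBLUP":
        return cls(y, X, vanraden_g(geno))


class TBLUP(_MixedBLUP):
    """Transcriptomic BLUP: y = Xb + t + e, t ~ N(0, T sigma2_t)."""

    model_name = "TBLUP"

    def __init__(self, y, X, T):
        super().__init__(y, X, [("t", T)])

    @classmethod
    def from_transcripts(cls, y, X, W) -> "TBLUP":
        return cls(y, X, transcript_t(W))


class GTBLUP(_MixedBLUP):
    """Joint model with independent genomic and transcriptomic effects."""

    model_name = "GTBLUP"

    def __init__(self, y, X, G, T):
        super().__init__(y, X, [("g", G), ("t", T)])


class GTCBLUP(_MixedBLUP):
    """Genomic + genotype-conditioned transcriptomic effects, with the
    conditioning ridge taken from the trait's own GBLUP heritability:
    lambda = m (1/h2 - 1), m the SNP count."""

    model_name = "GTCBLUP"

    def __init__(self, y, X, geno: GenotypeData, W, h2_trait: float = None,
                 use_m_tilde: bool = False, h2_floor: float = 1e-4):
        self.geno = geno
        self.W = np.asarray(W, dtype=float)
        self.G = vanraden_g(geno)
        if h2_trait is None:
            gres = GBLUP(y, X, self.G).fit()
            h2_trait = gres.variance_proportions().h2
        if h2_trait <= h2_floor:
            raise ValueError(
                "GBLUP heritability is at the zero boundary; lambda = m(1/h2 - 1) "
                "is undefined.  Supply h2_trait explicitly or use GTCBLUPi, whose "
                "grid search does not depend on the trait heritability."
            )
        self.h2_trait = min(float(h2_trait), 1.0 - 1e-12)
        m = geno.m_tilde if use_m_tilde else geno.m
        self.lam = m * (1.0 / self.h2_trait - 1.0)
        cond = _condition(self.W, geno, self.G, self.lam)
        self.W_c = cond.W_c
        self.T_c = conditioned_t(self.W_c, animal_ids=list(geno.animal_ids))
        super().__init__(y, X, [("g", self.G), ("t_c", self.T_c)])


@dataclass
class GridSearchResult:
    """Profile of the GTCBLUPi grid search over transcript heritability."""

    h2_t_hat: float
    lambda_hat: float
    profile: np.ndarray  # (n_grid, 2): h2_t, REML loglik (NaN where fit failed)
    best_fit: BLUPResults = field(repr=False, default=None)


class GTCBLUPiResults(BLUPResults):
    """GTCBLUPi fit: best conditioned model plus the h2_t profile."""

    def __init__(self, model, fit, grid: GridSearchResult):
        super().__init__(model, fit)
        self.grid = grid
        self.h2_t_hat = grid.h2_t_hat
        self.lambda_hat = grid.lambda_hat

    def summary(self) -> str:
        base = super().summary()
        return base + (f"\nh2_t (grid search): {self.h2_t_hat:.2f}"
                       f"   lambda: {self.lambda_hat:.4g}")

    def plot_profile(self, ax=None):
        """REML log-likelihood of the conditioned model as a function of the
        transcript-level heritability h2_t."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        prof = self.grid.profile
        ok = ~np.isnan(prof[:, 1])
        ax.plot(prof[ok, 0], prof[ok, 1], "o-", ms=3, color="0.3")
        ax.axvline(self.h2_t_hat, color="darkred", lw=1, ls="--",
                   label=f"$\\hat{{h}}^2_t$ = {self.h2_t_hat:.2f}")
        ax.set_xlabel(r"$\tilde{h}^2_t$")
        ax.set_ylabel("REML log-likelihood")
        ax.legend(frameon=False, fontsize=8)
        return ax


class GTCBLUPi(_MixedBLUP):
    """Conditioned model with the transcript heritability estimated by a
    profile-likelihood grid search in steps of `grid_step` over (0, 1)."""

    model_name = "GTCBLUPi"

    def __init__(self, y, X, geno: GenotypeData, W, grid_step: float = 0.01,
                 grid=None):
        self.geno = geno
        self.W = np.asarray(W, dtype=float)
        self.G = vanraden_g(geno)
        if grid is None:
            grid = np.arange(grid_step, 1.0, grid_step)
            grid = grid[(grid > 0) & (grid < 1)]
        self.grid = np.asarray(grid, dtype=float)
        self._y0, self._X0 = y, X
        super().__init__(y, X, [("g", self.G)])  # t_c term is set by fit()

    def fit(self, start=None, max_iter: int = 200) -> GTCBLUPiResults:
        y, X, geno, W, G = self._y0, self._X0, self.geno, self.W, self.G
        best = None
        profile = np.full((len(self.grid), 2), np.nan)
        warm = start
        for i, h2t in enumerate(self.grid):
            lam = lambda_from_h2(h2t, geno.m_tilde)
            cond = _condition(W, geno, G, lam)
            T_c = conditioned_t(cond.W_c, animal_ids=list(geno.animal_ids))
            try:
                res = ai_reml(y, X, [G.values, T_c.values], labels=["g", "t_c"],
                              start=warm, max_iter=max_iter)
            except (scipy.linalg.LinAlgError, ValueError):
                continue
            profile[i] = (h2t, res.loglik)
            warm = res.sigma2.copy()
            # strict > keeps the tie at the smaller h2_t (less conditioning)
            if best is None or res.loglik > best[1].loglik + 1e-12:
                best = (h2t, res, lam, cond.W_c, T_c)
        if best is None:
            raise RuntimeError("REML failed to converge at every grid point")
        h2_hat, fit, lam_hat, W_c, T_c = best
        self.random_terms = [("g", G), ("t_c", T_c)]
        self.W_c, self.T_c = W_c, T_c
        grid_res = GridSearchResult(h2_t_hat=float(h2_hat), lambda_hat=float(lam_hat),
                                    profile=profile)
        out = GTCBLUPiResults(self, fit, grid_res)
        grid_res.best_fit = out
        return out


def _condition(W, geno, G, lam):
    route = choose_route(geno.n, geno.m)
    if route == "direct":
        return condition_w_direct(W, geno, lam)
    return condition_w_woodbury(W, G, geno.m_tilde, lam)


def aic(fit: BLUPResults) -> float:
    if not fit.converged:
        raise ValueError("AIC requires a converged fit")
    return fit.aic


def lrt(full: BLUPResults, reduced: BLUPResults):
    """Likelihood-ratio test D = 2 [logL(full) - logL(reduced)].

    The p-value uses a chi-square with df = difference in the number of
    variance parameters.  For a variance component tested on its boundary
    this is conservative; the 50:50 mixture p-value is available via
    `lrt_boundary_p`.
    """
    D = 2.0 * (full.llf - reduced.llf)
    df = full.n_varparams - reduced.n_varparams
    if D < -1e-6:
        raise ValueError(f"negative LRT statistic D={D:.3g}: models not nested "
                         "or a fit did not converge")
    D = max(D, 0.0)
    if df <= 0:
        return D, 1.0 if D <= 1e-12 else float(scipy.stats.chi2.sf(D, 1))
    p = float(scipy.stats.chi2.sf(D, df)) if D > 0 else 1.0
    return D, p


def lrt_boundary_p(D: float, df: int = 1) -> float:
    """50:50 mixture of chi2_0 and chi2_df p-value for boundary tests."""
    if D <= 0:
        return 1.0
    return 0.5 * float(scipy.stats.chi2.sf(D, df))
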