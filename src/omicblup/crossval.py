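"""Cross-validation of prediction accuracy and paired model comparisons.

Random CV draws repeated 80/20 reference/validation splits; family-based CV
enumerates every combination of validation half-sib groups, keeping whole
families together so reference and validation animals are less related.
Accuracy is the Pearson correlation between predicted animal effects and
phenotypes pre-corrected for test-day effects; per-model accuracies are
summarized on Fisher's z scale and models are compared by per-fold paired
differences with a 95% confidence interval.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .relmat import RelationshipMatrix, DEFAULT_RIDGE

logger = logging.getLogger(__name__)


@dataclass
class FoldPlan:
    scheme: str  # 'random' | 'family'
    folds: list  # list of (reference_ids, validation_ids)
    seed: int = None

    @property
    def n_folds(self) -> int:
        return len(self.folds)


@dataclass
class CVResult:
    per_fold_accuracy: dict      # model -> np.ndarray of per-fold r
    mean_accuracy: dict = field(init=False)
    ci95: dict = field(init=False)

    def __post_init__(self):
        self.mean_accuracy, self.ci95 = {}, {}
        for m, rs in self.per_fold_accuracy.items():
            rs = np.asarray(rs, dtype=float)
            mean_r, lo, hi = fisher_ci(rs[~np.isnan(rs)])
            self.mean_accuracy[m] = mean_r
            self.ci95[m] = (lo, hi)

    @property
    def n_folds(self) -> int:
        return len(next(iter(self.per_fold_accuracy.values())))


@dataclass
class PairedComparison:
    model_a: str
    model_b: str
    per_fold_diff: np.ndarray
    mean_diff: float = field(init=False)
    ci95: tuple = field(init=False)
    significant: bool = field(init=False)

    def __post_init__(self):
        d = np.asarray(self.per_fold_diff, dtype=float)
        d = d[~np.isnan(d)]
        self.mean_diff = float(d.mean())
        half = 1.96 * float(d.std(ddof=1))
        self.ci95 = (self.mean_diff - half, self.mean_diff + half)
        self.significant = not (self.ci95[0] <= 0.0 <= self.ci95[1])


def make_folds(animals, scheme: str, frac_validation: float = 0.2,
               n_reps: int = 500, groups=None, seed: int = None) -> FoldPlan:
    """Build reference/validation folds.

    random: `n_reps` independent splits with validation size
    round(frac_validation * n).  family: every C(g, v) combination of
    v = round(frac_validation * g) validation groups occurs exactly once.
    """
    animals = list(animals)
    n = len(animals)
    if scheme == "random":
        v = int(round(frac_validation * n))
        if v == 0 or v == n:
            raise ValueError("validation fraction leaves an empty set")
        rng = np.random.default_rng(seed)
        folds = []
        for _ in range(n_reps):
            perm = rng.permutation(n)
            val = sorted(perm[:v])
            ref = sorted(perm[v:])
            folds.append(([animals[i] for i in ref], [animals[i] for i in val]))
        return FoldPlan("random", folds, seed)
    if scheme == "family":
        if groups is None:
            raise ValueError("family scheme requires group labels")
        groups = dict(zip(animals, list(groups)))
        uniq = sorted(set(groups.values()), key=str)
        g = len(uniq)
        v = int(round(frac_validation * g))
        if v == 0 or v == g:
            raise ValueError("validation fraction leaves no or all groups")
        folds = []
        for combo in itertools.combinations(uniq, v):
            val_groups = set(combo)
            val = [a for a in animals if groups[a] in val_groups]
            ref = [a for a in animals if groups[a] not in val_groups]
            folds.append((ref, val))
        return FoldPlan("family", folds, seed)
    raise ValueError(f"unknown scheme {scheme!r}")


def predict_validation(fit, K_full: dict, animal_ids, validation_ids,
                       ridge: float = DEFAULT_RIDGE) -> np.ndarray:
    """Conditional-expectation prediction of validation animal effects.

    For each random term, u_val = K_val,ref (K_ref,ref + eps I)^-1 u_ref;
    the total prediction is the sum over terms.  `fit` is a BLUPResults
    estimated on the reference animals; K_full maps term label -> matrix
    over all animals in `animal_ids` order.
    """
    idx = {a: i for i, a in enumerate(animal_ids)}
    ref_ids = fit.model.animal_ids if hasattr(fit.model, "animal_ids") else None
    ref_ids = getattr(fit, "reference_ids", ref_ids)
    if ref_ids is None:
        raise ValueError("fit does not carry reference animal ids")
    missing = [a for a in list(ref_ids) + list(validation_ids) if a not in idx]
    if missing:
        raise KeyError(f"animals missing from relationship matrices: {missing[:5]}")
    ri = np.array([idx[a] for a in ref_ids])
    vi = np.array([idx[a] for a in validation_ids])
    pred = np.zeros(len(vi))
    for label, u_ref in fit.blups.items():
        K = K_full[label]
        K = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, dtype=float)
        Krr = K[np.ix_(ri, ri)]
        Kvr = K[np.ix_(vi, ri)]
        Krr = Krr + ridge * float(np.mean(np.diag(Krr))) * np.eye(len(ri))
        pred += Kvr @ scipy.linalg.solve(Krr, u_ref, assume_a="pos")
    return pred


def accuracy(pred, y, X_testday, beta_testday=None) -> float:
    """Pearson r between predictions and test-day-corrected phenotypes.

    The correction uses b-hat from a least-squares fit of y on X_testday —
    by default estimated on the vectors given; pass `beta_testday` (e.g.
    estimated on the full data) to keep it fixed across folds.
    """
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X_testday, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    if beta_testday is None:
        beta_testday, *_ = np.linalg.lstsq(X, y, rcond=None)
    corrected = y - X @ beta_testday
    if pred.std() == 0 or corrected.std() == 0:
        return np.nan
    return float(np.corrcoef(pred, corrected)[0, 1])


def fisher_ci(rs):
    """Mean and normal-theory 95% CI of correlations on Fisher's z scale.

    z = arctanh(r) = 1/2 ln((1+r)/(1-r)); the mean and mean +- 1.96 SD(z)
    are back-transformed with r = tanh(z) = (e^2z - 1)/(e^2z + 1).
    """
    rs = np.asarray(rs, dtype=float)
    if np.any(np.abs(rs) >= 1):
        warnings.warn("|r| = 1 clipped for the Fisher transform", stacklevel=2)
        rs = np.clip(rs, -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(rs)
    zbar = z.mean()
    sd = z.std(ddof=1) if len(z) > 1 else 0.0
    return (float(np.tanh(zbar)),
            float(np.tanh(zbar - 1.96 * sd)),
            float(np.tanh(zbar + 1.96 * sd)))


def compare_models(result: CVResult, model_a: str, model_b: str) -> PairedComparison:
    """Paired per-fold accuracy difference (a - b) with a mean +- 1.96 SD CI."""
    ra = np.asarray(result.per_fold_accuracy[model_a], dtype=float)
    rb = np.asarray(result.per_fold_accuracy[model_b], dtype=float)
    if ra.shape != rb.shape:
        raise ValueError("models were not evaluated on identical folds")
    return PairedComparison(model_a, model_b, ra - rb)


def cross_validate(model_builders: dict, y, X, animal_ids, plan: FoldPlan,
                   K_full_by_model: dict, beta_full: bool = True,
                   max_iter: int = 200) -> CVResult:
    """Run the CV loop for several models on identical folds.

    Parameters
    ----------
    model_builders : model name -> callable(y_ref, X_ref, ref_index_array)
        returning a constructed (unfitted) model for the reference subset.
    K_full_by_model : model name -> {term label -> K over all animals}, or a
        callable(fit) returning that map (needed for conditioned models,
        whose all-animal T_c depends on the ridge chosen on the reference
        data).
    beta_full : estimate the test-day correction on the full data (default)
        rather than per fold.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    animal_ids = list(animal_ids)
    idx = {a: i for i, a in enumerate(animal_ids)}
    beta_td = np.linalg.lstsq(X, y, rcond=None)[0] if beta_full else None
    acc = {m: np.full(plan.n_folds, np.nan) for m in model_builders}
    for f, (ref, val) in enumerate(plan.folds):
        ri = np.array([idx[a] for a in ref])
        vi = np.array([idx[a] for a in val])
        for name, build in model_builders.items():
            model = build(y[ri], X[ri], ri)
            fit = model.fit(max_iter=max_iter)
            fit.reference_ids = list(ref)
            Kmap = K_full_by_model[name]
            if callable(Kmap):
                Kmap = Kmap(fit)
            pred = predict_validation(fit, Kmap, animal_ids, val)
            acc[name][f] = accuracy(pred, y[vi], X[vi], beta_testday=beta_td)
    return CVResult(acc)
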