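"""Relationship and conditioning matrices.

G is the VanRaden method-1 genomic relationship matrix Z Z' / m_tilde with
m_tilde = sum_j 2 p_j (1 - p_j).  T = W W' / k is the transcriptomic
relationship matrix.  Conditioning removes the genotype-predictable part of
the transcript columns with the ridge smoother S_lambda = Z (Z'Z + lambda I)^-1 Z',
giving W_c = (I - S_lambda) W and T_c = W_c W_c' / k.  Two algebraically
equivalent routes are provided: the direct m x m inversion and a Woodbury
rewrite that only inverts n x n matrices (preferable when m > n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .data import GenotypeData

#: Default relative ridge added to a relationship matrix before inversion
#: (T with k < n is singular by construction).
DEFAULT_RIDGE = 1e-6


@dataclass
class RelationshipMatrix:
    """n x n symmetric PSD similarity matrix among animals."""

    values: np.ndarray
    kind: str  # 'G' | 'T' | 'T_c'
    animal_ids: list = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def mean_diag(self) -> float:
        return float(np.mean(np.diag(self.values)))

    def ridged(self, eps: float = DEFAULT_RIDGE) -> np.ndarray:
        """Values with eps * mean(diag) added to the diagonal, for inversion."""
        return self.values + eps * self.mean_diag * np.eye(self.n)


@dataclass
class ConditioningResult:
    W_c: np.ndarray
    lam: float
    route: str  # 'direct' | 'woodbury'
    h2_t: float = None


def vanraden_g(geno: GenotypeData) -> RelationshipMatrix:
    """VanRaden method-1 G = Z Z' / sum_j 2 p_j (1 - p_j).

    Monomorphic SNPs contribute to neither numerator nor denominator
    (GenotypeData already excludes them from Z and m_tilde).
    """
    if geno.m == 0 or geno.m_tilde <= 0:
        raise ValueError("no polymorphic SNPs: G undefined")
    G = geno.Z @ geno.Z.T / geno.m_tilde
    return RelationshipMatrix((G + G.T) / 2.0, "G", list(geno.animal_ids))


def transcript_t(W, k: int = None, kind: str = "T", animal_ids=None) -> RelationshipMatrix:
    """T = W W' / k with k the number of transcript columns."""
    W = np.asarray(W, dtype=float)
    if k is None:
        k = W.shape[1]
    if k != W.shape[1]:
        raise ValueError(f"k={k} does not match W with {W.shape[1]} columns")
    if k == 0:
        raise ValueError("T undefined for zero transcripts")
    T = W @ W.T / k
    return RelationshipMatrix((T + T.T) / 2.0, kind, animal_ids)


def lambda_from_h2(h2_t: float, m_tilde: float) -> float:
    """Ridge parameter lambda = m_tilde * (1 / h2_t - 1).

    h2_t is the heritability of transcript-level effects; lambda -> 0 as
    h2_t -> 1 (full shrinkage of transcripts toward their genetic part)
    and lambda -> infinity as h2_t -> 0 (no conditioning).
    """
    if not (0 < h2_t < 1):
        raise ValueError("h2_t must lie strictly in (0, 1)")
    if m_tilde <= 0:
        raise ValueError("m_tilde must be positive")
    return m_tilde * (1.0 / h2_t - 1.0)


def condition_w_direct(W, geno: GenotypeData, lam: float) -> ConditioningResult:
    """W_c = (I - Z (Z'Z + lambda I_m)^-1 Z') W via the m x m inversion."""
    W = np.asarray(W, dtype=float)
    Z = geno.Z
    if W.shape[0] != Z.shape[0]:
        raise ValueError("W and Z must have the same number of rows (animals)")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    m = Z.shape[1]
    A = Z.T @ Z + lam * np.eye(m)
    ZtW = Z.T @ W
    W_c = W - Z @ scipy.linalg.solve(A, ZtW, assume_a="pos")
    return ConditioningResult(W_c, lam, "direct")


def condition_w_woodbury(W, G: RelationshipMatrix, m_tilde: float, lam: float) -> ConditioningResult:
    """W_c = (I - G* + G* (I + G*)^-1 G*) W with G* = G m_tilde / lambda.

    Woodbury rewrite of the direct route; only n x n matrices are inverted,
    which is the cheaper path when the SNP count exceeds the animal count.
    """
    W = np.asarray(W, dtype=float)
    if lam <= 0:
        raise ValueError("lambda must be positive")
    Gs = G.values * (m_tilde / lam)
    n = Gs.shape[0]
    inner = scipy.linalg.solve(np.eye(n) + Gs, Gs @ W, assume_a="pos")
    W_c = W - Gs @ W + Gs @ inner
    return ConditioningResult(W_c, lam, "woodbury")


def conditioned_t(W_c, k: int = None, animal_ids=None) -> RelationshipMatrix:
    """T_c = W_c W_c' / k."""
    if isinstance(W_c, ConditioningResult):
        W_c = W_c.W_c
    return transcript_t(W_c, k, kind="T_c", animal_ids=animal_ids)


def choose_route(n: int, m: int) -> str:
    """Direct (m x m inversion) when animals outnumber SNPs, else Woodbury.

    Ties go to the direct route.
    """
    return "direct" if n >= m else "woodbury"


def condition_w(W, geno: GenotypeData, lam: float, G: RelationshipMatrix = None) -> ConditioningResult:
    """Condition W on genotypes, picking the cheaper route automatically."""
    route = choose_route(geno.n, geno.m)
    if route == "direct":
        return condition_w_direct(W, geno, lam)
    if G is None:
        G = vanraden_g(geno)
    return condition_w_woodbury(W, G, geno.m_tilde, lam)
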