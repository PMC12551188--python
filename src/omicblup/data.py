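"""In-memory containers for genotype, transcript, phenotype and pedigree data.

All containers align animals by identifier; matrix-valued fields are plain
numpy arrays with identifier lists kept alongside, so the linear algebra
stays free of index bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenotypeData:
    """Animal x SNP dosage matrix with derived quantities for G construction.

    Attributes
    ----------
    dosages : (n, m) int array of allele counts in {0, 1, 2}.
    animal_ids : list of n identifiers.
    snp_ids : list of m identifiers.
    p : (m,) reference-allele frequencies (estimated from the sample unless
        supplied).
    polymorphic : (m,) boolean mask; monomorphic SNPs (p = 0 or 1) are
        excluded from the centered matrix Z and from the VanRaden scaling
        constant m_tilde = sum_j 2 p_j (1 - p_j).
    """

    dosages: np.ndarray
    animal_ids: list
    snp_ids: list
    p: np.ndarray = None
    polymorphic: np.ndarray = field(init=False, default=None)
    Z: np.ndarray = field(init=False, default=None)
    m_tilde: float = field(init=False, default=None)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D animal x SNP matrix")
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage out of range at animal {self.animal_ids[i]!r}, "
                f"SNP {self.snp_ids[j]!r}: {self.dosages[i, j]!r}"
            )
        if self.p is None:
            self.p = self.dosages.mean(axis=0) / 2.0
        else:
            self.p = np.asarray(self.p, dtype=float)
        self.polymorphic = (self.p > 0) & (self.p < 1)
        self.Z = (self.dosages - 2.0 * self.p)[:, self.polymorphic]
        self.m_tilde = float(np.sum(2.0 * self.p[self.polymorphic] * (1.0 - self.p[self.polymorphic])))

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        """Number of polymorphic SNPs entering Z."""
        return int(self.polymorphic.sum())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeData":
        """Build from a DataFrame indexed by animal_id with SNP columns."""
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.animal_ids, columns=self.snp_ids)


@dataclass
class TranscriptData:
    """Animal x transcript abundances: raw values and the pre-corrected,
    standardized matrix W used to build transcriptomic relationship matrices."""

    raw: np.ndarray
    W: np.ndarray
    animal_ids: list
    transcript_ids: list

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != self.raw.shape:
            raise ValueError("raw and W must have identical shape")

    @property
    def k(self) -> int:
        return self.W.shape[1]

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass
class PhenotypeData:
    """Trait vector (transformed, standardized) plus fixed-effect design.

    X holds test-day indicator columns (full-rank coding with intercept).
    """

    y: np.ndarray
    X: np.ndarray
    animal_ids: list
    trait: str = "trait"
    testday: np.ndarray = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y must have the same number of rows")


@dataclass
class Pedigree:
    """Three-generation F2-cross pedigree.

    One row per animal in `table` with columns animal_id, sire_id, dam_id,
    generation ('founder'|'F1'|'F2'), sex ('M'|'F'), family_group (paternal
    half-sib group = sire_id, F2 only).  Parents precede offspring.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"animal_id", "sire_id", "dam_id", "generation", "sex", "family_group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree missing columns: {sorted(missing)}")
        seen = set()
        for row in self.table.itertuples(index=False):
            for par in (row.sire_id, row.dam_id):
                if par is not None and par not in seen:
                    raise ValueError(f"parent {par!r} listed after offspring {row.animal_id!r}")
            seen.add(row.animal_id)

    def subset(self, generation: str) -> pd.DataFrame:
        return self.table[self.table.generation == generation]

    @property
    def f2_ids(self) -> list:
        return list(self.subset("F2").animal_id)

    @property
    def f2_groups(self) -> pd.Series:
        f2 = self.subset("F2")
        return pd.Series(f2.family_group.values, index=f2.animal_id)


@dataclass
class SimulationTruth:
    """Ground-truth parameters of a simulated dataset, for recovery tests."""

    sigma2_g_true: float
    sigma2_t_true: float
    sigma2_e_true: float
    h2_transcript_true: float
    transcript_effects_true: np.ndarray = None
    snp_effects_true: np.ndarray = None
    testday_effects_true: np.ndarray = None

    def __post_init__(self):
        for name in ("sigma2_g_true", "sigma2_t_true", "sigma2_e_true"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0 <= self.h2_transcript_true < 1):
            raise ValueError("h2_transcript_true must be in [0, 1)")
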