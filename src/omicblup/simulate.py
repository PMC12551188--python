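"""Synthetic F2-cross multi-omics datasets with known ground truth.

Emulates the study design the models target: two divergent founder lines
crossed to an F1, F1 sires mated 1:2 with F1 dams (paternal half-sib
groups, full-sib pairs nested within), biallelic SNPs gene-dropped through
the pedigree at independent loci, transcript abundances with a heritable
component of chosen magnitude, and phenotypes composed of an additive
genetic part, a transcript-mediated part, fixed test-day effects and
residual noise.  Every output is reproducible from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import GenotypeData, TranscriptData, PhenotypeData, Pedigree, SimulationTruth

#: SD of test-day effects on the standardized trait scale.
DEFAULT_TESTDAY_SD = 0.3
#: Fraction of SNPs controlling each transcript's heritable part.
DEFAULT_SNP_FRAC = 0.1


def simulate_pedigree(n_founder_per_line: int, n_f1_sires: int, n_f1_dams: int,
                      f2_per_mating: int, seed: int) -> Pedigree:
    """Three-generation pedigree: founders (two lines) -> F1 -> F2.

    F1 sires are mated 1:2 with F1 dams (each sire with two dams, no
    rotation); each mating produces `f2_per_mating` F2 offspring, so every
    sire founds one paternal half-sib group of 2 * f2_per_mating animals.
    """
    for name, v in (("n_founder_per_line", n_founder_per_line),
                    ("n_f1_sires", n_f1_sires), ("n_f1_dams", n_f1_dams),
                    ("f2_per_mating", f2_per_mating)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    if n_f1_dams != 2 * n_f1_sires:
        raise ValueError("1:2 mating ratio requires n_f1_dams = 2 * n_f1_sires")
    if n_founder_per_line < 2:
        raise ValueError("need at least one male and one female founder per line")
    rng = np.random.default_rng(seed)
    rows = []
    line_males, line_females = {}, {}
    for line in ("A", "B"):
        males, females = [], []
        for i in range(n_founder_per_line):
            sex = "M" if i < (n_founder_per_line + 1) // 2 else "F"
            aid = f"{line}{i:03d}"
            (males if sex == "M" else females).append(aid)
            rows.append((aid, None, None, "founder", sex, None))
        line_males[line], line_females[line] = males, females
    # F1: cross the lines (line-A sires x line-B dams), random parent per F1
    f1 = []
    for i in range(n_f1_sires + n_f1_dams):
        sex = "M" if i < n_f1_sires else "F"
        aid = f"F1_{i:03d}"
        sire = line_males["A"][rng.integers(len(line_males["A"]))]
        dam = line_females["B"][rng.integers(len(line_females["B"]))]
        rows.append((aid, sire, dam, "F1", sex, None))
        f1.append((aid, sex))
    sires = [a for a, s in f1 if s == "M"]
    dams = [a for a, s in f1 if s == "F"]
    idx = 0
    for si, sire in enumerate(sires):
        for dam in dams[2 * si: 2 * si + 2]:
            for _ in range(f2_per_mating):
                aid = f"F2_{idx:04d}"
                sex = "M" if rng.random() < 0.5 else "F"
                rows.append((aid, sire, dam, "F2", sex, sire))
                idx += 1
    table = pd.DataFrame(rows, columns=["animal_id", "sire_id", "dam_id",
                                        "generation", "sex", "family_group"])
    return Pedigree(table)


def simulate_genotypes(pedigree: Pedigree, n_snps: int,
                       founder_freq_range=(0.05, 0.95), seed: int = 0,
                       keep_alleles: bool = False) -> GenotypeData:
    """Gene-drop biallelic SNPs through the pedigree at independent loci.

    Founder allele frequencies are drawn per line and per SNP from
    `founder_freq_range` (uniform), so the two lines diverge.  Each
    offspring inherits one uniformly chosen allele from each parent.
    Returns genotypes of the F2 animals; monomorphic SNPs are flagged by
    the GenotypeData container.  With `keep_alleles=True` the phased
    allele pairs of all animals are attached as `.alleles` for audit.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    lo, hi = founder_freq_range
    if not (0 < lo <= hi < 1):
        raise ValueError("founder_freq_range must lie inside (0, 1)")
    tab = pedigree.table
    if len(tab) == 0:
        raise ValueError("empty pedigree")
    rng = np.random.default_rng(seed)
    freqs = {line: rng.uniform(lo, hi, size=n_snps) for line in ("A", "B")}
    alleles = {}
    for row in tab.itertuples(index=False):
        if row.generation == "founder":
            p = freqs[row.animal_id[0]]
            a = (rng.random((2, n_snps)) < p).astype(np.int8)
        else:
            a = np.empty((2, n_snps), dtype=np.int8)
            for slot, parent in enumerate((row.sire_id, row.dam_id)):
                pick = rng.integers(0, 2, size=n_snps)
                a[slot] = alleles[parent][pick, np.arange(n_snps)]
        alleles[row.animal_id] = a
    f2_ids = pedigree.f2_ids
    dosages = np.stack([alleles[a].sum(axis=0) for a in f2_ids])
    geno = GenotypeData(dosages, f2_ids, [f"snp{j}" for j in range(n_snps)])
    if keep_alleles:
        geno.alleles = alleles
    return geno


def simulate_transcripts(genotypes: GenotypeData, k: int, h2_transcript: float,
                         seed: int = 0, snp_frac: float = DEFAULT_SNP_FRAC):
    """Transcript abundances with a genotype-driven heritable component.

    Each transcript column is Z gamma + eps with gamma supported on a
    random `snp_frac` subset of SNPs; the genetic part is scaled so its
    realized variance fraction equals `h2_transcript`, then the column is
    standardized.  Returns (TranscriptData, SimulationTruth); the truth
    carries the per-transcript SNP effects (variance targets are filled in
    by simulate_phenotypes).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0 <= h2_transcript < 1):
        raise ValueError("h2_transcript must be in [0, 1)")
    rng = np.random.default_rng(seed)
    Z = genotypes.Z
    n, m = Z.shape
    n_causal = max(1, int(round(snp_frac * m)))
    gamma = np.zeros((m, k))
    cols = np.empty((n, k))
    for j in range(k):
        eps = rng.standard_normal(n)
        eps = (eps - eps.mean()) / eps.std(ddof=1)
        if h2_transcript > 0:
            sel = rng.choice(m, size=n_causal, replace=False)
            g = np.zeros(m)
            g[sel] = rng.standard_normal(n_causal)
            gv = Z @ g
            sd = gv.std(ddof=1)
            if sd > 0:
                scale = np.sqrt(h2_transcript) / sd
                gv = (gv - gv.mean()) * scale
                g *= scale
            gamma[:, j] = g
            col = gv + np.sqrt(1.0 - h2_transcript) * eps
        else:
            col = eps
        cols[:, j] = col
    W = np.column_stack([(c - c.mean()) / c.std(ddof=1) for c in cols.T])
    tdata = TranscriptData(raw=cols, W=W, animal_ids=list(genotypes.animal_ids),
                           transcript_ids=[f"tx{j}" for j in range(k)])
    truth = SimulationTruth(sigma2_g_true=0.0, sigma2_t_true=0.0, sigma2_e_true=0.0,
                            h2_transcript_true=h2_transcript, snp_effects_true=gamma)
    return tdata, truth


def simulate_phenotypes(genotypes: GenotypeData, transcripts: TranscriptData,
                        truth: SimulationTruth, n_testdays: int = 11,
                        seed: int = 0, testday_sd: float = DEFAULT_TESTDAY_SD,
                        trait: str = "trait",
                        condition_transcripts: bool = False) -> PhenotypeData:
    """Compose phenotypes y = X b + g + t + e at the target variances.

    g = Z alpha (polygenic, all SNPs), t = W tau (transcript-mediated) and
    e are each centered and rescaled so their realized sample variances
    equal the targets in `truth` exactly.  Test days are assigned in a
    balanced way; their effects are drawn once with SD `testday_sd`.

    With `condition_transcripts=True` the transcript-mediated part uses the
    conditioned matrix W_c at the ridge implied by the transcripts' own
    heritability, t = W_c tau: the heritable share of the transcript effect
    is then part of the genetic term rather than double-counted, which is
    the generative counterpart of the conditioned (GTCBLUP-family) model
    and the setting in which the transcript-heritability grid search has a
    well-defined target.  The default composes the unconditioned joint
    model (independent g and t).
    """
    if list(genotypes.animal_ids) != list(transcripts.animal_ids):
        raise ValueError("genotype and transcript animal sets differ")
    if n_testdays < 1:
        raise ValueError("n_testdays must be >= 1")
    for v in (truth.sigma2_g_true, truth.sigma2_t_true, truth.sigma2_e_true):
        if v < 0:
            raise ValueError("variance targets must be nonnegative")
    rng = np.random.default_rng(seed)
    n = genotypes.n

    def _scaled(raw, target):
        raw = raw - raw.mean()
        sd = raw.std(ddof=1)
        if target == 0 or sd == 0:
            return np.zeros(n)
        return raw * (np.sqrt(target) / sd)

    alpha = rng.standard_normal(genotypes.m)
    g = _scaled(genotypes.Z @ alpha, truth.sigma2_g_true)
    tau = rng.standard_normal(transcripts.k)
    W_eff = transcripts.W
    if condition_transcripts:
        from .relmat import condition_w, lambda_from_h2

        h2t = truth.h2_transcript_true
        if not (0 < h2t < 1):
            raise ValueError("condition_transcripts requires h2_transcript_true in (0,1)")
        lam = lambda_from_h2(h2t, genotypes.m_tilde)
        W_eff = condition_w(transcripts.W, genotypes, lam).W_c
    t = _scaled(W_eff @ tau, truth.sigma2_t_true)
    e = _scaled(rng.standard_normal(n), truth.sigma2_e_true)

    day = rng.permutation(np.arange(n) % n_testdays)
    X = np.zeros((n, n_testdays))
    X[np.arange(n), day] = 1.0
    b = rng.normal(0.0, testday_sd, size=n_testdays)
    y = X @ b + g + t + e

    truth.transcript_effects_true = tau
    truth.testday_effects_true = b
    return PhenotypeData(y=y, X=X, animal_ids=list(genotypes.animal_ids),
                         trait=trait, testday=day)


@dataclass
class SyntheticDataset:
    pedigree: Pedigree
    genotypes: GenotypeData
    transcripts: TranscriptData
    phenotypes: PhenotypeData
    truth: SimulationTruth

    @property
    def groups(self) -> pd.Series:
        """Paternal half-sib group of each F2 animal (for family-based CV)."""
        return self.pedigree.f2_groups.loc[self.genotypes.animal_ids]


def simulate_dataset(n_founder_per_line: int = 12, n_f1_sires: int = 10,
                     f2_per_mating: int = 24, n_snps: int = 4000, k: int = 80,
                     h2_transcript: float = 0.25, sigma2_g: float = 0.25,
                     sigma2_t: float = 0.35, sigma2_e: float = 0.40,
                     n_testdays: int = 11, seed: int = 0,
                     condition_transcripts: bool = False) -> SyntheticDataset:
    """One-call study-scale dataset (defaults mirror the F2 quail design:
    10 paternal half-sib groups, 480 F2 animals, 4k SNPs, ~80 transcripts,
    11 test days)."""
    ss = np.random.SeedSequence(seed)
    s_ped, s_geno, s_tx, s_ph = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4))
    ped = simulate_pedigree(n_founder_per_line, n_f1_sires, 2 * n_f1_sires,
                            f2_per_mating, seed=s_ped)
    geno = simulate_genotypes(ped, n_snps, seed=s_geno)
    tx, truth = simulate_transcripts(geno, k, h2_transcript, seed=s_tx)
    truth.sigma2_g_true = sigma2_g
    truth.sigma2_t_true = sigma2_t
    truth.sigma2_e_true = sigma2_e
    phen = simulate_phenotypes(geno, tx, truth, n_testdays=n_testdays, seed=s_ph,
                               condition_transcripts=condition_transcripts)
    return SyntheticDataset(ped, geno, tx, phen, truth)
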