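"""Synthetic F2-cross generator: pedigree, gene-dropping, transcripts, phenotypes."""

import numpy as np
import pandas as pd
import pytest

import omicblup as ob
from omicblup.simulate import (
    simulate_pedigree, simulate_genotypes, simulate_transcripts,
    simulate_phenotypes, simulate_dataset,
)


def numerator_relationship(table: pd.DataFrame) -> np.ndarray:
    """Pedigree numerator relationship matrix by the tabular method (oracle)."""
    ids = list(table.animal_id)
    pos = {a: i for i, a in enumerate(ids)}
    A = np.zeros((len(ids), len(ids)))
    for i, row in enumerate(table.itertuples(index=False)):
        s = pos.get(row.sire_id)
        d = pos.get(row.dam_id)
        A[i, i] = 1.0 + (0.5 * A[s, d] if s is not None and d is not None else 0.0)
        for j in range(i):
            a = 0.0
            if s is not None:
                a += 0.5 * A[j, s]
            if d is not None:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
    return A


class TestPedigree:
    def test_study_design_counts(self):
        ped = simulate_pedigree(12, 10, 20, 24, seed=1)
        f2 = ped.subset("F2")
        assert len(f2) == 480
        assert f2.family_group.nunique() == 10
        # full-sib litters nested within paternal half-sib groups
        assert (f2.groupby(["sire_id", "dam_id"]).size() == 24).all()
        assert (f2.family_group == f2.sire_id).all()

    def test_minimal_case(self):
        ped = simulate_pedigree(2, 1, 2, 1, seed=1)
        assert len(ped.f2_ids) == 2
        assert ped.subset("F2").family_group.nunique() == 1

    def test_deterministic(self):
        a = simulate_pedigree(12, 5, 10, 10, seed=7)
        b = simulate_pedigree(12, 5, 10, 10, seed=7)
        assert len(a.f2_ids) == 100
        pd.testing.assert_frame_equal(a.table, b.table)

    @pytest.mark.parametrize("args", [(0, 1, 2, 1), (2, 1, 3, 1), (2, -1, -2, 1)])
    def test_bad_counts_rejected(self, args):
        with pytest.raises(ValueError):
            simulate_pedigree(*args, seed=1)

    def test_half_sibs_related_at_least_quarter(self):
        """F2 animals sharing a sire have numerator relationship >= 0.25."""
        ped = simulate_pedigree(4, 2, 4, 3, seed=3)
        A = numerator_relationship(ped.table)
        pos = {a: i for i, a in enumerate(ped.table.animal_id)}
        f2 = ped.subset("F2")
        for sire, grp in f2.groupby("sire_id"):
            ids = [pos[a] for a in grp.animal_id]
            for i in ids:
                for j in ids:
                    if i != j:
                        assert A[i, j] >= 0.25 - 1e-12


class TestGenotypes:
    def test_mendelian_certainty(self):
        ped = simulate_pedigree(2, 1, 2, 2, seed=1)
        geno = simulate_genotypes(ped, 5, founder_freq_range=(0.5, 0.5), seed=2,
                                  keep_alleles=True)
        tab = ped.table.set_index("animal_id")
        for aid in ped.f2_ids:
            sire, dam = tab.loc[aid, "sire_id"], tab.loc[aid, "dam_id"]
            for a, parent in zip(geno.alleles[aid], (sire, dam)):
                pa = geno.alleles[parent]
                assert np.all((a == pa[0]) | (a == pa[1]))

    def test_allele_frequency_matches_founder_mean(self):
        """F2 frequency tracks the founder-line average under gene dropping."""
        ped = simulate_pedigree(12, 10, 20, 24, seed=4)
        devs = []
        for rep in range(10):
            geno = simulate_genotypes(ped, 400, seed=100 + rep)
            devs.append(geno.p.mean() - 0.5)
        # founder freqs ~ U(0.05, 0.95): mean 0.5; drift averages out over SNPs
        assert abs(np.mean(devs)) < 0.02

    def test_deterministic(self):
        ped = simulate_pedigree(4, 2, 4, 5, seed=5)
        a = simulate_genotypes(ped, 50, seed=9)
        b = simulate_genotypes(ped, 50, seed=9)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_empty_pedigree_rejected(self):
        from omicblup.data import Pedigree

        empty = Pedigree(pd.DataFrame(columns=["animal_id", "sire_id", "dam_id",
                                               "generation", "sex", "family_group"]))
        with pytest.raises(ValueError):
            simulate_genotypes(empty, 10, seed=1)


class TestTranscripts:
    def test_null_heritability_uncorrelated_with_genotypes(self, unrelated):
        geno, *_ = unrelated
        tx, _ = simulate_transcripts(geno, 10, 0.0, seed=3)
        # squared correlation of each column with each of 5 random genetic values
        rng = np.random.default_rng(1)
        gv = geno.Z @ rng.standard_normal((geno.m, 5))
        r2 = np.corrcoef(np.column_stack([tx.W, gv]).T)[:10, 10:] ** 2
        assert r2.mean() < 5.0 / geno.n  # noise level ~ 1/n

    def test_heritability_realized(self, f2_small):
        """Regression of columns on their own genetic values: slope ~ 1, R2 ~ h2."""
        geno = f2_small.genotypes
        slopes, r2s = [], []
        for rep in range(5):
            tx, truth = simulate_transcripts(geno, 20, 0.25, seed=50 + rep)
            gv = geno.Z @ truth.snp_effects_true
            for j in range(20):
                g = gv[:, j] - gv[:, j].mean()
                w = tx.W[:, j]
                slope = (g @ w) / (g @ g)
                slopes.append(slope)
                r2s.append(np.corrcoef(g, w)[0, 1] ** 2)
        assert abs(np.mean(slopes) - 1.0) < 0.1
        assert abs(np.mean(r2s) - 0.25) < 0.05

    def test_high_heritability_t_tracks_g(self, unrelated):
        geno, *_ = unrelated
        tx, truth = simulate_transcripts(geno, 15, 0.99, seed=4)
        gv = geno.Z @ truth.snp_effects_true
        for j in range(15):
            r = np.corrcoef(gv[:, j], tx.W[:, j])[0, 1]
            assert r > 0.99

    def test_columns_standardized(self, unrelated):
        geno, *_ = unrelated
        tx, _ = simulate_transcripts(geno, 8, 0.3, seed=5)
        np.testing.assert_allclose(tx.W.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(tx.W.std(axis=0, ddof=1), 1, atol=1e-10)

    def test_invalid_args_rejected(self, unrelated):
        geno, *_ = unrelated
        with pytest.raises(ValueError):
            simulate_transcripts(geno, 0, 0.2, seed=1)
        with pytest.raises(ValueError):
            simulate_transcripts(geno, 5, 1.0, seed=1)


class TestPhenotypes:
    def test_pure_noise_independent_of_omics(self, unrelated):
        geno, tx, _, _ = unrelated
        from omicblup.data import SimulationTruth

        truth = SimulationTruth(0.0, 0.0, 1.0, 0.25)
        accs = []
        for rep in range(20):
            ph = simulate_phenotypes(geno, tx, truth, n_testdays=4, seed=rep)
            resid = ph.y - ph.X @ np.linalg.lstsq(ph.X, ph.y, rcond=None)[0]
            gv = geno.Z @ np.random.default_rng(rep).standard_normal(geno.m)
            accs.append(np.corrcoef(resid, gv)[0, 1])
        assert abs(np.mean(accs)) < 0.1

    def test_component_variances_exact(self, unrelated):
        geno, tx, ph, truth = unrelated
        # components were rescaled to realized targets; total phenotypic
        # variance after test-day correction ~ sum of targets
        resid = ph.y - ph.X @ np.linalg.lstsq(ph.X, ph.y, rcond=None)[0]
        total = truth.sigma2_g_true + truth.sigma2_t_true + truth.sigma2_e_true
        assert abs(resid.var(ddof=1) - total) / total < 0.25

    def test_balanced_testdays(self, f2_small):
        counts = np.bincount(f2_small.phenotypes.testday)
        assert counts.max() - counts.min() <= 1

    def test_deterministic(self, unrelated):
        geno, tx, _, truth = unrelated
        a = simulate_phenotypes(geno, tx, truth, n_testdays=4, seed=99)
        b = simulate_phenotypes(geno, tx, truth, n_testdays=4, seed=99)
        np.testing.assert_array_equal(a.y, b.y)

    def test_mismatched_animals_rejected(self, unrelated, f2_small):
        geno, *_ = unrelated
        with pytest.raises(ValueError):
            simulate_phenotypes(geno, f2_small.transcripts, f2_small.truth, seed=1)


class TestDataset:
    def test_study_scale_shape(self, f2_study):
        assert f2_study.genotypes.n == 480
        assert f2_study.transcripts.k == 80
        assert f2_study.groups.nunique() == 10

    def test_realized_variances_converge_large_n(self):
        """At n = 2000 the realized component variances hit targets within 10%."""
        ds = simulate_dataset(n_snps=300, k=30, f2_per_mating=100, seed=31)
        resid = ds.phenotypes.y - ds.phenotypes.X @ np.linalg.lstsq(
            ds.phenotypes.X, ds.phenotypes.y, rcond=None)[0]
        assert ds.genotypes.n == 2000
        total = 0.25 + 0.35 + 0.40
        assert abs(resid.var(ddof=1) - total) / total < 0.10
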