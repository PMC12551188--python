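"""Fold construction, validation prediction, accuracy, Fisher z, comparisons."""

import numpy as np
import pytest

import omicblup as ob
from omicblup.crossval import (
    make_folds, predict_validation, accuracy, fisher_ci, compare_models,
    cross_validate, CVResult,
)


class TestMakeFolds:
    def test_random_sizes_480(self):
        plan = make_folds([f"a{i}" for i in range(480)], "random", 0.2, 500, seed=1)
        assert plan.n_folds == 500
        for ref, val in plan.folds[:10]:
            assert len(ref) == 384 and len(val) == 96
            assert not set(ref) & set(val)
            assert len(set(ref) | set(val)) == 480

    def test_family_enumeration_45(self):
        animals = [f"a{i}" for i in range(100)]
        groups = [i // 10 for i in range(100)]
        plan = make_folds(animals, "family", 0.2, groups=groups)
        assert plan.n_folds == 45
        gmap = dict(zip(animals, groups))
        for ref, val in plan.folds:
            assert len({gmap[a] for a in val}) == 2
            assert len({gmap[a] for a in ref}) == 8
            assert not {gmap[a] for a in val} & {gmap[a] for a in ref}

    def test_family_folds_cover_every_animal(self):
        animals = [f"a{i}" for i in range(30)]
        groups = [i % 5 for i in range(30)]
        plan = make_folds(animals, "family", 0.2, groups=groups)
        seen = set()
        for _, val in plan.folds:
            seen |= set(val)
        assert seen == set(animals)

    def test_deterministic(self):
        a = make_folds(list(range(50)), "random", 0.2, 10, seed=3)
        b = make_folds(list(range(50)), "random", 0.2, 10, seed=3)
        assert a.folds == b.folds

    def test_degenerate_fractions_rejected(self):
        with pytest.raises(ValueError):
            make_folds(list(range(10)), "random", 0.0, 5, seed=1)
        with pytest.raises(ValueError):
            make_folds(list(range(10)), "family", 0.2, groups=[0] * 10)


class TestPredictValidation:
    def _fit(self, y, X, K, ref_ids):
        res = ob.GBLUP(y, X, K).fit()
        res.reference_ids = list(ref_ids)
        return res

    def test_duplicated_animal_is_interpolation_fixed_point(self, rng):
        n = 30
        A = rng.normal(size=(n, 40))
        K = A @ A.T / 40
        ids = [f"a{i}" for i in range(n)] + ["dup"]
        Kf = np.zeros((n + 1, n + 1))
        Kf[:n, :n] = K
        Kf[n, :n] = K[0]
        Kf[:n, n] = K[0]
        Kf[n, n] = K[0, 0]
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        fit = self._fit(y, X, K, ids[:n])
        pred = predict_validation(fit, {"g": Kf}, ids, ["dup"], ridge=1e-10)
        assert pred[0] == pytest.approx(fit.blups["g"][0], abs=1e-5)

    def test_unrelated_validation_predicts_zero(self, rng):
        n = 20
        K = np.eye(n)
        ids = [f"a{i}" for i in range(n + 2)]
        Kf = np.eye(n + 2)  # off-diagonal block K_val,ref = 0
        y = rng.normal(size=n)
        fit = self._fit(y, np.ones((n, 1)), K, ids[:n])
        pred = predict_validation(fit, {"g": Kf}, ids, ids[n:])
        np.testing.assert_allclose(pred, 0.0, atol=1e-12)

    def test_missing_animal_rejected(self, rng):
        n = 10
        fit = self._fit(rng.normal(size=n), np.ones((n, 1)), np.eye(n),
                        [f"a{i}" for i in range(n)])
        with pytest.raises(KeyError):
            predict_validation(fit, {"g": np.eye(n)},
                               [f"a{i}" for i in range(n)], ["ghost"])

    def test_matches_mme_masking_oracle(self, f2_small):
        """Conditional-expectation prediction vs re-solving the MME with
        validation phenotypes masked: accuracies agree to 0.005."""
        ds = f2_small
        y = ob.standardize(ds.phenotypes.y)
        X = ds.phenotypes.X
        G = ob.vanraden_g(ds.genotypes)
        ids = list(ds.genotypes.animal_ids)
        n = len(ids)
        val = ids[:24]
        ref = ids[24:]
        ri = np.arange(24, n)
        fit = ob.GBLUP(y[ri], X[ri], ob.RelationshipMatrix(
            G.values[np.ix_(ri, ri)], "G")).fit()
        fit.reference_ids = ref
        pred = predict_validation(fit, {"g": G}, ids, val)
        # oracle: full MME, records restricted to reference animals
        s2g, s2e = fit.variance_components["g"], fit.sigma2_e
        Zrec = np.zeros((len(ri), n))
        Zrec[np.arange(len(ri)), ri] = 1.0
        Gi = np.linalg.inv(G.values + 1e-6 * np.eye(n))
        lam = s2e / s2g
        Xr = X[ri]
        lhs = np.block([[Xr.T @ Xr, Xr.T @ Zrec],
                        [Zrec.T @ Xr, Zrec.T @ Zrec + Gi * lam]])
        rhs = np.concatenate([Xr.T @ y[ri], Zrec.T @ y[ri]])
        sol = np.linalg.solve(lhs, rhs)
        u_all = sol[X.shape[1]:]
        pred_mme = u_all[:24]
        yv = y[:24]
        a1 = accuracy(pred, yv, X[:24], beta_testday=np.linalg.lstsq(X, y, rcond=None)[0])
        a2 = accuracy(pred_mme, yv, X[:24], beta_testday=np.linalg.lstsq(X, y, rcond=None)[0])
        assert abs(a1 - a2) <= 0.005


class TestAccuracy:
    def test_perfect_and_antiperfect(self, rng):
        n = 40
        X = np.ones((n, 1))
        y = rng.normal(size=n)
        corrected = y - y.mean()
        assert accuracy(corrected, y, X) == pytest.approx(1.0)
        assert accuracy(-corrected, y, X) == pytest.approx(-1.0)

    def test_null_distribution(self, rng):
        """Independent predictions: mean r ~ 0, SD ~ 1/sqrt(n-1)."""
        n, reps = 96, 1000
        X = np.ones((n, 1))
        rs = np.empty(reps)
        for i in range(reps):
            rs[i] = accuracy(rng.normal(size=n), rng.normal(size=n), X)
        assert abs(rs.mean()) < 0.02
        assert abs(rs.std() - 1 / np.sqrt(95)) < 0.02

    def test_invariance_to_shift_and_positive_scale(self, rng):
        n = 30
        X = np.ones((n, 1))
        pred, y = rng.normal(size=n), rng.normal(size=n)
        base = accuracy(pred, y, X)
        assert accuracy(3.0 * pred + 7.0, y, X) == pytest.approx(base, abs=1e-12)

    def test_zero_variance_returns_nan(self, rng):
        n = 20
        assert np.isnan(accuracy(np.zeros(n), rng.normal(size=n), np.ones((n, 1))))


class TestFisher:
    def test_all_zero(self):
        mean, lo, hi = fisher_ci([0.0, 0.0, 0.0])
        assert (mean, lo, hi) == (0.0, 0.0, 0.0)

    def test_closed_form_z_of_half(self):
        z = np.arctanh(0.5)
        assert z == pytest.approx(0.5 * np.log(3), abs=1e-12)
        assert z == pytest.approx(0.549306, abs=1e-6)

    def test_round_trip(self):
        r = np.linspace(-0.99, 0.99, 199)
        np.testing.assert_allclose(np.tanh(np.arctanh(r)), r, atol=1e-12)

    def test_clips_exact_one_with_warning(self):
        with pytest.warns(UserWarning):
            mean, lo, hi = fisher_ci([1.0, 0.5])
        assert mean < 1.0


class TestCompareModels:
    def test_identical_not_significant(self):
        rs = np.array([0.3, 0.4, 0.25, 0.35])
        res = CVResult({"a": rs, "b": rs.copy()})
        cmp = compare_models(res, "a", "b")
        assert cmp.mean_diff == 0.0 and not cmp.significant

    def test_constant_difference_significant(self):
        rs = np.array([0.3, 0.4, 0.25, 0.35])
        res = CVResult({"a": rs + 0.1, "b": rs})
        cmp = compare_models(res, "a", "b")
        assert cmp.mean_diff == pytest.approx(0.1)
        assert cmp.significant

    def test_fold_mismatch_rejected(self):
        res = CVResult({"a": np.array([0.1, 0.2]), "b": np.array([0.1, 0.2, 0.3])})
        with pytest.raises(ValueError):
            compare_models(res, "a", "b")


class TestCVLoop:
    def test_reproducible_and_sane(self, f2_small):
        ds = f2_small
        y = ob.standardize(ds.phenotypes.y)
        X = ds.phenotypes.X
        G = ob.vanraden_g(ds.genotypes)
        ids = list(ds.genotypes.animal_ids)
        plan = make_folds(ids, "random", 0.2, 6, seed=9)

        def build(y_r, X_r, ri):
            Gr = ob.RelationshipMatrix(G.values[np.ix_(ri, ri)], "G")
            return ob.GBLUP(y_r, X_r, Gr)

        out1 = cross_validate({"gblup": build}, y, X, ids, plan, {"gblup": {"g": G}})
        out2 = cross_validate({"gblup": build}, y, X, ids, plan, {"gblup": {"g": G}})
        np.testing.assert_array_equal(out1.per_fold_accuracy["gblup"],
                                      out2.per_fold_accuracy["gblup"])
        assert np.all(np.abs(out1.per_fold_accuracy["gblup"]) <= 1)
        # genomic signal is present: mean accuracy should be positive
        assert out1.mean_accuracy["gblup"] > 0
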