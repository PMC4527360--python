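import numpy as np
import pytest

from terroirpls import (
    ModelRecipe,
    crossval_q2,
    dummy_code,
    fit_pls2da,
    permutation_test,
    r2y,
    select_components,
    validate_model,
)
from terroirpls.validation import assign_folds, crossval_accuracy, _dummy_with_classes
from terroirpls.preprocess import Preprocessor
from terroirpls.latent import predict


class TestFoldAssignment:
    @pytest.mark.parametrize("n_folds", [2, 3, 6, 7, 8])
    def test_partition(self, n_folds):
        labels = np.array(list("abc") * 14)
        folds = assign_folds(labels, n_folds)
        assert len(folds) == 42
        assert set(folds) == set(range(n_folds))
        # every sample in exactly one fold is implied by the array form;
        # check stratification keeps every class in every training set
        for f in range(n_folds):
            for cls in "abc":
                assert np.any(labels[folds != f] == cls)

    def test_deterministic_without_seed(self):
        labels = np.array(list("ab") * 10)
        assert np.array_equal(assign_folds(labels, 4), assign_folds(labels, 4))

    def test_fold_losing_class_errors(self):
        labels = np.array(["a"] * 10 + ["b"])  # class b has one sample
        rec = ModelRecipe()
        X = np.random.default_rng(0).normal(size=(11, 3))
        with pytest.raises(ValueError, match="class"):
            crossval_q2(rec, X, labels, A=1, n_folds=2)


class TestCrossvalQ2:
    def test_noiseless_linear_relation_high_q2(self, rng):
        X = rng.normal(size=(12, 4))
        labels = np.where(X[:, 0] > 0, "hi", "lo")
        X[:, 0] = np.where(labels == "hi", 5.0, -5.0) + 0.01 * rng.normal(size=12)
        q2 = crossval_q2(ModelRecipe(), X, labels, A=1, n_folds=6)
        assert q2 >= 0.99

    def test_irrelevant_predictors_negative_q2(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 6))
            labels = np.array(["a", "b"] * 15)
            if crossval_q2(ModelRecipe(), X, labels, A=1, n_folds=7) <= 0:
                hits += 1
        assert hits >= 9

    def test_matches_brute_force_two_split_oracle(self, rng):
        """Hand-rolled 2-fold refit loop reproduces Q2 exactly."""
        X_raw = rng.lognormal(size=(8, 5))
        labels = np.array(["a", "b"] * 4)
        rec = ModelRecipe(preprocess=("log",))
        q2 = crossval_q2(rec, X_raw, labels, A=1, n_folds=2, seed=None)
        folds = assign_folds(labels, 2)
        classes = ["a", "b"]
        Yfull = _dummy_with_classes(labels, classes).Y
        press = ss = 0.0
        for f in (0, 1):
            tr, te = folds != f, folds == f
            prep = Preprocessor(("log", "center")).fit(X_raw[tr])
            m = fit_pls2da(prep.X_fitted_, _dummy_with_classes(labels[tr], classes), 1)
            Yhat = predict(m, prep.transform(X_raw[te]))
            press += np.sum((Yfull[te] - Yhat) ** 2)
            ss += np.sum((Yfull[te] - Yfull[tr].mean(axis=0)) ** 2)
        assert q2 == 1.0 - press / ss  # bitwise on PRESS terms

    def test_q2_equals_r2_deterministic_single_feature(self):
        """With one feature and class-balanced folds the training model is
        the full model, so Q2 = R2 exactly."""
        X = np.array([[1.0], [-1.0]] * 6)
        labels = np.array(["a", "b"] * 6)
        q2 = crossval_q2(ModelRecipe(), X, labels, A=1, n_folds=6)
        Y = dummy_code(labels)
        m = fit_pls2da(X - X.mean(axis=0), Y, 1)
        assert q2 == pytest.approx(r2y(m, Y), abs=1e-12)


class TestPermutationTest:
    def test_strong_signal_minimal_p(self, rng):
        X = rng.normal(size=(20, 5))
        labels = np.array(["a", "b"] * 10)
        X[:, 0] += np.where(labels == "a", 4.0, -4.0)
        rec = ModelRecipe()
        perm = permutation_test(rec, X, labels, A=1, n_perm=99, seed=5)
        assert perm.p_value == pytest.approx(1.0 / 100.0)
        assert perm.passed

    def test_observed_exceeds_null_oracle(self, rng):
        """p equals the explicit-loop count of null Q2 >= observed Q2."""
        X = rng.normal(size=(16, 4))
        labels = np.array(["a", "b"] * 8)
        rec = ModelRecipe()
        perm = permutation_test(rec, X, labels, A=1, n_perm=30, seed=2)
        count = int(np.sum(perm.null_q2 >= perm.observed_q2))
        assert perm.p_value == (1 + count) / 31

    def test_pure_noise_not_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(24, 5))
            labels = np.array(["a", "b"] * 12)
            perm = permutation_test(
                ModelRecipe(), X, labels, A=1, n_perm=39, seed=seed
            )
            if perm.p_value > 0.05:
                hits += 1
        assert hits >= 9

    def test_zero_permutations_error(self, rng):
        X = rng.normal(size=(8, 3))
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(
                ModelRecipe(), X, np.array(["a", "b"] * 4), A=1, n_perm=0
            )


class TestSelectComponents:
    def _recipe_and_data(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(21, 6))
        labels = np.array(["a", "b", "c"] * 7)
        X[:, 0] += np.where(labels == "a", 3.0, 0.0)
        X[:, 1] += np.where(labels == "b", 3.0, 0.0)
        return ModelRecipe(), X, labels

    def test_first_local_maximum_from_injected_sequence(self):
        rec, X, labels = self._recipe_and_data()
        fake = {1: 0.40, 2: 0.60, 3: 0.55}
        sel = select_components(
            rec, X, labels, max_A=3, n_perm=39, seed=1, cv=lambda A: fake[A]
        )
        assert sel.selected_A == 2
        assert sel.status == "accepted"

    def test_strictly_increasing_takes_max_with_warning_status(self):
        rec, X, labels = self._recipe_and_data()
        fake = {1: 0.1, 2: 0.2, 3: 0.3}
        sel = select_components(
            rec, X, labels, max_A=3, n_perm=39, seed=1, cv=lambda A: fake[A]
        )
        assert sel.selected_A == 3
        assert sel.status == "accepted_at_max"

    def test_no_passing_model_rejected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 5))  # no class signal at all
        labels = np.array(["a", "b"] * 10)
        sel = select_components(
            ModelRecipe(), X, labels, max_A=2, n_perm=39, seed=3
        )
        assert sel.status == "rejected"
        assert sel.selected_A is None


class TestR2Y:
    def test_perfect_interpolation(self, rng):
        X = rng.normal(size=(3, 3))
        X -= X.mean(axis=0)
        Y = dummy_code(["a", "b", "c"])
        m = fit_pls2da(X, Y, 2)
        assert r2y(m, Y) == pytest.approx(1.0, abs=1e-8)

    def test_class_means_decomposition_oracle(self):
        """A model predicting exactly the class means explains the
        between-class share of the response variance."""
        labels = np.array(["a"] * 4 + ["b"] * 8)
        Y = dummy_code(labels)
        X = np.where(labels == "a", 1.0, -0.5)[:, None]  # = centered dummy dir
        m = fit_pls2da(X, Y, 1)
        # X is noiseless class coding, so fitted values are the class means
        Yc = Y.Y - Y.Y.mean(axis=0)
        between = sum(
            (labels == c).sum() * (Yc[labels == c].mean(axis=0) ** 2).sum()
            for c in ("a", "b")
        )
        total = np.sum(Yc**2)
        assert r2y(m, Y) == pytest.approx(between / total, abs=1e-10)

    def test_constant_response_error(self, rng):
        X = rng.normal(size=(6, 3))
        Y = dummy_code(["a", "b"] * 3)
        m = fit_pls2da(X - X.mean(axis=0), Y, 1)
        Y.Y = np.ones_like(Y.Y)
        with pytest.raises(ValueError, match="zero variance"):
            r2y(m, Y)


class TestValidateModel:
    def test_full_protocol_on_separable_data(self, rng):
        X = rng.normal(size=(24, 6))
        labels = np.array(["a", "b", "c"] * 8)
        for k, c in enumerate("abc"):
            X[:, k] += np.where(labels == c, 4.0, 0.0)
        report = validate_model(
            ModelRecipe(), X, labels, max_A=3, schemes=(6, 7, 8),
            n_perm=39, seed=0,
        )
        assert report.status in ("accepted", "accepted_at_max")
        assert set(report.q2_by_scheme) == {6, 7, 8}
        assert all(v > 0.5 for v in report.q2_by_scheme.values())
        assert report.r2y > 0.5
        assert report.permutation.passed
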