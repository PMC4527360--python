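import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from terroirpls import (
    FeatureTable,
    Preprocessor,
    autoscale,
    internal_standard_normalize,
    log_transform,
    mean_center,
    median_fold_change_normalize,
)
from terroirpls.io import FeatureAnnotation


def _table(X, samples=None, features=None):
    X = np.asarray(X, dtype=float)
    samples = samples or [f"s{i}" for i in range(X.shape[0])]
    features = features or [f"f{j}" for j in range(X.shape[1])]
    return FeatureTable(pd.DataFrame(X, index=samples, columns=features))


def _annotation(features, keys, classes=None):
    return FeatureAnnotation(
        pd.DataFrame(
            {
                "chemical_class": classes or ["x"] * len(features),
                "internal_standard_key": keys,
            },
            index=features,
        )
    )


class TestInternalStandardNormalize:
    def test_sesquiterpene_divided_by_copaene(self):
        t = _table([[100.0]], features=["sesq1"])
        ann = _annotation(["sesq1"], ["alpha-copaene"], ["sesquiterpene"])
        areas = pd.DataFrame(
            {"alpha-copaene": [50.0], "d3-b-ionone": [1.0], "d13-hexanol": [1.0]},
            index=["s0"],
        )
        out = internal_standard_normalize(t, ann, areas)
        assert out.values[0, 0] == pytest.approx(2.0)

    def test_unit_areas_identity(self, rng):
        X = rng.lognormal(size=(3, 4))
        t = _table(X)
        ann = _annotation(t.features, ["d13-hexanol"] * 4)
        areas = pd.DataFrame(
            1.0, index=t.samples,
            columns=["alpha-copaene", "d3-b-ionone", "d13-hexanol"],
        )
        out = internal_standard_normalize(t, ann, areas)
        assert np.allclose(out.values, X)

    def test_matches_per_cell_division_oracle(self, rng):
        X = rng.lognormal(size=(4, 6))
        t = _table(X)
        keys = ["alpha-copaene", "d3-b-ionone", "d13-hexanol"] * 2
        ann = _annotation(t.features, keys)
        areas = pd.DataFrame(
            rng.uniform(0.5, 5.0, size=(4, 3)),
            index=t.samples,
            columns=["alpha-copaene", "d3-b-ionone", "d13-hexanol"],
        )
        out = internal_standard_normalize(t, ann, areas)
        for i, s in enumerate(t.samples):
            for j, key in enumerate(keys):
                assert out.values[i, j] == pytest.approx(
                    X[i, j] / areas.loc[s, key], rel=1e-12
                )

    def test_commutes_with_feature_reordering(self, rng):
        X = rng.lognormal(size=(3, 5))
        keys = ["alpha-copaene", "d13-hexanol", "d3-b-ionone",
                "d13-hexanol", "alpha-copaene"]
        t = _table(X)
        ann = _annotation(t.features, keys)
        areas = pd.DataFrame(
            rng.uniform(1, 3, size=(3, 3)), index=t.samples,
            columns=["alpha-copaene", "d3-b-ionone", "d13-hexanol"],
        )
        out = internal_standard_normalize(t, ann, areas)
        perm = [3, 1, 4, 0, 2]
        t2 = FeatureTable(t.data.iloc[:, perm])
        out2 = internal_standard_normalize(t2, ann, areas)
        pd.testing.assert_frame_equal(out.data.iloc[:, perm], out2.data)

    def test_zero_is_area_error_names_sample(self):
        t = _table([[1.0]], features=["a"])
        ann = _annotation(["a"], ["d13-hexanol"])
        areas = pd.DataFrame(
            {"alpha-copaene": [1.0], "d3-b-ionone": [1.0], "d13-hexanol": [0.0]},
            index=["s0"],
        )
        with pytest.raises(ValueError, match="d13-hexanol.*'s0'"):
            internal_standard_normalize(t, ann, areas)

    def test_missing_is_key_error(self):
        t = _table([[1.0]], features=["a"])
        ann = _annotation(["a"], ["none"])
        areas = pd.DataFrame(
            {"alpha-copaene": [1.0], "d3-b-ionone": [1.0], "d13-hexanol": [1.0]},
            index=["s0"],
        )
        with pytest.raises(ValueError, match="internal_standard_key"):
            internal_standard_normalize(t, ann, areas)


class TestMedianFoldChange:
    def test_scale_invariance_two_samples(self):
        A = np.array([1.0, 2.0, 3.0, 4.0])
        t = _table(np.vstack([A, 2 * A]))
        out, f = median_fold_change_normalize(t)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0)
        assert np.allclose(out.values[0], out.values[1])

    def test_single_sample_factor_one(self):
        t = _table([[1.0, 5.0, 2.0]])
        out, f = median_fold_change_normalize(t)
        assert f.iloc[0] == pytest.approx(1.0)
        assert np.allclose(out.values, t.values)

    def test_matches_median_of_ratios_oracle(self, rng):
        X = rng.lognormal(size=(5, 10))
        t = _table(X)
        out, f = median_fold_change_normalize(t)
        ref = np.median(X, axis=0)
        for i in range(5):
            expected = np.median(X[i] / ref)
            assert f.iloc[i] == expected
            assert np.allclose(out.values[i], X[i] / expected)

    def test_idempotent_with_stored_reference(self, rng):
        """Renormalizing against the same reference profile yields factors 1."""
        X = rng.lognormal(size=(6, 12))
        t = _table(X)
        ref = np.median(X, axis=0)
        out, _ = median_fold_change_normalize(t, reference=ref)
        _, f2 = median_fold_change_normalize(out, reference=ref)
        assert np.abs(f2.to_numpy() - 1.0).max() < 1e-10

    def test_disjoint_support_error(self):
        t = _table([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="no feature positive|no positive"):
            median_fold_change_normalize(t, reference=np.array([0.0, 1.0]))


class TestLogTransform:
    def test_reference_points(self):
        t = _table([[0.0, np.e - 1.0]])
        out = log_transform(t, epsilon=1.0)
        assert out.values[0, 0] == pytest.approx(0.0)
        assert out.values[0, 1] == pytest.approx(1.0)

    @settings(max_examples=40, derandomize=True)
    @given(
        st.floats(0.0, 1e6), st.floats(0.0, 1e6),
        st.floats(1e-6, 10.0),
    )
    def test_monotone(self, x1, x2, eps):
        lo, hi = sorted([x1, x2])
        if lo + eps == hi + eps:  # indistinguishable at float precision
            return
        t = _table([[lo, hi]])
        out = log_transform(t, epsilon=eps)
        assert out.values[0, 0] < out.values[0, 1]

    def test_negative_intensity_error(self):
        with pytest.raises(ValueError, match="negative"):
            log_transform(_table([[-1.0, 2.0]]))


class TestCenterScale:
    def test_centered_column_sums_zero(self, rng):
        t = _table(rng.normal(size=(7, 4)))
        out, means = mean_center(t)
        assert np.abs(out.values.sum(axis=0)).max() < 1e-10

    def test_autoscaled_unit_sd(self, rng):
        t = _table(rng.normal(size=(9, 5)))
        out, means, sds = autoscale(t)
        assert np.abs(out.values.std(axis=0, ddof=1) - 1).max() < 1e-10
        assert np.abs(out.values.mean(axis=0)).max() < 1e-10

    def test_zero_variance_feature_listed(self):
        t = _table([[1.0, 2.0], [1.0, 3.0]])
        with pytest.raises(ValueError, match="f0"):
            autoscale(t)

    def test_stored_params_reproduce_training_transform(self, rng):
        X = rng.lognormal(size=(8, 6))
        prep = Preprocessor(("mfc", "log", "autoscale")).fit(X)
        again = prep.transform(X)
        assert np.abs(again - prep.X_fitted_).max() < 1e-10


class TestFullChain:
    def test_scalar_multiple_samples_collapse_to_zero(self, rng):
        """mfc -> log -> center turns proportional samples into zero columns."""
        profile = rng.lognormal(size=30)
        scales = np.array([0.5, 1.0, 2.0, 4.0, 1.7])
        X = scales[:, None] * profile[None, :]
        out = Preprocessor(("mfc", "log", "center"), epsilon=1e-12).fit_transform(X)
        assert np.abs(out).max() < 1e-8
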