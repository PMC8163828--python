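import warnings

import numpy as np
import pandas as pd
import pytest

from fragsig.classification import (
    _oversample,
    average_roc,
    bootstrap_evaluate,
    harmonize,
    inner_select,
)

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


class TestHarmonize:
    def test_controls_end_standardized_per_source(self, rng):
        X = pd.DataFrame(rng.normal(5, 2, size=(40, 6)))
        controls = np.array([True] * 10 + [False] * 10 + [True] * 10 + [False] * 10)
        src = np.array(["a"] * 20 + ["b"] * 20)
        out = harmonize(X, controls, src)
        for s in ("a", "b"):
            ctrl = out[(src == s) & controls]
            np.testing.assert_allclose(ctrl.mean(), 0.0, atol=1e-12)
            np.testing.assert_allclose(ctrl.std(ddof=1), 1.0, atol=1e-12)

    def test_source_offsets_removed(self, rng):
        base = rng.normal(size=(30, 4))
        X = pd.DataFrame(np.vstack([base[:15] + 10.0, base[15:]]))
        controls = np.ones(30, bool)
        src = np.array(["a"] * 15 + ["b"] * 15)
        out = harmonize(X, controls, src)
        assert abs(out[src == "a"].mean().mean() - out[src == "b"].mean().mean()) < 1e-9

    def test_zero_spread_feature_dropped(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        X["b"] = 1.0
        out = harmonize(X, np.ones(20, bool), np.array(["s"] * 20))
        assert list(out.columns) == ["a", "c"]

    def test_too_few_controls_is_error(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="controls"):
            harmonize(X, np.array([True, False, False, False, False]),
                      np.array(["s"] * 5))


class TestOversample:
    def test_factor_is_ceiling_ratio(self):
        X = np.zeros((40, 2))
        y = np.array([0] * 30 + [1] * 10)
        Xo, yo = _oversample(X, y)
        # factor ceil(30/10) = 3: minority duplicated to 30
        assert (yo == 1).sum() == 30
        assert (yo == 0).sum() == 30

    def test_balanced_unchanged(self):
        X = np.zeros((20, 2))
        y = np.array([0] * 10 + [1] * 10)
        Xo, yo = _oversample(X, y)
        assert len(yo) == 20


class TestAverageRoc:
    def test_identical_curves_average_to_themselves(self):
        fpr = np.array([0.0, 0.2, 1.0])
        tpr = np.array([0.0, 0.9, 1.0])
        grid, mean_tpr, auc = average_roc([(fpr, tpr)] * 5)
        assert np.interp(0.2, grid, mean_tpr) == pytest.approx(0.9, abs=1e-3)

    def test_perfect_plus_random_gives_three_quarters(self):
        perfect = (np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 1.0]))
        random_ = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        _, _, auc = average_roc([perfect, random_])
        assert auc == pytest.approx(0.75, abs=0.005)

    def test_grid_endpoints_present(self):
        grid, mean_tpr, _ = average_roc([(np.array([0.0, 1.0]), np.array([0.0, 1.0]))])
        assert grid[0] == 0.0 and grid[-1] == 1.0
        assert mean_tpr[0] == 0.0 and mean_tpr[-1] == 1.0
        assert len(grid) == 1001

    def test_no_curves_is_error(self):
        with pytest.raises(ValueError):
            average_roc([])


class TestInnerSelect:
    def test_linear_signal_prefers_linear_family(self, rng):
        n = 60
        y = np.array([0] * 30 + [1] * 30)
        X = rng.normal(size=(n, 5))
        X[:, 0] += y * 4.0
        model = inner_select(X, y, seed=0)
        assert model.family in ("glm", "svm")
        assert model.inner_auc > 0.95

    def test_selection_deterministic(self, rng):
        X = rng.normal(size=(40, 4))
        y = np.array([0] * 20 + [1] * 20)
        a = inner_select(X, y, seed=3)
        b = inner_select(X, y, seed=3)
        assert a.family == b.family and a.params == b.params

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            inner_select(np.zeros((10, 2)), np.zeros(10, int))


class TestBootstrapEvaluate:
    def test_patient_samples_never_straddle_split(self, rng):
        n = 40
        y = np.array([0, 1] * 20)
        patients = np.repeat(np.arange(20), 2)  # two samples per patient
        X = pd.DataFrame(rng.normal(size=(n, 3)) + y[:, None] * 2)
        res = bootstrap_evaluate({"a": X}, y, patients, n_iter=4, seed=0)["a"]
        for train_p, test_p in res.splits:
            assert len(np.intersect1d(train_p, test_p)) == 0

    def test_meta_equals_base_when_bases_identical(self, rng):
        n = 50
        y = np.array([0] * 25 + [1] * 25)
        X = pd.DataFrame(rng.normal(size=(n, 3)) + y[:, None] * 2)
        sets = {k: X for k in ("s1", "s2", "s3", "s4")}
        res = bootstrap_evaluate(sets, y, np.arange(n), n_iter=2, seed=1, meta=True)
        # identical bases: the meta-learner is an affine map of one base, so
        # its ROC (and averaged AUC) matches the base's
        assert res["meta"].auc == pytest.approx(res["s1"].auc, abs=0.02)
        assert np.all((0.0 <= res["meta"].mean_tpr) & (res["meta"].mean_tpr <= 1.0))

    def test_meta_tracks_informative_base_among_noise(self, rng):
        n = 50
        y = np.array([0] * 25 + [1] * 25)
        informative = pd.DataFrame(rng.normal(size=(n, 3)) + y[:, None] * 2.5)
        sets = {"good": informative}
        for k in ("n1", "n2", "n3"):
            sets[k] = pd.DataFrame(rng.normal(size=(n, 3)))
        res = bootstrap_evaluate(sets, y, np.arange(n), n_iter=3, seed=4, meta=True)
        assert res["meta"].auc >= res["good"].auc - 0.02

    def test_probabilities_in_unit_interval(self, rng):
        n = 30
        y = np.array([0] * 15 + [1] * 15)
        X = pd.DataFrame(rng.normal(size=(n, 2)))
        res = bootstrap_evaluate({"a": X}, y, np.arange(n), n_iter=2, seed=2)["a"]
        assert 0.0 <= res.auc <= 1.0

    def test_impossible_test_rule_raises(self, rng):
        y = np.array([0] * 6 + [1] * 2)  # can never place 5 of each class in test
        X = pd.DataFrame(rng.normal(size=(8, 2)))
        with pytest.raises(RuntimeError):
            bootstrap_evaluate({"a": X}, y, np.arange(8), n_iter=1, seed=0)

    def test_deterministic_given_seed(self, rng):
        n = 36
        y = np.array([0] * 18 + [1] * 18)
        X = pd.DataFrame(rng.normal(size=(n, 3)) + y[:, None])
        a = bootstrap_evaluate({"x": X}, y, np.arange(n), n_iter=3, seed=9)["x"]
        b = bootstrap_evaluate({"x": X}, y, np.arange(n), n_iter=3, seed=9)["x"]
        np.testing.assert_array_equal(a.per_iteration_auc, b.per_iteration_auc)
        np.testing.assert_array_equal(a.mean_tpr, b.mean_tpr)
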