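"""Splitting, unicolumn statistics, stepwise selection and PLS modelling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import gridqsar as g
from gridqsar.qsar import _ols_loo_q2


def _matrix(X: np.ndarray, y: np.ndarray, names=None) -> g.DescriptorMatrix:
    names = names or [f"E_{i}" for i in range(X.shape[1])]
    ids = [f"c{i}" for i in range(X.shape[0])]
    return g.DescriptorMatrix(pd.DataFrame(X, index=ids, columns=names),
                              pd.Series(y, index=ids, name="pic50"))


def _full_split(m: g.DescriptorMatrix) -> g.SplitSpec:
    return g.SplitSpec.from_lists(m.compound_ids, ())


class TestUnicolumnStats:
    def test_simple_values(self):
        s = g.unicolumn_stats([1.0, 2.0, 3.0])
        assert (s.average, s.max, s.min, s.std_dev, s.sum) == (2.0, 3.0, 1.0, 1.0, 6.0)

    def test_singleton(self):
        s = g.unicolumn_stats([5.0])
        assert s.average == s.max == s.min == s.sum == 5.0
        assert s.std_dev == 0.0

    def test_training_extremes(self):
        # the training activity window of a typical congeneric series
        s = g.unicolumn_stats([5.31, 7.64])
        assert s.average == pytest.approx(6.475)
        assert s.max == 7.64 and s.min == 5.31

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            g.unicolumn_stats([])


class TestSplitChecks:
    def test_interpolative_window(self):
        ok, msgs = g.check_split_interpolative([5.31, 6.5, 7.64],
                                               [5.58, 7.099])
        assert ok and msgs == []

    def test_test_min_below_train_min(self):
        ok, msgs = g.check_split_interpolative([1.0, 2.0], [0.0, 1.5])
        assert not ok
        assert any("min" in m for m in msgs)

    def test_equal_sets_fail_strictness(self):
        ok, _ = g.check_split_interpolative([1.0, 2.0], [1.0, 2.0])
        assert not ok

    def test_split_interpolative_constructor(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.standard_normal((20, 3)), rng.uniform(5, 8, 20))
        split = g.split_interpolative(m, 4, seed=1)
        assert len(split.test_ids) == 4
        ok, _ = g.check_split_interpolative(
            m.subset(split.train_ids).y.tolist(),
            m.subset(split.test_ids).y.tolist())
        assert ok

    def test_overlapping_split_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            g.SplitSpec.from_lists(["a", "b"], ["b"])


class TestStepwiseForward:
    def _brute_force_best_pair(self, X, y):
        best, best_q2 = None, -np.inf
        for pair in itertools.combinations(range(X.shape[1]), 2):
            q2 = _ols_loo_q2(X[:, pair], y)
            if q2 > best_q2:
                best, best_q2 = pair, q2
        return set(best)

    @pytest.mark.parametrize("seed", range(10))
    def test_recovers_planted_pair_matching_brute_force(self, seed):
        planted = g.PlantedModel(None, [1.0, -0.7], 6.0, 0.0)
        m, truth = g.generate_descriptor_matrix(20, 50, planted, seed=seed)
        sel = g.stepwise_forward_select(m, _full_split(m), max_descriptors=2)
        assert set(sel) == set(truth.informative_descriptors)
        idx = [m.descriptor_names.index(c) for c in sel]
        brute = self._brute_force_best_pair(m.X.to_numpy(), m.y.to_numpy())
        assert set(idx) == brute

    def test_respects_max_descriptors_cap(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 20))
        y = X @ rng.standard_normal(20)  # signal everywhere
        m = _matrix(X, y)
        sel = g.stepwise_forward_select(m, _full_split(m), max_descriptors=4)
        assert len(sel) <= 4

    def test_duplicate_column_tie_keeps_lower_index(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(25)
        noise = rng.standard_normal((25, 3))
        X = np.column_stack([noise[:, 0], x, x, noise[:, 1]])
        m = _matrix(X, 6.0 + 2.0 * x)
        sel = g.stepwise_forward_select(m, _full_split(m), max_descriptors=2)
        assert sel[0] == m.descriptor_names[1]
        assert m.descriptor_names[2] not in sel

    def test_deterministic(self):
        planted = g.PlantedModel(None, [1.0, 0.5, -0.4], 6.0, 0.3)
        m, _ = g.generate_descriptor_matrix(25, 40, planted, seed=9)
        a = g.stepwise_forward_select(m, _full_split(m), 3)
        b = g.stepwise_forward_select(m, _full_split(m), 3)
        assert a == b

    def test_estimator_api(self):
        sel = g.StepwiseForwardSelector(max_descriptors=3)
        assert clone(sel).get_params()["max_descriptors"] == 3
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((20, 6)),
                         columns=[f"E_{i}" for i in range(6)])
        y = 1.5 * X["E_2"] + 5.0
        sel.fit(X, y)
        assert sel.selected_[0] == "E_2"
        assert sel.transform(X).shape[1] == len(sel.selected_)
        assert sel.get_support().sum() == len(sel.selected_)


class TestPLS:
    def test_single_descriptor_equals_simple_regression(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(15)
        y = 2.5 * x + 1.0 + rng.normal(0, 0.1, 15)
        m = _matrix(x[:, None], y)
        model = g.fit_pls(m, _full_split(m), ["E_0"], n_components=1)
        coef_expected = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert model.coefficients[0] == pytest.approx(coef_expected, rel=1e-9)
        assert model.intercept == pytest.approx(y.mean() - coef_expected * x.mean(),
                                                rel=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_full_rank_components_match_ols_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((20, 5))
        y = X @ rng.standard_normal(5) + rng.standard_normal(20) * 0.5
        m = _matrix(X, y)
        model = g.fit_pls(m, _full_split(m), m.descriptor_names, n_components=5)
        A = np.column_stack([np.ones(20), X])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        preds = model.predict(m.X)
        np.testing.assert_allclose(preds, A @ beta, atol=1e-8)

    def test_constant_y_gives_zero_coefficients(self):
        rng = np.random.default_rng(5)
        m = _matrix(rng.standard_normal((10, 3)), np.full(10, 6.2))
        model = g.fit_pls(m, _full_split(m), m.descriptor_names)
        assert model.coefficients == [0.0, 0.0, 0.0]
        assert model.intercept == 6.2

    def test_component_count_selected_by_loo(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((25, 4))
        y = X @ np.array([2.0, -1.0, 0.5, 0.2]) + 6.0
        m = _matrix(X, y)
        model = g.fit_pls(m, _full_split(m), m.descriptor_names)
        assert 1 <= model.n_components <= 4

    def test_regressor_estimator_api(self):
        reg = g.PLSQSARRegressor(n_components=2)
        assert clone(reg).get_params()["n_components"] == 2
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.standard_normal((15, 3)),
                         columns=["E_0", "E_1", "E_2"])
        y = X["E_0"] * 2 + 6
        reg.fit(X, y)
        assert reg.coef_.shape == (3,)
        assert reg.n_components_ == 2
        assert reg.training_mean_activity_ == pytest.approx(float(y.mean()))


class TestQSARModelEquation:
    def test_zero_vector_returns_intercept(self):
        model = g.published_model()
        zeros = {n: 0.0 for n in model.descriptor_names}
        assert model.predict(zeros) == 5.73211

    def test_unit_e86(self):
        model = g.published_model()
        vals = {"E_86": 1.0, "E_943": 0.0, "E_463": 0.0, "S_482": 0.0}
        assert model.predict(vals) == pytest.approx(9.63068, abs=1e-9)

    def test_linearity_in_inputs(self):
        model = g.published_model()
        rng = np.random.default_rng(8)
        v1 = {n: float(x) for n, x in zip(model.descriptor_names,
                                          rng.standard_normal(4))}
        v2 = {n: 2.0 * v for n, v in v1.items()}
        assert (model.predict(v2) - model.intercept) == pytest.approx(
            2.0 * (model.predict(v1) - model.intercept), rel=1e-12)

    def test_missing_descriptor_named(self):
        model = g.published_model()
        with pytest.raises(KeyError, match="E_943"):
            model.predict({"E_86": 0.0, "E_463": 0.0, "S_482": 0.0})

    def test_json_roundtrip(self):
        model = g.published_model()
        back = g.QSARModel.from_json(model.to_json())
        assert back.descriptor_names == model.descriptor_names
        assert back.coefficients == model.coefficients
        assert back.intercept == model.intercept


class TestContributions:
    def test_single_descriptor_sign(self):
        m = _matrix(np.linspace(0, 1, 6)[:, None], np.linspace(5, 6, 6))
        model = g.QSARModel(["E_0"], [-2.0], 6.0, 1)
        contrib = g.contribution_percentages(model, m)
        assert contrib["E_0"] == pytest.approx(-100.0)

    def test_equal_products_opposite_signs(self):
        X = np.column_stack([np.linspace(0, 1, 6), np.linspace(0, 2, 6)])
        m = _matrix(X, np.linspace(5, 6, 6))
        model = g.QSARModel(["E_0", "E_1"], [2.0, -1.0], 6.0, 1)
        contrib = g.contribution_percentages(model, m)
        assert contrib["E_0"] == pytest.approx(50.0)
        assert contrib["E_1"] == pytest.approx(-50.0)

    def test_hand_computed_products(self):
        # ranges 2, 4; coefficients 3, -0.5 -> products 6, -2 -> 75%, -25%
        X = np.column_stack([np.linspace(0, 2, 5), np.linspace(0, 4, 5)])
        m = _matrix(X, np.linspace(5, 6, 5))
        model = g.QSARModel(["E_0", "E_1"], [3.0, -0.5], 6.0, 1)
        contrib = g.contribution_percentages(model, m)
        assert contrib["E_0"] == pytest.approx(75.0)
        assert contrib["E_1"] == pytest.approx(-25.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_absolute_contributions_sum_to_100(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((12, 4))
        m = _matrix(X, rng.uniform(5, 8, 12))
        model = g.QSARModel(m.descriptor_names,
                            list(rng.standard_normal(4)), 6.0, 2)
        contrib = g.contribution_percentages(model, m)
        assert sum(abs(v) for v in contrib.values()) == pytest.approx(100.0,
                                                                      abs=1e-9)
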