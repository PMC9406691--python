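"""Descriptor filtering, GA subset selection and Williams-plot domain."""


import numpy as np
import pandas as pd
import pytest

from cwqsar import (
    GAMLRRegressor, MLRModel, filter_descriptors, ga_select, predict_mlr,
    williams_ad,
)
from cwqsar.gamlr import _ols_press_q2, exhaustive_select, subset_fitness
from cwqsar.synthetic import synthetic_descriptor_matrix


def _planted(n=30, p=8, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = 1.0 + 2.0 * X[:, 1] - 1.5 * X[:, 3]
    if noise:
        y = y + rng.normal(0, noise, n)
    return X, y


class TestFilterDescriptors:
    def test_constant_column_removed(self):
        df = pd.DataFrame({"a": [1.0] * 6, "b": np.arange(6.0)})
        y = np.arange(6.0)
        filtered = filter_descriptors(df, y)
        assert filtered.names == ["b"]
        assert filtered.dropped_constant == ["a"]

    def test_duplicate_pair_one_removed(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        df = pd.DataFrame({"a": x, "dup": x.copy(), "c": rng.normal(size=10)})
        y = 2 * x
        filtered = filter_descriptors(df, y)
        assert sum(n in filtered.names for n in ("a", "dup")) == 1
        assert "c" in filtered.names

    def test_keeps_the_response_correlated_member(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        noisy = x + rng.normal(0, 0.05, 40)  # r > 0.95, weaker to response
        df = pd.DataFrame({"clean": x, "noisy": noisy})
        y = 3 * x
        filtered = filter_descriptors(df, y)
        assert filtered.names == ["clean"]

    def test_planted_redundancy_matches_exhaustive_check(self):
        matrix, y, truth = synthetic_descriptor_matrix(
            n_molecules=25, n_descriptors=10, k_informative=2, seed=3
        )
        filtered = filter_descriptors(matrix, y)
        assert truth["constant_decoy"] in filtered.dropped_constant
        survivors = sum(
            name in filtered.names for name in truth["duplicate_pair"]
        )
        assert survivors == 1

    def test_all_removed_errors(self):
        df = pd.DataFrame({"a": [1.0] * 5})
        with pytest.raises(ValueError):
            filter_descriptors(df, np.arange(5.0))

    def test_scaling_parameters_stored(self):
        df = pd.DataFrame({
            "a": np.arange(10.0), "b": np.arange(10.0)[::-1] * 2
        })
        filtered = filter_descriptors(df, np.arange(10.0))
        scaled = filtered.scaled
        assert np.allclose(scaled.mean(), 0.0)
        assert np.allclose(scaled.std(ddof=0), 1.0)


class TestGaSelect:
    def test_recovers_planted_pair_and_coefficients(self):
        X, y = _planted()
        subset, fitness, _ = ga_select(
            X, y, model_size=2, population=10, generations=60, seed=0
        )
        oracle_subset, oracle_fit = exhaustive_select(X, y, 2)
        assert subset == oracle_subset == (1, 3)
        assert fitness == pytest.approx(oracle_fit, abs=1e-12)
        from cwqsar.gamlr import _ols_fit

        beta, r2 = _ols_fit(X[:, list(subset)], y)
        assert beta == pytest.approx([1.0, 2.0, -1.5], abs=1e-6)

    def test_full_model_equals_plain_ols(self):
        X, y = _planted(n=30, p=4, noise=0.1)
        subset, fitness, _ = ga_select(
            X, y, model_size=4, population=6, generations=5, seed=1
        )
        assert subset == (0, 1, 2, 3)
        assert fitness == pytest.approx(_ols_press_q2(X, y), abs=1e-12)

    def test_same_seed_same_model(self):
        X, y = _planted(p=10, noise=0.3)
        a = ga_select(X, y, model_size=3, generations=30, seed=7)
        b = ga_select(X, y, model_size=3, generations=30, seed=7)
        assert a[0] == b[0] and a[1] == b[1]

    def test_best_fitness_nondecreasing_elitism(self):
        X, y = _planted(p=10, noise=0.5)
        *_, trace = ga_select(X, y, model_size=3, generations=40, seed=2)
        assert np.all(np.diff(trace) >= 0)

    def test_matches_exhaustive_on_pool_of_15(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(25, 15))
        y = 0.5 + X[:, 2] - 2 * X[:, 8] + 0.5 * X[:, 12] \
            + rng.normal(0, 0.2, 25)
        subset, fitness, _ = ga_select(
            X, y, model_size=3, population=10, generations=200, seed=0
        )
        oracle_subset, oracle_fit = exhaustive_select(X, y, 3)
        assert subset == oracle_subset
        assert fitness == pytest.approx(oracle_fit, abs=1e-12)


class TestPressIdentity:
    def test_press_q2_equals_brute_force_loo(self):
        X, y = _planted(n=20, p=6, noise=0.4)
        subset = (0, 1, 3)
        Xs = X[:, list(subset)]
        press = 0.0
        for i in range(20):
            mask = np.arange(20) != i
            Z = np.column_stack([np.ones(19), Xs[mask]])
            beta, *_ = np.linalg.lstsq(Z, y[mask], rcond=None)
            zi = np.concatenate([[1.0], Xs[i]])
            press += (y[i] - zi @ beta) ** 2
        expected = 1 - press / np.sum((y - y.mean()) ** 2)
        assert subset_fitness(X, y, subset) == pytest.approx(
            expected, abs=1e-10
        )


class TestPredictMlr:
    REFERENCE = MLRModel(
        descriptors=["ATSC4p", "AATSC8m", "SpMin7_Bhp", "SpMin8_Bhi",
                     "topoShape"],
        coefficients={"ATSC4p": -0.2443, "AATSC8m": -0.0345,
                      "SpMin7_Bhp": -5.1954, "SpMin8_Bhi": 7.0601,
                      "topoShape": 1.2733},
        intercept=6.4712, r2=0.0, q2_loo=0.0,
    )

    def test_all_zero_returns_intercept(self):
        row = dict.fromkeys(self.REFERENCE.descriptors, 0.0)
        assert predict_mlr(self.REFERENCE, row) == 6.4712

    def test_single_descriptor_arithmetic(self):
        row = dict.fromkeys(self.REFERENCE.descriptors, 0.0)
        row["ATSC4p"] = 1.0
        assert predict_mlr(self.REFERENCE, row) == pytest.approx(6.2269)

    def test_missing_descriptor_rejected(self):
        with pytest.raises(KeyError):
            predict_mlr(self.REFERENCE, {"ATSC4p": 1.0})

    def test_json_round_trip(self):
        restored = MLRModel.from_json(self.REFERENCE.to_json())
        assert restored.coefficients == self.REFERENCE.coefficients
        assert restored.intercept == self.REFERENCE.intercept


class TestWilliamsAd:
    def test_centroid_has_minimal_leverage(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        X[0] = X[1:].mean(axis=0)  # row 0 sits exactly at the centroid
        y = X @ [1.0, 2.0, 3.0] + rng.normal(0, 0.1, 20)
        rows = williams_ad(X, y)
        levs = [r["leverage"] for r in rows]
        assert levs[0] == pytest.approx(1 / 20, abs=1e-12)
        assert min(levs) >= 1 / 20 - 1e-12

    def test_leverages_sum_to_k_plus_1(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        rows = williams_ad(X, y)
        assert sum(r["leverage"] for r in rows) == pytest.approx(5.0)

    def test_far_query_out_of_domain(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 2))
        y = X @ [1.0, -1.0] + rng.normal(0, 0.1, 20)
        query = np.array([[50.0, -50.0]])
        (row,) = williams_ad(X, y, query, np.array([100.0]))[20:]
        assert row["leverage"] > row["h_star"]
        assert not row["in_domain"]

    def test_residual_at_exactly_3_sigma_outside(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        y = X @ [1.0, 1.0] + rng.normal(0, 0.5, 30)
        Z = np.column_stack([np.ones(30), X])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        s = np.sqrt(np.sum((y - Z @ beta) ** 2) / (30 - 3))
        query = np.zeros((1, 2))
        y_query = np.array([beta[0] + 3.0 * s])  # residual exactly 3s
        (row,) = williams_ad(X, y, query, y_query)[30:]
        assert row["std_residual"] == pytest.approx(3.0)
        assert not row["in_domain"]


class TestEstimator:
    def test_fit_predict_on_synthetic_matrix(self):
        matrix, y, truth = synthetic_descriptor_matrix(
            n_molecules=30, n_descriptors=10, k_informative=2, seed=5
        )
        est = GAMLRRegressor(model_size=2, generations=40, random_state=0)
        est.fit(matrix, y)
        assert set(est.selected_) == set(truth["informative"])
        pred = est.predict(matrix)
        assert np.corrcoef(pred, y)[0, 1] ** 2 > 0.99
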