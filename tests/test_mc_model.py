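"""Correlation-weight model: splits, DCW, calibration, optimization."""

from collections import Counter

import numpy as np
import pytest

from cwqsar import (
    AttributeKey, AttributeProfile, CorrelationWeightRegressor, CWModel,
    MoleculeRecord, calibrate, dcw, make_splits, optimize, predict,
)
from cwqsar.mc_model import SplitDataset, block_rare, evaluate_r2


def _records(n, seed=0):
    rng = np.random.default_rng(seed)
    return [
        MoleculeRecord(str(i), "CC", float(rng.normal())) for i in range(n)
    ]


def _key(text, category="S"):
    return AttributeKey(text.ljust(12, "."), category)


def _profile(mol_id, counts):
    return AttributeProfile(mol_id, Counter(counts))


class TestMakeSplits:
    def test_75_25_of_33(self):
        for seed in range(5):
            sp = make_splits(_records(33), n_splits=1, seed=seed)[0]
            assert (len(sp.training), len(sp.test)) == (25, 8)

    def test_rounding_small(self):
        sp = make_splits(_records(4), n_splits=1, fraction=0.75, seed=1)[0]
        assert (len(sp.training), len(sp.test)) == (3, 1)

    def test_deterministic(self):
        a = make_splits(_records(20), n_splits=3, seed=5)
        b = make_splits(_records(20), n_splits=3, seed=5)
        for sa, sb in zip(a, b):
            assert [r.molecule_id for r in sa.training] == \
                [r.molecule_id for r in sb.training]

    def test_disjoint_and_balance_reported(self):
        sp = make_splits(_records(33), n_splits=1, seed=2)[0]
        train_ids = {r.molecule_id for r in sp.training}
        test_ids = {r.molecule_id for r in sp.test}
        assert not train_ids & test_ids
        assert {"train_mean", "test_mean", "mean_gap"} <= sp.balance.keys()

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            make_splits(_records(3), n_splits=1)


class TestDcwAndPredict:
    def test_empty_profile(self):
        model = CWModel(weights={}, threshold_T=1, n_epoch=1)
        assert dcw(_profile("m", {}), model) == 0.0

    def test_hand_sum_with_multiplicity(self):
        k1, k2 = _key("C"), _key("N")
        model = CWModel(weights={k1: 0.5, k2: -0.25}, threshold_T=1, n_epoch=1)
        assert dcw(_profile("m", {k1: 2, k2: 1}), model) == pytest.approx(0.75)

    def test_blocked_and_unknown_contribute_zero(self):
        k1, k2, k3 = _key("C"), _key("N"), _key("O")
        model = CWModel(
            weights={k1: 0.5, k2: 123.0}, threshold_T=2, n_epoch=1,
            blocked=frozenset([k2]),
        )
        prof = _profile("m", {k1: 1, k2: 5, k3: 7})
        assert dcw(prof, model) == pytest.approx(0.5)

    def test_dcw_additive_over_merged_profiles(self):
        k1, k2 = _key("C"), _key("N")
        model = CWModel(weights={k1: 0.3, k2: -0.8}, threshold_T=1, n_epoch=1)
        a = _profile("m", {k1: 2})
        b = _profile("m", {k1: 1, k2: 3})
        assert dcw(a.merge(b), model) == pytest.approx(
            dcw(a, model) + dcw(b, model)
        )

    def test_predict_is_calibration_line(self):
        k = _key("C")
        model = CWModel(weights={k: 2.0}, threshold_T=1, n_epoch=1,
                        intercept_C0=1.5, slope_C1=0.25)
        assert predict(model, _profile("m", {})) == pytest.approx(1.5)
        assert predict(model, _profile("m", {k: 2})) == pytest.approx(2.5)


class TestCalibrate:
    def test_exact_line(self):
        C0, C1, se0, se1 = calibrate([0.0, 1.0], [1.0, 3.0])
        assert (C0, C1) == (pytest.approx(1.0), pytest.approx(2.0))

    def test_recovers_truth_within_3_se(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 50)
        y = 2.0 + 0.5 * x + rng.normal(0, 0.3, 50)
        C0, C1, se0, se1 = calibrate(x, y)
        assert abs(C0 - 2.0) < 3 * se0
        assert abs(C1 - 0.5) < 3 * se1

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            calibrate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlockRare:
    def test_t1_blocks_nothing(self):
        profs = [_profile("a", {_key("C"): 1}), _profile("b", {_key("N"): 2})]
        assert block_rare(profs, 1) == frozenset()

    def test_counting_oracle(self):
        keys = [_key(t) for t in "CNOFS"]
        rng = np.random.default_rng(3)
        profs = [
            _profile(str(i), {k: 1 for k in keys if rng.random() < 0.5})
            for i in range(5)
        ]
        T = 2
        expected = {
            k for k in keys
            if sum(1 for p in profs if k in p.counts) < T
        }
        assert block_rare(profs, T) == expected


class TestOptimize:
    def test_trace_monotone_nondecreasing(self, trained_model):
        trace = np.array(trained_model.trace)
        assert np.all(np.diff(trace) >= 0)

    def test_reproducible_bit_identical(self, study_split):
        a = optimize(study_split, T=1, n_epoch=2, seed=9)
        b = optimize(study_split, T=1, n_epoch=2, seed=9)
        assert a.weights == b.weights
        assert (a.intercept_C0, a.slope_C1) == (b.intercept_C0, b.slope_C1)

    def test_runs_beat_scrambled_null(self, study_split, run_models):
        rng = np.random.default_rng(0)
        y = np.array([r.activity for r in study_split.training])
        scrambled_r2 = []
        for _ in range(3):
            sp = study_split.with_training_activities(rng.permutation(y))
            m = optimize(sp, T=1, n_epoch=8, seed=1)
            scrambled_r2.append(m.trace[-1])
        null_mean = np.mean(scrambled_r2)
        for model in run_models:
            assert model.trace[-1] > null_mean

    def test_blocked_key_weight_never_used(self, study_split):
        model = optimize(study_split, T=30, n_epoch=1, seed=0)
        # T above the training-set size blocks every rare key
        some_blocked = next(iter(model.blocked))
        from cwqsar.mc_model import profile_for

        rec = study_split.test[0]
        before = predict(model, profile_for(rec.smiles))
        model.weights[some_blocked] = 1e6
        after = predict(model, profile_for(rec.smiles))
        assert before == after


class TestSerialization:
    def test_json_round_trip_bit_exact(self, trained_model):
        restored = CWModel.from_json(trained_model.to_json())
        assert restored.weights == trained_model.weights
        assert restored.blocked == trained_model.blocked
        assert restored.intercept_C0 == trained_model.intercept_C0
        assert restored.slope_C1 == trained_model.slope_C1
        assert restored.threshold_T == trained_model.threshold_T


class TestEstimator:
    def test_sklearn_interface(self, congeneric_series):
        records, _ = congeneric_series
        X = [r.smiles for r in records]
        y = [r.activity for r in records]
        est = CorrelationWeightRegressor(n_epoch=3, random_state=0)
        assert est.get_params()["n_epoch"] == 3
        est.fit(X[:30], y[:30])
        pred = est.predict(X[30:])
        assert pred.shape == (len(X) - 30,)
        assert np.isfinite(pred).all()
        clone_params = est.get_params()
        est2 = CorrelationWeightRegressor(**clone_params).fit(X[:30], y[:30])
        assert est2.intercept_ == est.intercept_

    def test_unfitted_predict_raises(self):
        with pytest.raises(ValueError):
            CorrelationWeightRegressor().predict(["CC"])


def test_evaluate_r2_perfect_when_activity_linear_in_dcw(study_split):
    model = optimize(study_split, T=1, n_epoch=1, seed=0)
    from cwqsar.mc_model import profile_for

    recs = [
        MoleculeRecord(
            r.molecule_id, r.smiles,
            model.intercept_C0
            + model.slope_C1 * dcw(profile_for(r.smiles), model),
        )
        for r in study_split.test
    ]
    assert evaluate_r2(model, recs) == pytest.approx(1.0)
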