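import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import brute_force_stump, mcc_oracle, rank_oracle
from sevc.core import (
    ContingencyMatrix,
    EnsembleModel,
    accuracy,
    ensemble_predict,
    fit_ensemble,
    mc_cv,
    mcc,
    rank_by_importance,
    select_model_size,
    stump_vote,
    train_stump,
)
from sevc.features import FeatureMatrix, build_feature_matrix
from sevc.scales import AminoAcidScale, ScaleTable, random_scale


class TestTrainStump:
    def test_separable(self):
        st_ = train_stump([0.1, 0.2, 0.8, 0.9], [-1, -1, 1, 1])
        assert st_.threshold == pytest.approx(0.5)
        assert (st_.class_low, st_.class_high) == (-1, 1)
        assert (st_.prob_low, st_.prob_high) == (1.0, 1.0)
        assert st_.vote(0.0) == -1.0
        assert st_.vote(1.0) == 1.0

    def test_alternating_tie_breaks_to_smallest_threshold(self):
        # Candidate splits 1.5 / 2.5 / 3.5 carry weighted Gini 1/3, 1/2, 1/3;
        # the tie resolves to the smallest threshold 1.5 and the high leaf
        # votes +2/3 (enumerated by hand and checked by the brute-force
        # oracle below).
        st_ = train_stump([1, 2, 3, 4], [-1, 1, -1, 1])
        assert st_.threshold == pytest.approx(1.5)
        assert st_.class_high == 1
        assert st_.vote(3.0) == pytest.approx(2.0 / 3.0)

    def test_single_class_degenerate(self):
        st_ = train_stump([1.0, 2.0, 3.0], [1, 1, 1])
        assert st_.threshold == float("-inf")
        assert st_.class_low == st_.class_high == 1
        assert st_.prob_low == st_.prob_high == 1.0

    def test_constant_feature_degenerate(self):
        st_ = train_stump([2.0, 2.0, 2.0, 2.0], [1, -1, 1, -1])
        assert st_.threshold == float("-inf")
        assert st_.class_low == -1  # majority tie -> insoluble

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 13))
            feats = np.round(rng.normal(size=n), 2)  # rounding provokes ties
            labels = rng.choice([-1, 1], size=n)
            got = train_stump(feats, labels)
            thr, cl, ch, pl, ph = brute_force_stump(feats.tolist(), labels.tolist())
            assert got.threshold == pytest.approx(thr)
            assert (got.class_low, got.class_high) == (cl, ch)
            assert got.prob_low == pytest.approx(pl)
            assert got.prob_high == pytest.approx(ph)


class TestStumpVote:
    def test_magnitude_is_probability(self):
        st_ = train_stump([0, 1, 2, 3, 4, 5], [-1, -1, -1, 1, -1, 1])
        assert stump_vote(st_, 5.0) == pytest.approx(2.0 / 3.0)

    def test_boundary_goes_low(self):
        st_ = train_stump([0.0, 1.0], [-1, 1])
        assert stump_vote(st_, st_.threshold) == -1.0
        assert stump_vote(st_, st_.threshold + 1e-9) == 1.0


class TestMetrics:
    def test_perfect(self):
        assert mcc(ContingencyMatrix(5, 5, 0, 0)) == pytest.approx(1.0)
        assert accuracy(ContingencyMatrix(5, 5, 0, 0)) == pytest.approx(1.0)

    def test_random(self):
        assert mcc(ContingencyMatrix(3, 3, 3, 3)) == pytest.approx(0.0)
        assert accuracy(ContingencyMatrix(1, 1, 1, 1)) == pytest.approx(0.5)

    def test_worked_example(self):
        # 10 / sqrt(600), from the oracle's direct arithmetic.
        c = ContingencyMatrix(tp=4, tn=3, fp=1, fn=2)
        assert mcc(c) == pytest.approx(mcc_oracle(4, 3, 1, 2))
        assert mcc(c) == pytest.approx(10.0 / np.sqrt(600.0))

    def test_zero_denominator_convention(self):
        assert mcc(ContingencyMatrix(0, 3, 0, 2)) == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mcc(ContingencyMatrix(0, 0, 0, 0))
        with pytest.raises(ValueError):
            accuracy(ContingencyMatrix(0, 0, 0, 0))

    @settings(max_examples=100, deadline=None)
    @given(*(st.integers(min_value=0, max_value=30) for _ in range(4)))
    def test_matches_oracle_and_symmetry(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        c = ContingencyMatrix(tp, tn, fp, fn)
        assert mcc(c) == pytest.approx(mcc_oracle(tp, tn, fp, fn))
        swapped = ContingencyMatrix(tn, tp, fn, fp)  # class-label swap
        assert mcc(c) == pytest.approx(mcc(swapped))
        assert accuracy(c) + (fp + fn) / c.total == pytest.approx(1.0)


def _fm(values, names=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    names = names or [f"s{j}" for j in range(values.shape[1])]
    return FeatureMatrix(values, [f"c{i}" for i in range(values.shape[0])], names)


class TestEnsemblePredict:
    def _model(self, votes):
        # Constant stumps: both leaves vote sign(v) with probability |v|.
        from sevc.core import DecisionStump

        stumps = [
            DecisionStump(f"s{j}", -1e9, 1 if v >= 0 else -1, 1 if v >= 0 else -1,
                          abs(v), abs(v))
            for j, v in enumerate(votes)
        ]
        return EnsembleModel(stumps, len(stumps))

    def test_mean_vote(self):
        model = self._model([0.9, -0.5])
        p, cls = ensemble_predict(model, _fm([[0.0, 0.0]]))
        assert p[0] == pytest.approx(0.2)
        assert cls[0] == 1

    def test_zero_is_insoluble(self):
        model = self._model([0.5, -0.5])
        p, cls = ensemble_predict(model, _fm([[0.0, 0.0]]))
        assert p[0] == pytest.approx(0.0)
        assert cls[0] == -1

    def test_modifier_offset(self):
        model = self._model([0.6, 1e-12])  # raw p ~= 0.3
        model.modifier = {"H": -0.5}
        p, cls = ensemble_predict(model, _fm([[0.0, 0.0]]), strategy_ids=["H"])
        assert p[0] == pytest.approx(-0.2)
        assert cls[0] == -1

    def test_missing_column_raises(self):
        model = self._model([0.9])
        with pytest.raises(KeyError):
            ensemble_predict(model, _fm([[0.0]], names=["other"]))

    def test_duplicate_scale_does_not_change_p(self, rng):
        feats = rng.normal(size=(30, 1))
        labels = np.where(feats[:, 0] + rng.normal(0, 0.3, 30) > 0, 1, -1)
        st_ = train_stump(feats[:, 0], labels, scale_name="s0")
        dup = st_.__class__("s1", st_.threshold, st_.class_low, st_.class_high,
                            st_.prob_low, st_.prob_high)
        one = EnsembleModel([st_], 1)
        two = EnsembleModel([st_, dup], 2)
        fm2 = _fm(np.column_stack([feats, feats]))
        p1, _ = ensemble_predict(one, fm2)
        p2, _ = ensemble_predict(two, fm2)
        assert np.allclose(p1, p2)


class TestRankByImportance:
    def test_perfect_scale_first(self, rng):
        sep = np.concatenate([-np.abs(rng.normal(size=10)) - 1, np.abs(rng.normal(size=10)) + 1])
        noise = rng.normal(size=20)
        labels = np.array([-1] * 10 + [1] * 10)
        ranking = rank_by_importance(_fm(np.column_stack([noise, sep]), ["junk", "sep"]), labels)
        assert ranking[0][0] == "sep"
        assert ranking[0][1] == pytest.approx(1.0)

    def test_sign_flip_invariance(self, rng):
        feats = rng.normal(size=(40, 3))
        labels = np.where(feats[:, 0] + 0.5 * rng.normal(size=40) > 0, 1, -1)
        base = rank_by_importance(_fm(feats), labels)
        flipped = rank_by_importance(_fm(feats * np.array([1, -1, 1])), labels)
        assert [n for n, _ in base] == [n for n, _ in flipped]
        assert np.allclose([m for _, m in base], [m for _, m in flipped])

    def test_matches_brute_force_sort(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 12))
            k = int(rng.integers(1, 5))
            feats = np.round(rng.normal(size=(n, k)), 1)
            labels = rng.choice([-1, 1], size=n)
            names = [f"s{j}" for j in range(k)]
            got = rank_by_importance(_fm(feats, names), labels)
            expected = rank_oracle(feats, labels.tolist(), names)
            assert [n_ for n_, _ in got] == [n_ for n_, _ in expected]
            assert np.allclose([m for _, m in got], [m for _, m in expected])


class TestMcCv:
    def test_split_sizes_and_determinism(self, split_dataset, small_panel):
        table, fm = small_panel
        labels = split_dataset["train_labels"]
        res = mc_cv(fm, labels, n_runs=5, seed=3)
        assert res.val_indices.shape == (5, 192)
        res2 = mc_cv(fm, labels, n_runs=5, seed=3)
        assert np.array_equal(res.mcc, res2.mcc)
        assert np.array_equal(res.val_indices, res2.val_indices)

    def test_generating_scale_dominates(self, split_dataset, small_panel):
        # Simulation oracle: with the generating scale in the table and
        # moderate noise, the single-stump model's median validation MCC
        # is high.
        table, fm = small_panel
        res = mc_cv(fm, split_dataset["train_labels"], n_runs=25, seed=4)
        assert res.median_mcc()[0] >= 0.7

    def test_separable_single_stump(self, rng):
        feats = rng.normal(size=(80, 2))
        labels = np.where(feats[:, 0] > 0, 1, -1)
        res = mc_cv(_fm(feats), labels, n_runs=25, seed=5)
        assert res.median_mcc()[0] >= 0.9

    def test_null_scale_near_zero(self, rng):
        feats = rng.normal(size=(100, 1))
        labels = rng.choice([-1, 1], size=100)
        res = mc_cv(_fm(feats), labels, n_runs=200, seed=6)
        assert abs(res.median_mcc()[0]) <= 0.1

    def test_p_bounded(self, split_dataset, small_panel):
        _, fm = small_panel
        res = mc_cv(fm, split_dataset["train_labels"], n_runs=3, seed=7,
                    keep_continuous=True)
        assert np.all(np.abs(res.continuous) <= 1.0 + 1e-6)

    def test_requested_sizes_only(self, split_dataset, small_panel):
        _, fm = small_panel
        res = mc_cv(fm, split_dataset["train_labels"], n_runs=2, seed=8, model_sizes=[2, 4])
        assert res.model_sizes.tolist() == [2, 4]
        assert res.mcc.shape == (2, 2)


class TestSelectModelSize:
    def _result(self, medians):
        medians = np.asarray(medians, dtype=float)
        from sevc.core import MCCVResult

        return MCCVResult(
            model_sizes=np.arange(1, medians.size + 1),
            mcc=medians[None, :],
            accuracy=medians[None, :],
            val_indices=np.zeros((1, 0), dtype=np.int64),
        )

    def test_argmax(self):
        assert select_model_size(self._result([0.2, 0.6, 0.5])) == 2

    def test_tie_smallest(self):
        assert select_model_size(self._result([0.6, 0.6])) == 1

    def test_single(self):
        assert select_model_size(self._result([0.3])) == 1


class TestFitEnsemble:
    def test_round_trip_json(self, tmp_path, rng):
        feats = rng.normal(size=(30, 3))
        labels = np.where(feats[:, 1] > 0, 1, -1)
        model = fit_ensemble(_fm(feats), labels, modifier={"A": 0.01})
        path = tmp_path / "model.json"
        model.to_json(path)
        back = EnsembleModel.from_json(path)
        assert back.stumps == model.stumps
        assert back.n_included == model.n_included
        assert back.modifier == {"A": 0.01}
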