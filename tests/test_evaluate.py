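"""Split construction, leakage checks, night aggregation, scoring, and the
repeated protocol."""

import numpy as np
import pytest

from migrasleep import (ExperimentConfig, SplitError, ValidationError,
                        aggregate_night_predictions, balanced_accuracy,
                        build_comparison_matrix, make_loso_split,
                        make_personal_split, run_repeated_experiment)
from migrasleep.augment import (MIGRAINE_COMPARISON, NON_MIGRAINE_COMPARISON,
                                ComparisonObservation)
from migrasleep.evaluate import check_leakage, flatten_by_subject

from conftest import make_night_set


def _subject_obs(rng, n_mig=17, n_non=12, subject="S1", seed=0):
    return build_comparison_matrix(
        make_night_set(rng, n_mig, n_non, subject_id=subject), seed)


class TestPersonalSplit:
    def test_subject1_shaped_test_set_sizes(self):
        """17 migraine / 12 non-migraine nights: the test set holds
        2 x 12 = 24 migraine comparisons and round(0.2 x 66) = 13
        non-migraine comparisons."""
        rng = np.random.default_rng(0)
        obs = _subject_obs(rng)
        plan = make_personal_split(obs, seed=1)
        labels = [obs[i].label for i in plan.test_indices]
        assert labels.count(MIGRAINE_COMPARISON) == 24
        assert labels.count(NON_MIGRAINE_COMPARISON) == 13
        assert len(plan.test_migraine_night_ids) == 2

    def test_no_test_migraine_night_leaks_into_folds(self):
        rng = np.random.default_rng(1)
        for trial in range(100):
            obs = _subject_obs(rng, n_mig=5, n_non=8, seed=trial)
            plan = make_personal_split(obs, seed=trial)
            check_leakage(obs, plan)  # raises SplitError on violation
            outside = np.concatenate(plan.folds)
            for i in outside:
                if obs[i].label == MIGRAINE_COMPARISON:
                    assert obs[i].left_night_id not in plan.test_migraine_night_ids

    def test_fold_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(2)
        obs = _subject_obs(rng)
        plan = make_personal_split(obs, seed=3)
        sizes = [len(f) for f in plan.folds]
        assert len(plan.folds) == 5
        assert max(sizes) - min(sizes) <= 1

    def test_folds_and_test_partition_everything(self):
        rng = np.random.default_rng(3)
        obs = _subject_obs(rng, 6, 9)
        plan = make_personal_split(obs, seed=4)
        combined = np.sort(np.concatenate([plan.test_indices, *plan.folds]))
        assert np.array_equal(combined, np.arange(len(obs)))

    def test_too_few_migraine_nights_names_deficit(self):
        rng = np.random.default_rng(4)
        obs = _subject_obs(rng, n_mig=2, n_non=8)
        with pytest.raises(SplitError, match="migraine nights"):
            make_personal_split(obs, seed=0)


class TestLosoSplit:
    def _cohort(self, rng, n_subjects=4):
        return {f"S{i}": _subject_obs(rng, 5, 8, subject=f"S{i}", seed=i)
                for i in range(n_subjects)}

    def test_each_subject_held_out_once(self):
        rng = np.random.default_rng(5)
        cohort = self._cohort(rng)
        flat = flatten_by_subject(cohort)
        for s in cohort:
            plan = make_loso_split(cohort, s, seed=1)
            held = {flat[i].subject_id for i in plan.test_indices}
            assert held == {s}
            for fold in plan.folds:
                assert all(flat[i].subject_id != s for i in fold)

    def test_union_of_train_and_test_is_everything(self):
        rng = np.random.default_rng(6)
        cohort = self._cohort(rng)
        plan = make_loso_split(cohort, "S2", seed=2)
        n_total = sum(len(v) for v in cohort.values())
        combined = np.sort(np.concatenate([plan.test_indices, *plan.folds]))
        assert np.array_equal(combined, np.arange(n_total))

    def test_unknown_subject_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValidationError):
            make_loso_split(self._cohort(rng), "S99")


def _obs(label, left, right, sign=1):
    return ComparisonObservation(np.zeros(110), label, left, right, sign)


class TestNightAggregation:
    def test_majority_vote(self):
        preds = [(_obs(MIGRAINE_COMPARISON, "m1", "n1"), MIGRAINE_COMPARISON),
                 (_obs(MIGRAINE_COMPARISON, "m1", "n2"), MIGRAINE_COMPARISON),
                 (_obs(MIGRAINE_COMPARISON, "m1", "n3"), NON_MIGRAINE_COMPARISON)]
        assert aggregate_night_predictions(preds)["m1"] == "pre_migraine"

    def test_tie_favors_migraine_alert(self):
        preds = [(_obs(MIGRAINE_COMPARISON, "m1", "n1"), MIGRAINE_COMPARISON),
                 (_obs(MIGRAINE_COMPARISON, "m1", "n2"), NON_MIGRAINE_COMPARISON)]
        assert aggregate_night_predictions(preds)["m1"] == "pre_migraine"

    def test_non_migraine_comparison_votes_on_both_nights(self):
        preds = [(_obs(NON_MIGRAINE_COMPARISON, "n1", "n2"),
                  NON_MIGRAINE_COMPARISON)]
        out = aggregate_night_predictions(preds)
        assert out == {"n1": "non_migraine", "n2": "non_migraine"}

    def test_night_without_votes_is_absent(self):
        preds = [(_obs(MIGRAINE_COMPARISON, "m1", "n1"), MIGRAINE_COMPARISON)]
        out = aggregate_night_predictions(preds)
        assert "n1" not in out  # the right night of a migraine comparison
        assert set(out) == {"m1"}

    def test_empty_predictions_empty_output(self):
        assert aggregate_night_predictions([]) == {}


class TestBalancedAccuracy:
    def test_all_correct_is_one(self):
        t = ["pre_migraine", "non_migraine"]
        assert balanced_accuracy(t, t)[0] == 1.0

    def test_one_class_fully_wrong_is_half(self):
        truth = ["pre_migraine", "pre_migraine", "non_migraine", "non_migraine"]
        pred = ["non_migraine", "non_migraine", "non_migraine", "non_migraine"]
        bacc, sens, spec = balanced_accuracy(truth, pred)
        assert bacc == 0.5
        assert sens == 1.0   # non-migraine fully recognized
        assert spec == 0.0   # migraine nights all missed

    def test_mean_of_class_rates(self):
        truth = ["pre_migraine"] * 5 + ["non_migraine"] * 5
        pred = (["pre_migraine"] * 3 + ["non_migraine"] * 2
                + ["non_migraine"] * 4 + ["pre_migraine"])
        bacc, sens, spec = balanced_accuracy(truth, pred)
        assert spec == pytest.approx(0.6)
        assert sens == pytest.approx(0.8)
        assert bacc == pytest.approx(0.7)

    def test_missing_class_in_truth_is_error(self):
        with pytest.raises(ValidationError):
            balanced_accuracy(["non_migraine"] * 3, ["non_migraine"] * 3)


class TestRepeatedExperiment:
    def _cohort_vectors(self, effect=3.0, n_subj=2):
        rng = np.random.default_rng(11)
        vecs = []
        for i in range(n_subj):
            vecs.extend(make_night_set(rng, 6, 10, subject_id=f"S{i}",
                                       shift=effect))
        return vecs

    def test_default_config_runs_twenty_repetitions(self):
        cfg = ExperimentConfig()
        assert cfg.n_repetitions == 20

    def test_identical_seed_identical_report(self):
        vecs = self._cohort_vectors()
        cfg = ExperimentConfig(n_repetitions=2)
        a = run_repeated_experiment(vecs, cfg, seed=5)
        b = run_repeated_experiment(vecs, cfg, seed=5)
        assert a.records.equals(b.records)

    def test_strong_effect_reaches_high_personal_accuracy(self):
        vecs = self._cohort_vectors(effect=4.0)
        rep = run_repeated_experiment(
            vecs, ExperimentConfig(n_repetitions=4), seed=6)
        assert rep.mean_balanced_accuracy >= 0.85

    def test_subject_with_too_few_migraine_nights_recorded_not_evaluable(self):
        rng = np.random.default_rng(12)
        vecs = make_night_set(rng, 2, 10, subject_id="Sfew")  # below minimum
        vecs += self._cohort_vectors(n_subj=1)
        rep = run_repeated_experiment(
            vecs, ExperimentConfig(n_repetitions=2), seed=7)
        s0 = rep.records[rep.records.subject_id == "Sfew"]
        assert s0.balanced_accuracy.isna().all()
        other = rep.records[rep.records.subject_id != "Sfew"]
        assert other.balanced_accuracy.notna().all()

    def test_aggregate_has_per_subject_and_overall_rows(self):
        vecs = self._cohort_vectors()
        rep = run_repeated_experiment(
            vecs, ExperimentConfig(n_repetitions=2), seed=8)
        agg = rep.aggregate()
        assert set(agg.index) == {"S0", "S1", "overall"}
        assert (agg["balanced_accuracy_mean"] <= 1.0).all()
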