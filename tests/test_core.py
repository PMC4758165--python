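import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import xmittn as x
from xmittn.cohort import Diagnosis, EXP1_FEATURES, Experiment
from xmittn.core import GiniDistribution, SplitPlan, _fold_seed
from xmittn.exceptions import ConfigurationError, UndefinedGiniError
from conftest import make_subject


def gini_pair_counting(labels, scores):
    """Independent oracle: enumerate every positive-negative pair."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    auroc = wins / (len(pos) * len(neg))
    return 2.0 * auroc - 1.0


class TestGini:
    @pytest.mark.parametrize(
        "labels, scores, expected",
        [
            ((1, 1, 0, 0), (0.9, 0.8, 0.3, 0.1), 1.0),   # perfect ranking
            ((1, 1, 0, 0), (0.5, 0.5, 0.5, 0.5), 0.0),   # all tied = chance
            ((1, 1, 0, 0), (0.2, 0.9, 0.8, 0.1), 0.5),   # 3 of 4 pairs ordered
            ((0, 0, 1, 1), (0.9, 0.8, 0.3, 0.1), -1.0),  # perfectly reversed
        ],
    )
    def test_worked_examples(self, labels, scores, expected):
        assert x.compute_gini(labels, scores) == pytest.approx(expected)

    def test_matches_pair_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n = rng.integers(4, 31)
            labels = np.zeros(n, dtype=int)
            labels[: rng.integers(1, n)] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
            assert abs(
                x.compute_gini(labels, scores) - gini_pair_counting(labels, scores)
            ) < 1e-12

    @pytest.mark.parametrize("transform", [np.exp, np.arctan, lambda s: 3 * s + 1])
    def test_invariant_under_strictly_increasing_transforms(self, transform):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        scores = rng.normal(size=40)
        assert x.compute_gini(labels, transform(scores)) == pytest.approx(
            x.compute_gini(labels, scores), abs=1e-12
        )

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedGiniError):
            x.compute_gini([1, 1, 1], [0.1, 0.2, 0.3])


class TestStage3:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ((0.1, 0.2, 0.3, 0.4), 0.0),
            ((-0.1, 0.0, 0.2, 0.3), 0.5),      # two of four at or below 0
            ((-0.5, -0.1, -0.2), 1.0),
        ],
    )
    def test_count_rule(self, values, expected):
        assert x.stage3_pvalue(values) == pytest.approx(expected)

    def test_missing_folds_excluded_from_denominator(self):
        assert x.stage3_pvalue([np.nan, -0.1, 0.2]) == pytest.approx(0.5)

    @given(st.lists(st.floats(-1, 1), min_size=1, max_size=50),
           st.floats(0.0, 0.5))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_uniform_shifts(self, values, shift):
        up = [v + shift for v in values]
        assert x.stage3_pvalue(up) <= x.stage3_pvalue(values)

    def test_empty_vector_is_error(self):
        with pytest.raises(ValueError):
            x.stage3_pvalue([])


class TestSplits:
    def _labels(self):
        return np.array([0] * 135 + [1] * 95)

    def test_sizes_disjointness_and_stratification(self):
        plan = x.make_splits(self._labels(), SplitPlan(n_folds=25, master_seed=3))
        assert len(plan.train_indices) == 25
        labels = self._labels()
        for tr, cv in zip(plan.train_indices, plan.cv_indices):
            assert len(tr) == 180 and len(cv) == 50
            assert len(np.intersect1d(tr, cv)) == 0
            # 135:95 class ratio preserved to integer rounding
            assert (labels[tr] == 0).sum() == 106
            assert (labels[cv] == 0).sum() == 29

    def test_same_seed_reproduces_identical_folds(self):
        p1 = x.make_splits(self._labels(), SplitPlan(n_folds=10, master_seed=9))
        p2 = x.make_splits(self._labels(), SplitPlan(n_folds=10, master_seed=9))
        for a, b in zip(p1.train_indices, p2.train_indices):
            np.testing.assert_array_equal(a, b)

    def test_exhaustive_boundary_uses_every_subject(self):
        labels = np.array([0] * 12 + [1] * 8)
        plan = x.make_splits(labels, SplitPlan(n_folds=5, train_size=15, cv_size=5))
        for tr, cv in zip(plan.train_indices, plan.cv_indices):
            assert len(np.union1d(tr, cv)) == 20

    def test_oversized_plan_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            x.make_splits(np.array([0, 1] * 10), SplitPlan(train_size=18, cv_size=5))

    def test_fold_seeds_distinct_and_below_2_31(self):
        seeds = {_fold_seed(0, f, a) for f in range(50) for a in ("svm", "knn")}
        assert len(seeds) == 100
        assert all(0 <= s < 2**31 for s in seeds)


class TestSelection:
    def _dist(self, p_target, n=1000):
        values = np.full(n, 0.5)
        values[: int(round(p_target * n))] = -0.5
        return GiniDistribution("svm", Experiment.EXP2, values)

    def test_strict_threshold_and_table_pattern(self):
        results = {
            ("random_forest", Experiment.EXP2): self._dist(0.043),
            ("svm", Experiment.EXP2): self._dist(0.033),
            ("logistic", Experiment.EXP1): self._dist(0.510),
            ("knn", Experiment.EXP2): self._dist(0.069),
        }
        selected = x.select_models(results, alpha=0.05)
        assert set(selected) == {("random_forest", Experiment.EXP2),
                                 ("svm", Experiment.EXP2)}

    def test_p_exactly_alpha_not_selected(self):
        results = {("svm", Experiment.EXP1): self._dist(0.05, n=20)}
        assert results[("svm", Experiment.EXP1)].p_value == pytest.approx(0.05)
        assert x.select_models(results, alpha=0.05) == []

    def test_all_null_gives_empty_selection(self):
        results = {("svm", Experiment.EXP1): self._dist(0.5)}
        assert x.select_models(results) == []


# ---------------------------------------------------------------------------
# Stage 4
# ---------------------------------------------------------------------------

class _TtauModel:
    """Duck-typed frozen model scoring by the t-Tau column alone."""

    algorithm = "stub"
    feature_names_ = EXP1_FEATURES
    threshold_ = 0.5

    def __init__(self, threshold=200.0, constant=None):
        self._thr = threshold
        self._constant = constant

    def predict_score(self, X, feature_names=None):
        X = np.asarray(X, dtype=float)
        if self._constant is not None:
            return np.full(len(X), self._constant)
        return X[:, 4]

    def predict(self, X, feature_names=None):
        X = np.asarray(X, dtype=float)
        if self._constant is not None:
            return np.ones(len(X), dtype=int)  # everything called AD
        return (X[:, 4] >= self._thr).astype(int)


def _two_class_cohort(n_mci=4, n_ad=4):
    subjects = [
        make_subject(f"m{i}", Diagnosis.MCI_AD, ttau=100.0 + i, abeta42=100.0)
        for i in range(n_mci)
    ] + [
        make_subject(f"a{i}", Diagnosis.AD, ttau=300.0 + i, abeta42=100.0)
        for i in range(n_ad)
    ]
    return x.Cohort("boot", subjects)


class TestBootstrapValidation:
    def test_oracle_model_hits_closed_form_metrics(self):
        result = x.bootstrap_validate(
            _TtauModel(), _two_class_cohort(), n_boot=200, per_class=10,
            master_seed=0, experiment="EXP1",
        )
        assert result.sensitivity == 1.0
        assert result.specificity == 1.0
        assert result.accuracy == 1.0
        assert result.p_value == 0.0
        assert (result.gini_values == 1.0).all()

    def test_all_ad_model_hits_closed_form_metrics(self):
        result = x.bootstrap_validate(
            _TtauModel(constant=0.7), _two_class_cohort(), n_boot=200,
            per_class=10, master_seed=0, experiment="EXP1",
        )
        assert result.sensitivity == 1.0
        assert result.specificity == 0.0
        assert result.accuracy == 0.5
        assert result.p_value == 1.0           # every replicate Gini is 0
        assert (result.gini_values == 0.0).all()

    def test_per_subject_tallies_match_binomial_expectation(self):
        n_boot = 1500
        result = x.bootstrap_validate(
            _TtauModel(constant=0.7), _two_class_cohort(n_mci=2, n_ad=2),
            n_boot=n_boot, per_class=2, master_seed=1, experiment="EXP1",
        )
        # per replicate each subject's sampling count is Binomial(2, 1/2):
        # mean 1, var 1/2 -> total sd = sqrt(n_boot / 2) ~ 27
        sd = np.sqrt(n_boot / 2)
        assert np.all(np.abs(result.times_sampled - n_boot) < 5 * sd)
        # the all-AD model labels every draw AD
        np.testing.assert_array_equal(result.times_labeled_ad, result.times_sampled)
        assert result.times_sampled.sum() == 4 * n_boot

    def test_missing_class_is_error(self):
        cohort = x.Cohort("one", [make_subject("a", Diagnosis.AD)])
        with pytest.raises(ValueError, match="both classes"):
            x.bootstrap_validate(_TtauModel(), cohort, n_boot=5, per_class=2,
                                 experiment="EXP1")


# ---------------------------------------------------------------------------
# Training stage behaviour
# ---------------------------------------------------------------------------

def _permute_stage_labels(cohort, rng):
    """Shuffle MCI-AD/AD diagnoses across clinical subjects, keeping counts."""
    clinical = cohort.by_diagnosis(Diagnosis.MCI_AD, Diagnosis.AD)
    labels = [s.diagnosis for s in clinical]
    rng.shuffle(labels)
    relabeled = {
        s.subject_id: dataclasses.replace(s, diagnosis=d)
        for s, d in zip(clinical, labels)
    }
    subjects = [relabeled.get(s.subject_id, s) for s in cohort.subjects]
    return x.Cohort(cohort.cohort_id, subjects)


class TestTrainingStage:
    def test_strong_signal_detected_and_null_boundary_folds(self, adni_like_cohort):
        # staged pair: stage signal confined to C3/FH
        train, _ = x.generate_staged_pair(c3_shift=-1.5, fh_shift=-1.5,
                                          master_seed=2)
        train = x.normalize_c3(train)
        plan = SplitPlan(n_folds=30, master_seed=2)
        results = x.run_training_stage(train, plan, algorithms=["svm"])
        assert results[("svm", Experiment.EXP2)].p_value < 0.05
        assert results[("svm", Experiment.EXP2)].n_folds == 30

    def test_single_fold_distribution(self, adni_like_cohort):
        plan = SplitPlan(n_folds=1, master_seed=0)
        results = x.run_training_stage(adni_like_cohort, plan,
                                       algorithms=["logistic"],
                                       experiments=["EXP1"])
        dist = results[("logistic", Experiment.EXP1)]
        assert dist.n_folds == 1
        assert dist.p_value in (0.0, 1.0)

    def test_same_splits_shared_across_algorithms_and_experiments(self,
                                                                  adni_like_cohort):
        plan = x.make_splits(
            x.build_feature_matrix(adni_like_cohort, "EXP2").labels,
            SplitPlan(n_folds=3, master_seed=4),
        )
        results = x.run_training_stage(adni_like_cohort, plan,
                                       algorithms=["knn", "naive_bayes"])
        lengths = {d.n_folds for d in results.values()}
        assert lengths == {3}
        assert len(results) == 4  # 2 algorithms x 2 experiments

    def test_label_permutation_destroys_significance(self):
        train, _ = x.generate_staged_pair(c3_shift=-1.0, fh_shift=-1.0,
                                          master_seed=6)
        rng = np.random.default_rng(6)
        algorithms = ["logistic", "svm", "naive_bayes"]
        sig_counts = {(a, e): 0 for a in algorithms for e in Experiment}
        n_reps = 5
        for rep in range(n_reps):
            permuted = x.normalize_c3(_permute_stage_labels(train, rng))
            plan = SplitPlan(n_folds=100, master_seed=rep)
            results = x.run_training_stage(permuted, plan, algorithms=algorithms)
            for key, dist in results.items():
                sig_counts[key] += dist.p_value < 0.05
        assert all(count <= 1 for count in sig_counts.values()), sig_counts


def test_freeze_final_model_uses_all_subjects(adni_like_cohort):
    model = x.freeze_final_model(adni_like_cohort, "svm", "EXP2", random_state=1)
    assert model.feature_names_ == ("age", "sex_male", "apoe4", "abeta42",
                                    "ttau", "ptau181", "c3_z", "fh")
    matrix = x.build_feature_matrix(adni_like_cohort, "EXP2")
    assert len(model.predict_score(matrix)) == 230


def test_report_table_shape_and_blank_test_cells(adni_like_cohort):
    plan = SplitPlan(n_folds=2, master_seed=0)
    results = x.run_training_stage(adni_like_cohort, plan,
                                   algorithms=["logistic", "svm"])
    table = x.report_table2(results)
    assert table.shape[0] == 9                       # one row per algorithm
    assert {"p_exp1_train", "p_exp2_train", "p_exp1_test",
            "p_exp2_test"} <= set(table.columns)
    assert table["p_exp1_test"].isna().all()         # nothing validated yet
    assert np.isnan(table.loc["K-Nearest Neighbor", "p_exp1_train"])
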