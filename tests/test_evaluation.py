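import json

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

import sepselect as ss
from sepselect.errors import DomainError
from sepselect.io_expression import ClassMap, ExpressionMatrix


def matrix_with_counts(counts, seed=0):
    rng = np.random.default_rng(seed)
    names = tuple(f"C{i + 1}" for i in range(len(counts)))
    labels = np.concatenate([np.repeat(n, c) for n, c in zip(names, counts)])
    n = labels.size
    return ExpressionMatrix(
        values=rng.normal(size=(n, 4)),
        sample_ids=[f"s{i}" for i in range(n)],
        gene_ids=["g1", "g2", "g3", "g4"],
        labels=labels.astype(object),
        class_map=ClassMap(names),
    )


class TestMakeSplit:
    def test_60_40_arithmetic(self):
        m = matrix_with_counts([5, 5])
        plan = ss.make_split(m, train_fraction=0.6, seed=0)
        assert len(plan.train_indices) == 6
        assert len(plan.test_indices) == 4

    def test_study_counts_stratified_within_one_sample(self):
        m = matrix_with_counts([8, 10, 26, 10, 10])
        plan = ss.make_split(m, train_fraction=0.6, seed=1)
        labels = m.labels
        for name, count in m.class_counts().items():
            in_train = sum(labels[i] == name for i in plan.train_indices)
            assert abs(in_train - 0.6 * count) <= 1.0

    def test_partition_covers_all_samples_exactly_once(self):
        m = matrix_with_counts([8, 10, 26, 10, 10])
        plan = ss.make_split(m, seed=3)
        combined = sorted(plan.train_indices + plan.test_indices)
        assert combined == list(range(m.n_samples))

    def test_same_seed_identical_plans(self):
        m = matrix_with_counts([6, 6, 6])
        assert ss.make_split(m, seed=5) == ss.make_split(m, seed=5)
        assert ss.make_split(m, seed=5) != ss.make_split(m, seed=6)

    def test_singleton_class_under_stratification_names_class(self):
        m = matrix_with_counts([1, 5])
        with pytest.raises(DomainError, match="C1"):
            ss.make_split(m, stratified=True)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2])
    def test_train_fraction_domain(self, frac):
        m = matrix_with_counts([4, 4])
        with pytest.raises(DomainError):
            ss.make_split(m, train_fraction=frac)


class TestKFold:
    def test_five_folds_of_two(self):
        m = matrix_with_counts([5, 5])
        plan = ss.kfold(m, n_folds=5, seed=0)
        assert len(plan.folds) == 5
        assert all(len(f) == 2 for f in plan.folds)

    def test_folds_partition_all_indices(self):
        m = matrix_with_counts([8, 10, 26, 10, 10])
        plan = ss.kfold(m, n_folds=5, seed=2)
        seen = sorted(i for f in plan.folds for i in f)
        assert seen == list(range(m.n_samples))
        sizes = sorted(len(f) for f in plan.folds)
        assert sizes[-1] - sizes[0] <= 1

    def test_leave_one_out_boundary(self):
        m = matrix_with_counts([5, 5])
        plan = ss.kfold(m, n_folds=10, seed=0, stratified=False)
        assert all(len(f) == 1 for f in plan.folds)

    def test_class_smaller_than_fold_count_rejected(self):
        m = matrix_with_counts([3, 10])
        with pytest.raises(DomainError, match="C1"):
            ss.kfold(m, n_folds=5)


class TestEvaluate:
    two = ClassMap(("pos", "neg"))

    def test_perfect_prediction_all_metrics_one(self):
        truth = ["pos", "neg", "pos", "neg"]
        rep = ss.evaluate(truth, truth, self.two)
        assert rep.accuracy == rep.precision == rep.recall == rep.f1 == 1.0

    def test_hand_worked_binary_confusion(self):
        # confusion [[3,1],[2,4]]: 3 true pos predicted pos, 1 pos->neg,
        # 2 neg->pos, 4 neg->neg
        truth = ["pos"] * 4 + ["neg"] * 6
        pred = ["pos"] * 3 + ["neg"] + ["pos"] * 2 + ["neg"] * 4
        rep = ss.evaluate(truth, pred, self.two)
        np.testing.assert_array_equal(rep.confusion, [[3, 1], [2, 4]])
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.per_class["pos"]["precision"] == pytest.approx(3 / 5)
        assert rep.per_class["pos"]["recall"] == pytest.approx(3 / 4)

    def test_degenerate_all_one_class_predictor(self):
        truth = ["pos", "pos", "neg", "neg"]
        pred = ["pos"] * 4
        rep = ss.evaluate(truth, pred, self.two)
        assert rep.per_class["pos"]["recall"] == 1.0
        assert rep.per_class["neg"]["recall"] == 0.0
        assert rep.per_class["neg"]["precision"] == 0.0  # zero-denominator rule

    def test_micro_precision_equals_micro_recall_equals_accuracy(self):
        rng = np.random.default_rng(0)
        names = ("a", "b", "c")
        cm = ClassMap(names)
        truth = rng.choice(names, size=60)
        pred = rng.choice(names, size=60)
        rep = ss.evaluate(truth, pred, cm, averaging="micro")
        assert rep.precision == pytest.approx(rep.accuracy)
        assert rep.recall == pytest.approx(rep.accuracy)

    def test_weighted_metrics_agree_with_sklearn(self):
        rng = np.random.default_rng(1)
        names = ("a", "b", "c", "d")
        cm = ClassMap(names)
        truth = rng.choice(names, size=80)
        pred = rng.choice(names, size=80)
        rep = ss.evaluate(truth, pred, cm, averaging="weighted")
        p, r, f, _ = precision_recall_fscore_support(
            truth, pred, labels=list(names), average="weighted", zero_division=0
        )
        assert rep.precision == pytest.approx(p)
        assert rep.recall == pytest.approx(r)
        assert rep.f1 == pytest.approx(f)

    def test_macro_equals_weighted_on_balanced_labels(self):
        names = ("a", "b")
        cm = ClassMap(names)
        truth = ["a"] * 10 + ["b"] * 10
        rng = np.random.default_rng(2)
        pred = rng.choice(names, size=20)
        macro = ss.evaluate(truth, pred, cm, averaging="macro")
        weighted = ss.evaluate(truth, pred, cm, averaging="weighted")
        assert macro.precision == pytest.approx(weighted.precision)
        assert macro.f1 == pytest.approx(weighted.f1)

    def test_confusion_conservation_and_per_class_totals(self):
        rng = np.random.default_rng(3)
        names = ("a", "b", "c")
        cm = ClassMap(names)
        truth = rng.choice(names, size=45)
        pred = rng.choice(names, size=45)
        rep = ss.evaluate(truth, pred, cm)
        assert rep.confusion.sum() == 45
        for stats in rep.per_class.values():
            assert stats["tp"] + stats["fp"] + stats["fn"] + stats["tn"] == 45

    def test_specificity_uses_tn_over_tn_plus_fp(self):
        truth = ["pos"] * 4 + ["neg"] * 6
        pred = ["pos"] * 3 + ["neg"] + ["pos"] * 2 + ["neg"] * 4
        rep = ss.evaluate(truth, pred, self.two)
        assert rep.per_class["pos"]["specificity"] == pytest.approx(4 / 6)

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(Exception):
            ss.evaluate(["pos"], ["other"], self.two)


class TestRunPipeline:
    def test_five_reports_with_config_and_split_echo(self, sim_small):
        matrix, _ = sim_small
        reports = ss.run_pipeline(matrix, k=10, seed=1)
        assert len(reports) == 5
        kinds = [r.model_config["kind"] for r in reports]
        assert kinds == list(ss.MODEL_KINDS)
        for r in reports:
            assert r.split_plan is not None
            assert r.preprocess_config is not None
            assert len(r.extras["selected_gene_indices"]) == 10

    def test_identical_seeds_give_byte_identical_json(self, sim_small):
        matrix, _ = sim_small
        cfgs = [ss.ModelConfig(kind="svm_pca", seed=9)]
        a = ss.run_pipeline(matrix, k=8, seed=4, model_configs=cfgs)[0]
        b = ss.run_pipeline(matrix, k=8, seed=4, model_configs=cfgs)[0]
        assert ss.report_to_json(a) == ss.report_to_json(b)

    def test_report_json_is_valid_and_stable_schema(self, sim_small):
        matrix, _ = sim_small
        cfgs = [ss.ModelConfig(kind="decision_tree", seed=0)]
        rep = ss.run_pipeline(matrix, k=5, seed=0, model_configs=cfgs)[0]
        parsed = json.loads(ss.report_to_json(rep))
        for key in ("confusion_matrix", "accuracy", "precision", "recall", "f1",
                    "per_class", "model_config", "split_plan"):
            assert key in parsed

    def test_cross_validation_accuracy_reported(self, sim_small):
        matrix, _ = sim_small
        cfgs = [ss.ModelConfig(kind="linear_onehot", seed=0)]
        rep = ss.run_pipeline(matrix, k=5, seed=0, model_configs=cfgs, cv_folds=5)[0]
        assert rep.extras["cv_folds"] == 5
        assert len(rep.extras["cv_fold_accuracies"]) == 5
        assert 0.0 <= rep.extras["cv_accuracy"] <= 1.0

    def test_selection_fit_on_training_rows_only(self, sim_small):
        """Changing test-row values must not change the selected genes."""
        matrix, _ = sim_small
        cfgs = [ss.ModelConfig(kind="decision_tree", seed=0)]
        rep1 = ss.run_pipeline(matrix, k=6, seed=4, model_configs=cfgs)[0]
        perturbed = matrix.subset_samples(range(matrix.n_samples))
        test_rows = rep1.split_plan["test_indices"]
        perturbed.values[test_rows] += np.random.default_rng(0).normal(
            0, 50, size=perturbed.values[test_rows].shape
        )
        rep2 = ss.run_pipeline(perturbed, k=6, seed=4, model_configs=cfgs)[0]
        assert rep1.extras["selected_gene_indices"] == rep2.extras[
            "selected_gene_indices"
        ]
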