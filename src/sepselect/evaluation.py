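"""Splitting, metrics, and the end-to-end selection/classification pipeline.

Metrics follow the usual multiclass one-vs-rest decomposition: per class,
TP/FP/FN/TN are read off the confusion matrix (rows = true, columns =
predicted), then

    accuracy  = (number correct) / n
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * P * R / (P + R)

aggregated by weighted (class-support), macro, or micro averaging
(weighted is the default).  Per-class specificity TN / (TN + FP) is
reported alongside — some published tables print the specificity formula
under the name "precision", and carrying both makes such comparisons
explicit.  Zero-denominator per-class metrics are defined as 0.

``run_pipeline`` executes preprocess -> split -> select -> fit -> predict
-> evaluate for each configured model, with every random stage seeded by a
fixed offset from one global seed, and emits JSON-stable reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .classifiers import ModelConfig, fit as fit_model
from .errors import DomainError
from .io_expression import ClassMap, ExpressionMatrix
from .preprocessing import PreprocessConfig, Standardizer
from .selector import DEFAULT_K, select_features

__all__ = [
    "SplitPlan",
    "EvaluationReport",
    "make_split",
    "kfold",
    "evaluate",
    "run_pipeline",
    "report_to_json",
    "summary_table",
]

# fixed seed offsets so one stage's stochasticity never perturbs another's
SPLIT_SEED_OFFSET = 101
MODEL_SEED_OFFSET = 211
FOLD_SEED_OFFSET = 307


@dataclass(frozen=True)
class SplitPlan:
    """A train/test partition (or k-fold assignment) with its provenance."""

    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    seed: int
    stratified: bool
    folds: tuple[tuple[int, ...], ...] | None = None  # test fold index lists

    def __post_init__(self) -> None:
        if set(self.train_indices) & set(self.test_indices):
            raise DomainError("train and test indices overlap")

    def as_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "train_indices": list(self.train_indices),
            "test_indices": list(self.test_indices),
            "seed": self.seed,
            "stratified": self.stratified,
        }
        if self.folds is not None:
            d["folds"] = [list(f) for f in self.folds]
        return d


def make_split(
    matrix: ExpressionMatrix,
    train_fraction: float = 0.6,
    seed: int = 42,
    stratified: bool = True,
) -> SplitPlan:
    """Deterministic train/test split (stratified by class by default)."""
    if not 0.0 < train_fraction < 1.0:
        raise DomainError("train_fraction must be in (0, 1)")
    labels = matrix.labels
    if stratified:
        for name, count in matrix.class_counts().items():
            if count < 2:
                raise DomainError(
                    f"class {name!r} has {count} sample(s); stratified splitting "
                    "needs at least 2 per class"
                )
    idx = np.arange(matrix.n_samples)
    train, test = train_test_split(
        idx,
        train_size=train_fraction,
        random_state=seed,
        stratify=labels if stratified else None,
        shuffle=True,
    )
    return SplitPlan(
        train_indices=tuple(int(i) for i in np.sort(train)),
        test_indices=tuple(int(i) for i in np.sort(test)),
        seed=seed,
        stratified=stratified,
    )


def kfold(
    matrix: ExpressionMatrix,
    n_folds: int = 5,
    seed: int = 42,
    stratified: bool = True,
) -> SplitPlan:
    """K-fold partition: every sample in exactly one test fold, fold sizes
    differing by at most one."""
    if n_folds < 2:
        raise DomainError("need at least 2 folds")
    if stratified:
        for name, count in matrix.class_counts().items():
            if count < n_folds:
                raise DomainError(
                    f"class {name!r} has {count} samples, fewer than {n_folds} folds"
                )
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(matrix.values, matrix.labels)
    else:
        if n_folds > matrix.n_samples:
            raise DomainError("more folds than samples")
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(matrix.values)
    folds = tuple(tuple(int(i) for i in test) for _, test in split_iter)
    return SplitPlan(
        train_indices=(),
        test_indices=(),
        seed=seed,
        stratified=stratified,
        folds=folds,
    )


@dataclass
class EvaluationReport:
    """Confusion matrix plus the four headline metrics and per-class detail."""

    confusion: np.ndarray  # c x c, rows = true, columns = predicted
    class_names: tuple[str, ...]
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    averaging: str
    per_class: dict[str, dict[str, float]]
    n_evaluated: int
    model_config: dict[str, Any] | None = None
    split_plan: dict[str, Any] | None = None
    preprocess_config: dict[str, Any] | None = None
    evaluation_set: str = "test"
    extras: dict[str, Any] = field(default_factory=dict)

    def as_dict(self) -> dict[str, Any]:
        return {
            "confusion_matrix": self.confusion.tolist(),
            "class_names": list(self.class_names),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "specificity": self.specificity,
            "averaging": self.averaging,
            "per_class": self.per_class,
            "n_evaluated": self.n_evaluated,
            "evaluation_set": self.evaluation_set,
            "model_config": self.model_config,
            "split_plan": self.split_plan,
            "preprocess_config": self.preprocess_config,
            "extras": self.extras,
            "note": (
                "precision is TP/(TP+FP); specificity TN/(TN+FP) is reported "
                "separately"
            ),
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def evaluate(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_map: ClassMap,
    averaging: str = "weighted",
) -> EvaluationReport:
    """Confusion matrix and accuracy/precision/recall/F1 for one prediction."""
    if averaging not in ("weighted", "macro", "micro"):
        raise DomainError(f"unknown averaging {averaging!r}")
    y_true = [str(x) for x in true_labels]
    y_pred = [str(x) for x in predicted_labels]
    if len(y_true) != len(y_pred):
        raise DomainError("label vectors differ in length")
    c = class_map.n_classes
    names = class_map.names
    conf = np.zeros((c, c), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        conf[class_map.code(t) - 1, class_map.code(p) - 1] += 1

    n = conf.sum()
    accuracy = _safe_div(np.trace(conf), n)
    per_class: dict[str, dict[str, float]] = {}
    tp_all = fp_all = fn_all = 0
    precs, recs, f1s, specs, support = [], [], [], [], []
    for j, name in enumerate(names):
        tp = int(conf[j, j])
        fp = int(conf[:, j].sum() - tp)
        fn = int(conf[j, :].sum() - tp)
        tn = int(n - tp - fp - fn)
        p = _safe_div(tp, tp + fp)
        r = _safe_div(tp, tp + fn)
        f = _safe_div(2 * p * r, p + r)
        s = _safe_div(tn, tn + fp)
        per_class[name] = {
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "precision": p, "recall": r, "f1": f, "specificity": s,
            "support": tp + fn,
        }
        precs.append(p); recs.append(r); f1s.append(f); specs.append(s)
        support.append(tp + fn)
        tp_all += tp; fp_all += fp; fn_all += fn

    if averaging == "macro":
        w = np.full(c, 1.0 / c)
        precision = float(np.dot(w, precs))
        recall = float(np.dot(w, recs))
        f1 = float(np.dot(w, f1s))
        specificity = float(np.dot(w, specs))
    elif averaging == "weighted":
        w = np.asarray(support, dtype=np.float64)
        w = w / w.sum() if w.sum() else np.full(c, 1.0 / c)
        precision = float(np.dot(w, precs))
        recall = float(np.dot(w, recs))
        f1 = float(np.dot(w, f1s))
        specificity = float(np.dot(w, specs))
    else:  # micro: pool counts; for single-label multiclass this equals accuracy
        precision = _safe_div(tp_all, tp_all + fp_all)
        recall = _safe_div(tp_all, tp_all + fn_all)
        f1 = _safe_div(2 * precision * recall, precision + recall)
        tn_all = c * n - tp_all - fp_all - fn_all
        specificity = _safe_div(tn_all, tn_all + fp_all)

    return EvaluationReport(
        confusion=conf,
        class_names=names,
        accuracy=float(accuracy),
        precision=precision,
        recall=recall,
        f1=f1,
        specificity=specificity,
        averaging=averaging,
        per_class=per_class,
        n_evaluated=int(n),
    )


def report_to_json(report: EvaluationReport) -> str:
    """Canonical JSON form; byte-identical for identical resolved configs."""
    return json.dumps(report.as_dict(), sort_keys=True, indent=2)


def _fit_eval_once(
    matrix: ExpressionMatrix,
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    preprocess: PreprocessConfig,
    k: int,
    direction: str,
    select_on_standardized: bool,
    model_config: ModelConfig,
    averaging: str,
):
    """One train/test round: select genes on training rows, standardize the
    selected block, fit, predict. Returns (report, selection)."""
    train = matrix.subset_samples(train_idx)
    test = matrix.subset_samples(test_idx)

    select_input = train
    if select_on_standardized and preprocess.standardize:
        scaler_all = Standardizer(preprocess).fit(train.values, train.gene_ids)
        from .preprocessing import replace_values

        select_input = replace_values(train, scaler_all.transform(train.values))
    selection = select_features(select_input, k=k, direction=direction)
    sel = selection.selected

    X_train = train.values[:, sel]
    X_test = test.values[:, sel]
    if preprocess.standardize or preprocess.abs_transform:
        scaler = Standardizer(preprocess)
        if preprocess.fit_on_training_only:
            scaler.fit(X_train)
        else:
            scaler.fit(matrix.values[:, sel])
        X_train = scaler.transform(X_train)
        X_test = scaler.transform(X_test)

    train_sel = ExpressionMatrix(
        values=X_train,
        sample_ids=list(train.sample_ids),
        gene_ids=[matrix.gene_ids[i] for i in sel],
        labels=train.labels,
        class_map=matrix.class_map,
    )
    model = fit_model(train_sel, model_config)
    predicted = model.predict(X_test)
    report = evaluate(test.labels, predicted, matrix.class_map, averaging=averaging)
    if model_config.kind == "lstm":
        report.extras["training_history"] = {
            "loss": [float(x) for x in model._state.history["loss"]],
            "accuracy": [float(x) for x in model._state.history["accuracy"]],
        }
    return report, selection


def run_pipeline(
    matrix: ExpressionMatrix,
    preprocess: PreprocessConfig | None = None,
    k: int = DEFAULT_K,
    model_configs: Sequence[ModelConfig] | None = None,
    train_fraction: float = 0.6,
    seed: int = 42,
    stratified: bool = True,
    direction: str = "descending",
    select_on_standardized: bool = False,
    averaging: str = "weighted",
    cv_folds: int | None = None,
) -> list[EvaluationReport]:
    """Full pipeline for every configured model.

    Steps: stratified 60/40 split -> separability selection of k genes on
    the training rows -> z-scoring of the selected block (fit on train) ->
    fit -> predict on the held-out rows -> metrics.  With ``cv_folds`` set,
    a k-fold cross-validated accuracy over the whole matrix is added to
    each report's extras.  All randomness derives from ``seed`` through
    fixed per-stage offsets.
    """
    preprocess = preprocess or PreprocessConfig()
    if model_configs is None:
        model_configs = [
            ModelConfig(kind=kind, seed=seed + MODEL_SEED_OFFSET + i)
            for i, kind in enumerate(
                ("random_forest", "decision_tree", "linear_onehot", "svm_pca", "lstm")
            )
        ]
    plan = make_split(
        matrix, train_fraction=train_fraction, seed=seed + SPLIT_SEED_OFFSET,
        stratified=stratified,
    )
    fold_plan = (
        kfold(matrix, n_folds=cv_folds, seed=seed + FOLD_SEED_OFFSET, stratified=stratified)
        if cv_folds
        else None
    )

    reports: list[EvaluationReport] = []
    for mc in model_configs:
        report, selection = _fit_eval_once(
            matrix, plan.train_indices, plan.test_indices, preprocess, k,
            direction, select_on_standardized, mc, averaging,
        )
        report.model_config = mc.as_dict()
        report.split_plan = plan.as_dict()
        report.preprocess_config = preprocess.as_dict()
        report.extras["selected_gene_indices"] = [int(i) for i in selection.selected]
        report.extras["selected_gene_ids"] = selection.selected_gene_ids()
        report.extras["k"] = k
        report.extras["sort_direction"] = direction

        if fold_plan is not None:
            all_idx = np.arange(matrix.n_samples)
            fold_accs = []
            for test_fold in fold_plan.folds:
                train_fold = np.setdiff1d(all_idx, np.asarray(test_fold))
                fold_report, _ = _fit_eval_once(
                    matrix, train_fold, test_fold, preprocess, k,
                    direction, select_on_standardized, mc, averaging,
                )
                fold_accs.append(fold_report.accuracy)
            report.extras["cv_folds"] = cv_folds
            report.extras["cv_fold_accuracies"] = fold_accs
            report.extras["cv_accuracy"] = float(np.mean(fold_accs))
        reports.append(report)
    return reports


def summary_table(reports: Sequence[EvaluationReport]) -> str:
    """Plain-text table of the headline metrics, one row per model."""
    header = f"{'Model':<16}{'Accuracy':>10}{'Precision':>11}{'Recall':>9}{'F1':>9}"
    has_cv = any("cv_accuracy" in r.extras for r in reports)
    if has_cv:
        header += f"{'CV-Acc':>9}"
    lines = [header]
    for r in reports:
        kind = (r.model_config or {}).get("kind", "?")
        line = (
            f"{kind:<16}{r.accuracy:>10.4f}{r.precision:>11.4f}"
            f"{r.recall:>9.4f}{r.f1:>9.4f}"
        )
        if has_cv:
            cv = r.extras.get("cv_accuracy")
            line += f"{cv:>9.4f}" if cv is not None else f"{'-':>9}"
        lines.append(line)
    return "\n".join(lines)
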