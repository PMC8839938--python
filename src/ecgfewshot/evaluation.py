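"""Evaluation: class-center (prototype) classification, metrics,
downstream classifier heads, cross-validation, subset ablation.

The few-shot evaluation protocol mirrors deployment against a database of
professionally labeled signals:

1. split the held-out records per class into a "database" half and a
   "query" half, truncating database classes to equal cardinality;
2. embed all records into the 20-D space;
3. average each class's database embeddings into a class center vector;
4. label each query by its nearest (Euclidean) class center;
5. score predictions against the true labels.

Metrics follow the standard confusion-count formulas: Acc = (TP+TN)/all,
Precision = TP/(TP+FP), Recall = TP/(TP+FN), F1 the harmonic mean,
Specificity = TN/(TN+FP), and AUC the trapezoidal area under the ROC
threshold sweep. Multiclass values are macro-averaged one-vs-rest; ROC
scores for the proximity classifier are the negated center distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skmetrics
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .network import FewShotEncoder
from .segmentation import QRSSet
from .training import TrainingConfig, split_dataset, train_fsl

__all__ = [
    "ClassCenters",
    "EvaluationReport",
    "embed_dataset",
    "split_database_query",
    "class_centers",
    "nearest_center_classify",
    "compute_metrics",
    "fsl_evaluate",
    "downstream_classify",
    "crossvalidate",
    "aggregate_reports",
    "subset_ablation",
    "DOWNSTREAM_MODELS",
]

METRIC_NAMES = (
    "accuracy", "precision", "recall", "f1", "auc", "specificity", "sensitivity",
)


@dataclass
class ClassCenters:
    """Per-class mean embedding and database cardinality, in label order."""

    labels: list[str]
    centers: np.ndarray          # (n_classes, dim)
    cardinality: dict[str, int] = field(default_factory=dict)


@dataclass
class EvaluationReport:
    """Confusion matrix plus the scalar metric set for one evaluation."""

    labels: list[str]
    confusion: np.ndarray        # (n_classes, n_classes), true x predicted
    metrics: dict[str, float]
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)


def embed_dataset(
    model: FewShotEncoder, dataset: list[QRSSet]
) -> tuple[np.ndarray, np.ndarray]:
    """Embed every record; returns (X of shape (N, 20), labels array)."""
    X = np.stack([model.embed_record(qs).f for qs in dataset])
    y = np.array([qs.superclass for qs in dataset])
    return X, y


def split_database_query(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Split labeled embeddings into database and query halves.

    Per class, members are shuffled and the first floor(n/2) go to the
    database, the rest to the query set; database classes are then
    truncated to the smallest class's size so every class has the same
    cardinality, and the truncated members rejoin the query set. The
    query half keeps its natural imbalance.
    """
    classes = sorted(set(y))
    halves: dict[str, np.ndarray] = {}
    query_idx: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 members")
        idx = rng.permutation(idx)
        half = len(idx) // 2
        halves[c] = idx[:half]
        query_idx.append(idx[half:])
    m = min(len(v) for v in halves.values())
    db_idx = np.concatenate([halves[c][:m] for c in classes])
    q_idx = np.concatenate(query_idx + [halves[c][m:] for c in classes])
    return (X[db_idx], y[db_idx]), (X[q_idx], y[q_idx])


def class_centers(X: np.ndarray, y: np.ndarray,
                  labels: list[str] | None = None) -> ClassCenters:
    """Arithmetic-mean embedding per class (the prototype vectors)."""
    labels = labels or sorted(set(y))
    centers, card = [], {}
    for c in labels:
        members = X[y == c]
        if len(members) == 0:
            raise ValueError(f"class {c!r} absent from the database")
        centers.append(members.mean(axis=0))
        card[c] = len(members)
    return ClassCenters(labels=list(labels), centers=np.stack(centers),
                        cardinality=card)


def nearest_center_classify(
    query: np.ndarray, centers: ClassCenters
) -> tuple[str, np.ndarray]:
    """Label a query by its nearest class center.

    Returns the label (ties broken by catalog order) and per-class scores
    for ROC analysis: the negated Euclidean distances, monotone in the
    decision rule.
    """
    d = np.linalg.norm(centers.centers - np.asarray(query)[None, :], axis=1)
    return centers.labels[int(np.argmin(d))], -d


def _binary_counts(truth: np.ndarray, pred: np.ndarray, c: str):
    tp = int(np.sum((truth == c) & (pred == c)))
    fp = int(np.sum((truth != c) & (pred == c)))
    fn = int(np.sum((truth == c) & (pred != c)))
    tn = int(np.sum((truth != c) & (pred != c)))
    return tp, fp, tn, fn


def compute_metrics(
    truth: np.ndarray,
    predicted: np.ndarray,
    scores: np.ndarray | None = None,
    labels: list[str] | None = None,
) -> EvaluationReport:
    """Confusion matrix and the metric set from truth/prediction/scores.

    Binary metrics use the stated confusion-count formulas; with more than
    two classes each metric is macro-averaged one-vs-rest. ``scores`` is
    an (N, n_classes) matrix aligned with ``labels``; AUC is skipped
    (``nan``) when scores are absent and raises on single-class truth.
    """
    truth, predicted = np.asarray(truth), np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction lengths differ")
    labels = list(labels) if labels is not None else sorted(set(truth) | set(predicted))
    if not set(truth) | set(predicted) <= set(labels):
        raise ValueError("label outside the catalog")
    index = {c: i for i, c in enumerate(labels)}

    n = len(labels)
    confusion = np.zeros((n, n), dtype=int)
    for t, p in zip(truth, predicted):
        confusion[index[t], index[p]] += 1

    per = {name: [] for name in METRIC_NAMES if name != "auc"}
    per_class: dict[str, dict[str, float]] = {}
    for c in labels:
        tp, fp, tn, fn = _binary_counts(truth, predicted, c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        vals = {
            "accuracy": (tp + tn) / (tp + fp + tn + fn),
            "precision": prec,
            "recall": rec,
            "f1": 2 * prec * rec / (prec + rec) if prec + rec else 0.0,
            "specificity": tn / (tn + fp) if tn + fp else 0.0,
            "sensitivity": rec,
        }
        per_class[c] = vals
        for name, v in vals.items():
            per[name].append(v)

    out = {name: float(np.mean(v)) for name, v in per.items()}
    # overall accuracy = trace / total (equals the binary formula for 2 classes)
    out["accuracy"] = float(np.trace(confusion) / confusion.sum())

    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (len(truth), n):
            raise ValueError("scores must be (n_queries, n_classes), label-aligned")
        present = [c for c in labels if np.any(truth == c)]
        if len(present) < 2:
            raise ValueError("AUC undefined for single-class truth")
        aucs = [
            skmetrics.roc_auc_score((truth == c).astype(int), scores[:, index[c]])
            for c in present
            if 0 < np.sum(truth == c) < len(truth)
        ]
        out["auc"] = float(np.mean(aucs))
    else:
        out["auc"] = float("nan")

    return EvaluationReport(labels=labels, confusion=confusion, metrics=out,
                            per_class=per_class)


def fsl_evaluate(
    model: FewShotEncoder,
    test: list[QRSSet],
    rng: np.random.Generator,
    labels: list[str] | None = None,
) -> EvaluationReport:
    """The 5-step database/query class-center evaluation on test records."""
    X, y = embed_dataset(model, test)
    (Xdb, ydb), (Xq, yq) = split_database_query(X, y, rng)
    centers = class_centers(Xdb, ydb, labels)
    preds, scores = [], []
    for q in Xq:
        label, sc = nearest_center_classify(q, centers)
        preds.append(label)
        scores.append(sc)
    return compute_metrics(yq, np.array(preds), np.stack(scores), centers.labels)


def _make_model(name: str, seed: int):
    table = {
        "xgboost": lambda: XGBClassifier(random_state=seed, n_jobs=1, verbosity=0),
        "random-forest": lambda: RandomForestClassifier(random_state=seed),
        "decision-tree": lambda: DecisionTreeClassifier(random_state=seed),
        "knn-5": lambda: KNeighborsClassifier(n_neighbors=5),
        "knn-20": lambda: KNeighborsClassifier(n_neighbors=20),
        "svm-linear": lambda: SVC(kernel="linear", random_state=seed),
        "svm-poly": lambda: SVC(kernel="poly", random_state=seed),
        "svm-rbf": lambda: SVC(kernel="rbf", random_state=seed),
        "svm-sigmoid": lambda: SVC(kernel="sigmoid", random_state=seed),
    }
    if name not in table:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(table)}")
    return table[name]()


DOWNSTREAM_MODELS = (
    "xgboost", "random-forest", "decision-tree", "knn-5", "knn-20",
    "svm-linear", "svm-poly", "svm-rbf", "svm-sigmoid",
)


def downstream_classify(
    train_X: np.ndarray, train_y: np.ndarray,
    test_X: np.ndarray, test_y: np.ndarray,
    model_name: str, seed: int = 0,
) -> EvaluationReport:
    """Fit one named classifier on training embeddings and score it.

    Hyperparameters are the library defaults (k = 5 / 20 for the two
    nearest-neighbor variants; the four SVM kernels as named). Decision
    scores feed the ROC sweep where the library exposes them.
    """
    labels = sorted(set(train_y) | set(test_y))
    clf = _make_model(model_name, seed)
    enc = {c: i for i, c in enumerate(labels)}
    yt = np.array([enc[c] for c in train_y])
    clf.fit(train_X, yt)
    pred_idx = np.asarray(clf.predict(test_X))
    pred = np.array([labels[i] for i in pred_idx])

    scores = None
    if hasattr(clf, "predict_proba"):
        try:
            proba = clf.predict_proba(test_X)
            scores = np.zeros((len(test_y), len(labels)))
            for j, cls_idx in enumerate(clf.classes_):
                scores[:, int(cls_idx)] = proba[:, j]
        except Exception:
            scores = None
    elif hasattr(clf, "decision_function"):
        df = clf.decision_function(test_X)
        if df.ndim == 1:  # binary: one margin column
            scores = np.column_stack([-df, df])
        else:
            scores = df
    return compute_metrics(test_y, pred, scores, labels)


def aggregate_reports(reports: list[EvaluationReport]) -> dict[str, dict[str, float]]:
    """avg / min / max / std per metric across folds."""
    out = {}
    for name in METRIC_NAMES:
        vals = np.array([r.metrics[name] for r in reports], dtype=float)
        out[name] = {
            "avg": float(np.nanmean(vals)),
            "min": float(np.nanmin(vals)),
            "max": float(np.nanmax(vals)),
            "std": float(np.nanstd(vals)),
        }
    return out


def crossvalidate(
    dataset: list[QRSSet],
    config: TrainingConfig | None = None,
    n_folds: int = 5,
) -> tuple[dict[str, dict[str, float]], list[EvaluationReport], list[int]]:
    """Train and evaluate ``n_folds`` independent repetitions from scratch.

    Each repetition redraws a 70/15/15 split with its own recorded seed,
    trains the few-shot encoder, and runs the database/query evaluation on
    its test split; metrics are aggregated as avg/min/max/std. Returns the
    aggregate, the per-fold reports, and the per-fold seeds.
    """
    config = config or TrainingConfig()
    reports = []
    fold_seeds = []
    for fold in range(n_folds):
        fold_config = TrainingConfig(
            margin=config.margin, lr=config.lr, betas=config.betas,
            batch_size=config.batch_size, max_epochs=config.max_epochs,
            patience=config.patience, fractions=config.fractions,
            seed=config.seed + 1000 * fold, class_weighting=config.class_weighting,
        )
        fold_seeds.append(fold_config.seed)
        model, _ = train_fsl(dataset, fold_config)
        _, _, test = split_dataset(dataset, fold_config.fractions, fold_config.seed)
        rng = np.random.default_rng(fold_config.seed + 7)
        reports.append(fsl_evaluate(model, test, rng))
    return aggregate_reports(reports), reports, fold_seeds


def subset_ablation(
    train_X: np.ndarray, train_y: np.ndarray,
    test_X: np.ndarray, test_y: np.ndarray,
    fractions=(0.01, 0.05, 0.10, 0.50, 1.00),
    model_name: str = "random-forest",
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> dict[float, float]:
    """Test-subset size ablation with the stated downstream classifier.

    The classifier is fit once on the training embeddings; for each
    fraction an independent seeded random subset of the test set of that
    relative size is drawn and its accuracy recorded. A fraction of 1.0
    reproduces the full-set evaluation exactly.
    """
    rng = rng or np.random.default_rng(seed)
    labels = sorted(set(train_y) | set(test_y))
    clf = _make_model(model_name, seed)
    enc = {c: i for i, c in enumerate(labels)}
    clf.fit(train_X, np.array([enc[c] for c in train_y]))
    out = {}
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        k = max(1, int(round(frac * len(test_y))))
        idx = np.arange(len(test_y)) if frac == 1.0 else rng.choice(
            len(test_y), size=k, replace=False
        )
        sub_y = test_y[idx]
        if set(sub_y) != set(labels):
            raise ValueError(
                f"subset at fraction {frac} is too small to contain all classes"
            )
        pred = np.array([labels[i] for i in clf.predict(test_X[idx])])
        out[float(frac)] = float(np.mean(pred == sub_y))
    return out
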