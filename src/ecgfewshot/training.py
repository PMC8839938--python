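"""Training: triplet-margin metric learning and the softmax baseline.

The few-shot encoder is trained on triplets (anchor, positive, negative)
of records with the triplet margin loss

    L(a, p, n) = max(d(a, p) - d(a, n) + m, 0),   m = 1,

where ``d`` is the Euclidean distance between 20-D record embeddings. The
loss is zero exactly when d(a,p) <= d(a,n) - m. Batches are homogeneous in
QRS count: the count is drawn from the frequency-weighted distribution of
QRS cardinalities in the training set, and every member record of the
batch has exactly that many beats.

The baseline trains the same encoder with an added class-sized fully
connected layer under softmax cross-entropy, with the same split /
early-stopping / checkpoint protocol: 70/15/15 record-level splits, Adam,
a checkpoint at each new validation best, early stop on patience
exhaustion or a 10,000-epoch cap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import EncoderConfig, FewShotEncoder
from .segmentation import QRSSet

__all__ = [
    "TrainingConfig",
    "TripletBatch",
    "TrainingHistory",
    "Adam",
    "euclidean_distance",
    "triplet_margin_loss",
    "cross_entropy",
    "split_dataset",
    "sample_triplet_batch",
    "train_fsl",
    "train_softmax",
]


def euclidean_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance; symmetric, zero iff the vectors are equal."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.sum((x - y) ** 2)))


def triplet_margin_loss(a: np.ndarray, p: np.ndarray, n: np.ndarray,
                        m: float = 1.0) -> float:
    """max(d(a,p) - d(a,n) + m, 0) with Euclidean d."""
    if m <= 0:
        raise ValueError("margin must be > 0")
    return max(euclidean_distance(a, p) - euclidean_distance(a, n) + m, 0.0)


def cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    """-sum_c y_c ln p_c for a probability vector p and one-hot target y."""
    p, y = np.asarray(p, dtype=float), np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError("shape mismatch between probabilities and target")
    true = p[y > 0]
    if np.any(true <= 0):
        raise ValueError("zero probability at the true class")
    return float(-np.sum(y[y > 0] * np.log(true)))


@dataclass
class TrainingConfig:
    margin: float = 1.0
    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 32
    max_epochs: int = 10_000
    patience: int = 50
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    class_weighting: str = "frequency"  # or "uniform"

    def __post_init__(self) -> None:
        if not self.margin > 0:
            raise ValueError("margin must be > 0")
        if not math.isclose(sum(self.fractions), 1.0):
            raise ValueError("split fractions must sum to 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TripletBatch:
    """Anchor/positive/negative record sets sharing one QRS cardinality."""

    anchors: list[QRSSet]
    positives: list[QRSSet]
    negatives: list[QRSSet]
    qrs_count: int

    def __post_init__(self) -> None:
        if not len(self.anchors) == len(self.positives) == len(self.negatives):
            raise ValueError("triplet lists must have equal length")
        for a, p, n in zip(self.anchors, self.positives, self.negatives):
            if not len(a) == len(p) == len(n) == self.qrs_count:
                raise ValueError("all member sets must share the batch QRS count")
            if p.superclass != a.superclass:
                raise ValueError("positive must share the anchor's class")
            if n.superclass == a.superclass:
                raise ValueError("negative must differ from the anchor's class")

    def stacked(self) -> np.ndarray:
        """(3B, n, 12, 100): anchors, then positives, then negatives."""
        return np.stack(
            [qs.stacked() for qs in self.anchors + self.positives + self.negatives]
        )


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = -np.inf
    best_state: list[np.ndarray] | None = None


def split_dataset(dataset: list, fractions=(0.70, 0.15, 0.15), seed: int = 0):
    """Record-level seeded shuffle split into (train, validation, test).

    The splits are pairwise disjoint and cover the dataset; sizes follow
    the fractions up to rounding of the cumulative cut points.
    """
    if not dataset:
        raise ValueError("empty dataset")
    if not math.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    n = len(dataset)
    perm = np.random.default_rng(seed).permutation(n)
    c1 = int(round(fractions[0] * n))
    c2 = int(round((fractions[0] + fractions[1]) * n))
    idx = (perm[:c1], perm[c1:c2], perm[c2:])
    return tuple([dataset[i] for i in part] for part in idx)


def _class_of(qs: QRSSet) -> str:
    if qs.superclass is None:
        raise ValueError(f"record {qs.record_id} has no class label")
    return qs.superclass


def sample_triplet_batch(
    dataset: list[QRSSet],
    batch_size: int,
    rng: np.random.Generator,
    class_weighting: str = "frequency",
    max_attempts: int = 1000,
) -> TripletBatch:
    """Draw one homogeneous-cardinality triplet batch.

    The batch's QRS count is sampled from the frequency-weighted
    distribution of cardinalities in the dataset; the anchor class from the
    class-frequency distribution (or uniform); anchor and positive are
    distinct records of that class, the negative any record of another
    class, all restricted to records with the batch's QRS count. Counts
    whose restriction cannot support a triplet are redrawn.
    """
    counts = np.array([len(qs) for qs in dataset])
    labels = np.array([_class_of(qs) for qs in dataset])
    values, freq = np.unique(counts, return_counts=True)

    chosen = None
    for _ in range(max_attempts):
        c = rng.choice(values, p=freq / freq.sum())
        subset = np.flatnonzero(counts == c)
        sub_labels = labels[subset]
        uniq, cnt = np.unique(sub_labels, return_counts=True)
        feasible = [
            l for l, k in zip(uniq, cnt) if k >= 2 and len(subset) - k >= 1
        ]
        if feasible:
            chosen = (int(c), subset, sub_labels, feasible)
            break
    if chosen is None:
        raise RuntimeError("no QRS count supports a triplet after max_attempts draws")
    c, subset, sub_labels, feasible = chosen

    if class_weighting == "frequency":
        weights = np.array([(labels == l).sum() for l in feasible], dtype=float)
    elif class_weighting == "uniform":
        weights = np.ones(len(feasible))
    else:
        raise ValueError(f"unknown class weighting {class_weighting!r}")
    weights /= weights.sum()

    anchors, positives, negatives = [], [], []
    for _ in range(batch_size):
        cls = rng.choice(feasible, p=weights)
        same = subset[sub_labels == cls]
        other = subset[sub_labels != cls]
        a, p = rng.choice(same, size=2, replace=False)
        n = rng.choice(other)
        anchors.append(dataset[a])
        positives.append(dataset[p])
        negatives.append(dataset[n])
    return TripletBatch(anchors, positives, negatives, qrs_count=c)


class Adam:
    """Adam optimizer over (parameter, gradient) array pairs."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.eps = lr, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _proximity_accuracy(model: FewShotEncoder, train: list[QRSSet],
                        val: list[QRSSet]) -> float:
    """Validation accuracy of nearest-class-center classification with
    centers estimated from the training split."""
    by_class: dict[str, list[np.ndarray]] = {}
    for qs in train:
        by_class.setdefault(_class_of(qs), []).append(model.embed_record(qs).f)
    classes = sorted(by_class)
    centers = np.stack([np.mean(by_class[c], axis=0) for c in classes])
    correct = 0
    for qs in val:
        f = model.embed_record(qs).f
        pred = classes[int(np.argmin(np.linalg.norm(centers - f, axis=1)))]
        correct += pred == _class_of(qs)
    return correct / len(val)


def _snapshot(model: FewShotEncoder) -> list[np.ndarray]:
    return [p.copy() for p, _ in model.parameters()]


def _run_epochs(model, config, n_train, run_batch, val_metric):
    """Shared epoch loop: batches, validation, checkpointing, early stop."""
    history = TrainingHistory()
    n_batches = max(1, math.ceil(n_train / config.batch_size))
    rng = np.random.default_rng(config.seed + 1)
    since_best = 0
    for epoch in range(config.max_epochs):
        losses = [run_batch(rng) for _ in range(n_batches)]
        acc = val_metric()
        history.train_loss.append(float(np.mean(losses)))
        history.val_accuracy.append(acc)
        if acc > history.best_val_accuracy:
            history.best_val_accuracy = acc
            history.best_epoch = epoch
            history.best_state = _snapshot(model)
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if history.best_state is not None:
        model.set_state(history.best_state)
    return history


def train_fsl(
    dataset: list[QRSSet], config: TrainingConfig | None = None
) -> tuple[FewShotEncoder, TrainingHistory]:
    """Train the few-shot encoder with the triplet margin loss.

    Splits the dataset 70/15/15, optimizes sampled triplet batches with
    Adam, tracks validation proximity accuracy (class centers from the
    training split), checkpoints at each new validation best, and returns
    the model restored to its best checkpoint.
    """
    config = config or TrainingConfig()
    train, val, _ = split_dataset(dataset, config.fractions, config.seed)
    if len({_class_of(q) for q in train}) < 2 or len(val) == 0:
        raise ValueError("need >= 2 classes in the training split and a non-empty validation split")
    model = FewShotEncoder(EncoderConfig(), seed=config.seed)
    opt = Adam(model.parameters(), lr=config.lr, betas=config.betas)
    m, eps = config.margin, 1e-12

    def run_batch(rng: np.random.Generator) -> float:
        batch = sample_triplet_batch(
            train, config.batch_size, rng, config.class_weighting
        )
        B = len(batch.anchors)
        F = model.forward_records(batch.stacked())
        Fa, Fp, Fn = F[:B], F[B : 2 * B], F[2 * B :]
        dap = np.linalg.norm(Fa - Fp, axis=1)
        dan = np.linalg.norm(Fa - Fn, axis=1)
        per = np.maximum(dap - dan + m, 0.0)
        active = per > 0
        # gradient of mean loss wrt the three embedding blocks
        gap = (Fa - Fp) / (dap[:, None] + eps)
        gan = (Fa - Fn) / (dan[:, None] + eps)
        dF = np.zeros_like(F)
        w = active[:, None] / B
        dF[:B] = w * (gap - gan)
        dF[B : 2 * B] = -w * gap
        dF[2 * B :] = w * gan
        model.zero_grad()
        model.backward_records(dF)
        opt.step()
        return float(per.mean())

    history = _run_epochs(
        model, config, len(train), run_batch,
        lambda: _proximity_accuracy(model, train, val),
    )
    return model, history


def train_softmax(
    dataset: list[QRSSet], n_classes: int, config: TrainingConfig | None = None
) -> tuple[FewShotEncoder, TrainingHistory, list[str]]:
    """Train the softmax baseline: encoder + class-sized head, cross-entropy.

    Minibatches group labeled records of identical QRS count (the same
    homogeneity constraint as triplet batches). Returns the model, the
    history, and the class order used for the head's output units.
    """
    config = config or TrainingConfig()
    classes = sorted({_class_of(q) for q in dataset})
    if len(classes) != n_classes:
        raise ValueError(f"dataset spans {len(classes)} classes, expected {n_classes}")
    class_index = {c: i for i, c in enumerate(classes)}
    train, val, _ = split_dataset(dataset, config.fractions, config.seed)
    model = FewShotEncoder(EncoderConfig(n_classes=n_classes), seed=config.seed)
    opt = Adam(model.parameters(), lr=config.lr, betas=config.betas)

    counts = np.array([len(q) for q in train])
    groups = {int(c): np.flatnonzero(counts == c) for c in np.unique(counts)}
    values = np.array(sorted(groups))
    freq = np.array([len(groups[int(v)]) for v in values], dtype=float)

    def run_batch(rng: np.random.Generator) -> float:
        c = int(rng.choice(values, p=freq / freq.sum()))
        idx = rng.choice(groups[c], size=min(config.batch_size, len(groups[c])),
                         replace=False)
        recs = [train[i] for i in idx]
        y = np.array([class_index[_class_of(r)] for r in recs])
        logits = model.forward_logits(np.stack([r.stacked() for r in recs]))
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        loss = float(-np.mean(np.log(p[np.arange(len(y)), y] + 1e-300)))
        dlogits = p.copy()
        dlogits[np.arange(len(y)), y] -= 1.0
        model.zero_grad()
        model.backward_logits(dlogits / len(y))
        opt.step()
        return loss

    def val_accuracy() -> float:
        correct = 0
        for qs in val:
            probs = model.softmax_head(model.embed_record(qs).f)
            correct += classes[int(np.argmax(probs))] == _class_of(qs)
        return correct / len(val)

    history = _run_epochs(model, config, len(train), run_batch, val_accuracy)
    return model, history, classes
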