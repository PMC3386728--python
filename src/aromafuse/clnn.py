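"""Competitive-learning neural network over LDA discriminant scores.

A single winner-take-all layer of S neurons clusters the discriminant
scores without labels.  For an input p the net input of neuron i is

    n_i = -||p - w_i|| + b_i,

so with zero biases the maximum net input is 0, attained exactly when p
equals a weight vector.  The winner (highest net input, lowest index on
ties) emits 1, all others 0, and only the winner's weight moves, by the
Kohonen rule w <- w + alpha (p - w).  A conscience mechanism tracks each
neuron's running win frequency c_i and sets its bias to

    b_i = exp(1 - ln c_i) - e,

which grows without bound for a neuron that keeps losing, pulling dead
neurons back into the competition; at uniform win rates all biases are
equal and the competition reduces to nearest neighbour.

After training, neurons are mapped to classes from a labelled subset:
neurons whose weights are mutually closer than twice the quantization
error are first merged into one detected cluster (two prototypes inside
the same point cloud are one group, not two), and each detected cluster
takes the majority class of the rows it wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

E = float(np.e)


@dataclass
class CompetitionResult:
    net: np.ndarray
    winner: int
    output: np.ndarray  # one-hot


@dataclass
class CLNNModel:
    weights: np.ndarray            # (S, L)
    biases: np.ndarray             # (S,)
    win_freq: np.ndarray           # (S,) running win frequencies, on the simplex
    learning_rate: float
    bias_learning_rate: float
    epochs: int
    quantization_error: float = float("nan")
    neuron_to_class: dict[int, object] = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    def assign(self, X: np.ndarray) -> np.ndarray:
        """Winning neuron index for each row (trained biases included)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        dists = np.linalg.norm(X[:, None, :] - self.weights[None, :, :], axis=2)
        return np.argmax(-dists + self.biases[None, :], axis=1)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "biases": self.biases.tolist(),
            "win_freq": self.win_freq.tolist(),
            "learning_rate": self.learning_rate,
            "bias_learning_rate": self.bias_learning_rate,
            "epochs": self.epochs,
            "quantization_error": self.quantization_error,
            "neuron_to_class": {
                str(k): v.item() if hasattr(v, "item") else v
                for k, v in self.neuron_to_class.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CLNNModel":
        d = json.loads(Path(path).read_text())
        return cls(
            weights=np.array(d["weights"]),
            biases=np.array(d["biases"]),
            win_freq=np.array(d["win_freq"]),
            learning_rate=d["learning_rate"],
            bias_learning_rate=d["bias_learning_rate"],
            epochs=d["epochs"],
            quantization_error=d["quantization_error"],
            neuron_to_class={int(k): v for k, v in d["neuron_to_class"].items()},
        )


def net_input(p: np.ndarray, W: np.ndarray, b: np.ndarray | float = 0.0) -> np.ndarray:
    """Net input n_i = -||p - w_i||_2 + b_i of every neuron."""
    p = np.asarray(p, dtype=float)
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if p.shape[-1] != W.shape[1]:
        raise ValueError(f"input has {p.shape[-1]} dims, weights expect {W.shape[1]}")
    b = np.broadcast_to(np.asarray(b, dtype=float), (W.shape[0],))
    return -np.linalg.norm(W - p, axis=1) + b


def compete(n: np.ndarray) -> CompetitionResult:
    """Winner-take-all: highest net input wins, lowest index breaks ties."""
    n = np.asarray(n, dtype=float)
    if n.size == 0:
        raise ValueError("empty net input")
    if not np.all(np.isfinite(n)):
        raise ValueError("net input must be finite")
    winner = int(np.argmax(n))
    a = np.zeros_like(n)
    a[winner] = 1.0
    return CompetitionResult(net=n, winner=winner, output=a)


def kohonen_update(w: np.ndarray, p: np.ndarray, alpha: float) -> np.ndarray:
    """Move the winning weight toward the input: w + alpha (p - w)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"learning rate {alpha} outside [0, 1]")
    w = np.asarray(w, dtype=float)
    p = np.asarray(p, dtype=float)
    return w + alpha * (p - w)


def _conscience_bias(c: np.ndarray) -> np.ndarray:
    return np.exp(1.0 - np.log(c)) - E


def bias_update(
    c: np.ndarray,
    b: np.ndarray,
    winner: int,
    bias_lr: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Conscience update of win frequencies and biases.

    c'_i = (1 - lam) c_i + lam [i == winner]  (exponential running average)
    b'_i = exp(1 - ln c'_i) - e

    With lam = 0 nothing changes.  A neuron that never wins has c decaying
    geometrically, so its bias increases strictly.
    """
    c = np.asarray(c, dtype=float)
    if not 0.0 <= bias_lr < 1.0:
        raise ValueError("bias learning rate must be in [0, 1)")
    if bias_lr == 0.0:
        return c.copy(), np.asarray(b, dtype=float).copy()
    a = np.zeros_like(c)
    a[winner] = 1.0
    c_new = (1.0 - bias_lr) * c + bias_lr * a
    return c_new, _conscience_bias(c_new)


def _quantization_error(X: np.ndarray, model_W: np.ndarray, b: np.ndarray) -> float:
    dists = np.linalg.norm(X[:, None, :] - model_W[None, :, :], axis=2)
    winners = np.argmax(-dists + b[None, :], axis=1)
    return float(dists[np.arange(len(X)), winners].mean())


def train(
    scores: np.ndarray,
    n_neurons: int = 6,
    alpha: float = 0.1,
    bias_lr: float = 0.001,
    epochs: int = 200,
    repeats: int = 3,
    seed: int = 0,
    init: str = "maxmin",
    init_weights: np.ndarray | None = None,
    alpha_decay: float = 1.0,
) -> CLNNModel:
    """Train the competitive layer; keep the best of ``repeats`` runs.

    Each repeat presents every row once per epoch in a freshly shuffled
    order: compete, Kohonen-update the winner, conscience-update the
    biases.  Repeats differ in their random stream; the run with the
    lowest mean quantization error (mean distance of each row to its
    winning weight) is kept.  Deterministic under a fixed seed.

    ``init='maxmin'`` (default) seeds the weights at training rows chosen
    by greedy farthest-point traversal from a random start, so every
    well-separated cluster holds a prototype from the outset.  This
    matters because discriminant-score clusters can differ in separation
    by orders of magnitude: the conscience bias of a neuron that still
    wins a few rows saturates, so it can never bridge the largest gaps,
    and a network started with all weights coincident ('midpoint', at the
    centre of the data bounding box) gets stuck with two prototypes in one
    cluster and none in another.  ``init='random'`` draws each weight
    uniformly inside the bounding box.  Explicit ``init_weights`` override
    all of these.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    n, L = X.shape
    if n_neurons < 1:
        raise ValueError("need at least one neuron")
    if n_neurons > n:
        raise ValueError(f"{n_neurons} neurons but only {n} rows")
    lo, hi = X.min(axis=0), X.max(axis=0)
    best: CLNNModel | None = None
    for r in range(repeats):
        rng = np.random.default_rng([seed, r])
        if init_weights is not None:
            W = np.array(init_weights, dtype=float, copy=True)
            if W.shape != (n_neurons, L):
                raise ValueError("init_weights shape mismatch")
        elif init == "maxmin":
            chosen = [int(rng.integers(n))]
            d = np.linalg.norm(X - X[chosen[0]], axis=1)
            while len(chosen) < n_neurons:
                nxt = int(np.argmax(d))
                chosen.append(nxt)
                d = np.minimum(d, np.linalg.norm(X - X[nxt], axis=1))
            W = X[chosen].copy()
        elif init == "midpoint":
            W = np.tile((lo + hi) / 2.0, (n_neurons, 1))
        elif init == "random":
            W = rng.uniform(lo, hi, (n_neurons, L))
        else:
            raise ValueError(f"unknown init {init!r}")
        c = np.full(n_neurons, 1.0 / n_neurons)
        b = _conscience_bias(c) if bias_lr > 0 else np.zeros(n_neurons)
        lr = alpha
        for _ in range(epochs):
            for i in rng.permutation(n):
                p = X[i]
                res = compete(net_input(p, W, b))
                W[res.winner] = kohonen_update(W[res.winner], p, lr)
                c, b = bias_update(c, b, res.winner, bias_lr)
            lr *= alpha_decay  # optional schedule; 1.0 keeps alpha constant
        qe = _quantization_error(X, W, b)
        model = CLNNModel(
            weights=W,
            biases=b,
            win_freq=c,
            learning_rate=alpha,
            bias_learning_rate=bias_lr,
            epochs=epochs,
            quantization_error=qe,
        )
        if best is None or qe < best.quantization_error:
            best = model
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Cluster detection and class mapping
# ---------------------------------------------------------------------------

@dataclass
class MappingResult:
    assignments: np.ndarray          # winning neuron per row
    neuron_to_class: dict[int, object]
    cluster_groups: list[list[int]]  # merged neuron groups (active neurons only)
    n_clusters_detected: int
    n_classes_detected: int
    quantization_error: float


def assign_and_map(
    model: CLNNModel,
    scores: np.ndarray,
    labels: np.ndarray | pd.Series,
    merge_factor: float = 2.0,
) -> MappingResult:
    """Assign rows to neurons, merge co-located neurons, map clusters to classes.

    Two active neurons whose weights are closer than ``merge_factor`` times
    the quantization error are prototypes of the same detected cluster and
    are merged (transitively).  Each detected cluster is mapped to the
    majority class of the rows its neurons win (ties to the lowest class
    label); ``n_classes_detected`` counts the distinct classes over
    detected clusters.  Neurons that win nothing stay unmapped and do not
    count as clusters.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    y = np.asarray(labels)
    winners = model.assign(X)
    dists = np.linalg.norm(X - model.weights[winners], axis=1)
    qe = float(dists.mean())
    active = sorted(set(winners.tolist()))
    parent = {i: i for i in active}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for ai in range(len(active)):
        for aj in range(ai + 1, len(active)):
            i, j = active[ai], active[aj]
            if np.linalg.norm(model.weights[i] - model.weights[j]) <= merge_factor * qe:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in active:
        groups.setdefault(find(i), []).append(i)
    cluster_groups = sorted(groups.values(), key=min)
    neuron_to_class: dict[int, object] = {}
    for group in cluster_groups:
        members = y[np.isin(winners, group)]
        vals, counts = np.unique(members, return_counts=True)
        majority = vals[np.argmax(counts)]  # first max = lowest label on ties
        for i in group:
            neuron_to_class[i] = majority
    classes_detected = {neuron_to_class[g[0]] for g in cluster_groups}
    model.neuron_to_class = dict(neuron_to_class)
    return MappingResult(
        assignments=winners,
        neuron_to_class=neuron_to_class,
        cluster_groups=cluster_groups,
        n_clusters_detected=len(cluster_groups),
        n_classes_detected=len(classes_detected),
        quantization_error=qe,
    )


def classify(model: CLNNModel, scores: np.ndarray) -> np.ndarray:
    """Predict class labels via the neuron-to-class map.

    Rows won by an unmapped neuron fall back to the nearest mapped
    neuron's class.
    """
    if not model.neuron_to_class:
        raise ValueError("model has no neuron-to-class map; run assign_and_map first")
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    winners = model.assign(X)
    mapped = np.array(sorted(model.neuron_to_class))
    out = []
    for row, w in zip(X, winners):
        if w in model.neuron_to_class:
            out.append(model.neuron_to_class[w])
        else:
            d = np.linalg.norm(model.weights[mapped] - row, axis=1)
            out.append(model.neuron_to_class[int(mapped[np.argmin(d)])])
    return np.array(out)


# ---------------------------------------------------------------------------
# Train/test evaluation (25 % / 75 % protocol)
# ---------------------------------------------------------------------------

@dataclass
class SplitReport:
    n_train: int
    n_test: int
    n_clusters_detected: int
    n_classes_detected: int
    accuracy_pct: float
    per_class_accuracy: dict[object, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_train": self.n_train,
                    "n_test": self.n_test,
                    "n_clusters_detected": self.n_clusters_detected,
                    "n_classes_detected": self.n_classes_detected,
                    "accuracy_pct": self.accuracy_pct,
                }
            ]
        )


def stratified_split(
    y: np.ndarray, train_frac: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split; returns (train_idx, test_idx)."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        k = int(round(train_frac * len(idx)))
        if k == 0 or k == len(idx):
            raise ValueError(f"class {c!r} absent from one side of the split")
        train.append(idx[:k])
        test.append(idx[k:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def evaluate_split(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    train_frac: float = 0.25,
    seed: int = 0,
    n_score_components: int = 3,
    n_neurons: int | None = None,
    alpha: float = 0.1,
    bias_lr: float = 0.001,
    epochs: int = 200,
    repeats: int = 3,
) -> SplitReport:
    """The LDA-CLNN evaluation protocol on one stratified split.

    LDA is fitted on the training portion only; the CLNN is trained and
    its neurons mapped to classes on the training discriminant scores;
    accuracy is the fraction of held-out rows whose mapped class equals
    the true label.  No held-out row influences the fit in any way.
    """
    from aromafuse.chemometrics import lda_fit

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    train_idx, test_idx = stratified_split(y, train_frac, seed)
    lda = lda_fit(X[train_idx], y[train_idx])
    if n_neurons is None:
        n_neurons = len(lda.classes)
    tr_scores = lda.scores(X[train_idx], n_score_components)
    te_scores = lda.scores(X[test_idx], n_score_components)
    model = train(
        tr_scores,
        n_neurons=n_neurons,
        alpha=alpha,
        bias_lr=bias_lr,
        epochs=epochs,
        repeats=repeats,
        seed=seed,
    )
    mapping = assign_and_map(model, tr_scores, y[train_idx])
    preds = classify(model, te_scores)
    correct = preds == y[test_idx]
    per_class = {
        c: float(100.0 * correct[y[test_idx] == c].mean()) for c in np.unique(y)
    }
    return SplitReport(
        n_train=len(train_idx),
        n_test=len(test_idx),
        n_clusters_detected=mapping.n_clusters_detected,
        n_classes_detected=mapping.n_classes_detected,
        accuracy_pct=float(100.0 * correct.mean()),
        per_class_accuracy=per_class,
    )
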