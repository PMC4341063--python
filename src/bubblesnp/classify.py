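"""Bubble feature vectors and a C4.5-style decision-tree classifier.

Each candidate bubble is described by coverage and sub-graph complexity
attributes: the summed two-colour coverage over all 2k+2 cycle vertices,
the own-colour coverage summed over each branch's internal vertices, and
the fraction of branching vertices in the host sub-graph. A decision tree
trained on labelled bubbles (real SNP vs false positive) filters candidate
calls.

The tree follows C4.5 semantics: gain-ratio splits on numeric attributes
with thresholds at midpoints between sorted distinct values, a minimum
leaf size of 2, and error-based pruning at confidence 0.25 using the
binomial upper confidence limit of the leaf error rate. Ties at a split
threshold route to the left (<=) branch.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta

from .bubbles import BubbleCycle, SubGraph, UsageError
from .graph import UndirectedBubbleGraph

FEATURE_COLUMNS = (
    "total_coverage",
    "branch0_coverage",
    "branch1_coverage",
    "subgraph_branching",
)
REAL, FALSE_POSITIVE = "real", "false_positive"


@dataclass
class BubbleFeatureVector:
    """Attributes of one bubble used for classification."""

    bubble_id: str
    total_coverage: int
    branch0_coverage: int
    branch1_coverage: int
    subgraph_branching: float  # branching vertices / sub-graph vertices
    subgraph_branching_count: int
    label: str | None = None

    def as_dict(self) -> dict:
        return {
            "bubble_id": self.bubble_id,
            "total_coverage": self.total_coverage,
            "branch0_coverage": self.branch0_coverage,
            "branch1_coverage": self.branch1_coverage,
            "subgraph_branching": self.subgraph_branching,
            "subgraph_branching_count": self.subgraph_branching_count,
            "label": self.label,
        }


def extract_features(
    bubble: BubbleCycle,
    sub: SubGraph,
    graph: UndirectedBubbleGraph | None = None,
    bubble_id: str = "",
    label: str | None = None,
) -> BubbleFeatureVector:
    """Compute the feature vector of a bubble found within a sub-graph."""
    g = sub.graph
    cycle = bubble.cycle_vertices
    if any(not g.has_vertex(v) for v in cycle):
        raise UsageError("bubble is not contained in the sub-graph")
    total = sum(sum(g.coverage(v)) for v in cycle)
    branch_cov = [
        sum(g.coverage(v)[b.colour] for v in b.internal) for b in bubble.branches
    ]
    n_branching = sub.branching_count()
    return BubbleFeatureVector(
        bubble_id=bubble_id,
        total_coverage=total,
        branch0_coverage=branch_cov[0],
        branch1_coverage=branch_cov[1],
        subgraph_branching=n_branching / sub.n_vertices,
        subgraph_branching_count=n_branching,
        label=label,
    )


def features_to_frame(vectors) -> pd.DataFrame:
    return pd.DataFrame([v.as_dict() for v in vectors])


def write_features(vectors_or_frame, path) -> None:
    df = (
        vectors_or_frame
        if isinstance(vectors_or_frame, pd.DataFrame)
        else features_to_frame(vectors_or_frame)
    )
    df.to_csv(path, sep="\t", index=False)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# C4.5-style decision tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeParams:
    min_leaf_size: int = 2
    confidence: float = 0.25
    prune: bool = True


@dataclass
class TreeNode:
    counts: dict[str, int]
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def majority(self) -> str:
        # deterministic tie-break: larger count, then lexicographic label
        return max(sorted(self.counts), key=lambda c: self.counts[c])

    @property
    def errors(self) -> int:
        return self.n - self.counts[self.majority]

    def n_nodes(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + self.left.n_nodes() + self.right.n_nodes()


@dataclass
class DecisionTree:
    root: TreeNode
    features: tuple[str, ...]
    classes: tuple[str, ...]
    params: TreeParams = field(default_factory=TreeParams)


def _entropy(counts) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def gain_ratio(values: np.ndarray, labels: np.ndarray, threshold: float) -> tuple[float, float]:
    """(information gain, gain ratio) of a binary split at ``threshold``.

    Straightforward definition used directly by the split scan; small
    inputs only, no incremental bookkeeping.
    """
    classes, y = np.unique(labels, return_inverse=True)
    total = np.bincount(y, minlength=len(classes)).astype(float)
    mask = values <= threshold
    left = np.bincount(y[mask], minlength=len(classes)).astype(float)
    right = total - left
    n, nl, nr = total.sum(), left.sum(), right.sum()
    if nl == 0 or nr == 0:
        return 0.0, 0.0
    gain = _entropy(total) - (nl / n) * _entropy(left) - (nr / n) * _entropy(right)
    split_info = _entropy(np.array([nl, nr]))
    return float(gain), float(gain / split_info) if split_info > 0 else 0.0


def _best_split(X: np.ndarray, y: np.ndarray, features, min_leaf: int):
    best = None  # (ratio, feature_index, threshold)
    for j in range(X.shape[1]):
        vals = np.unique(X[:, j])
        if len(vals) < 2:
            continue
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2.0
            nl = int((X[:, j] <= thr).sum())
            nr = len(y) - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            gain, ratio = gain_ratio(X[:, j], y, thr)
            if gain <= 1e-12:
                continue
            cand = (ratio, -j, -thr)
            if best is None or cand > (best[0], -best[1], -best[2]):
                best = (ratio, j, thr)
    return best


def _counts(y: np.ndarray, classes) -> dict[str, int]:
    return {c: int((y == c).sum()) for c in classes}


def _grow(X, y, features, classes, params: TreeParams) -> TreeNode:
    node = TreeNode(counts=_counts(y, classes))
    if len(np.unique(y)) <= 1:
        return node
    best = _best_split(X, y, features, params.min_leaf_size)
    if best is None:
        return node
    _, j, thr = best
    mask = X[:, j] <= thr
    node.feature = features[j]
    node.threshold = float(thr)
    node.left = _grow(X[mask], y[mask], features, classes, params)
    node.right = _grow(X[~mask], y[~mask], features, classes, params)
    return node


def _upper_error(errors: int, n: int, cf: float) -> float:
    """Upper confidence limit of the binomial error rate (exact beta quantile)."""
    if n == 0:
        return 0.0
    if errors >= n:
        return 1.0
    return float(beta.ppf(1.0 - cf, errors + 1, n - errors))


def _prune(node: TreeNode, cf: float) -> float:
    """Error-based pruning; returns the subtree's estimated error count."""
    if node.is_leaf:
        return node.n * _upper_error(node.errors, node.n, cf)
    est_subtree = _prune(node.left, cf) + _prune(node.right, cf)
    est_leaf = node.n * _upper_error(node.errors, node.n, cf)
    if est_leaf <= est_subtree + 1e-9:
        node.feature = None
        node.threshold = None
        node.left = None
        node.right = None
        return est_leaf
    return est_subtree


def train_tree(data, params: TreeParams | None = None, seed: int = 0) -> DecisionTree:
    """Train a decision tree on labelled feature vectors.

    ``data`` is a DataFrame with the feature columns and a ``label`` column,
    or a list of labelled :class:`BubbleFeatureVector`. Training is
    deterministic given the input order; ``seed`` is accepted for interface
    symmetry with the evaluation protocol.
    """
    params = params or TreeParams()
    if not isinstance(data, pd.DataFrame):
        data = features_to_frame(data)
    if len(data) == 0:
        raise UsageError("empty training set")
    if data["label"].isna().any():
        raise UsageError("training data contains unlabelled rows")
    features = tuple(c for c in FEATURE_COLUMNS if c in data.columns)
    if not features:
        raise UsageError("no known feature columns present")
    X = data.loc[:, list(features)].to_numpy(dtype=float)
    y = data["label"].to_numpy(dtype=object)
    classes = tuple(sorted(set(y)))
    root = _grow(X, y, features, classes, params)
    if params.prune:
        _prune(root, params.confidence)
    return DecisionTree(root=root, features=features, classes=classes, params=params)


def predict(tree: DecisionTree, vector) -> tuple[str, float]:
    """Route a feature vector through the tree; returns (label, probability).

    The probability is the fraction of training instances of the predicted
    class in the reached leaf. Values equal to a threshold go left.
    """
    if isinstance(vector, BubbleFeatureVector):
        vector = vector.as_dict()
    elif isinstance(vector, pd.Series):
        vector = vector.to_dict()
    missing = [f for f in tree.features if f not in vector]
    if missing:
        raise UsageError(f"feature vector is missing {missing}")
    node = tree.root
    while not node.is_leaf:
        node = node.left if float(vector[node.feature]) <= node.threshold else node.right
    label = node.majority
    prob = node.counts[label] / node.n if node.n else 1.0
    return label, prob


def predict_frame(tree: DecisionTree, df: pd.DataFrame) -> pd.DataFrame:
    preds = [predict(tree, row) for _, row in df.iterrows()]
    out = df.copy()
    out["predicted"] = [p[0] for p in preds]
    out["probability"] = [p[1] for p in preds]
    return out


# ---------------------------------------------------------------------------
# evaluation protocol: repeated stratified 2/3 - 1/3 splits
# ---------------------------------------------------------------------------


def _binary_metrics(truth, predicted, positive=REAL) -> dict[str, float]:
    tp = sum(1 for t, p in zip(truth, predicted) if t == positive and p == positive)
    fn = sum(1 for t, p in zip(truth, predicted) if t == positive and p != positive)
    fp = sum(1 for t, p in zip(truth, predicted) if t != positive and p == positive)
    tn = sum(1 for t, p in zip(truth, predicted) if t != positive and p != positive)
    nan = float("nan")
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else nan,
        "specificity": tn / (tn + fp) if tn + fp else nan,
        "accuracy": tp / (tp + fp) if tp + fp else nan,
    }


def evaluate_runs(
    data,
    n_runs: int = 10,
    seed: int = 0,
    params: TreeParams | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Repeated hold-out evaluation of the classifier.

    Each run draws an independent stratified split (two thirds training,
    one third testing, class proportions preserved), trains a tree, and
    scores the test third with sensitivity, specificity and accuracy
    (accuracy = fraction of predicted-real bubbles that are real). Returns
    the per-run table and the means over runs.
    """
    if not isinstance(data, pd.DataFrame):
        data = features_to_frame(data)
    labels = data["label"].to_numpy(dtype=object)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise UsageError("evaluation requires both classes in the dataset")
    master = random.Random(seed)
    run_seeds = [master.randrange(2**31) for _ in range(n_runs)]
    rows = []
    for run, rs in enumerate(run_seeds):
        rng = random.Random(rs)
        train_idx: list[int] = []
        test_idx: list[int] = []
        for cls in classes:
            idx = [i for i, lab in enumerate(labels) if lab == cls]
            rng.shuffle(idx)
            n_train = min(max(1, round(len(idx) * 2 / 3)), len(idx))
            train_idx.extend(idx[:n_train])
            test_idx.extend(idx[n_train:])
        tree = train_tree(data.iloc[sorted(train_idx)], params=params, seed=rs)
        test = data.iloc[sorted(test_idx)]
        predicted = [predict(tree, row)[0] for _, row in test.iterrows()]
        metrics = _binary_metrics(test["label"].tolist(), predicted)
        rows.append({"run": run, **metrics})
    per_run = pd.DataFrame(rows)
    means = {
        m: float(np.nanmean(per_run[m].to_numpy(dtype=float)))
        for m in ("sensitivity", "specificity", "accuracy")
    }
    return per_run, means


# ---------------------------------------------------------------------------
# tree serialization (indented, human-readable, re-parseable)
# ---------------------------------------------------------------------------


def tree_to_text(tree: DecisionTree) -> str:
    lines = [
        "#bubblesnp-tree\tv1",
        "#features\t" + ",".join(tree.features),
        "#classes\t" + ",".join(tree.classes),
    ]

    def emit(node: TreeNode, depth: int) -> None:
        pad = "  " * depth
        counts = " ".join(str(node.counts[c]) for c in tree.classes)
        if node.is_leaf:
            lines.append(f"{pad}leaf {node.majority} [{counts}]")
        else:
            lines.append(f"{pad}node {node.feature} <= {node.threshold!r} [{counts}]")
            emit(node.left, depth + 1)
            emit(node.right, depth + 1)

    emit(tree.root, 0)
    return "\n".join(lines) + "\n"


def tree_from_text(text: str) -> DecisionTree:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 4 or not lines[0].startswith("#bubblesnp-tree"):
        raise UsageError("not a serialized decision tree")
    features = tuple(lines[1].split("\t", 1)[1].split(","))
    classes = tuple(lines[2].split("\t", 1)[1].split(","))

    def parse_counts(token: str) -> dict[str, int]:
        vals = token.strip("[]").split()
        return dict(zip(classes, map(int, vals)))

    pos = 3

    def parse(depth: int) -> TreeNode:
        nonlocal pos
        line = lines[pos]
        indent = (len(line) - len(line.lstrip())) // 2
        if indent != depth:
            raise UsageError(f"bad indentation at line {pos + 1}")
        pos += 1
        parts = line.split()
        if parts[0] == "leaf":
            return TreeNode(counts=parse_counts(line[line.index("[") :]))
        if parts[0] == "node":
            node = TreeNode(
                counts=parse_counts(line[line.index("[") :]),
                feature=parts[1],
                threshold=float(parts[3]),
            )
            node.left = parse(depth + 1)
            node.right = parse(depth + 1)
            return node
        raise UsageError(f"unknown tree record at line {pos}")

    root = parse(0)
    if pos != len(lines):
        raise UsageError("trailing content after tree")
    return DecisionTree(root=root, features=features, classes=classes)


def write_tree(tree: DecisionTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_text(tree))


def read_tree(path) -> DecisionTree:
    with open(path) as fh:
        return tree_from_text(fh.read())
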