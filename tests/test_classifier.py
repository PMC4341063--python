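import math
import random

import numpy as np
import pandas as pd
import pytest

from bubblesnp.bubbles import SearchConfig, UsageError, find_bubbles, search
from bubblesnp.classify import (
    TreeParams,
    evaluate_runs,
    extract_features,
    gain_ratio,
    predict,
    train_tree,
    tree_from_text,
    tree_to_text,
)
from bubblesnp.pipeline import build_undirected_graph

from conftest import TOY_K, build_ug


def _frame(values, labels):
    return pd.DataFrame(
        {
            "total_coverage": values,
            "branch0_coverage": 0,
            "branch1_coverage": 0,
            "subgraph_branching": 0.0,
            "label": labels,
        }
    )


# -- features ---------------------------------------------------------------


def test_features_toy(toy_bubble, toy_ug):
    from bubblesnp.bubbles import build_subgraph

    sub = build_subgraph(toy_ug, "TAA", SearchConfig(max_subgraph_size=100))
    vec = extract_features(toy_bubble, sub, toy_ug, bubble_id="b0")
    assert vec.total_coverage == 10
    assert vec.branch0_coverage == 3
    assert vec.branch1_coverage == 3
    assert vec.subgraph_branching == pytest.approx(2 / 9)
    assert vec.subgraph_branching_count == 2


def test_features_double_multiplicity_scales_coverage_only():
    ug1 = build_ug(["TAACGGCA"], ["TAATGGCA"], TOY_K)
    ug2 = build_ug(["TAACGGCA"] * 2, ["TAATGGCA"] * 2, TOY_K)
    from bubblesnp.bubbles import build_subgraph

    vecs = []
    for ug in (ug1, ug2):
        bubble = find_bubbles(ug)[0]
        sub = build_subgraph(ug, "TAA", SearchConfig())
        vecs.append(extract_features(bubble, sub, ug))
    v1, v2 = vecs
    assert v2.total_coverage == 2 * v1.total_coverage
    assert v2.branch0_coverage == 2 * v1.branch0_coverage
    assert v2.subgraph_branching == v1.subgraph_branching


def test_features_cycle_only_subgraph(toy_bubble, toy_ug):
    from bubblesnp.bubbles import SubGraph

    sub = SubGraph(seed="TAA", graph=toy_ug.induced(toy_bubble.cycle_vertices))
    vec = extract_features(toy_bubble, sub, toy_ug)
    assert vec.subgraph_branching == pytest.approx(2 / (2 * TOY_K + 2))


def test_features_bubble_outside_subgraph(toy_bubble, toy_ug):
    from bubblesnp.bubbles import SubGraph

    sub = SubGraph(seed="TAA", graph=toy_ug.induced(["TAA", "AAC"]))
    with pytest.raises(UsageError):
        extract_features(toy_bubble, sub, toy_ug)


# -- tree training ----------------------------------------------------------


def test_separable_split_at_midpoint():
    df = _frame([1, 2, 9, 10], ["real", "real", "false_positive", "false_positive"])
    tree = train_tree(df)
    assert tree.root.feature == "total_coverage"
    assert tree.root.threshold == pytest.approx(5.5)
    for val, expected in ((1.5, "real"), (9.0, "false_positive")):
        label, prob = predict(tree, {"total_coverage": val, "branch0_coverage": 0,
                                     "branch1_coverage": 0, "subgraph_branching": 0.0})
        assert label == expected and prob == 1.0


def test_single_class_gives_leaf():
    tree = train_tree(_frame([1, 2, 3], ["real"] * 3))
    assert tree.root.is_leaf
    assert tree.root.majority == "real"


def test_identical_features_mixed_labels_majority_leaf():
    tree = train_tree(_frame([5, 5, 5], ["real", "real", "false_positive"]))
    assert tree.root.is_leaf
    label, prob = predict(tree, {"total_coverage": 5, "branch0_coverage": 0,
                                 "branch1_coverage": 0, "subgraph_branching": 0.0})
    assert label == "real" and prob == pytest.approx(2 / 3)


def test_empty_training_set_rejected():
    with pytest.raises(UsageError):
        train_tree(_frame([], []))


def test_threshold_tie_routes_left():
    df = _frame([1, 2, 9, 10], ["real", "real", "false_positive", "false_positive"])
    tree = train_tree(df)
    label, _ = predict(tree, {"total_coverage": 5.5, "branch0_coverage": 0,
                              "branch1_coverage": 0, "subgraph_branching": 0.0})
    assert label == "real"  # value equal to the threshold goes to <=


def test_schema_mismatch_rejected():
    tree = train_tree(_frame([1, 9], ["real", "false_positive"]),
                      TreeParams(min_leaf_size=1))
    with pytest.raises(UsageError):
        predict(tree, {"wrong_feature": 1.0})


def _brute_force_gain_ratio(values, labels, threshold):
    """Plain-definition entropy arithmetic, independent of the implementation."""

    def entropy(group):
        n = len(group)
        if n == 0:
            return 0.0
        h = 0.0
        for lab in set(group):
            p = group.count(lab) / n
            h -= p * math.log2(p)
        return h

    left = [l for v, l in zip(values, labels) if v <= threshold]
    right = [l for v, l in zip(values, labels) if v > threshold]
    n = len(labels)
    gain = entropy(labels) - (len(left) / n) * entropy(left) - (len(right) / n) * entropy(right)
    nl, nr = len(left), len(right)
    split = 0.0
    for part in (nl, nr):
        if part:
            split -= (part / n) * math.log2(part / n)
    return gain, (gain / split if split else 0.0)


@pytest.mark.parametrize("seed", range(10))
def test_gain_ratio_matches_brute_force(seed):
    rng = random.Random(seed)
    n = rng.randrange(4, 21)
    values = [rng.randrange(0, 12) for _ in range(n)]
    labels = [rng.choice(["real", "false_positive"]) for _ in range(n)]
    vals = np.array(values, dtype=float)
    labs = np.array(labels, dtype=object)
    for thr in sorted({(a + b) / 2 for a, b in zip(sorted(set(values))[:-1],
                                                   sorted(set(values))[1:])}):
        gain, ratio = gain_ratio(vals, labs, thr)
        bf_gain, bf_ratio = _brute_force_gain_ratio(values, labels, thr)
        assert gain == pytest.approx(bf_gain, abs=1e-12)
        assert ratio == pytest.approx(bf_ratio, abs=1e-12)


def test_unpruned_tree_fits_distinct_features_perfectly():
    rng = random.Random(3)
    values = rng.sample(range(100), 20)
    labels = [rng.choice(["real", "false_positive"]) for _ in range(20)]
    df = _frame(values, labels)
    tree = train_tree(df, TreeParams(min_leaf_size=1, prune=False))
    correct = 0
    for v, lab in zip(values, labels):
        got, _ = predict(tree, {"total_coverage": v, "branch0_coverage": 0,
                                "branch1_coverage": 0, "subgraph_branching": 0.0})
        correct += got == lab
    assert correct == 20


def test_pruning_never_adds_nodes():
    rng = random.Random(4)
    values = [rng.randrange(0, 20) for _ in range(40)]
    labels = [rng.choice(["real", "false_positive"]) for _ in range(40)]
    df = _frame(values, labels)
    unpruned = train_tree(df, TreeParams(prune=False))
    pruned = train_tree(df, TreeParams(prune=True))
    assert pruned.root.n_nodes() <= unpruned.root.n_nodes()


# -- evaluation protocol ----------------------------------------------------


def test_evaluate_runs_separable_dataset():
    rng = random.Random(0)
    rows = [(rng.uniform(0, 3), "real") for _ in range(30)]
    rows += [(rng.uniform(7, 10), "false_positive") for _ in range(30)]
    df = _frame([r[0] for r in rows], [r[1] for r in rows])
    per_run, means = evaluate_runs(df, n_runs=10, seed=1)
    assert len(per_run) == 10
    assert means["accuracy"] == pytest.approx(1.0)
    assert means["sensitivity"] == pytest.approx(1.0)
    assert means["specificity"] == pytest.approx(1.0)


def test_evaluate_runs_deterministic():
    rng = random.Random(2)
    df = _frame([rng.uniform(0, 10) for _ in range(60)],
                [rng.choice(["real", "false_positive"]) for _ in range(60)])
    a, am = evaluate_runs(df, n_runs=5, seed=9)
    b, bm = evaluate_runs(df, n_runs=5, seed=9)
    pd.testing.assert_frame_equal(a, b)
    assert am == bm


def test_evaluate_runs_permutation_null():
    """With labels independent of features, the precision-style accuracy
    approaches the positive-class base rate."""
    rng = random.Random(10)
    n = 420
    labels = ["real"] * 252 + ["false_positive"] * 168  # 60% real
    rng.shuffle(labels)
    df = _frame([rng.uniform(0, 10) for _ in range(n)], labels)
    _, means = evaluate_runs(df, n_runs=20, seed=10)
    assert means["accuracy"] == pytest.approx(0.6, abs=0.1)


def test_evaluate_runs_single_class_rejected():
    with pytest.raises(UsageError):
        evaluate_runs(_frame([1, 2], ["real", "real"]), n_runs=2, seed=0)


# -- serialization ----------------------------------------------------------


def test_tree_text_roundtrip():
    rng = random.Random(6)
    df = _frame([rng.randrange(0, 30) for _ in range(30)],
                [rng.choice(["real", "false_positive"]) for _ in range(30)])
    tree = train_tree(df)
    text = tree_to_text(tree)
    back = tree_from_text(text)
    assert tree_to_text(back) == text
    probe = {"total_coverage": 12, "branch0_coverage": 0,
             "branch1_coverage": 0, "subgraph_branching": 0.0}
    assert predict(back, probe) == predict(tree, probe)
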