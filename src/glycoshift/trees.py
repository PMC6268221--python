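"""CART classification trees and random forests on shift descriptors.

Both learners split nodes on single descriptors at midpoints of
consecutive distinct values, scoring splits by the decrease in Gini
impurity.  The single-tree path (CART) grows with a minimum node size,
then applies cost-complexity (weakest-link) pruning with the pruning
strength selected by seeded cross-validation.  The forest grows many
unpruned trees on bootstrap samples, restricting each node to a random
descriptor subset, and estimates its error on the out-of-bag objects;
it also yields permutation (mean-decrease-accuracy) and Gini
(mean-decrease-impurity) descriptor importances and the terminal-node
proximity between objects.

Tie conventions are fixed and exact: equal-gain splits prefer the
lowest descriptor index, then the lowest threshold; equal-vote classes
prefer the earlier class in the alphabet.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .encoding import N_DESCRIPTORS

__all__ = [
    "Tree",
    "CARTModel",
    "ForestModel",
    "ImportanceReport",
    "gini_impurity",
    "best_split",
    "train_cart",
    "train_rf",
    "oob_report",
    "importance",
    "proximity",
    "apply_reference_tree",
    "rules_text",
]


def gini_impurity(class_counts: Sequence[float]) -> float:
    """Gini index 1 - sum(p_k^2) of a node's class tallies."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative class counts")
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot compute impurity of an empty node")
    p = counts / total
    return float(1.0 - np.sum(p * p))


def _encode_labels(y: Sequence, classes: Sequence | None = None) -> tuple[np.ndarray, list]:
    if classes is None:
        classes = sorted(set(y))
    index = {c: i for i, c in enumerate(classes)}
    return np.array([index[v] for v in y], dtype=np.int64), list(classes)


def best_split(
    X: np.ndarray,
    y: Sequence,
    candidate_descriptors: Sequence[int] | None = None,
    n_classes: int | None = None,
) -> tuple[int, float, float] | None:
    """Best (descriptor, threshold, impurity decrease) over the candidates.

    The left child takes objects with value strictly below the
    threshold; thresholds are midpoints of consecutive distinct sorted
    values.  Returns ``None`` when no candidate descriptor admits a
    valid split (all values constant).  ``y`` may be raw labels or
    pre-encoded integers (pass ``n_classes`` for the latter).
    """
    X = np.asarray(X, dtype=float)
    if n_classes is None:
        y_enc, classes = _encode_labels(y)
        k = len(classes)
    else:
        y_enc, k = np.asarray(y, dtype=np.int64), n_classes
    m = y_enc.size
    if m < 2:
        return None
    if candidate_descriptors is None:
        candidate_descriptors = range(X.shape[1])
    counts = np.bincount(y_enc, minlength=k)
    parent = 1.0 - float(np.sum((counts / m) ** 2))
    sum_sq_total = float(np.sum(counts.astype(float) ** 2))
    best: tuple[int, float, float] | None = None
    eye = np.eye(k, dtype=np.int64)
    onehot_cache: np.ndarray | None = None
    for j in sorted(int(j) for j in candidate_descriptors):
        xj = X[:, j]
        order = np.argsort(xj, kind="stable")
        xs = xj[order]
        valid = xs[1:] > xs[:-1]
        if not valid.any():
            continue
        left = np.cumsum(eye[y_enc[order]], axis=0)[:-1]
        nl = np.arange(1, m, dtype=float)
        nr = m - nl
        sl = np.sum(left.astype(float) ** 2, axis=1)
        right = counts[None, :] - left
        sr = np.sum(right.astype(float) ** 2, axis=1)
        score = sl / nl + sr / nr
        score[~valid] = -np.inf
        i = int(np.argmax(score))
        decrease = score[i] / m - sum_sq_total / (m * m)
        if best is None or decrease > best[2]:
            threshold = (xs[i] + xs[i + 1]) / 2.0
            best = (j, float(threshold), float(decrease))
    if best is None or best[2] <= 1e-15:
        return None
    return best


@dataclass
class Tree:
    """A binary classification tree in flat-array form.

    ``feature[i] == -1`` marks a leaf; otherwise objects with
    ``x[feature[i]] < threshold[i]`` descend to ``left[i]`` and the rest
    to ``right[i]``.  ``counts`` holds per-node class tallies of the
    training objects, ``decrease`` the per-object Gini decrease of the
    node's split (0 for leaves).
    """

    feature: list[int] = field(default_factory=list)
    threshold: list[float] = field(default_factory=list)
    left: list[int] = field(default_factory=list)
    right: list[int] = field(default_factory=list)
    counts: list[list[int]] = field(default_factory=list)
    pred: list[int] = field(default_factory=list)
    decrease: list[float] = field(default_factory=list)
    classes: list = field(default_factory=list)

    def _add_node(self, counts: np.ndarray) -> int:
        self.feature.append(-1)
        self.threshold.append(math.nan)
        self.left.append(-1)
        self.right.append(-1)
        self.counts.append([int(c) for c in counts])
        self.pred.append(int(np.argmax(counts)))
        self.decrease.append(0.0)
        return len(self.feature) - 1

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def node_size(self, i: int) -> int:
        return int(sum(self.counts[i]))

    def is_leaf(self, i: int, collapsed: np.ndarray | None = None) -> bool:
        if collapsed is not None and collapsed[i]:
            return True
        return self.feature[i] == -1

    def leaf_indices(self, X: np.ndarray, collapsed: np.ndarray | None = None) -> np.ndarray:
        """Terminal node index for each row of ``X`` (vectorised descent)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        node = np.zeros(X.shape[0], dtype=np.int64)
        feature = np.asarray(self.feature)
        threshold = np.asarray(self.threshold)
        left = np.asarray(self.left)
        right = np.asarray(self.right)
        stop = feature < 0
        if collapsed is not None:
            stop = stop | np.asarray(collapsed, dtype=bool)
        while True:
            active = ~stop[node]
            if not active.any():
                return node
            idx = np.flatnonzero(active)
            nd = node[idx]
            go_left = X[idx, feature[nd]] < threshold[nd]
            node[idx] = np.where(go_left, left[nd], right[nd])

    def predict_encoded(self, X: np.ndarray, collapsed: np.ndarray | None = None) -> np.ndarray:
        leaves = self.leaf_indices(X, collapsed)
        return np.asarray(self.pred)[leaves]

    def predict(self, X: np.ndarray, collapsed: np.ndarray | None = None) -> np.ndarray:
        return np.asarray(self.classes, dtype=object)[self.predict_encoded(X, collapsed)]

    def max_depth(self, collapsed: np.ndarray | None = None) -> int:
        depth = 0
        stack = [(0, 0)]
        while stack:
            i, d = stack.pop()
            depth = max(depth, d)
            if not self.is_leaf(i, collapsed):
                stack.append((self.left[i], d + 1))
                stack.append((self.right[i], d + 1))
        return depth

    def internal_features(self, collapsed: np.ndarray | None = None) -> list[int]:
        """Split features of reachable internal nodes, in preorder."""
        out: list[int] = []
        stack = [0]
        while stack:
            i = stack.pop()
            if self.is_leaf(i, collapsed):
                continue
            out.append(self.feature[i])
            stack.append(self.right[i])
            stack.append(self.left[i])
        return out

    def to_dict(self) -> dict:
        return {
            "feature": list(self.feature),
            "threshold": [None if math.isnan(t) else t for t in self.threshold],
            "left": list(self.left),
            "right": list(self.right),
            "counts": [list(c) for c in self.counts],
            "pred": list(self.pred),
            "decrease": list(self.decrease),
            "classes": list(self.classes),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Tree":
        return cls(
            feature=list(data["feature"]),
            threshold=[math.nan if t is None else float(t) for t in data["threshold"]],
            left=list(data["left"]),
            right=list(data["right"]),
            counts=[list(c) for c in data["counts"]],
            pred=list(data["pred"]),
            decrease=list(data["decrease"]),
            classes=list(data["classes"]),
        )


def _grow_tree(
    X: np.ndarray,
    y_enc: np.ndarray,
    k: int,
    classes: list,
    min_split: int,
    rng: np.random.Generator | None = None,
    mtry: int | None = None,
) -> Tree:
    tree = Tree(classes=classes)
    p = X.shape[1]

    def build(idx: np.ndarray) -> int:
        counts = np.bincount(y_enc[idx], minlength=k)
        node = tree._add_node(counts)
        if idx.size < min_split or np.count_nonzero(counts) < 2:
            return node
        if mtry is not None and rng is not None:
            candidates = np.sort(rng.choice(p, size=min(mtry, p), replace=False))
        else:
            candidates = None
        split = best_split(X[idx], y_enc[idx], candidates, n_classes=k)
        if split is None:
            return node
        j, thr, dec = split
        mask = X[idx, j] < thr
        tree.feature[node] = j
        tree.threshold[node] = thr
        tree.decrease[node] = dec
        tree.left[node] = build(idx[mask])
        tree.right[node] = build(idx[~mask])
        return node

    build(np.arange(y_enc.size))
    return tree


# ---------------------------------------------------------------------------
# CART: cost-complexity pruning with cross-validated strength
# ---------------------------------------------------------------------------


def _pruning_path(tree: Tree) -> list[tuple[float, list[int]]]:
    """Weakest-link sequence [(alpha, nodes collapsed at that alpha), ...].

    Alphas are per-object misclassification costs; collapsing every
    group with alpha <= a yields the optimal subtree for penalty a.
    """
    n_total = tree.node_size(0)
    collapsed = np.zeros(tree.n_nodes, dtype=bool)
    path: list[tuple[float, list[int]]] = []

    def subtree_stats(i: int) -> tuple[float, int]:
        """(misclassification cost, leaf count) of the current subtree at i."""
        if tree.is_leaf(i, collapsed):
            errors = tree.node_size(i) - tree.counts[i][tree.pred[i]]
            return errors / n_total, 1
        rl, ll = subtree_stats(tree.left[i])
        rr, lr = subtree_stats(tree.right[i])
        return rl + rr, ll + lr

    def reachable_internal() -> list[int]:
        out: list[int] = []
        stack = [0]
        while stack:
            i = stack.pop()
            if tree.is_leaf(i, collapsed):
                continue
            out.append(i)
            stack.append(tree.left[i])
            stack.append(tree.right[i])
        return out

    while not tree.is_leaf(0, collapsed):
        nodes = reachable_internal()
        gs = {}
        for i in nodes:
            r_sub, leaves = subtree_stats(i)
            r_leaf = (tree.node_size(i) - tree.counts[i][tree.pred[i]]) / n_total
            gs[i] = (r_leaf - r_sub) / (leaves - 1)
        best_g = min(gs.values())
        group = [i for i in nodes if gs[i] <= best_g + 1e-12]
        for i in group:
            collapsed[i] = True
        path.append((max(0.0, float(best_g)), group))
    return path


def _collapse_at(tree: Tree, path: list[tuple[float, list[int]]], alpha: float) -> np.ndarray:
    collapsed = np.zeros(tree.n_nodes, dtype=bool)
    for a, group in path:
        if a <= alpha + 1e-12:
            for i in group:
                collapsed[i] = True
    # only nodes still reachable matter; unreachable marks are harmless
    return collapsed


@dataclass
class CARTModel:
    """A pruned classification tree (full tree + collapse mask kept)."""

    tree: Tree
    collapsed: np.ndarray
    alpha: float
    task: str = ""

    @property
    def classes(self) -> list:
        return self.tree.classes

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.tree.predict(X, self.collapsed)

    def max_depth(self) -> int:
        return self.tree.max_depth(self.collapsed)

    def internal_features(self) -> list[int]:
        return self.tree.internal_features(self.collapsed)

    def to_dict(self) -> dict:
        return {
            "kind": "cart",
            "task": self.task,
            "alpha": self.alpha,
            "collapsed": [bool(b) for b in self.collapsed],
            "tree": self.tree.to_dict(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CARTModel":
        return cls(
            tree=Tree.from_dict(data["tree"]),
            collapsed=np.array(data["collapsed"], dtype=bool),
            alpha=float(data["alpha"]),
            task=data.get("task", ""),
        )


def train_cart(
    X: np.ndarray,
    y: Sequence,
    *,
    min_split: int = 20,
    complexity: float = 0.01,
    cv_folds: int = 10,
    seed: int = 0,
    classes: Sequence | None = None,
    task: str = "",
) -> CARTModel:
    """Grow and prune a CART tree.

    The tree grows by recursive best splits until nodes are pure or
    smaller than ``min_split``, then cost-complexity pruning selects,
    among the nested subtrees, the one whose pruning strength minimises
    seeded ``cv_folds``-fold cross-validated misclassification; the
    ``complexity`` parameter acts as a floor on the pruning strength
    relative to the root error (so ``complexity=inf`` collapses to the
    root leaf).
    """
    X = np.asarray(X, dtype=float)
    y_enc, class_list = _encode_labels(y, classes)
    k = len(class_list)
    full = _grow_tree(X, y_enc, k, class_list, min_split=min_split)
    path = _pruning_path(full)
    root_rate = (full.node_size(0) - max(full.counts[0])) / full.node_size(0)
    if full.feature[0] == -1 or root_rate == 0.0:
        alpha = 0.0 if not math.isinf(complexity) else math.inf
        return CARTModel(tree=full, collapsed=_collapse_at(full, path, alpha), alpha=alpha, task=task)
    candidates = sorted({0.0, *(a for a, _ in path)})
    if len(candidates) > 1 and cv_folds >= 2 and y_enc.size >= cv_folds:
        # each candidate alpha represents the interval up to the next
        # knot of the pruning path; evaluate it at a representative
        # interior point so fold trees (whose knots sit at slightly
        # different alphas) are pruned the same way the full tree is
        eval_points = [
            (candidates[ci] + candidates[ci + 1]) / 2.0 if ci + 1 < len(candidates) else 2.0 * candidates[ci]
            for ci in range(len(candidates))
        ]
        rng = np.random.default_rng(seed)
        order = rng.permutation(y_enc.size)
        folds = np.array_split(order, cv_folds)
        cv_errors = np.zeros(len(candidates))
        for fold in folds:
            mask = np.ones(y_enc.size, dtype=bool)
            mask[fold] = False
            if np.count_nonzero(np.bincount(y_enc[mask], minlength=k) > 0) < 1:
                continue
            sub = _grow_tree(X[mask], y_enc[mask], k, class_list, min_split=min_split)
            sub_path = _pruning_path(sub)
            for ci, a in enumerate(eval_points):
                pred = sub.predict_encoded(X[fold], _collapse_at(sub, sub_path, a))
                cv_errors[ci] += int(np.sum(pred != y_enc[fold]))
        best = int(np.max(np.flatnonzero(cv_errors == cv_errors.min())))  # ties -> simplest tree
        alpha = candidates[best]
    else:
        alpha = 0.0
    alpha = max(alpha, complexity * root_rate)
    return CARTModel(tree=full, collapsed=_collapse_at(full, path, alpha), alpha=float(alpha), task=task)


# ---------------------------------------------------------------------------
# Random forest
# ---------------------------------------------------------------------------

DEFAULT_MTRY = int(math.floor(math.sqrt(N_DESCRIPTORS)))  # 4 descriptors per node


@dataclass
class ForestModel:
    """Bootstrap ensemble of unpruned trees with stored bag memberships."""

    trees: list[Tree]
    bootstrap_indices: np.ndarray  # (n_trees, n_train)
    classes: list
    mtry: int
    seed: int
    task: str = ""

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def vote_proba(self, X: np.ndarray) -> np.ndarray:
        """Vote share per class over all trees (rows sum to 1)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        votes = np.zeros((X.shape[0], len(self.classes)))
        for tree in self.trees:
            pred = tree.predict_encoded(X)
            votes[np.arange(X.shape[0]), pred] += 1.0
        return votes / votes.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.vote_proba(X)
        return np.asarray(self.classes, dtype=object)[np.argmax(proba, axis=1)]

    def to_dict(self) -> dict:
        return {
            "kind": "rf",
            "task": self.task,
            "classes": list(self.classes),
            "mtry": self.mtry,
            "seed": self.seed,
            "bootstrap_indices": self.bootstrap_indices.tolist(),
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ForestModel":
        return cls(
            trees=[Tree.from_dict(t) for t in data["trees"]],
            bootstrap_indices=np.array(data["bootstrap_indices"], dtype=np.int64),
            classes=list(data["classes"]),
            mtry=int(data["mtry"]),
            seed=int(data["seed"]),
            task=data.get("task", ""),
        )


def train_rf(
    X: np.ndarray,
    y: Sequence,
    *,
    n_trees: int = 1000,
    mtry: int = DEFAULT_MTRY,
    seed: int = 0,
    classes: Sequence | None = None,
    task: str = "",
) -> ForestModel:
    """Grow ``n_trees`` unpruned trees on bootstrap samples.

    Each node considers ``mtry`` randomly drawn descriptors (default
    floor(sqrt(23)) = 4).  Deterministic for a given seed.
    """
    X = np.asarray(X, dtype=float)
    y_enc, class_list = _encode_labels(y, classes)
    k = len(class_list)
    n = y_enc.size
    if n < 2:
        raise ValueError("need at least two training objects")
    rng = np.random.default_rng(seed)
    trees: list[Tree] = []
    bags = np.empty((n_trees, n), dtype=np.int64)
    for t in range(n_trees):
        bag = rng.integers(0, n, size=n)
        bags[t] = bag
        trees.append(_grow_tree(X[bag], y_enc[bag], k, class_list, min_split=2, rng=rng, mtry=mtry))
    return ForestModel(trees=trees, bootstrap_indices=bags, classes=class_list, mtry=mtry, seed=seed, task=task)


def _oob_masks(model: ForestModel, n: int) -> np.ndarray:
    masks = np.ones((model.n_trees, n), dtype=bool)
    for t in range(model.n_trees):
        masks[t, model.bootstrap_indices[t]] = False
    return masks


def oob_votes(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """Per-object class votes restricted to trees where the object is out-of-bag."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    votes = np.zeros((n, len(model.classes)))
    masks = _oob_masks(model, n)
    for t, tree in enumerate(model.trees):
        idx = np.flatnonzero(masks[t])
        if idx.size == 0:
            continue
        pred = tree.predict_encoded(X[idx])
        votes[idx, pred] += 1.0
    return votes


def oob_report(model: ForestModel, X: np.ndarray, y: Sequence):
    """Out-of-bag evaluation: (TaskReport, vote-share probabilities).

    Objects never out-of-bag (possible with very few trees) are excluded
    from the confusion counts, with a warning; their probability rows
    are NaN.
    """
    from .evaluation import ConfusionMatrix, TaskReport

    votes = oob_votes(model, X)
    covered = votes.sum(axis=1) > 0
    if not covered.all():
        warnings.warn(
            f"{int(np.sum(~covered))} object(s) were in-bag for every tree and are excluded",
            stacklevel=2,
        )
    proba = np.full_like(votes, np.nan)
    proba[covered] = votes[covered] / votes[covered].sum(axis=1, keepdims=True)
    y = np.asarray(list(y), dtype=object)
    pred = np.asarray(model.classes, dtype=object)[np.argmax(votes, axis=1)]
    cm = ConfusionMatrix.from_labels(
        model.task or "task", model.classes, y[covered], pred[covered]
    )
    return TaskReport.from_confusion(cm), proba


@dataclass
class ImportanceReport:
    """Descriptor importances: permutation (MDA) and Gini (MDG)."""

    mean_decrease_accuracy: np.ndarray
    mean_decrease_gini: np.ndarray
    task: str = ""

    def ranking(self, measure: str = "gini") -> list[str]:
        values = self.mean_decrease_gini if measure == "gini" else self.mean_decrease_accuracy
        order = np.argsort(-values, kind="stable")
        return [f"C{j + 1}" for j in order]

    def top(self, n: int = 10, measure: str = "gini") -> list[str]:
        return self.ranking(measure)[:n]


def importance(model: ForestModel, X: np.ndarray, y: Sequence, seed: int = 0) -> ImportanceReport:
    """Permutation and Gini importances of the 23 descriptors.

    MDA: mean over trees of (out-of-bag error after permuting the
    descriptor among the tree's out-of-bag objects) minus (baseline
    out-of-bag error).  MDG: mean over trees of the total Gini decrease
    attributed to the descriptor (node decrease weighted by node size).
    """
    X = np.asarray(X, dtype=float)
    y_enc, _ = _encode_labels(y, model.classes)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    masks = _oob_masks(model, n)
    mda = np.zeros(p)
    mdg = np.zeros(p)
    used_trees = 0
    for t, tree in enumerate(model.trees):
        for i in range(tree.n_nodes):
            if tree.feature[i] >= 0:
                mdg[tree.feature[i]] += tree.decrease[i] * tree.node_size(i)
        idx = np.flatnonzero(masks[t])
        if idx.size == 0:
            continue
        used_trees += 1
        Xo = X[idx]
        yo = y_enc[idx]
        base_err = float(np.mean(tree.predict_encoded(Xo) != yo))
        perm = rng.permutation(idx.size)
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            mda[j] += float(np.mean(tree.predict_encoded(Xp) != yo)) - base_err
    mda /= max(used_trees, 1)
    mdg /= model.n_trees
    return ImportanceReport(mean_decrease_accuracy=mda, mean_decrease_gini=mdg, task=model.task)


def proximity(model: ForestModel, X: np.ndarray) -> np.ndarray:
    """Fraction of trees in which two objects share a terminal node."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    sim = np.zeros((n, n))
    for tree in model.trees:
        leaves = tree.leaf_indices(X)
        sim += leaves[:, None] == leaves[None, :]
    return sim / model.n_trees


# ---------------------------------------------------------------------------
# Reference rule cascade for the reducing-end anomer
# ---------------------------------------------------------------------------


def apply_reference_tree(x: np.ndarray) -> str:
    """Reducing-end anomer (``"A"`` = alpha, ``"B"`` = beta) from the
    published rule cascade, shipped as a frozen fixture classifier.

    The cascade reads the encoded descriptor vector top-down:
    C16 < 72.52 ppm -> alpha; otherwise compounds with C6 >= 57.16 ppm
    (no 6-deoxy methyl or N-acetyl methyl among the six lowest shifts)
    -> beta, while in the low-C6 branch C21 >= 96.52 ppm -> beta, else
    C23 >= 175.3 ppm (an N-acetyl carbonyl) -> beta, else alpha.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (N_DESCRIPTORS,):
        raise ValueError(f"expected an encoded {N_DESCRIPTORS}-vector")
    c6, c16, c21, c23 = x[5], x[15], x[20], x[22]
    if c16 < 72.52:
        return "A"
    if c6 >= 57.16:
        return "B"
    if c21 >= 96.52:
        return "B"
    if c23 >= 175.3:
        return "B"
    return "A"


def rules_text(model: CARTModel, feature_names: Sequence[str] | None = None) -> str:
    """Indented if/else rendering of a pruned tree's decision rules."""
    tree = model.tree
    names = feature_names or [f"C{j + 1}" for j in range(N_DESCRIPTORS)]

    def render(i: int, depth: int) -> list[str]:
        pad = "  " * depth
        if tree.is_leaf(i, model.collapsed):
            counts = tree.counts[i]
            return [f"{pad}predict {tree.classes[tree.pred[i]]}  (counts: "
                    + ", ".join(f"{c}={n}" for c, n in zip(tree.classes, counts)) + ")"]
        j, thr = tree.feature[i], tree.threshold[i]
        lines = [f"{pad}if {names[j]} < {thr:.2f} ppm:"]
        lines += render(tree.left[i], depth + 1)
        lines.append(f"{pad}else:  # {names[j]} >= {thr:.2f} ppm")
        lines += render(tree.right[i], depth + 1)
        return lines

    return "\n".join(render(0, 0))
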