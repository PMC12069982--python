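"""EGBF: second-order gradient boosting with fuzzy-entropy-modulated splits.

The model is an additive ensemble of regression trees, one tree per class
per boosting round, trained on softmax cross-entropy. Each round fits trees
to the first/second derivatives (p, q) of the loss at the current margins;
a leaf's optimal weight is

    u* = -P / (Q + beta)            (standard; P = sum p, Q = sum q)
    u* = -P / (2Q + beta)           (variant "as_printed")

and the structural score of a tree is -1/2 sum_k P_k^2/(Q_k + beta) +
alpha * H over its H leaves. Split search is greedy and depth-wise over
crisp thresholds derived from the low/medium/high fuzzy terms of each
feature; candidates are ranked by a convex combination of the structural
gain and the feature's fuzzy-entropy gain, both min-max rescaled within
the node's candidate set:

    score = (1 - lambda) * g_struct_hat + lambda * M_hat

so lambda = 0 reduces exactly to plain second-order boosting. Trees route
crisply at predict time; fuzzy memberships enter only the split scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .fuzzy import FuzzyTermSet, fit_fuzzy_terms, fuzzy_gain

__all__ = [
    "EGBFConfig",
    "TreeNode",
    "EGBFModel",
    "softmax_grad_hess",
    "leaf_weight",
    "structural_score",
    "grow_tree",
    "fit",
]


@dataclass(frozen=True)
class EGBFConfig:
    rounds: int = 100                 # boosting rounds B
    learning_rate: float = 0.3
    max_depth: int = 3
    alpha: float = 0.0                # per-leaf penalty
    beta: float = 1.0                 # leaf-weight L2 penalty
    fuzzy_weight: float = 0.5         # lambda: fuzzy-gain share of the split score
    leaf_denominator: str = "standard"   # or "as_printed"
    entropy_sign: str = "conventional"   # or "as_printed"
    min_child_hessian: float = 1e-3
    n_classes: int = 0                # 0: infer from training labels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.alpha < 0 or self.beta < 0 or self.min_child_hessian < 0:
            raise ValueError("alpha, beta, min_child_hessian must be non-negative")
        if not 0.0 <= self.fuzzy_weight <= 1.0:
            raise ValueError("fuzzy_weight must lie in [0, 1]")
        if self.leaf_denominator not in ("standard", "as_printed"):
            raise ValueError("leaf_denominator must be 'standard' or 'as_printed'")
        if self.entropy_sign not in ("conventional", "as_printed"):
            raise ValueError("entropy_sign must be 'conventional' or 'as_printed'")


@dataclass
class TreeNode:
    """Binary regression-tree node: either a split or a leaf weight."""

    feature: int = -1
    term: str = ""
    threshold: float = 0.0
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    value: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        out = np.empty(X.shape[0])
        self._fill(X, np.arange(X.shape[0]), out)
        return out

    def _fill(self, X, rows, out) -> None:
        if self.is_leaf:
            out[rows] = self.value
            return
        go_left = X[rows, self.feature] <= self.threshold
        self.left._fill(X, rows[go_left], out)
        self.right._fill(X, rows[~go_left], out)

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"value": self.value}
        return {
            "feature": self.feature, "term": self.term, "threshold": self.threshold,
            "left": self.left.to_dict(), "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "value" in d:
            return cls(value=float(d["value"]))
        return cls(
            feature=int(d["feature"]), term=d["term"], threshold=float(d["threshold"]),
            left=cls.from_dict(d["left"]), right=cls.from_dict(d["right"]),
        )


def softmax_grad_hess(scores: np.ndarray, labels: np.ndarray):
    """First and second derivatives of softmax cross-entropy per sample/class.

    p = pi - onehot(label); q = pi (1 - pi), floored at 1e-16.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n, C = scores.shape
    if labels.min() < 0 or labels.max() >= C:
        raise ValueError(f"labels must lie in [0, {C})")
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    pi = e / e.sum(axis=1, keepdims=True)
    p = pi.copy()
    p[np.arange(n), labels] -= 1.0
    q = np.maximum(pi * (1.0 - pi), 1e-16)
    return p, q


def leaf_weight(P: float, Q: float, beta: float, variant: str = "standard") -> float:
    """Optimal additive weight for a leaf with gradient/hessian sums P, Q."""
    denom = (Q + beta) if variant == "standard" else (2.0 * Q + beta)
    if denom <= 0:
        raise ZeroDivisionError("leaf-weight denominator must be positive")
    return -P / denom


def structural_score(leaf_aggregates, alpha: float, beta: float) -> float:
    """Regularized objective of a fixed tree structure (lower is better).

    leaf_aggregates: iterable of (P_k, Q_k) per leaf.
    """
    total = 0.0
    H = 0
    for P, Q in leaf_aggregates:
        if Q + beta <= 0:
            raise ZeroDivisionError("structure-score denominator must be positive")
        total += P * P / (Q + beta)
        H += 1
    return -0.5 * total + alpha * H


def _split_gain(P, Q, PL, QL, alpha, beta) -> float:
    """Structural gain of one split: parent-as-leaf score minus children score."""
    parent = structural_score([(P, Q)], alpha, beta)
    child = structural_score([(PL, QL), (P - PL, Q - QL)], alpha, beta)
    return parent - child


def grow_tree(
    X: np.ndarray,
    labels: np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
    terms: FuzzyTermSet,
    config: EGBFConfig,
) -> TreeNode:
    """Greedy depth-wise growth of one fuzzy-split regression tree.

    labels are the original class labels (they feed the fuzzy-entropy
    gain); p and q are the per-sample derivatives the tree regresses on.
    Unsplittable nodes become leaves with the learning-rate-scaled optimal
    weight.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    if X.shape[0] == 0:
        raise ValueError("cannot grow a tree on zero rows")
    classes = np.arange(int(labels.max()) + 1 if labels.size else 1)
    onehot = (labels[:, None] == classes[None, :]).astype(float)
    lam = config.fuzzy_weight

    def build(rows: np.ndarray, depth: int) -> TreeNode:
        P, Q = p[rows].sum(), q[rows].sum()
        make_leaf = lambda: TreeNode(
            value=config.learning_rate
            * leaf_weight(P, Q, config.beta, config.leaf_denominator)
        )
        if depth >= config.max_depth or rows.size < 2:
            return make_leaf()

        cands = []  # (gain, fuzzy_gain, feature, term, threshold, left_mask)
        for j, ft in enumerate(terms.features):
            thrs = ft.thresholds()
            if not thrs:
                continue
            xj = X[rows, j]
            mu = ft.membership(xj)                       # rows x terms
            masses = onehot[rows].T @ mu                  # classes x terms
            parent_counts = onehot[rows].sum(axis=0)
            try:
                M = fuzzy_gain(parent_counts, list(masses.T), config.entropy_sign)
            except ValueError:
                M = 0.0
            for term, thr in thrs:
                left = xj <= thr
                QL = q[rows][left].sum()
                if left.all() or not left.any():
                    continue
                if QL < config.min_child_hessian or (Q - QL) < config.min_child_hessian:
                    continue
                PL = p[rows][left].sum()
                g = _split_gain(P, Q, PL, QL, config.alpha, config.beta)
                if g <= 0:
                    continue
                cands.append((g, M, j, term, thr, left))
        if not cands:
            return make_leaf()

        gs = np.array([c[0] for c in cands])
        ms = np.array([c[1] for c in cands])

        def rescale(v: np.ndarray) -> np.ndarray:
            span = v.max() - v.min()
            return np.zeros_like(v) if span == 0 else (v - v.min()) / span

        combined = (1.0 - lam) * rescale(gs) + lam * rescale(ms)
        best = int(np.argmax(combined))  # first max -> deterministic tie-break
        g, M, j, term, thr, left = cands[best]
        node = TreeNode(feature=j, term=term, threshold=thr)
        node.left = build(rows[left], depth + 1)
        node.right = build(rows[~left], depth + 1)
        return node

    return build(np.arange(X.shape[0]), 0)


@dataclass
class EGBFModel:
    """Fitted EGBF ensemble: per-class tree lists plus fuzzification state."""

    config: EGBFConfig
    terms: FuzzyTermSet
    class_labels: list
    base_score: np.ndarray                     # log class priors, length C
    trees: list[list[TreeNode]] = field(default_factory=list)  # [round][class]
    train_logloss: list[float] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != len(self.terms.features):
            raise ValueError(
                f"expected {len(self.terms.features)} feature columns, got shape {X.shape}"
            )
        margins = np.tile(self.base_score, (X.shape[0], 1))
        for round_trees in self.trees:
            for c, tree in enumerate(round_trees):
                margins[:, c] += tree.predict(X)
        return margins

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        m = self.decision_scores(X)
        z = m - m.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = np.argmax(self.predict_proba(X), axis=1)  # first max: lowest index
        return np.asarray(self.class_labels)[idx]

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "config": asdict(self.config),
            "terms": self.terms.to_dict(),
            "class_labels": [str(c) for c in self.class_labels] if isinstance(
                self.class_labels[0], str) else list(map(int, self.class_labels)),
            "base_score": self.base_score.tolist(),
            "trees": [[t.to_dict() for t in rnd] for rnd in self.trees],
            "train_logloss": list(map(float, self.train_logloss)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EGBFModel":
        if d.get("format_version") != 1:
            raise ValueError(f"unsupported model format version: {d.get('format_version')}")
        return cls(
            config=EGBFConfig(**d["config"]),
            terms=FuzzyTermSet.from_dict(d["terms"]),
            class_labels=list(d["class_labels"]),
            base_score=np.asarray(d["base_score"], float),
            trees=[[TreeNode.from_dict(t) for t in rnd] for rnd in d["trees"]],
            train_logloss=list(d["train_logloss"]),
        )


def _logloss(margins: np.ndarray, y: np.ndarray) -> float:
    z = margins - margins.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(y.size), y].mean())


def fit(X, y, config: EGBFConfig | None = None) -> EGBFModel:
    """Train an EGBF ensemble on features X and class labels y.

    Labels may be strings or integers; the model remembers the label order.
    The base score is the log class prior, so a zero-round model predicts
    the priors. Training multiclass log-loss is recorded per round.
    """
    config = config or EGBFConfig()
    X = np.asarray(X, float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one label per row")
    class_labels, y_idx = np.unique(y, return_inverse=True)
    C = max(class_labels.size, config.n_classes)
    if class_labels.size < 2:
        raise ValueError("training data contains a single class; nothing to boost")

    terms = fit_fuzzy_terms(X)
    priors = np.bincount(y_idx, minlength=C).astype(float)
    priors = np.maximum(priors, 1e-12) / priors.sum()
    base = np.log(priors)

    model = EGBFModel(config, terms, list(class_labels), base)
    margins = np.tile(base, (X.shape[0], 1))
    model.train_logloss.append(_logloss(margins, y_idx))
    for _ in range(config.rounds):
        p, q = softmax_grad_hess(margins, y_idx)
        round_trees = []
        for c in range(C):
            tree = grow_tree(X, y_idx, p[:, c], q[:, c], terms, config)
            margins[:, c] += tree.predict(X)
            round_trees.append(tree)
        model.trees.append(round_trees)
        model.train_logloss.append(_logloss(margins, y_idx))
    return model
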