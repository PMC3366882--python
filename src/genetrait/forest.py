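"""Random-Forest ensemble with casewise (local) permutation importance.

Per-sample, per-feature contribution scores require each tree's bootstrap
record: a feature's score for a sample is the drop in that sample's
out-of-bag vote for its true class when the feature is permuted among the
tree's out-of-bag samples.  Impurity-based importances cannot provide this
(no per-sample sign), so the ensemble keeps explicit bootstrap bookkeeping.

Trees are grown through scikit-learn's Cython tree builder (Gini criterion,
best-split with a random sqrt-sized feature subset per node, bootstrap
expressed as sample weights -- the exact construction RandomForestClassifier
uses) because at panel scale (dozens of samples) per-estimator Python
overhead would dominate the run time by two orders of magnitude.

Permutation draw order is part of the contract (tests replay it): trees in
index order, and within a tree the features used by its splits in ascending
feature index, one permutation each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree._criterion import Gini
from sklearn.tree._splitter import BestSplitter
from sklearn.tree._tree import DepthFirstTreeBuilder, Tree

from .datatypes import ContributionCube, ValidationError

_MAX_DEPTH = np.iinfo(np.int32).max


@dataclass
class _TreeRecord:
    """One grown tree: flattened node arrays plus its bootstrap record."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    leaf_class: np.ndarray   # argmax class index per node
    boot_weight: np.ndarray  # bootstrap multiplicity per sample
    oob_idx: np.ndarray      # samples with bootstrap weight zero


def _apply_idx(rec: _TreeRecord, X: np.ndarray) -> np.ndarray:
    """Leaf node index reached by each row of X."""
    left, right = rec.children_left, rec.children_right
    feat, thresh = rec.feature, rec.threshold
    out = np.empty(X.shape[0], dtype=np.intp)
    for i in range(X.shape[0]):
        node = 0
        while left[node] != -1:
            node = left[node] if X[i, feat[node]] <= thresh[node] else right[node]
        out[i] = node
    return out


def _predict_idx(rec: _TreeRecord, X: np.ndarray) -> np.ndarray:
    """Predicted class indices for rows of X by explicit node traversal."""
    left, right = rec.children_left, rec.children_right
    feat, thresh = rec.feature, rec.threshold
    out = np.empty(X.shape[0], dtype=np.intp)
    for i in range(X.shape[0]):
        node = 0
        while left[node] != -1:
            node = left[node] if X[i, feat[node]] <= thresh[node] else right[node]
        out[i] = rec.leaf_class[node]
    return out


class BaggedForest:
    """Bootstrap ensemble of CART trees with retained OOB bookkeeping."""

    def __init__(self, n_trees: int = 200, rng=None, max_features: str | int = "sqrt"):
        if n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        self.n_trees = int(n_trees)
        self.rng = np.random.default_rng(0) if rng is None else rng
        self.max_features = max_features
        self.trees: list[_TreeRecord] = []
        self.classes_: np.ndarray | None = None

    def _resolve_max_features(self, p: int) -> int:
        if self.max_features == "sqrt":
            return max(1, int(np.sqrt(p)))
        if self.max_features is None:
            return p
        return max(1, min(p, int(self.max_features)))

    def fit(self, X: np.ndarray, y) -> "BaggedForest":
        X = np.ascontiguousarray(np.asarray(X, dtype=np.float32))
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        k = len(self.classes_)
        if k < 2:
            raise ValidationError("cannot fit an ensemble on a single-class bag")
        n, p = X.shape
        self._X = X
        self._y = y_enc.astype(np.intp)
        y_build = np.ascontiguousarray(y_enc, dtype=np.float64).reshape(-1, 1)
        n_classes = np.array([k], dtype=np.intp)
        max_feat = self._resolve_max_features(p)
        seed = int(self.rng.integers(0, 2**31 - 1))
        splitter = BestSplitter(Gini(1, n_classes), max_feat, 1, 0.0,
                                np.random.RandomState(seed), None)
        builder = DepthFirstTreeBuilder(splitter, 2, 1, 0.0, _MAX_DEPTH, 0.0)
        self.trees = []
        for _ in range(self.n_trees):
            boot = self.rng.integers(0, n, size=n)
            weight = np.bincount(boot, minlength=n).astype(np.float64)
            tree = Tree(p, n_classes, 1)
            builder.build(tree, X, y_build, weight, None)
            self.trees.append(_TreeRecord(
                children_left=tree.children_left.copy(),
                children_right=tree.children_right.copy(),
                feature=tree.feature.copy(),
                threshold=tree.threshold.copy(),
                leaf_class=np.argmax(tree.value[:, 0, :], axis=1),
                boot_weight=weight,
                oob_idx=np.flatnonzero(weight == 0),
            ))
        return self

    # -- out-of-bag votes ----------------------------------------------------
    def oob_votes(self) -> np.ndarray:
        """samples x classes matrix of OOB vote counts."""
        n = self._X.shape[0]
        votes = np.zeros((n, len(self.classes_)), dtype=float)
        for rec in self.trees:
            if rec.oob_idx.size == 0:
                continue
            pred = _predict_idx(rec, self._X[rec.oob_idx])
            votes[rec.oob_idx, pred] += 1
        return votes

    def oob_vote_fractions(self) -> np.ndarray:
        votes = self.oob_votes()
        totals = votes.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = votes / totals
        return frac  # NaN rows: sample never out-of-bag

    def oob_predictions(self) -> np.ndarray:
        """OOB majority-vote class index per sample; -1 = never OOB or tied.

        A tie between classes counts as misclassification.
        """
        votes = self.oob_votes()
        pred = np.full(votes.shape[0], -1, dtype=np.intp)
        for i, row in enumerate(votes):
            if row.sum() == 0:
                continue
            top = np.flatnonzero(row == row.max())
            pred[i] = top[0] if len(top) == 1 else -1
        return pred

    def class_errors(self) -> pd.Series:
        """Per-class OOB error fraction (ties and never-OOB count as errors)."""
        pred = self.oob_predictions()
        out = {}
        for k, cls in enumerate(self.classes_):
            mask = self._y == k
            out[cls] = float(np.mean(pred[mask] != k)) if mask.any() else np.nan
        return pd.Series(out)

    # -- casewise importance -------------------------------------------------
    def casewise_importance(self, rng) -> np.ndarray:
        """features x samples matrix of local importance scores.

        score(f, s) = mean over trees with s out-of-bag of
        [tree votes s's true class with f intact] - [same with f's values
        permuted among that tree's out-of-bag samples].  Features unused by a
        tree contribute zero from that tree.  NaN where s was never
        out-of-bag.
        """
        X, y = self._X, self._y
        n, p = X.shape
        delta = np.zeros((p, n))
        n_oob = np.zeros(n)
        for rec in self.trees:
            oob = rec.oob_idx
            if oob.size == 0:
                continue
            base = _predict_idx(rec, X[oob])
            base_correct = (base == y[oob]).astype(float)
            n_oob[oob] += 1
            used = np.unique(rec.feature[rec.feature >= 0])
            Xo = np.array(X[oob])
            for f in used:
                saved = Xo[:, f].copy()
                Xo[:, f] = saved[rng.permutation(oob.size)]
                perm = _predict_idx(rec, Xo)
                Xo[:, f] = saved
                delta[f, oob] += base_correct - (perm == y[oob]).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = delta / n_oob
        scores[:, n_oob == 0] = np.nan
        return scores


# ---------------------------------------------------------------------------
# Bag-level wrappers working on labelled DataFrames
# ---------------------------------------------------------------------------

def fit_forest_bag(values: pd.DataFrame, labels: pd.Series, n_trees: int,
                   rng) -> BaggedForest:
    """Fit an ensemble on one bag (values restricted to the bag's samples)."""
    labels = labels.loc[values.index]
    if labels.nunique() < 2:
        raise ValidationError("single-class bag: cannot classify")
    forest = BaggedForest(n_trees=n_trees, rng=rng)
    forest.fit(values.to_numpy(), labels.to_numpy())
    return forest


def casewise_cube(forest: BaggedForest, values: pd.DataFrame, labels: pd.Series,
                  rng) -> ContributionCube:
    """Package a fitted bag's casewise scores and OOB bookkeeping."""
    labels = labels.loc[values.index]
    scores = forest.casewise_importance(rng)
    frac = forest.oob_vote_fractions()
    pred = forest.oob_predictions()
    y = np.searchsorted(forest.classes_, labels.to_numpy())
    never = np.isnan(frac).all(axis=1)  # no OOB votes at all
    seen = ~never
    correct = (pred == y) & seen
    incorrect = seen & ~correct  # vote ties count as misclassified
    tallies = pd.DataFrame({"n_correct": correct.astype(int),
                            "n_incorrect": incorrect.astype(int)},
                           index=values.index)
    return ContributionCube(
        scores=pd.DataFrame(scores, index=values.columns, columns=values.index),
        class_errors=forest.class_errors(),
        vote_fractions=pd.DataFrame(frac, index=values.index, columns=forest.classes_),
        vote_tallies=tallies,
        labels=labels,
    )
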