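"""Exact path-dependent Shapley values for decision-tree ensembles.

Implements the polynomial-time TreeSHAP recursion over a single tree,
where the conditional expectation of the model given a feature subset is
defined by the tree's own cover (training-sample weights): splits on
out-of-coalition features average the two children weighted by cover.

``brute_force_shap`` computes the same quantity by direct enumeration of
feature subsets; it is exponential in the number of features a tree uses
and exists as the independent check for the fast recursion.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np


class TreeArrays:
    """Flat-array view of one regression tree."""

    def __init__(self, children_left, children_right, feature, threshold, value, cover):
        self.children_left = np.asarray(children_left)
        self.children_right = np.asarray(children_right)
        self.feature = np.asarray(feature)
        self.threshold = np.asarray(threshold, dtype=float)
        self.value = np.asarray(value, dtype=float)
        self.cover = np.asarray(cover, dtype=float)

    @classmethod
    def from_sklearn(cls, sk_tree, class1: bool = False):
        t = sk_tree.tree_
        val = t.value[:, 0, :]
        if class1:
            # classifier trees store per-class weights; explain P(class 1)
            totals = val.sum(axis=1)
            value = np.divide(val[:, 1], totals, out=np.zeros_like(totals), where=totals > 0)
        else:
            value = val[:, 0]
        return cls(
            t.children_left,
            t.children_right,
            t.feature,
            t.threshold,
            value,
            t.weighted_n_node_samples,
        )


def _expvalue(tree: TreeArrays, x: np.ndarray, subset: frozenset, node: int = 0) -> float:
    """Cover-weighted conditional expectation given the coalition ``subset``."""
    if tree.children_left[node] == -1:
        return float(tree.value[node])
    f = tree.feature[node]
    left, right = tree.children_left[node], tree.children_right[node]
    if f in subset:
        child = left if x[f] <= tree.threshold[node] else right
        return _expvalue(tree, x, subset, child)
    wl, wr = tree.cover[left], tree.cover[right]
    return (
        wl * _expvalue(tree, x, subset, left) + wr * _expvalue(tree, x, subset, right)
    ) / (wl + wr)


def brute_force_shap(tree: TreeArrays, x: np.ndarray) -> np.ndarray:
    """Exact Shapley values by subset enumeration (oracle; small trees only)."""
    x = np.asarray(x, dtype=float)
    used = sorted({int(f) for f in tree.feature if f >= 0})
    phi = np.zeros(len(x))
    M = len(used)
    for j in used:
        others = [f for f in used if f != j]
        for size in range(M):
            for combo in combinations(others, size):
                S = frozenset(combo)
                weight = factorial(size) * factorial(M - size - 1) / factorial(M)
                phi[j] += weight * (
                    _expvalue(tree, x, S | {j}) - _expvalue(tree, x, S)
                )
    return phi


class _Path:
    """Unique-feature path with Shapley permutation weights."""

    __slots__ = ("d", "z", "o", "w")

    def __init__(self):
        self.d: list[int] = []
        self.z: list[float] = []
        self.o: list[float] = []
        self.w: list[float] = []

    def copy(self) -> "_Path":
        p = _Path()
        p.d = self.d.copy()
        p.z = self.z.copy()
        p.o = self.o.copy()
        p.w = self.w.copy()
        return p


def _extend(m: _Path, pz: float, po: float, pi: int) -> None:
    l = len(m.d)
    m.d.append(pi)
    m.z.append(pz)
    m.o.append(po)
    m.w.append(1.0 if l == 0 else 0.0)
    for i in range(l - 1, -1, -1):
        m.w[i + 1] += po * m.w[i] * (i + 1) / (l + 1)
        m.w[i] = pz * m.w[i] * (l - i) / (l + 1)


def _unwind(m: _Path, i: int) -> None:
    l = len(m.d) - 1
    n = m.w[l]
    o, z = m.o[i], m.z[i]
    for j in range(l - 1, -1, -1):
        if o != 0:
            t = m.w[j]
            m.w[j] = n * (l + 1) / ((j + 1) * o)
            n = t - m.w[j] * z * (l - j) / (l + 1)
        else:
            m.w[j] = m.w[j] * (l + 1) / (z * (l - j))
    for j in range(i, l):
        m.d[j] = m.d[j + 1]
        m.z[j] = m.z[j + 1]
        m.o[j] = m.o[j + 1]
    m.d.pop(), m.z.pop(), m.o.pop(), m.w.pop()


def _unwound_sum(m: _Path, i: int) -> float:
    """Sum of path weights after hypothetically unwinding element i."""
    l = len(m.d) - 1
    o, z = m.o[i], m.z[i]
    total = 0.0
    n = m.w[l]
    for j in range(l - 1, -1, -1):
        if o != 0:
            t = n * (l + 1) / ((j + 1) * o)
            total += t
            n = m.w[j] - t * z * (l - j) / (l + 1)
        else:
            total += m.w[j] * (l + 1) / (z * (l - j))
    return total


def tree_shap(tree: TreeArrays, x: np.ndarray, n_features: int) -> np.ndarray:
    """Exact path-dependent Shapley values for one sample and one tree."""
    x = np.asarray(x, dtype=float)
    phi = np.zeros(n_features)

    def recurse(node: int, m: _Path, pz: float, po: float, pi: int) -> None:
        m = m.copy()
        _extend(m, pz, po, pi)
        left = tree.children_left[node]
        if left == -1:
            v = float(tree.value[node])
            for i in range(1, len(m.d)):
                w = _unwound_sum(m, i)
                phi[m.d[i]] += w * (m.o[i] - m.z[i]) * v
            return
        right = tree.children_right[node]
        f = int(tree.feature[node])
        hot, cold = (
            (left, right) if x[f] <= tree.threshold[node] else (right, left)
        )
        iz, io = 1.0, 1.0
        try:
            k = m.d.index(f)
        except ValueError:
            k = -1
        if k >= 0:
            iz, io = m.z[k], m.o[k]
            _unwind(m, k)
        r = tree.cover[node]
        recurse(hot, m, iz * tree.cover[hot] / r, io, f)
        recurse(cold, m, iz * tree.cover[cold] / r, 0.0, f)

    recurse(0, _Path(), 1.0, 1.0, -1)
    return phi


def tree_expected_value(tree: TreeArrays) -> float:
    """Cover-weighted mean prediction (the tree's base value)."""
    return _expvalue(tree, np.zeros(0), frozenset())


def ensemble_shap(trees: list[TreeArrays], X: np.ndarray, average: bool = True):
    """Shapley values and base value for a forest (mean or sum of trees)."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    phi = np.zeros((n, d))
    base = 0.0
    for tree in trees:
        for i in range(n):
            phi[i] += tree_shap(tree, X[i], d)
        base += tree_expected_value(tree)
    if average:
        phi /= len(trees)
        base /= len(trees)
    return phi, base
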