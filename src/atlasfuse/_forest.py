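"""Compiled random-forest kernels for the per-voxel classifiers.

The label-fusion loop trains one small forest per ambiguous voxel — tens
of thousands of fits on ~200-sample training sets — so the whole forest
is grown by one numba kernel following Breiman's algorithm: each tree is
built on an independent bootstrap multiset of the training samples, to
purity (minimum leaf size 1), choosing at every node the best Gini split
among ``n_split`` predictors sampled uniformly at random. Thresholds are
midpoints between consecutive distinct feature values of the node's
members, and a node becomes a leaf when it is pure or no sampled
predictor varies among its members.

Because all trees of a forest share the same feature matrix, every
feature column is argsorted once per forest (a vectorized numpy argsort,
passed in by the caller); node evaluation is then a single linear pass
over the presorted order restricted to the node's in-bag members, with no
per-node sorting.
The bootstrap enters as integer sample multiplicities: out-of-bag samples
take no part in growth. Trees are exact, not approximated; the test suite
cross-checks behavior against scikit-learn's reference tree induction.

Determinism: the forest seed fixes the per-tree seeds, which fix both the
bootstrap and the per-node feature sampling.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["grow_forest", "forest_votes", "predict_tree", "tree_depth"]


@njit(cache=True)
def grow_forest(
    xt: np.ndarray,     # (F, n) float32, feature-major training matrix
    order: np.ndarray,  # (F, n) int32: per-feature argsort of the samples
    y: np.ndarray,      # (n,) uint8 labels
    n_tree: int,
    n_split: int,
    seed: int,
):
    """Grow ``n_tree`` classification trees; returns stacked flat arrays.

    Returns (feature, threshold, left, right, count0, count1, node_counts)
    where the first six are (n_tree, max_nodes) arrays and ``node_counts``
    holds each tree's used node count. Internal nodes have ``feature >= 0``
    and child indices; leaves have ``feature == -1``. ``count0/count1``
    are the per-node weighted (bootstrap-multiplicity) class counts.
    """
    n_features, n = xt.shape
    k = n_split if n_split < n_features else n_features
    max_nodes = 2 * n + 1

    feature = np.full((n_tree, max_nodes), -1, np.int32)
    threshold = np.zeros((n_tree, max_nodes), np.float64)
    left = np.full((n_tree, max_nodes), -1, np.int32)
    right = np.full((n_tree, max_nodes), -1, np.int32)
    count0 = np.zeros((n_tree, max_nodes), np.float64)
    count1 = np.zeros((n_tree, max_nodes), np.float64)
    node_counts = np.zeros(n_tree, np.int32)

    np.random.seed(seed)
    tree_seeds = np.empty(n_tree, np.int64)
    for t in range(n_tree):
        tree_seeds[t] = np.random.randint(0, 2 ** 31)

    w = np.empty(n, np.float64)       # bootstrap multiplicities
    node_of = np.empty(n, np.int32)   # current node of each in-bag sample
    cand = np.empty(k, np.int64)
    stack_node = np.empty(max_nodes, np.int32)
    stack_c0 = np.empty(max_nodes, np.float64)
    stack_c1 = np.empty(max_nodes, np.float64)

    for t in range(n_tree):
        np.random.seed(tree_seeds[t])
        for i in range(n):
            w[i] = 0.0
        for _ in range(n):
            w[np.random.randint(0, n)] += 1.0
        root0 = 0.0
        root1 = 0.0
        for i in range(n):
            if w[i] > 0.0:
                node_of[i] = 0
                if y[i] == 1:
                    root1 += w[i]
                else:
                    root0 += w[i]
            else:
                node_of[i] = -1  # out of bag

        stack_node[0] = 0
        stack_c0[0] = root0
        stack_c1[0] = root1
        top = 1
        node_count = 1

        while top > 0:
            top -= 1
            node = stack_node[top]
            c0 = stack_c0[top]
            c1 = stack_c1[top]
            count0[t, node] = c0
            count1[t, node] = c1
            if c0 == 0.0 or c1 == 0.0:
                continue  # pure leaf

            # sample k distinct candidate predictors (rejection sampling)
            nc = 0
            while nc < k:
                f = np.random.randint(0, n_features)
                dup = False
                for j in range(nc):
                    if cand[j] == f:
                        dup = True
                        break
                if not dup:
                    cand[nc] = f
                    nc += 1

            total = c0 + c1
            best_proxy = -np.inf
            best_f = -1
            best_thr = 0.0
            for ci in range(k):
                f = cand[ci]
                row = xt[f]
                ord_f = order[f]
                l0 = 0.0
                l1 = 0.0
                have_prev = False
                prev = np.float32(0.0)
                for i in range(n):
                    s = ord_f[i]
                    if node_of[s] != node:
                        continue
                    v = row[s]
                    if have_prev and v > prev:
                        nl = l0 + l1
                        nr = total - nl
                        r0 = c0 - l0
                        r1 = c1 - l1
                        # Gini proxy: maximize squared counts over side size
                        proxy = (l0 * l0 + l1 * l1) / nl \
                            + (r0 * r0 + r1 * r1) / nr
                        if proxy > best_proxy:
                            best_proxy = proxy
                            best_f = f
                            best_thr = 0.5 * (float(prev) + float(v))
                    if y[s] == 1:
                        l1 += w[s]
                    else:
                        l0 += w[s]
                    prev = v
                    have_prev = True
            if best_f < 0:
                continue  # no sampled predictor varies: impure leaf

            # partition members by the chosen split
            lid = node_count
            rid = node_count + 1
            lc0 = 0.0
            lc1 = 0.0
            row = xt[best_f]
            for i in range(n):
                if node_of[i] != node:
                    continue
                if row[i] <= best_thr:
                    node_of[i] = lid
                    if y[i] == 1:
                        lc1 += w[i]
                    else:
                        lc0 += w[i]
                else:
                    node_of[i] = rid
            rc0 = c0 - lc0
            rc1 = c1 - lc1
            if lc0 + lc1 == 0.0 or rc0 + rc1 == 0.0:
                # numerically degenerate split: revert to an impure leaf
                for i in range(n):
                    if node_of[i] == lid or node_of[i] == rid:
                        node_of[i] = node
                continue

            feature[t, node] = best_f
            threshold[t, node] = best_thr
            left[t, node] = lid
            right[t, node] = rid
            stack_node[top] = lid
            stack_c0[top] = lc0
            stack_c1[top] = lc1
            stack_node[top + 1] = rid
            stack_c0[top + 1] = rc0
            stack_c1[top + 1] = rc1
            top += 2
            node_count += 2

        node_counts[t] = node_count

    return feature, threshold, left, right, count0, count1, node_counts


@njit(cache=True)
def forest_votes(
    feature: np.ndarray,
    threshold: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    count0: np.ndarray,
    count1: np.ndarray,
    x: np.ndarray,
) -> np.ndarray:
    """Hard 0/1 decision of every tree for one feature vector (ties -> 0)."""
    n_tree = feature.shape[0]
    votes = np.empty(n_tree, np.uint8)
    for t in range(n_tree):
        node = 0
        while feature[t, node] >= 0:
            if x[feature[t, node]] <= threshold[t, node]:
                node = left[t, node]
            else:
                node = right[t, node]
        votes[t] = 1 if count1[t, node] > count0[t, node] else 0
    return votes


@njit(cache=True)
def predict_tree(
    feature: np.ndarray,
    threshold: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    count0: np.ndarray,
    count1: np.ndarray,
    x: np.ndarray,
) -> int:
    """Hard decision of a single tree in flat-array form (ties -> 0)."""
    node = 0
    while feature[node] >= 0:
        if x[feature[node]] <= threshold[node]:
            node = left[node]
        else:
            node = right[node]
    return 1 if count1[node] > count0[node] else 0


def tree_depth(left: np.ndarray, right: np.ndarray, node_count: int) -> int:
    """Depth of a tree in flat-array form (root = depth 0); for diagnostics."""
    depth = np.zeros(node_count, dtype=np.int64)
    for node in range(node_count):
        if left[node] >= 0:
            depth[left[node]] = depth[node] + 1
            depth[right[node]] = depth[node] + 1
    return int(depth.max()) if node_count else 0
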