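"""Per-voxel random-forest label fusion.

For every ambiguous voxel ``x`` (where the registered atlases disagree), a
dedicated classifier is built from the atlases' own neighborhoods: every
atlas voxel in the ``(2r+1)**3`` neighborhood of ``x`` contributes a
(feature vector, atlas label) training sample. From these candidates the
``k`` positives and ``k`` negatives whose features lie closest (Euclidean)
to the target voxel's features are kept, a random forest is trained on the
balanced subset, and the voxel's foreground probability is the fraction of
trees voting foreground:

    p(f_x) = (1/N_Tree) * sum_i T_i(f_x),   T_i in {0, 1}.

Unanimous voxels bypass classification (probability 0 or 1), so the
output probability map agrees with majority voting wherever the atlases
agree and re-decides only the ambiguous band.

Forests are scikit-learn ``RandomForestClassifier`` ensembles with
canonical settings: Gini impurity, unlimited depth, minimum leaf size 1,
bootstrap resampling of the balanced subset, and ``N_Split`` predictors
sampled per node split. Per-voxel seeds are derived deterministically from
the master seed and the voxel's linear index, so results are reproducible
under any scheduling or atlas processing order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._forest import forest_votes, grow_forest, predict_tree

from .errors import DegenerateTrainingSetError
from .features import PatchParams, extract_feature_matrix
from .io import AtlasPair, Volume, check_common_grid
from .preprocess import VotePartition

__all__ = [
    "RFParams",
    "TrainingSet",
    "ForestModel",
    "assemble_candidates",
    "select_balanced_subset",
    "train_forest",
    "predict_probability",
    "rf_segment",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RFParams:
    """Forest hyperparameters: per-class subset size ``k``, tree count
    ``N_Tree``, predictors per split ``N_Split``, and the RNG seed."""

    k: int = 100
    n_tree: int = 200
    n_split: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.n_tree < 1 or self.n_split < 1:
            raise ValueError("k, n_tree and n_split must all be >= 1")


@dataclass
class TrainingSet:
    """Feature rows with binary labels and per-sample provenance."""

    features: np.ndarray  # (n, F)
    labels: np.ndarray    # (n,) in {0, 1}
    provenance: list[tuple[str, tuple[int, int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features))
        self.labels = np.asarray(self.labels).astype(np.uint8).ravel()
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels length mismatch")
        if np.setdiff1d(self.labels, [0, 1]).size:
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return int(self.labels.shape[0])


@dataclass
class FlatTree:
    """One classification tree in flat-array form (see ``_forest``)."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    count0: np.ndarray
    count1: np.ndarray
    node_count: int

    def predict_one(self, x: np.ndarray) -> int:
        """The tree's hard 0/1 decision for one feature vector."""
        return int(
            predict_tree(
                np.ascontiguousarray(self.feature),
                np.ascontiguousarray(self.threshold),
                np.ascontiguousarray(self.left),
                np.ascontiguousarray(self.right),
                np.ascontiguousarray(self.count0),
                np.ascontiguousarray(self.count1),
                np.ascontiguousarray(x, dtype=np.float32),
            )
        )


@dataclass
class ForestModel:
    """A trained forest in stacked flat-array form, plus metadata.

    The six stacked arrays are (N_Tree, max_nodes); ``trees`` exposes
    per-tree views for inspection and tree-by-tree vote checks.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    count0: np.ndarray
    count1: np.ndarray
    node_counts: np.ndarray
    params: RFParams
    n_pos: int
    n_neg: int
    n_features: int

    @property
    def n_trees(self) -> int:
        return int(self.feature.shape[0])

    @property
    def trees(self) -> list[FlatTree]:
        return [
            FlatTree(
                self.feature[t], self.threshold[t], self.left[t],
                self.right[t], self.count0[t], self.count1[t],
                int(self.node_counts[t]),
            )
            for t in range(self.n_trees)
        ]


def _neighborhood_offsets(r: int) -> np.ndarray:
    """Lexicographically ordered (2r+1)**3 integer offsets."""
    rng = np.arange(-r, r + 1)
    return np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)


def assemble_candidates(
    atlases: list[AtlasPair],
    x: tuple[int, int, int],
    params: PatchParams | None = None,
) -> TrainingSet:
    """All candidate training samples for voxel ``x``.

    For each atlas (in order) and each neighborhood offset (lexicographic),
    the candidate is the feature vector of the atlas voxel ``x + offset``
    with that voxel's atlas label: exactly ``(2r+1)**3 * N`` samples.
    Neighbor indices are clamped to the volume extent (edge replication),
    matching the patch-extraction convention.
    """
    params = params or PatchParams()
    if not atlases:
        raise ValueError("no atlases given")
    shape = atlases[0].intensity.shape
    x = np.asarray(x, dtype=np.intp)
    nb = np.clip(x[None, :] + _neighborhood_offsets(params.r),
                 0, np.asarray(shape) - 1)
    feats, labels, prov = [], [], []
    for pair in atlases:
        feats.append(extract_feature_matrix(pair.intensity, nb, params))
        labels.append(pair.label.data[nb[:, 0], nb[:, 1], nb[:, 2]])
        prov.extend((pair.id, tuple(int(v) for v in v3)) for v3 in nb)
    return TrainingSet(np.concatenate(feats), np.concatenate(labels), prov)


def _balanced_indices(
    features: np.ndarray, labels: np.ndarray, target_feature: np.ndarray, k: int
) -> np.ndarray:
    """Indices of the <=k nearest candidates per class (stable ties)."""
    diff = features - np.asarray(target_feature, dtype=features.dtype)[None, :]
    d2 = (diff * diff).sum(axis=1, dtype=np.float64)
    picked = []
    for cls in (1, 0):
        idx = np.flatnonzero(labels == cls)
        order = idx[np.argsort(d2[idx], kind="stable")][:k]
        picked.append(order)
    return np.concatenate(picked)


def select_balanced_subset(
    candidates: TrainingSet, target_feature: np.ndarray, k: int
) -> TrainingSet:
    """The ``k`` most similar positives and ``k`` most similar negatives.

    Similarity is Euclidean distance in feature space; ties are broken by
    candidate order (stable). If a class has fewer than ``k`` candidates,
    all of that class are taken and a shortage is logged; if a class is
    entirely absent a :class:`DegenerateTrainingSetError` is raised so the
    caller can fall back to the unanimous label.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate set")
    labels = candidates.labels
    n_pos, n_neg = int((labels == 1).sum()), int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateTrainingSetError(
            f"single-class candidate set (pos={n_pos}, neg={n_neg})"
        )
    if min(n_pos, n_neg) < k:
        log.debug("class shortage: pos=%d neg=%d < k=%d", n_pos, n_neg, k)
    sel = _balanced_indices(candidates.features, labels, target_feature, k)
    prov = [candidates.provenance[i] for i in sel] if candidates.provenance else []
    return TrainingSet(candidates.features[sel], labels[sel], prov)


def train_forest(training: TrainingSet, params: RFParams) -> ForestModel:
    """Fit ``N_Tree`` classification trees, each on a bootstrap resample.

    Each tree is grown on an independent bootstrap multiset of the
    training samples with ``N_Split`` predictors sampled per node (see
    :mod:`atlasfuse._forest`); per-tree seeds derive from ``params.seed``,
    so the forest is deterministic given the seed.
    """
    labels = training.labels
    n_pos, n_neg = int((labels == 1).sum()), int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateTrainingSetError(
            f"cannot train on a single class (pos={n_pos}, neg={n_neg})"
        )
    x = np.asarray(training.features, dtype=np.float32)
    if not np.isfinite(x).all():
        raise ValueError("non-finite feature values in training set")
    xt = np.ascontiguousarray(x.T)  # feature-major for the tree kernels
    order = np.argsort(xt, axis=1).astype(np.int32)  # shared by all trees
    y = np.ascontiguousarray(labels, dtype=np.uint8)
    n_split = min(params.n_split, x.shape[1])
    arrays = grow_forest(
        xt, order, y, params.n_tree, n_split, params.seed % (2 ** 31)
    )
    return ForestModel(*arrays, params, n_pos, n_neg, x.shape[1])


def tree_votes(model: ForestModel, f_x: np.ndarray) -> np.ndarray:
    """The hard 0/1 decision of every tree for one feature vector."""
    f_x = np.ascontiguousarray(f_x, dtype=np.float32).ravel()
    if f_x.shape[0] != model.n_features:
        raise ValueError(
            f"feature dimension {f_x.shape[0]} != model dimension {model.n_features}"
        )
    return forest_votes(
        model.feature, model.threshold, model.left, model.right,
        model.count0, model.count1, f_x,
    )


def predict_probability(model: ForestModel, f_x: np.ndarray) -> float:
    """Foreground probability = fraction of trees voting foreground.

    Each tree casts the hard 0/1 decision of the leaf ``f_x`` falls into,
    so the result lies on the ``1/N_Tree`` lattice exactly as the vote
    average defines it.
    """
    votes = tree_votes(model, f_x)
    return float(votes.sum()) / votes.shape[0]


def voxel_seed(master_seed: int, linear_index: int) -> int:
    """Deterministic per-voxel RNG seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(linear_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def rf_segment(
    target: Volume,
    atlases: list[AtlasPair],
    partition: VotePartition,
    patch_params: PatchParams | None = None,
    rf_params: RFParams | None = None,
) -> Volume:
    """Probabilistic segmentation of the target.

    Unanimous-foreground voxels get probability 1, unanimous-background 0
    (the majority-voting short-circuit); each ambiguous voxel gets the
    vote-fraction probability of its own forest; voxels outside the
    bounding box get 0. Thresholding at 0.5 yields the hard RF result.

    Atlas features are computed in bulk for the neighborhood-dilated
    ambiguous set — a candidate's features depend only on the atlas voxel,
    not on which target voxel is being decided — which is what makes the
    per-voxel-forest loop tractable.
    """
    patch_params = patch_params or PatchParams()
    rf_params = rf_params or RFParams()
    if not atlases:
        raise ValueError("no atlases given")
    check_common_grid([target] + [a.intensity for a in atlases])

    shape = target.shape
    prob = np.zeros(shape, dtype=np.float32)
    prob[partition.unanimous_fg] = 1.0

    amb = np.argwhere(partition.ambiguous)
    if amb.shape[0] == 0:
        return Volume(prob, target.affine, name="rf_probability")

    offsets = _neighborhood_offsets(patch_params.r)
    nb = np.clip(amb[:, None, :] + offsets[None, :, :],
                 0, np.asarray(shape) - 1)            # (M, K, 3)
    nb_lin = np.ravel_multi_index(
        (nb[..., 0], nb[..., 1], nb[..., 2]), shape)  # (M, K)
    needed = np.unique(nb_lin)
    nb_rows = np.searchsorted(needed, nb_lin)         # rows into per-atlas arrays
    needed_ijk = np.stack(np.unravel_index(needed, shape), axis=1)

    log.info(
        "rf_segment: %d ambiguous voxels, %d atlas voxels featured per atlas",
        amb.shape[0], needed.shape[0],
    )
    atlas_feats = [
        extract_feature_matrix(p.intensity, needed_ijk, patch_params) for p in atlases
    ]
    atlas_labels = [p.label.data.ravel()[needed] for p in atlases]
    target_feats = extract_feature_matrix(target, amb, patch_params)

    n_degenerate = 0
    for m in range(amb.shape[0]):
        rows = nb_rows[m]
        feats = np.concatenate([af[rows] for af in atlas_feats])
        labels = np.concatenate([al[rows] for al in atlas_labels])
        f_t = target_feats[m]
        n_pos = int((labels == 1).sum())
        if n_pos == 0 or n_pos == labels.shape[0]:
            # all candidates agree: take that class directly
            prob[tuple(amb[m])] = 1.0 if n_pos else 0.0
            n_degenerate += 1
            continue
        sel = _balanced_indices(feats, labels, f_t, rf_params.k)
        lin = int(np.ravel_multi_index(tuple(amb[m]), shape))
        seed = voxel_seed(rf_params.seed, lin)
        model = train_forest(
            TrainingSet(feats[sel], labels[sel]),
            RFParams(rf_params.k, rf_params.n_tree, rf_params.n_split, seed),
        )
        prob[tuple(amb[m])] = predict_probability(model, f_t)
    if n_degenerate:
        log.debug("rf_segment: %d voxels had single-class candidates", n_degenerate)
    return Volume(prob, target.affine, name="rf_probability")
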