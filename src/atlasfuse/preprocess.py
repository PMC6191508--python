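"""Bounding box, atlas selection by NMI, and majority voting.

Per-voxel label fusion is expensive, so all computation is restricted to a
bounding box guaranteed to contain the structure: the union of the
registered atlas foregrounds dilated by a margin (default 10 voxels).
Within the box, the most similar atlases are chosen by ranking normalized
mutual information (NMI) against the target, majority voting produces an
initial segmentation, and only the voxels where the atlases disagree
(ambiguous voxels) are re-decided by the learned fusion downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .io import AtlasPair, LabelVolume, Volume, check_common_grid

__all__ = [
    "BoundingBox",
    "VotePartition",
    "compute_bounding_box",
    "normalized_mutual_information",
    "select_atlases",
    "majority_vote",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned voxel box, lower inclusive / upper exclusive, 0-based."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not all(l < u for l, u in zip(self.lower, self.upper)):
            raise ValueError(f"degenerate bounding box {self.lower}..{self.upper}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, u) for l, u in zip(self.lower, self.upper))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(u - l for l, u in zip(self.lower, self.upper))

    @property
    def volume(self) -> int:
        return int(np.prod(self.shape))

    def to_json(self) -> str:
        return json.dumps([*self.lower, *self.upper])

    @classmethod
    def from_json(cls, s: str) -> "BoundingBox":
        v = json.loads(s)
        return cls(tuple(v[:3]), tuple(v[3:]))


@dataclass
class VotePartition:
    """Majority-voting outcome: vote fractions and the three disjoint masks.

    ``vote_map`` holds, per voxel inside the box, the fraction of atlases
    voting foreground (0 outside the box). ``unanimous_fg``/``unanimous_bg``
    mark box voxels with 100% agreement; ``ambiguous`` marks the rest of the
    box. The three masks partition the box.
    """

    box: BoundingBox
    vote_map: np.ndarray
    unanimous_fg: np.ndarray
    unanimous_bg: np.ndarray
    ambiguous: np.ndarray
    n_atlases: int

    def hard_segmentation(self) -> np.ndarray:
        """Majority-vote labels: vote fraction >= 0.5 -> foreground.

        Ties (exactly 0.5) go to foreground — a fixed convention that only
        matters for the even-N baseline; 0.5-vote voxels are ambiguous and
        re-decided downstream in the learned pipelines.
        """
        out = np.zeros(self.vote_map.shape, dtype=np.uint8)
        sl = self.box.slices
        out[sl] = (self.vote_map[sl] >= 0.5).astype(np.uint8)
        return out


def compute_bounding_box(
    atlas_labels: list[LabelVolume], margin: int = 10
) -> BoundingBox:
    """Margin-dilated bounding box of the union of atlas foregrounds,
    clipped to the image extent."""
    if not atlas_labels:
        raise ValueError("no atlas labels given")
    union = np.zeros(atlas_labels[0].shape, dtype=bool)
    for lab in atlas_labels:
        union |= lab.data > 0
    if not union.any():
        raise ValueError("all atlas labels are empty; cannot derive a bounding box")
    idx = np.argwhere(union)
    lower = np.maximum(idx.min(axis=0) - margin, 0)
    upper = np.minimum(idx.max(axis=0) + 1 + margin, union.shape)
    return BoundingBox(tuple(int(v) for v in lower), tuple(int(v) for v in upper))


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def normalized_mutual_information(
    a: Volume, b: Volume, box: BoundingBox | None = None, bins: int = 32
) -> float:
    """NMI = (H(A) + H(B)) / H(A, B) from a joint histogram inside the box.

    Histograms use ``bins`` equal-width bins spanning each image's min-max
    inside the box; entropies are in nats with 0*log(0) := 0. The score is
    2 for identical (or monotonically rescaled, bin-aligned) images and
    approaches 1 for independent ones. A constant image carries no
    information: NMI is defined as 1 and a warning is logged.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    sl = box.slices if box is not None else (slice(None),) * 3
    av = np.asarray(a.data[sl], dtype=np.float64).ravel()
    bv = np.asarray(b.data[sl], dtype=np.float64).ravel()
    if av.min() == av.max() or bv.min() == bv.max():
        log.warning("NMI: constant image inside the box; returning 1.0")
        return 1.0
    joint, _, _ = np.histogram2d(av, bv, bins=bins)
    pxy = joint / joint.sum()
    hx = _entropy(pxy.sum(axis=1))
    hy = _entropy(pxy.sum(axis=0))
    hxy = _entropy(pxy.ravel())
    return (hx + hy) / hxy


def select_atlases(
    target: Volume,
    library: list[AtlasPair],
    box: BoundingBox | None = None,
    n_select: int = 20,
    bins: int = 32,
) -> list[AtlasPair]:
    """Rank the atlas library by NMI against the target inside the box and
    return the ``n_select`` most similar pairs.

    Ordering is by decreasing NMI with ties broken by library order
    (stable sort), so the selection is permutation-equivariant up to ties.
    """
    if not library:
        raise ValueError("empty atlas library")
    if len(library) < n_select:
        log.warning(
            "atlas library has only %d pairs (< n_select=%d); returning all",
            len(library), n_select,
        )
    scores = np.asarray(
        [normalized_mutual_information(target, p.intensity, box, bins) for p in library]
    )
    order = np.argsort(-scores, kind="stable")[:n_select]
    return [library[i] for i in order]


def majority_vote(
    atlas_labels: list[LabelVolume], box: BoundingBox
) -> VotePartition:
    """Vote fractions and the unanimous/ambiguous partition inside the box."""
    if not atlas_labels:
        raise ValueError("no atlas labels given")
    check_common_grid(atlas_labels)
    shape = atlas_labels[0].shape
    sl = box.slices
    counts = np.zeros(box.shape, dtype=np.int64)
    for lab in atlas_labels:
        counts += lab.data[sl] > 0
    n = len(atlas_labels)
    vote_box = counts / float(n)

    vote_map = np.zeros(shape, dtype=np.float32)
    vote_map[sl] = vote_box.astype(np.float32)

    in_box = np.zeros(shape, dtype=bool)
    in_box[sl] = True
    fg = np.zeros(shape, dtype=bool)
    bg = np.zeros(shape, dtype=bool)
    fg[sl] = counts == n
    bg[sl] = counts == 0
    amb = in_box & ~fg & ~bg
    return VotePartition(box, vote_map, fg, bg, amb, n)
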