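"""Segmentation accuracy metrics between a manual label A and a result B.

Four overlap ratios (Dice, Jaccard, Precision, Recall) are voxel-count
ratios; five distances (MD, HD, HD95, ASSD, RMSD) are Euclidean surface
distances in mm, computed between boundary voxel sets. Definitions:

    Dice      = 2|A n B| / (|A| + |B|)
    Jaccard   = |A n B| / |A u B|
    Precision = |A n B| / |B|
    Recall    = |A n B| / |A|
    MD        = mean_{e in dA} min_{f in dB} d(e, f)        (directed A->B)
    HD        = max(H(A,B), H(B,A)),  H(A,B) = max_{e in dA} min_{f in dB} d(e,f)
    HD95      = HD after removing the largest 5% of each directed distance set
    ASSD      = (mean_{dA} min d + mean_{dB} min d) / 2
    RMSD      = sqrt((D_A^2 + D_B^2) / (|dA| + |dB|)),
                D_A^2 = sum_{e in dA} min_f d(e, f)^2

The boundary dA is the set of foreground voxels with at least one
6-connected background neighbor (the image border counts as background);
boundary coordinates are voxel index times spacing, in mm. MD is directed
manual -> automatic and is not symmetrized. HD95 trims the ceil(0.05 n)
largest distances from each directed set (keeping at least one) before
taking the max of the two directed maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from math import ceil, sqrt

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyMaskError
from .io import LabelVolume, check_common_grid

__all__ = [
    "MetricsReport",
    "overlap_metrics",
    "extract_surface",
    "distance_metrics",
    "evaluate",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = (
    "dice", "jaccard", "precision", "recall", "md", "hd", "hd95", "assd", "rmsd",
)


@dataclass(frozen=True)
class MetricsReport:
    """The nine metrics: overlap ratios in [0, 1], distances in mm."""

    dice: float
    jaccard: float
    precision: float
    recall: float
    md: float
    hd: float
    hd95: float
    assd: float
    rmsd: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def overlap_metrics(A: LabelVolume, B: LabelVolume) -> tuple[float, float, float, float]:
    """(Dice, Jaccard, Precision, Recall) between manual A and result B."""
    check_common_grid([A, B], ids=["A", "B"])
    a = A.data > 0
    b = B.data > 0
    va, vb = int(a.sum()), int(b.sum())
    if va == 0:
        raise EmptyMaskError("manual label A is empty")
    if vb == 0:
        raise EmptyMaskError("automatic result B is empty")
    inter = int((a & b).sum())
    union = va + vb - inter
    return (
        2.0 * inter / (va + vb),
        inter / union,
        inter / vb,
        inter / va,
    )


def extract_surface(M: LabelVolume) -> np.ndarray:
    """Boundary voxel coordinates in mm.

    A boundary voxel is a foreground voxel with at least one 6-connected
    background neighbor; voxels on the image border always qualify.
    Returns an (n, 3) float array of index * spacing.
    """
    mask = M.data > 0
    if not mask.any():
        raise EmptyMaskError("cannot extract the surface of an empty mask")
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    interior = np.ones_like(mask)
    for axis in range(3):
        for step in (-1, 1):
            interior &= np.roll(padded, step, axis=axis)[1:-1, 1:-1, 1:-1]
    boundary = mask & ~interior
    coords = np.argwhere(boundary).astype(np.float64)
    return coords * np.asarray(M.spacing)[None, :]


def _trim_largest(d: np.ndarray) -> np.ndarray:
    """Drop the ceil(5% of n) largest values, keeping at least one."""
    n = d.size
    m = ceil(0.05 * n)
    kept = np.sort(d)[: max(n - m, 1)]
    return kept


def distance_metrics(
    A: LabelVolume, B: LabelVolume
) -> tuple[float, float, float, float, float]:
    """(MD, HD, HD95, ASSD, RMSD) in mm between manual A and result B."""
    check_common_grid([A, B], ids=["A", "B"])
    sa = extract_surface(A)
    sb = extract_surface(B)
    d_ab = cKDTree(sb).query(sa)[0]  # for each boundary voxel of A
    d_ba = cKDTree(sa).query(sb)[0]
    md = float(d_ab.mean())
    hd = float(max(d_ab.max(), d_ba.max()))
    hd95 = float(max(_trim_largest(d_ab).max(), _trim_largest(d_ba).max()))
    assd = float((d_ab.mean() + d_ba.mean()) / 2.0)
    rmsd = sqrt(((d_ab ** 2).sum() + (d_ba ** 2).sum()) / (sa.shape[0] + sb.shape[0]))
    return md, hd, hd95, assd, rmsd


def evaluate(A: LabelVolume, B: LabelVolume) -> MetricsReport:
    """All nine metrics between manual label A and automatic result B."""
    dice, jac, prec, rec = overlap_metrics(A, B)
    md, hd, hd95, assd, rmsd = distance_metrics(A, B)
    return MetricsReport(dice, jac, prec, rec, md, hd, hd95, assd, rmsd)
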