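"""Patch-based texture feature extraction.

Every voxel is characterized by its cubic neighborhood patch of side
``2*r_s + 1`` (default 7x7x7). The patch is z-scored (mean 0, sd 1) and a
bank of discrete texture filters is evaluated at every patch position; the
normalized intensities and all filter responses are concatenated into one
fixed-length feature vector. The same pipeline is applied identically to
the target image and to every atlas image, so features are comparable
across volumes.

Because the z-scoring precedes filtering, the whole feature vector is
invariant to positive affine intensity transforms ``a*I + b`` (a > 0) of
the patch — the property that makes the features robust to the per-subject
intensity discrepancies that registration cannot remove.

Filter bank (all applied to the normalized patch, edge replication at the
patch border, one full response map per family and axis):

* first-order central differences along each axis, ``(f[+1]-f[-1])/2``;
* second-order differences along each axis, ``f[+1]-2f[0]+f[-1]``;
* hyperplane filters: mean over the 3x3 plane perpendicular to each axis
  minus the center value;
* 3D Sobel along each axis (derivative ``[-1,0,1]`` smoothed by
  ``[1,2,1]`` in the two orthogonal axes);
* 27-point discrete Laplacian (26 neighbors weight 1, center -26);
* range filter: local max minus local min over the 3x3x3 neighborhood.

With the default radius the vector has 15 blocks of 343 values = 5145
features. The block layout is frozen by :func:`feature_layout` and a
golden-layout test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Volume

__all__ = [
    "PatchParams",
    "feature_layout",
    "extract_patch",
    "normalize_patch",
    "filter_bank",
    "extract_feature_vector",
    "extract_feature_matrix",
]

#: guard below which a patch is treated as constant during z-scoring
_SD_GUARD = 1e-12


@dataclass(frozen=True)
class PatchParams:
    """Patch radius ``r_s`` (feature patches) and neighborhood radius ``r``
    (training-sample neighborhoods), both in voxels."""

    r_s: int = 3
    r: int = 1

    def __post_init__(self) -> None:
        if self.r_s < 1:
            raise ValueError("r_s must be >= 1")
        if self.r < 0:
            raise ValueError("r must be >= 0")

    @property
    def side(self) -> int:
        return 2 * self.r_s + 1


# Block names in concatenation order; each block spans one full patch map.
_BLOCK_NAMES = (
    "intensity",
    "diff1_x", "diff1_y", "diff1_z",
    "diff2_x", "diff2_y", "diff2_z",
    "hyperplane_x", "hyperplane_y", "hyperplane_z",
    "sobel_x", "sobel_y", "sobel_z",
    "laplacian",
    "range",
)


def feature_layout(params: PatchParams | None = None) -> list[tuple[str, int]]:
    """Ordered ``(block name, length)`` pairs describing the feature vector."""
    params = params or PatchParams()
    n = params.side ** 3
    return [(name, n) for name in _BLOCK_NAMES]


def feature_length(params: PatchParams | None = None) -> int:
    return sum(n for _, n in feature_layout(params))


def extract_patch(volume: Volume, center: tuple[int, int, int], r_s: int) -> np.ndarray:
    """Extract the ``(2*r_s+1)**3`` patch centered at a voxel.

    Out-of-bounds positions are filled by edge replication, so patches near
    the volume border keep the full size.
    """
    center = tuple(int(c) for c in center)
    shape = volume.shape
    for axis, c in enumerate(center):
        if not 0 <= c < shape[axis]:
            raise IndexError(f"patch center {center} outside volume of shape {shape}")
    padded = np.pad(volume.data, r_s, mode="edge")
    sl = tuple(slice(c, c + 2 * r_s + 1) for c in center)
    return np.asarray(padded[sl], dtype=np.float64)


def normalize_patch(patch: np.ndarray) -> np.ndarray:
    """Z-score a patch; a constant patch maps to all zeros."""
    patch = np.asarray(patch, dtype=np.float64)
    sd = patch.std()
    if sd < _SD_GUARD:
        return np.zeros_like(patch)
    return (patch - patch.mean()) / sd


def _pad1(patches: np.ndarray) -> np.ndarray:
    """Edge-replicate a (M, s, s, s) patch stack by 1 voxel per spatial axis."""
    return np.pad(patches, ((0, 0), (1, 1), (1, 1), (1, 1)), mode="edge")


def _tap(padded: np.ndarray, d: tuple[int, int, int], side: int) -> np.ndarray:
    """View of the padded stack shifted by offset d, same shape as the patch."""
    return padded[
        :,
        1 + d[0]: 1 + d[0] + side,
        1 + d[1]: 1 + d[1] + side,
        1 + d[2]: 1 + d[2] + side,
    ]


def _axis_offset(axis: int, step: int) -> tuple[int, int, int]:
    d = [0, 0, 0]
    d[axis] = step
    return tuple(d)  # type: ignore[return-value]


def _filter_bank_stack(norm: np.ndarray) -> dict[str, np.ndarray]:
    """Filter responses for a stack of normalized patches (M, s, s, s)."""
    side = norm.shape[1]
    if side < 3:
        raise ValueError("filter bank requires patch side >= 3")
    p = _pad1(norm)
    c = _tap(p, (0, 0, 0), side)
    out: dict[str, np.ndarray] = {"intensity": norm}

    for axis, ax_name in enumerate("xyz"):
        plus = _tap(p, _axis_offset(axis, 1), side)
        minus = _tap(p, _axis_offset(axis, -1), side)
        out[f"diff1_{ax_name}"] = (plus - minus) / 2.0
        out[f"diff2_{ax_name}"] = plus - 2.0 * c + minus

    # hyperplane: mean over the 3x3 plane with zero offset along `axis`
    for axis, ax_name in enumerate("xyz"):
        acc = np.zeros_like(c)
        for u in (-1, 0, 1):
            for v in (-1, 0, 1):
                d = [0, 0, 0]
                other = [a for a in range(3) if a != axis]
                d[other[0]], d[other[1]] = u, v
                acc += _tap(p, tuple(d), side)
        out[f"hyperplane_{ax_name}"] = acc / 9.0 - c

    # 3D Sobel: derivative [-1,0,1] along `axis`, smoothing [1,2,1] elsewhere
    smooth = {-1: 1.0, 0: 2.0, 1: 1.0}
    for axis, ax_name in enumerate("xyz"):
        acc = np.zeros_like(c)
        other = [a for a in range(3) if a != axis]
        for step in (-1, 1):
            for u in (-1, 0, 1):
                for v in (-1, 0, 1):
                    d = [0, 0, 0]
                    d[axis] = step
                    d[other[0]], d[other[1]] = u, v
                    acc += step * smooth[u] * smooth[v] * _tap(p, tuple(d), side)
        out[f"sobel_{ax_name}"] = acc

    lap = -26.0 * c
    mx = c.copy()
    mn = c.copy()
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                t = _tap(p, (dx, dy, dz), side)
                lap = lap + t
                np.maximum(mx, t, out=mx)
                np.minimum(mn, t, out=mn)
    out["laplacian"] = lap
    out["range"] = mx - mn
    return out


def filter_bank(normalized_patch: np.ndarray) -> dict[str, np.ndarray]:
    """Evaluate the texture filter bank on one normalized patch.

    Returns a dict keyed by block name (see :func:`feature_layout`), each
    value a response map of the patch's shape. ``intensity`` is the input
    itself, included so the dict carries the full feature layout.
    """
    stack = np.asarray(normalized_patch, dtype=np.float64)[None]
    return {k: v[0] for k, v in _filter_bank_stack(stack).items()}


def _features_from_patches(patches: np.ndarray) -> np.ndarray:
    """(M, s, s, s) raw patches -> (M, F) feature matrix, float32.

    The z-scoring statistics are accumulated in float64; the normalized
    patches and filter responses are float32, which is ample for texture
    features and halves the memory traffic of the batch path.
    """
    m = patches.mean(axis=(1, 2, 3), keepdims=True, dtype=np.float64)
    sd = patches.std(axis=(1, 2, 3), keepdims=True, dtype=np.float64)
    norm = np.where(
        sd > _SD_GUARD, (patches - m) / np.maximum(sd, _SD_GUARD), 0.0
    ).astype(np.float32)
    responses = _filter_bank_stack(norm)
    n = patches.shape[0]
    blocks = [responses[name].reshape(n, -1) for name in _BLOCK_NAMES]
    return np.concatenate(blocks, axis=1, dtype=np.float32)


def extract_feature_matrix(
    volume: Volume, voxels: np.ndarray, params: PatchParams | None = None
) -> np.ndarray:
    """Feature vectors for many voxels at once.

    Parameters
    ----------
    volume
        Source image.
    voxels
        (M, 3) integer voxel indices.
    params
        Patch parameters; defaults to ``PatchParams()``.

    Returns
    -------
    (M, F) float32 matrix, rows ordered as ``voxels``.
    """
    params = params or PatchParams()
    voxels = np.atleast_2d(np.asarray(voxels, dtype=np.intp))
    shape = volume.shape
    if voxels.size and (
        (voxels < 0).any() or (voxels >= np.asarray(shape)).any()
    ):
        raise IndexError("voxel index outside volume")
    r = params.r_s
    padded = np.pad(np.asarray(volume.data, dtype=np.float32), r, mode="edge")
    windows = np.lib.stride_tricks.sliding_window_view(
        padded, (params.side,) * 3
    )
    patches = windows[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
    return _features_from_patches(np.ascontiguousarray(patches))


def extract_feature_vector(
    volume: Volume, voxel: tuple[int, int, int], params: PatchParams | None = None
) -> np.ndarray:
    """The feature vector of a single voxel (1D float32, length F)."""
    return extract_feature_matrix(volume, np.asarray([voxel]), params)[0]
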