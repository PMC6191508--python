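"""Synthetic phantoms and atlas libraries for download-free testing.

The generator emulates the statistical structure the fusion method
assumes, at desk scale: a smooth blob-shaped foreground (an ellipsoid with
a low-frequency boundary perturbation) standing in for the hippocampus,
distinct foreground/background intensity means on a 0-255-like grayscale
(so the default similarity scale sigma = 10 is meaningful), a smooth
multiplicative bias field, and i.i.d. Gaussian noise. Each atlas is the
ground truth warped by an independent Gaussian-smoothed random
displacement field (standing in for residual registration error) followed
by a per-atlas affine intensity perturbation (gain/offset, standing in for
inter-subject intensity discrepancy) and fresh noise.

Everything is deterministic given the seeds; no global RNG state is
touched. What the phantoms do not emulate: real anatomy, MRI physics
(Rician noise, partial-volume effects beyond linear interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .io import AtlasPair, LabelVolume, Volume

__all__ = [
    "PhantomSpec",
    "AtlasLibrarySpec",
    "make_phantom",
    "make_atlas_library",
    "make_dataset",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of one synthetic target.

    Intensities are on a 0-255-like scale; the blob is an ellipsoid of the
    given radii whose implicit surface is perturbed by a smooth random
    field of relative amplitude ``perturb_amp``.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    center: tuple[float, float, float] = (16.0, 16.0, 16.0)
    radii: tuple[float, float, float] = (8.0, 6.0, 5.0)
    bg_mean: float = 80.0
    fg_mean: float = 160.0
    noise_sd: float = 10.0
    bias_amp: float = 0.05
    bias_smooth: float = 8.0
    perturb_amp: float = 0.1
    perturb_smooth: float = 6.0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fg_mean == self.bg_mean:
            raise ValueError("foreground and background means must differ")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        for c, r, s in zip(self.center, self.radii, self.shape):
            if c - r < 0 or c + r > s - 1:
                raise ValueError("blob must lie strictly inside the grid")


@dataclass(frozen=True)
class AtlasLibrarySpec:
    """Atlas count and the perturbations applied to the ground truth.

    ``deform_amp`` is the standard deviation of the voxel displacement
    magnitude (in voxels); ``deform_smooth`` the Gaussian smoothing sd of
    the random field. Gain/offset ranges are sampled uniformly per atlas.
    """

    n_atlases: int = 10
    deform_amp: float = 2.0
    deform_smooth: float = 4.0
    gain_range: tuple[float, float] = (0.9, 1.1)
    offset_range: tuple[float, float] = (-10.0, 10.0)
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atlases < 1:
            raise ValueError("need at least one atlas")
        if self.deform_amp < 0:
            raise ValueError("deformation amplitude must be >= 0")


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _smooth_unit_field(
    rng: np.random.Generator, shape: tuple[int, int, int], smooth: float
) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to unit standard deviation."""
    field = gaussian_filter(rng.standard_normal(shape), smooth, mode="nearest")
    sd = field.std()
    return field / sd if sd > 0 else field


def make_phantom(spec: PhantomSpec) -> tuple[Volume, LabelVolume]:
    """One target phantom: intensity volume and its ground-truth label."""
    rng = np.random.default_rng(spec.seed)
    grids = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in spec.shape),
                        indexing="ij")
    implicit = sum(
        ((g - c) / r) ** 2 for g, c, r in zip(grids, spec.center, spec.radii)
    )
    if spec.perturb_amp > 0:
        implicit = implicit + spec.perturb_amp * _smooth_unit_field(
            rng, spec.shape, spec.perturb_smooth
        )
    mask = (implicit <= 1.0).astype(np.uint8)

    intensity = np.where(mask > 0, spec.fg_mean, spec.bg_mean).astype(np.float64)
    if spec.bias_amp > 0:
        bias = 1.0 + spec.bias_amp * _smooth_unit_field(
            rng, spec.shape, spec.bias_smooth
        )
        intensity *= bias
    if spec.noise_sd > 0:
        intensity += spec.noise_sd * rng.standard_normal(spec.shape)

    aff = _affine(spec.spacing)
    return (
        Volume(intensity.astype(np.float32), aff, name="phantom"),
        LabelVolume(mask, aff, name="phantom_label"),
    )


def _warp(
    data: np.ndarray, disp: np.ndarray, order: int
) -> np.ndarray:
    coords = np.meshgrid(*(np.arange(s, dtype=np.float64) for s in data.shape),
                         indexing="ij")
    sample = [c + d for c, d in zip(coords, disp)]
    return map_coordinates(data.astype(np.float64), sample, order=order,
                           mode="nearest")


def make_atlas_library(
    truth: tuple[Volume, LabelVolume], spec: AtlasLibrarySpec
) -> list[AtlasPair]:
    """Independent warped/perturbed copies of the ground truth."""
    vol, lab = truth
    rng = np.random.default_rng(spec.seed)
    shape = vol.shape
    # per-component sd so the displacement-magnitude sd equals deform_amp
    comp_sd = spec.deform_amp / np.sqrt(3.0)
    pairs = []
    for i in range(spec.n_atlases):
        disp = np.stack(
            [comp_sd * _smooth_unit_field(rng, shape, spec.deform_smooth)
             for _ in range(3)]
        )
        if spec.deform_amp == 0:
            disp[:] = 0.0
        warped_int = _warp(vol.data, disp, order=1)
        warped_lab = _warp(lab.data, disp, order=0)
        gain = rng.uniform(*spec.gain_range)
        offset = rng.uniform(*spec.offset_range)
        intensity = gain * warped_int + offset
        if spec.noise_sd > 0:
            intensity += spec.noise_sd * rng.standard_normal(shape)
        pairs.append(
            AtlasPair(
                Volume(intensity.astype(np.float32), vol.affine,
                       name=f"atlas_{i:02d}"),
                LabelVolume(np.rint(warped_lab).astype(np.uint8), vol.affine,
                            name=f"atlas_{i:02d}_label"),
                id=f"atlas_{i:02d}",
            )
        )
    return pairs


def make_dataset(
    n_subjects: int,
    phantom_spec: PhantomSpec | None = None,
    library_spec: AtlasLibrarySpec | None = None,
    master_seed: int = 0,
) -> list[tuple[Volume, LabelVolume, list[AtlasPair]]]:
    """Independent (target, truth, atlas library) triples per subject.

    Per-subject blob centers and radii are jittered slightly so truths are
    distinct; all randomness derives from ``master_seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    phantom_spec = phantom_spec or PhantomSpec()
    library_spec = library_spec or AtlasLibrarySpec()
    root = np.random.SeedSequence(master_seed)
    subjects = []
    for child in root.spawn(n_subjects):
        jitter_rng = np.random.default_rng(child)
        seeds = child.generate_state(2) % (2 ** 31)
        center = tuple(
            float(c + jitter_rng.uniform(-1.5, 1.5)) for c in phantom_spec.center
        )
        radii = tuple(
            float(max(2.0, r + jitter_rng.uniform(-1.0, 1.0)))
            for r in phantom_spec.radii
        )
        p_spec = replace(phantom_spec, center=center, radii=radii,
                         seed=int(seeds[0]))
        l_spec = replace(library_spec, seed=int(seeds[1]))
        vol, lab = make_phantom(p_spec)
        atlases = make_atlas_library((vol, lab), l_spec)
        subjects.append((vol, lab, atlases))
    return subjects
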