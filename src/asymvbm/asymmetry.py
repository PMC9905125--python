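"""Hemispheric asymmetry mapping.

Implements the flipped-segment asymmetry-index protocol: left-right
flipping about the mid-sagittal plane, symmetric template construction by
voxel-wise averaging of originals and their flips, right-hemisphere
masking, the asymmetry-index (AI) formula, and Gaussian smoothing.

The AI at a right-hemisphere voxel is::

    AI = ((i1 - i2) / ((i1 + i2) * 0.5)) * i3

where ``i1`` is the original GM value (right hemisphere), ``i2`` the
left-right-flipped value at the same voxel (i.e. the left-hemisphere
homologue), and ``i3`` the right-hemisphere mask. Positive AI means
rightward asymmetry. For non-negative inputs AI lies in [-2, 2].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import GMVolume, world_x

__all__ = [
    "AIMap",
    "HemisphereMask",
    "build_symmetric_template",
    "compute_ai",
    "flip_lr",
    "fwhm_to_sigma",
    "gaussian_smooth",
    "make_right_mask",
]

#: i1 + i2 below this is treated as empty and AI is set to 0.
AI_DENOM_EPS = 1e-6

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full width at half maximum to its sigma."""
    return fwhm / _FWHM_PER_SIGMA


@dataclass
class HemisphereMask:
    """Binary right-hemisphere mask sharing a GMVolume's geometry."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def as_volume(self) -> GMVolume:
        return GMVolume(self.data.astype(np.float64), self.affine.copy())


@dataclass
class AIMap:
    """Voxel-wise asymmetry-index lattice, zero outside the mask."""

    data: np.ndarray
    affine: np.ndarray
    mask: HemisphereMask
    smoothed: bool = False

    @property
    def values(self) -> np.ndarray:
        """AI values at mask voxels, in fixed (C-order) scan order."""
        return self.data[self.mask.data]


def _check_flippable(vol: GMVolume) -> None:
    nx = vol.shape[0]
    if nx % 2 != 0:
        raise ValueError("grid extent across the midline must be even")
    # midline voxel-column centers must sit symmetrically about world x = 0
    center = vol.affine[0, 0] * (nx - 1) / 2.0 + vol.affine[0, 3]
    if abs(center) > 1e-6:
        raise ValueError("grid is not centered on world x = 0; cannot flip exactly")
    off_axis = np.abs(vol.affine[0, 1:3]).max() + np.abs(vol.affine[1:3, 0]).max()
    if off_axis > 1e-9:
        raise ValueError("oblique affine: x axis must be a pure world-x direction")


def flip_lr(vol: GMVolume) -> GMVolume:
    """Mirror a volume about the mid-sagittal (world x = 0) plane.

    The voxel at world (x, y, z) receives the value from (-x, y, z); with a
    centered even grid this is an exact index reversal, so the operation is
    an involution and preserves the voxel sum bit-exactly.
    """
    _check_flippable(vol)
    return vol.like(np.ascontiguousarray(vol.data[::-1, :, :]))


def build_symmetric_template(volumes: list[GMVolume]) -> GMVolume:
    """Voxel-wise mean of all input volumes and all their left-right flips.

    The result equals its own flip bit-exactly by construction.
    """
    if not volumes:
        raise ValueError("cannot build a template from an empty volume list")
    first = volumes[0]
    _check_flippable(first)
    acc = np.zeros(first.shape, dtype=np.float64)
    for vol in volumes:
        first.require_geometry(vol)
        acc += vol.data
    mean = acc / len(volumes)
    # symmetrize last: m + flip(m) is commutative voxel-wise, so the result
    # equals its own flip bit-exactly regardless of accumulation order
    return first.like(0.5 * (mean + mean[::-1, :, :]))


def make_right_mask(template: GMVolume, gm_threshold: float = 0.2) -> HemisphereMask:
    """Voxels with world x > 0 whose template GM value reaches the threshold."""
    if not 0.0 <= gm_threshold <= 1.0:
        raise ValueError(f"gm_threshold must be in [0, 1], got {gm_threshold}")
    right = world_x(template) > 0
    mask = right & (template.data >= gm_threshold)
    if gm_threshold == 0.0:
        mask = right & (template.data > 0)
    return HemisphereMask(mask, template.affine.copy())


def compute_ai(
    original: GMVolume,
    flipped: GMVolume,
    mask: HemisphereMask,
    check_flip: bool = False,
) -> AIMap:
    """Voxel-wise asymmetry index ``((i1-i2)/((i1+i2)*0.5))*i3``.

    Voxels where ``i1 + i2 < AI_DENOM_EPS`` get AI = 0 (no tissue on either
    side); everything outside the mask is 0.
    """
    original.require_geometry(flipped)
    if original.shape != mask.data.shape:
        raise ValueError("mask geometry does not match the volumes")
    if check_flip and not np.array_equal(flipped.data, flip_lr(original).data):
        raise ValueError("flipped volume is not the exact left-right flip of original")
    i1, i2 = original.data, flipped.data
    denom = (i1 + i2) * 0.5
    ai = np.zeros_like(i1)
    ok = (i1 + i2) >= AI_DENOM_EPS
    np.divide(i1 - i2, denom, out=ai, where=ok)
    ai[~mask.data] = 0.0
    return AIMap(ai, original.affine.copy(), mask, smoothed=False)


def gaussian_smooth(obj: "AIMap | GMVolume", fwhm_mm: float):
    """Separable Gaussian smoothing with the kernel given as FWHM in mm.

    Sigma per axis is ``fwhm / (2*sqrt(2*ln 2))`` converted to voxel units.
    Boundary handling is constant-preserving (nearest-edge replication);
    ``fwhm_mm = 0`` is the identity. AI maps are smoothed on the full
    lattice and re-masked afterwards, so mask-edge attenuation is accepted
    rather than renormalized.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if isinstance(obj, AIMap):
        vsz = np.sqrt((np.asarray(obj.affine)[:3, :3] ** 2).sum(axis=0))
        if fwhm_mm == 0:
            return AIMap(obj.data.copy(), obj.affine, obj.mask, smoothed=obj.smoothed)
        sigma_vox = fwhm_to_sigma(fwhm_mm) / vsz
        sm = ndimage.gaussian_filter(obj.data, sigma=sigma_vox, mode="nearest")
        sm[~obj.mask.data] = 0.0
        return AIMap(sm, obj.affine, obj.mask, smoothed=True)
    if fwhm_mm == 0:
        return obj.like(obj.data.copy())
    sigma_vox = fwhm_to_sigma(fwhm_mm) / obj.voxel_size
    return obj.like(ndimage.gaussian_filter(obj.data, sigma=sigma_vox, mode="nearest"))
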