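"""Volume container and NIfTI I/O for gray-matter probability lattices.

All grids used by this package are centered on the mid-sagittal plane:
the world ``x = 0`` plane lies exactly halfway between two voxel columns,
so a left-right flip is an index reversal and needs no interpolation.
World coordinates follow the RAS convention (+x = subject's right).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["GMVolume", "centered_affine", "load_volume", "save_volume", "world_x"]


def centered_affine(shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    """RAS affine placing the grid center at world origin.

    Voxel ``i`` along axis ``j`` maps to world ``(i - (n_j - 1)/2) * voxel_size``;
    with an even first extent the midline falls between two columns.
    """
    affine = np.eye(4)
    for j in range(3):
        affine[j, j] = voxel_size
        affine[j, 3] = -(shape[j] - 1) / 2.0 * voxel_size
    return affine


@dataclass
class GMVolume:
    """A 3-D lattice of gray-matter probability with world geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values; GM probabilities live in [0, 1] but derived maps
        (asymmetry indices, t-statistics) reuse the container.
    affine : ndarray, shape (4, 4)
        Voxel-to-world map, RAS millimetres.
    """

    data: np.ndarray
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D lattice, got ndim={self.data.ndim}")
        if self.affine is None:
            self.affine = centered_affine(self.data.shape, 1.0)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Millimetres per voxel along each axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def like(self, data: np.ndarray) -> "GMVolume":
        """New volume with the same geometry and different data."""
        return GMVolume(np.asarray(data, dtype=np.float64), self.affine.copy())

    def same_geometry(self, other: "GMVolume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_geometry(self, other: "GMVolume") -> None:
        if not self.same_geometry(other):
            raise ValueError("volume geometry mismatch (shape or affine differ)")

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm coordinates."""
        idx = np.atleast_2d(idx).astype(float)
        return (self.affine[:3, :3] @ idx.T).T + self.affine[:3, 3]


def world_x(vol: GMVolume) -> np.ndarray:
    """World x coordinate of every voxel (broadcastable over the lattice)."""
    nx = vol.shape[0]
    i = np.arange(nx)
    xs = vol.affine[0, 0] * i + vol.affine[0, 3]
    return xs[:, None, None]


def load_volume(path: str) -> GMVolume:
    """Read a NIfTI file, reorienting to RAS axis order if necessary."""
    img = nib.load(path)
    img = nib.as_closest_canonical(img)
    return GMVolume(np.asarray(img.get_fdata(), dtype=np.float64), img.affine)


def save_volume(vol: GMVolume, path: str) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine), path)
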