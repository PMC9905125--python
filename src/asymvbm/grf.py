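"""Gaussian-random-field cluster-level inference.

Implements residual-based smoothness (FWHM/resel) estimation, connected
component labeling of suprathreshold voxels, and closed-form corrected
cluster p-values for a smooth Gaussian field: with resel count R, a
cluster-forming threshold u (normal deviate), search volume S voxels and
extent k voxels,

    E[m] = R * (4 ln 2)^{3/2} * (2 pi)^{-2} * (u^2 - 1) * exp(-u^2 / 2)
    E[N] = S * Phi(-u)
    P(extent >= k) = exp(-beta * k^{2/3}),  beta = (Gamma(5/2) E[m]/E[N])^{2/3}
    corrected p     = 1 - exp(-E[m] * P(extent >= k))

t-maps are Gaussianized voxel-wise (probability transform to normal
deviates) before thresholding, since the expected-cluster formulas above
are for Gaussian fields. Rightward and leftward differences are tested as
two one-tailed families, each at the voxel threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.special import gamma as gamma_fn

from .glm import TMap

__all__ = [
    "ClusterResult",
    "SmoothnessEstimate",
    "cluster_p_rft",
    "dice_overlap",
    "estimate_fwhm",
    "gaussianize_t",
    "label_clusters",
    "significant_clusters",
]

_4LN2 = 4.0 * np.log(2.0)

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class SmoothnessEstimate:
    fwhm_mm: np.ndarray  # per-axis FWHM in mm
    fwhm_vox: np.ndarray  # per-axis FWHM in voxels
    resel_count: float
    search_volume: int  # mask voxels

    @property
    def sub_voxel(self) -> bool:
        """True when any estimated FWHM falls below one voxel (flagged)."""
        return bool((self.fwhm_vox < 1.0).any())


def estimate_fwhm(
    residuals: np.ndarray,
    mask: np.ndarray,
    voxel_size: float | np.ndarray,
) -> SmoothnessEstimate:
    """Per-axis smoothness from spatial first-differences of residuals.

    ``residuals`` is (n_images, V) over mask voxels in C scan order, or
    (n_images, nx, ny, nz). Residual images are normalized voxel-wise to
    unit variance; the roughness along axis j is the variance of their
    first differences (pairs with both ends in the mask), and
    ``FWHM_j = sqrt(4 ln 2 / lambda_j)`` voxels.
    """
    mask = np.asarray(mask, dtype=bool)
    vsz = np.broadcast_to(np.asarray(voxel_size, dtype=np.float64), (3,))
    if residuals.ndim == 2:
        n, v = residuals.shape
        if v != int(mask.sum()):
            raise ValueError("residual columns do not match mask voxel count")
        lattice = np.zeros((n,) + mask.shape)
        lattice[:, mask] = residuals
    elif residuals.ndim == 4:
        lattice = np.asarray(residuals, dtype=np.float64)
        n = lattice.shape[0]
    else:
        raise ValueError("residuals must be (n, V) or (n, nx, ny, nz)")
    if n < 3:
        raise ValueError("need at least 3 residual images")
    if not mask.any():
        raise ValueError("empty mask")

    # voxel-wise unit variance so roughness reads as a correlation decay
    var = (lattice**2).mean(axis=0)
    ok = var > 0
    if not (ok & mask).any():
        raise ValueError("residuals are constant inside the mask")
    norm = np.zeros_like(lattice)
    norm[:, ok] = lattice[:, ok] / np.sqrt(var[ok])

    lambdas = np.empty(3)
    for j in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[j] = slice(None, -1)
        sl_hi[j] = slice(1, None)
        pair_ok = mask[tuple(sl_lo)] & mask[tuple(sl_hi)] & ok[tuple(sl_lo)] & ok[
            tuple(sl_hi)
        ]
        if not pair_ok.any():
            raise ValueError(f"no in-mask voxel pairs along axis {j}")
        diffs = (
            norm[(slice(None),) + tuple(sl_hi)] - norm[(slice(None),) + tuple(sl_lo)]
        )[:, pair_ok]
        lambdas[j] = (diffs**2).mean()
    if (lambdas <= 0).any():
        raise ValueError("constant residuals: zero roughness")
    fwhm_vox = np.sqrt(_4LN2 / lambdas)
    fwhm_mm = fwhm_vox * vsz
    search = int(mask.sum())
    resels = search * float(np.prod(vsz / fwhm_mm))
    return SmoothnessEstimate(fwhm_mm, fwhm_vox, resels, search)


def _structure(connectivity: int) -> np.ndarray:
    try:
        return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")


def label_clusters(
    stat_map: np.ndarray,
    threshold: float,
    connectivity: int = 18,
) -> tuple[np.ndarray, int, np.ndarray, int]:
    """Connected components above +threshold and below -threshold.

    Returns ``(labels_pos, n_pos, labels_neg, n_neg)``; label images are 0
    outside clusters and 1..n inside.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    struct = _structure(connectivity)
    lab_pos, n_pos = ndimage.label(stat_map >= threshold, structure=struct)
    lab_neg, n_neg = ndimage.label(stat_map <= -threshold, structure=struct)
    return lab_pos, n_pos, lab_neg, n_neg


def gaussianize_t(t: np.ndarray, df: int) -> np.ndarray:
    """Probability-transform t-values to equivalent normal deviates."""
    t = np.asarray(t, dtype=np.float64)
    # symmetric tail transform avoids cdf saturation for large |t|
    tail = stats.t.sf(np.abs(t), df)
    tail = np.clip(tail, 1e-300, 0.5)
    z = stats.norm.isf(tail)
    return np.sign(t) * z


def expected_clusters(u: float, resel_count: float) -> float:
    """Expected suprathreshold cluster count E[m] for a Gaussian field."""
    return (
        resel_count
        * _4LN2**1.5
        * (2.0 * np.pi) ** -2
        * (u**2 - 1.0)
        * np.exp(-(u**2) / 2.0)
    )


def cluster_p_rft(
    extent: int,
    u: float,
    smoothness: SmoothnessEstimate,
    df: int | None = None,
) -> float:
    """Family-wise corrected p for a cluster of ``extent`` voxels."""
    if extent < 0:
        raise ValueError("extent must be non-negative")
    if u <= 1:
        raise ValueError("cluster-forming threshold u must exceed 1")
    e_m = expected_clusters(u, smoothness.resel_count)
    e_n = smoothness.search_volume * stats.norm.sf(u)
    if not np.isfinite(e_m) or not np.isfinite(e_n) or e_n <= 0:
        raise FloatingPointError(
            f"non-finite RFT intermediates: E[m]={e_m}, E[N]={e_n}, u={u}, "
            f"resels={smoothness.resel_count}"
        )
    beta = (gamma_fn(2.5) * e_m / e_n) ** (2.0 / 3.0)
    p_ge_k = np.exp(-beta * extent ** (2.0 / 3.0))
    return float(1.0 - np.exp(-e_m * p_ge_k))


@dataclass
class ClusterResult:
    """Significant clusters plus their voxel masks, Table-style schema."""

    table: pd.DataFrame
    masks: dict[int, np.ndarray] = field(default_factory=dict)
    smoothness: SmoothnessEstimate | None = None
    threshold_t: float = np.nan
    threshold_z: float = np.nan

    def __len__(self) -> int:
        return len(self.table)


_TABLE_COLUMNS = [
    "cluster_id",
    "direction",
    "extent_voxels",
    "peak_x",
    "peak_y",
    "peak_z",
    "peak_t",
    "corrected_p",
]


def significant_clusters(
    tmap: TMap,
    smoothness: SmoothnessEstimate | None = None,
    voxel_p: float = 0.005,
    cluster_p: float = 0.05,
    connectivity: int = 18,
) -> ClusterResult:
    """GRF-corrected cluster table at the given voxel / cluster thresholds.

    The t-map is Gaussianized, thresholded at the one-tailed normal deviate
    of ``voxel_p`` in each direction, labeled, and each cluster's extent is
    converted to a corrected p; clusters with corrected p < ``cluster_p``
    are reported with peak world coordinates, peak t, and direction
    (positive t = cases more rightward).
    """
    if not (0 < voxel_p < 1 and 0 < cluster_p < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    if smoothness is None:
        vsz = np.sqrt((np.asarray(tmap.affine)[:3, :3] ** 2).sum(axis=0))
        smoothness = estimate_fwhm(tmap.residuals, tmap.mask.data, vsz)
    u = float(stats.norm.isf(voxel_p))
    t_thr = float(stats.t.isf(voxel_p, tmap.df))
    z = np.where(tmap.mask.data, gaussianize_t(tmap.data, tmap.df), 0.0)

    lab_pos, n_pos, lab_neg, n_neg = label_clusters(z, u, connectivity)
    rows = []
    masks: dict[int, np.ndarray] = {}
    cid = 0
    for labels, count, sign in ((lab_pos, n_pos, 1), (lab_neg, n_neg, -1)):
        for k in range(1, count + 1):
            voxels = labels == k
            extent = int(voxels.sum())
            p_corr = cluster_p_rft(extent, u, smoothness)
            if p_corr >= cluster_p:
                continue
            cid += 1
            tvals = np.where(voxels, tmap.data, 0.0)
            peak_flat = np.argmax(sign * tvals)
            peak_idx = np.unravel_index(peak_flat, tvals.shape)
            world = (
                np.asarray(tmap.affine)[:3, :3] @ np.asarray(peak_idx, dtype=float)
                + np.asarray(tmap.affine)[:3, 3]
            )
            rows.append(
                {
                    "cluster_id": cid,
                    "direction": "rightward" if sign > 0 else "leftward",
                    "extent_voxels": extent,
                    "peak_x": float(world[0]),
                    "peak_y": float(world[1]),
                    "peak_z": float(world[2]),
                    "peak_t": float(tmap.data[peak_idx]),
                    "corrected_p": p_corr,
                }
            )
            masks[cid] = voxels
    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    return ClusterResult(table, masks, smoothness, t_thr, u)


def dice_overlap(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Dice coefficient 2|A&B| / (|A| + |B|); 0 when both maps are empty."""
    a = np.asarray(map_a, dtype=bool)
    b = np.asarray(map_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("geometry mismatch between binary maps")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / total
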