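"""Semi-automated region-growing segmentation of the FLAIR-hyperintense tumor.

Growth is in-plane from a user seed, with an intensity band around the
running region mean deciding membership, and converged slices propagating
seeds to their vertical neighbors — the slice-by-slice iteration a reader
typically performs. Scan order is raster (row-major), so the result is
deterministic.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SeedPoint",
    "RegionGrowConfig",
    "RoiMask",
    "region_grow",
    "extract_roi_values",
]


@dataclass(frozen=True)
class SeedPoint:
    """0-based voxel indices of the operator's seed click."""

    z: int
    y: int
    x: int


@dataclass
class RegionGrowConfig:
    """Inclusion band half-width as a fraction of the running region mean,
    in-plane connectivity (4 or 8), and an iteration cap."""

    tolerance_frac: float = 0.2
    connectivity: int = 8
    max_iters: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.tolerance_frac < 1.0:
            raise ValueError("tolerance_frac must be in (0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")


@dataclass
class RoiMask:
    """Binary tumor mask."""

    mask: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


_OFFSETS_4 = ((-1, 0), (0, -1), (0, 1), (1, 0))
_OFFSETS_8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1))


def region_grow(flair: np.ndarray, seed: SeedPoint,
                config: RegionGrowConfig | None = None,
                exclusion_mask: np.ndarray | None = None) -> RoiMask:
    """Grow the FLAIR-hyperintense region from ``seed``.

    A voxel joins when (1-tol)*m0 <= intensity <= (1+tol)*m0, where ``m0`` is
    the mean over the seed's in-plane 3x3 neighborhood. The reference is fixed
    (not a running mean): a fixed band makes the mask monotone in the
    tolerance and keeps the grown region anchored to the tissue class the
    operator clicked. Growth is in-plane; once a slice stops adding voxels,
    accepted voxels seed the adjacent slices (the vertical neighbor must
    itself pass the band). ``exclusion_mask`` marks voxels an operator has
    vetoed (e.g. obvious leukoaraiosis).
    """
    if config is None:
        config = RegionGrowConfig()
    flair = np.asarray(flair, dtype=float)
    nz, ny, nx = flair.shape
    if not (0 <= seed.z < nz and 0 <= seed.y < ny and 0 <= seed.x < nx):
        raise ValueError("seed outside volume bounds")
    if flair[seed.z, seed.y, seed.x] < np.median(flair):
        raise ValueError("seed intensity below the volume median")
    excluded = (np.zeros(flair.shape, dtype=bool) if exclusion_mask is None
                else np.asarray(exclusion_mask, dtype=bool))

    offsets = _OFFSETS_4 if config.connectivity == 4 else _OFFSETS_8
    mask = np.zeros(flair.shape, dtype=bool)
    mask[seed.z, seed.y, seed.x] = True
    neigh = flair[seed.z,
                  max(seed.y - 1, 0):seed.y + 2,
                  max(seed.x - 1, 0):seed.x + 2]
    m0 = float(neigh.mean())
    lo_band = (1 - config.tolerance_frac) * m0
    hi_band = (1 + config.tolerance_frac) * m0

    def in_band(val: float) -> bool:
        return lo_band <= val <= hi_band

    for _ in range(config.max_iters):
        added_any = False
        # in-plane growth on every slice that currently holds region voxels
        for z in range(nz):
            if not mask[z].any():
                continue
            queue = deque(tuple(v) for v in np.argwhere(mask[z]))
            while queue:
                y, x = queue.popleft()
                for dy, dx in offsets:
                    yy, xx = y + dy, x + dx
                    if not (0 <= yy < ny and 0 <= xx < nx):
                        continue
                    if mask[z, yy, xx] or excluded[z, yy, xx]:
                        continue
                    if in_band(flair[z, yy, xx]):
                        mask[z, yy, xx] = True
                        queue.append((yy, xx))
                        added_any = True
        # propagate converged slices to their vertical neighbors
        for z in range(nz):
            if not mask[z].any():
                continue
            for zz in (z - 1, z + 1):
                if not 0 <= zz < nz:
                    continue
                for y, x in (tuple(v) for v in np.argwhere(mask[z])):
                    if mask[zz, y, x] or excluded[zz, y, x]:
                        continue
                    if in_band(flair[zz, y, x]):
                        mask[zz, y, x] = True
                        added_any = True
        if not added_any:
            break

    if mask.sum() == 1:
        warnings.warn("region growing accepted no voxels beyond the seed",
                      stacklevel=2)
    return RoiMask(mask=mask)


def extract_roi_values(volume: np.ndarray, roi: RoiMask) -> np.ndarray:
    """Values of ``volume`` inside the ROI, in deterministic raster order."""
    volume = np.asarray(volume)
    if volume.shape != roi.mask.shape:
        raise ValueError(
            f"grid mismatch: map {volume.shape} vs mask {roi.mask.shape}")
    if roi.n_voxels == 0:
        warnings.warn("empty ROI: no values extracted", stacklevel=2)
        return np.empty(0, dtype=volume.dtype)
    return volume[roi.mask.astype(bool)]
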