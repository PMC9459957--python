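"""Point-cloud pre-processing and scalar phenotypic traits.

The pipeline applied to every plant scan before trait extraction:

1. statistical outlier removal — discard points whose mean distance to their
   ``k`` nearest neighbours is anomalously large relative to the cloud-wide
   distribution of that statistic;
2. Z-axis cropping — keep a working window ``[z_min, z_max]``, which removes
   the pot below and stray returns above the plant;

after which plant height is simply the maximum ``z`` (the disc surface is
``z = 0``) and total volume is estimated by voxel counting: the number of
occupied voxels of a regular grid times a per-voxel volume coefficient
(default 2.5e-3 cm^3, the platform's experimentally calibrated value; the
matching voxel edge is the coefficient's cube root).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .geometry import PointCloud

__all__ = [
    "OutlierParams",
    "VoxelGrid",
    "remove_outliers",
    "crop_pot",
    "plant_height",
    "voxel_volume",
]

DEFAULT_VOXEL_COEFF_CM3 = 2.5e-3


@dataclass
class OutlierParams:
    """Statistical-outlier-removal parameters (common-practice defaults)."""

    k_neighbors: int = 20
    std_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.std_ratio <= 0:
            raise ValueError("std_ratio must be positive")


@dataclass
class VoxelGrid:
    """Regular voxel grid used for volume estimation.

    ``volume_coeff`` is the calibrated plant volume contributed by one
    occupied voxel; when ``voxel_edge`` is omitted it defaults to
    ``volume_coeff ** (1/3)`` so that occupied-voxel count times coefficient
    converges to true solid volume for densely sampled solids.
    """

    volume_coeff: float = DEFAULT_VOXEL_COEFF_CM3
    voxel_edge: float | None = None

    def __post_init__(self) -> None:
        if self.volume_coeff <= 0:
            raise ValueError("volume coefficient must be positive")
        if self.voxel_edge is None:
            self.voxel_edge = self.volume_coeff ** (1.0 / 3.0)
        if self.voxel_edge <= 0:
            raise ValueError("voxel edge must be positive")


def remove_outliers(cloud: PointCloud, params: OutlierParams | None = None) -> PointCloud:
    """Statistical outlier removal; never adds points, keeps attributes aligned."""
    params = params or OutlierParams()
    n = len(cloud)
    if n <= params.k_neighbors:
        warnings.warn(
            f"cloud has only {n} points (k={params.k_neighbors}); returned unchanged",
            stacklevel=2,
        )
        return cloud
    nn = NearestNeighbors(n_neighbors=params.k_neighbors + 1).fit(cloud.points)
    dists, _ = nn.kneighbors(cloud.points)
    mean_dist = dists[:, 1:].mean(axis=1)  # drop self-distance
    thresh = mean_dist.mean() + params.std_ratio * mean_dist.std()
    return cloud.select(mean_dist <= thresh)


def crop_pot(cloud: PointCloud, z_min: float, z_max: float = np.inf) -> PointCloud:
    """Keep the working window ``z_min <= z <= z_max`` (pot removal)."""
    if not z_min < z_max:
        raise ValueError("need z_min < z_max")
    z = cloud.points[:, 2]
    return cloud.select((z >= z_min) & (z <= z_max))


def plant_height(cloud: PointCloud) -> float:
    """Plant height above the disc surface: the maximum z (cm)."""
    if len(cloud) == 0:
        raise ValueError("no points: cannot measure height of an empty cloud")
    return float(cloud.points[:, 2].max())


def voxel_volume(cloud: PointCloud, grid: VoxelGrid | None = None) -> float:
    """Voxel-count volume estimate (cm^3).

    Counts distinct occupied voxels of the axis-aligned grid whose lattice
    contains the cloud's minimum corner voxel and multiplies by the per-voxel
    coefficient.  The lattice is anchored on multiples of the voxel edge so
    that adding points can never decrease the count.
    """
    grid = grid or VoxelGrid()
    if len(cloud) == 0:
        return 0.0
    idx = np.floor(cloud.points / grid.voxel_edge)
    occupied = len(np.unique(idx.astype(np.int64), axis=0))
    return grid.volume_coeff * occupied
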