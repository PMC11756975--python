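"""Statistical outlier removal for SfM point clouds.

Classic k-nearest-neighbour statistical filter: for every point compute
the mean distance to its k nearest neighbours; points whose mean distance
is anomalously large relative to the cloud-wide distribution are treated
as reconstruction noise and removed.  Applied once, before classification
and before each volume computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import PointCloud


@dataclass(frozen=True)
class DenoiseParams:
    """k_neighbors: neighbourhood size; std_multiplier: sigma cut (mode='sigma')
    or absolute mean-distance cut in metres (mode='absolute')."""

    k_neighbors: int = 10
    std_multiplier: float = 1.0
    mode: str = "sigma"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.std_multiplier <= 0:
            raise ValueError("std_multiplier must be positive")
        if self.mode not in ("sigma", "absolute"):
            raise ValueError("mode must be 'sigma' or 'absolute'")


def knn_mean_distance(cloud: PointCloud, k: int) -> np.ndarray:
    """Per-point mean Euclidean distance to the k nearest *other* points."""
    n = len(cloud)
    if n <= k:
        raise ValueError(f"cloud has {n} points; need more than k={k}")
    tree = cKDTree(cloud.coords)
    # first neighbour is the point itself (distance 0)
    dist, _ = tree.query(cloud.coords, k=k + 1)
    return dist[:, 1:].mean(axis=1)


def statistical_outlier_filter(
    cloud: PointCloud, params: DenoiseParams = DenoiseParams()
) -> tuple[PointCloud, int]:
    """Remove outliers; returns (filtered cloud, number removed).

    sigma mode: a point is an outlier when its knn mean distance exceeds
    mu + m*sigma, where mu and sigma are taken over the whole cloud.
    absolute mode: outlier when the mean distance exceeds std_multiplier
    metres directly.
    """
    d = knn_mean_distance(cloud, params.k_neighbors)
    if params.mode == "sigma":
        threshold = d.mean() + params.std_multiplier * d.std()
    else:
        threshold = params.std_multiplier
    keep = d <= threshold
    return cloud.select(keep), int((~keep).sum())
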