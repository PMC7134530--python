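"""Unsupervised scar-segmentation baselines over the atrial wall shell.

All three comparators classify raw intensities of voxels inside a wall
shell derived from the ground-truth anatomy at a fixed 2.25 mm thickness —
mirroring how threshold- and cluster-based scar quantification has
historically relied on a given wall segmentation, and isolating scar
detection from anatomy errors:

- 2-SD thresholding: scar iff intensity > blood mean + 2 * blood sd;
- k-means (k = 2) on wall intensities, highest-centroid cluster = scar;
- fuzzy c-means (c = 2, fuzzifier m = 2) with majority membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .phantom import PhantomSample, wall_shell
from .volumes import LabelVolume, Volume


@dataclass
class WallIntensitySample:
    """Intensities of the voxels inside a wall shell, with blood-pool stats.

    ``voxel_indices`` holds the (z, y, x) coordinate of each intensity so a
    binary decision over the sequence can be scattered back onto the grid.
    """

    intensities: np.ndarray
    voxel_indices: np.ndarray
    blood_stats: tuple[float, float]
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.size == 0:
            raise ValueError("wall intensity sample is empty")
        if self.blood_stats[1] < 0:
            raise ValueError("blood sd must be >= 0")

    def mask_from_flags(self, flags: np.ndarray) -> LabelVolume:
        grid = np.zeros(self.grid_shape, dtype=np.uint8)
        idx = self.voxel_indices[np.asarray(flags, dtype=bool)]
        grid[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
        return LabelVolume(grid)


def wall_sample(
    image: Volume,
    anatomy: LabelVolume,
    wall_mm: float = 2.25,
    blood_erosion: int = 1,
) -> WallIntensitySample:
    """Extract wall-shell intensities and blood-pool statistics from a scan.

    Blood statistics are measured on the anatomy mask eroded by
    ``blood_erosion`` voxels, keeping partial-volume boundary voxels out of
    the reference distribution.
    """
    shell = wall_shell(anatomy, image.spacing, wall_mm).as_bool()
    blood = anatomy.as_bool()
    if blood_erosion > 0:
        eroded = ndimage.binary_erosion(blood, iterations=blood_erosion)
        if eroded.any():
            blood = eroded
    vals = image.voxels[blood]
    return WallIntensitySample(
        intensities=image.voxels[shell],
        voxel_indices=np.argwhere(shell),
        blood_stats=(float(vals.mean()), float(vals.std())),
        grid_shape=image.shape,
    )


def sample_from_phantom(sample: PhantomSample, wall_mm: float | None = None) -> WallIntensitySample:
    """Convenience: build the wall sample for a generated phantom."""
    wall_mm = wall_mm if wall_mm is not None else sample.spec.wall_thickness_mm
    return wall_sample(sample.image, sample.anatomy, wall_mm=wall_mm)


# ---------------------------------------------------------------------------
# Methods
# ---------------------------------------------------------------------------

def two_sd_threshold(sample: WallIntensitySample) -> LabelVolume:
    """Label scar where intensity > blood mean + 2 * blood sd."""
    mean, sd = sample.blood_stats
    if sd == 0 and np.all(sample.intensities == sample.intensities[0]):
        warnings.warn("degenerate wall sample (constant intensities, zero sd)")
    return sample.mask_from_flags(sample.intensities > mean + 2.0 * sd)


def kmeans_scar(sample: WallIntensitySample, k: int = 2, seed: int = 0) -> LabelVolume:
    """1-D k-means (Lloyd, k-means++ seeding); highest-centroid cluster = scar.

    If all centroids coincide there is no meaningful bright cluster and the
    conservative empty mask is returned.
    """
    x = sample.intensities.reshape(-1, 1)
    if len(x) < k:
        raise ValueError(f"need at least {k} wall voxels for k-means, got {len(x)}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    centroids = km.cluster_centers_.ravel()
    if np.allclose(centroids, centroids[0]):
        return sample.mask_from_flags(np.zeros(len(x), dtype=bool))
    return sample.mask_from_flags(km.labels_ == int(np.argmax(centroids)))


def fuzzy_cmeans_scar(
    sample: WallIntensitySample,
    c: int = 2,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> tuple[np.ndarray, LabelVolume]:
    """Fuzzy c-means on wall intensities; scar = majority membership in the
    highest-centroid cluster.

    Alternates the standard updates — memberships
    ``u_ij = 1 / sum_k (d_ij / d_kj) ** (2 / (m - 1))`` and centroids
    ``v_i = sum_j u_ij**m x_j / sum_j u_ij**m`` — until the largest centroid
    shift falls below `tol`. A voxel at zero distance to a centroid receives
    full membership in that cluster (the limit rule).

    Returns ``(memberships, mask)`` with memberships of shape (c, n) whose
    columns sum to one.
    """
    if m <= 1.0:
        raise ValueError("fuzzifier m must be > 1")
    x = sample.intensities.astype(float)
    n = len(x)
    if n < c:
        raise ValueError(f"need at least {c} wall voxels for FCM, got {n}")
    # deterministic spread-quantile initialization; degenerate data where the
    # quantiles coincide gets an infinitesimal symmetric split
    del seed  # kept in the signature for interface stability; FCM is deterministic
    centroids = np.quantile(x, (np.arange(c) + 0.5) / c)
    if np.allclose(centroids, centroids[0]):
        centroids = centroids + 1e-9 * np.arange(c) * max(1.0, abs(float(centroids[0])))
    power = 2.0 / (m - 1.0)
    u = np.full((c, n), 1.0 / c)
    for _ in range(max_iter):
        d = np.abs(x[None, :] - centroids[:, None])  # (c, n)
        zero = d <= 1e-15
        u = np.empty_like(d)
        any_zero = zero.any(axis=0)
        if any_zero.any():
            cols = np.where(any_zero)[0]
            u[:, cols] = zero[:, cols] / zero[:, cols].sum(axis=0)
        ok = ~any_zero
        if ok.any():
            ratio = (d[:, ok][None, :, :] / d[:, ok][:, None, :]) ** power  # (c, c, n)
            u[:, ok] = 1.0 / ratio.sum(axis=0)
        um = u**m
        new_centroids = (um @ x) / um.sum(axis=1)
        shift = np.max(np.abs(new_centroids - centroids))
        centroids = new_centroids
        if shift < tol:
            break
    if np.allclose(centroids, centroids[0]):
        return u, sample.mask_from_flags(np.zeros(n, dtype=bool))
    scar_cluster = int(np.argmax(centroids))
    return u, sample.mask_from_flags(np.argmax(u, axis=0) == scar_cluster)
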