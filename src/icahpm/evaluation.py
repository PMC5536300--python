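"""Recovery metrics against the synthetic ground truth.

Utilities that score how well the pipeline recovered what the cohort
generator planted: greedy matching of reproducible clusters to planted
sources, Dice overlap of surviving clusters with planted support, and a
familywise-error calibration loop for the Monte-Carlo extent threshold.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .group_stats import (
    build_design,
    fit_voxelwise_glm,
    monte_carlo_extent_threshold,
    threshold_clusters,
)
from .hpm import ReproducibleCluster

__all__ = [
    "match_clusters_to_sources",
    "dice_overlap",
    "fwer_calibration",
]


def match_clusters_to_sources(
    clusters: list[ReproducibleCluster],
    source_maps: np.ndarray,
    mask: np.ndarray,
) -> dict[int, tuple[int, float]]:
    """Greedy max-|correlation| assignment of clusters to planted sources.

    Returns ``{source_index: (cluster_id, correlation)}``; each cluster is
    used at most once. Correlations are between each cluster's mean
    subject-representative z-map (over the mask) and the canonical source
    maps.
    """
    k = source_maps.shape[0]
    src = source_maps.reshape(k, -1)[:, mask.ravel()]
    corr = np.zeros((k, len(clusters)))
    for j, cl in enumerate(clusters):
        rep = np.mean(np.stack(list(cl.subject_representatives.values())), axis=0)
        for i in range(k):
            corr[i, j] = np.corrcoef(src[i], rep)[0, 1]
    corr = np.abs(corr)
    assignment: dict[int, tuple[int, float]] = {}
    used: set[int] = set()
    flat = sorted(
        ((corr[i, j], i, j) for i in range(k) for j in range(len(clusters))),
        reverse=True,
    )
    for c, i, j in flat:
        if i in assignment or j in used:
            continue
        assignment[i] = (clusters[j].cluster_id, float(c))
        used.add(j)
    return assignment


def dice_overlap(voxels_a: np.ndarray, support_b: np.ndarray) -> float:
    """Dice coefficient between a cluster's voxel list (n x 3 indices) and
    a boolean support volume."""
    a = np.zeros(support_b.shape, dtype=bool)
    a[tuple(np.asarray(voxels_a).T)] = True
    inter = np.count_nonzero(a & support_b)
    denom = np.count_nonzero(a) + np.count_nonzero(support_b)
    return 2.0 * inter / denom if denom else 0.0


def fwer_calibration(
    mask_shape: tuple[int, int, int] = (12, 12, 10),
    voxel_size_mm: tuple[float, float, float] = (3.75, 3.75, 3.5),
    smoothness_fwhm_mm: float = 8.0,
    n_subjects: tuple[int, int] = (15, 15),
    n_cohorts: int = 200,
    voxel_p: float = 0.01,
    fwer: float = 0.05,
    n_iter: int = 1000,
    seed: int = 0,
) -> tuple[float, int]:
    """Fraction of null cohorts producing any surviving cluster.

    Simulates ``n_cohorts`` cohorts of smooth null maps (no group effect),
    fits the voxelwise group GLM, and applies the voxel + Monte-Carlo
    extent threshold. Under correct calibration the false-positive cohort
    fraction matches the nominal familywise rate. Returns
    ``(fraction, extent_threshold)``.
    """
    mask = np.ones(mask_shape, dtype=bool)
    root = np.random.SeedSequence(seed)
    s_mc, s_cohorts = root.spawn(2)
    extent = monte_carlo_extent_threshold(
        mask, smoothness_fwhm_mm, voxel_size_mm,
        voxel_p=voxel_p, fwer=fwer, n_iter=n_iter, seed=s_mc,
    )
    sigma_vox = [
        (smoothness_fwhm_mm / np.sqrt(8 * np.log(2))) / v for v in voxel_size_mm
    ]
    n = sum(n_subjects)
    groups = ["patient"] * n_subjects[0] + ["control"] * n_subjects[1]
    design, names, contrast = build_design(groups)
    cohort_seeds = s_cohorts.spawn(n_cohorts)
    hits = 0
    m = int(np.prod(mask_shape))
    for cs in cohort_seeds:
        rng = np.random.default_rng(cs)
        maps = np.empty((n, m))
        for i in range(n):
            vol = ndimage.gaussian_filter(
                rng.standard_normal(mask_shape), sigma=sigma_vox, mode="constant"
            )
            v = vol.ravel()
            maps[i] = (v - v.mean()) / v.std()
        t, df = fit_voxelwise_glm(maps, design, contrast, names)
        t3 = t.reshape(mask_shape)
        survivors = threshold_clusters(t3, df, voxel_p=voxel_p, extent=extent, mask=mask)
        if survivors:
            hits += 1
    return hits / n_cohorts, extent
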