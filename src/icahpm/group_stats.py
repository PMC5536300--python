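"""Voxelwise second-level inference on per-subject representative maps.

A per-cluster ordinary-least-squares model (group + age + sex, optionally
an age-by-group interaction) gives a voxelwise t-map for the group
contrast; multiple comparisons are handled by combining an uncorrected
voxel threshold (default p = 0.01 two-sided) with a cluster-extent
threshold calibrated by Monte-Carlo simulation of smooth Gaussian null
maps. Severity correlations are plain Pearson r on per-subject scalar
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "SurvivingCluster",
    "GroupDiffMap",
    "build_design",
    "fit_voxelwise_glm",
    "estimate_smoothness_fwhm",
    "monte_carlo_extent_threshold",
    "threshold_clusters",
    "severity_correlation",
]

#: 26-neighbour connectivity in 3D.
CONNECTIVITY_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SurvivingCluster:
    sign: int  # +1 or -1
    peak_voxel: tuple[int, int, int]
    peak_t: float
    extent: int
    voxels: np.ndarray  # (n, 3) indices


@dataclass
class GroupDiffMap:
    cluster_id: int | str
    t_map: np.ndarray  # 3D, zeros off-mask
    df: int
    voxel_p_threshold: float
    extent_threshold_voxels: int
    surviving_clusters: list[SurvivingCluster] = field(default_factory=list)


def build_design(
    groups: list[str],
    ages: np.ndarray | None = None,
    sexes: list[str] | None = None,
    interaction: bool = False,
    patient_label: str = "patient",
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Design matrix [intercept, group, age, sex(, age x group)] and the
    group contrast (patient minus control).

    Group is coded +1 patient / -1 control so the contrast on its column
    estimates half the group difference with any coding-independent t.
    Age is mean-centered; sex coded +1 male / -1 female.
    """
    n = len(groups)
    gcol = np.array([1.0 if g == patient_label else -1.0 for g in groups])
    cols = [np.ones(n), gcol]
    names = ["intercept", "group"]
    if ages is not None:
        a = np.asarray(ages, dtype=float)
        a = a - a.mean()
        cols.append(a)
        names.append("age")
    if sexes is not None:
        cols.append(np.array([1.0 if s == "M" else -1.0 for s in sexes]))
        names.append("sex")
    if interaction:
        if ages is None:
            raise ValueError("interaction requires ages")
        cols.append(cols[1] * cols[2])
        names.append("age_x_group")
    x = np.column_stack(cols)
    contrast = np.zeros(x.shape[1])
    contrast[1] = 1.0
    return x, names, contrast


def fit_voxelwise_glm(
    maps: np.ndarray,
    design: np.ndarray,
    contrast: np.ndarray,
    design_names: list[str] | None = None,
) -> tuple[np.ndarray, int]:
    """OLS fit per voxel; returns the contrast t-map and residual df.

    ``maps`` is (n_subjects, n_voxels). With design [1, group] only, the
    group-contrast t equals the pooled two-sample t exactly.
    """
    y = np.asarray(maps, dtype=float)
    x = np.asarray(design, dtype=float)
    c = np.asarray(contrast, dtype=float)
    n, p = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        names = design_names or [f"col{i}" for i in range(p)]
        # Identify columns whose removal restores full rank.
        bad = [
            names[i]
            for i in range(p)
            if np.linalg.matrix_rank(np.delete(x, i, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient (collinear: {bad})")
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y  # (p, M)
    resid = y - x @ beta
    sigma2 = np.sum(resid**2, axis=0) / df
    se = np.sqrt(np.maximum(c @ xtx_inv @ c, 0.0) * sigma2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, (c @ beta) / se, 0.0)
    return t, df


def estimate_smoothness_fwhm(
    residual_maps: np.ndarray, mask: np.ndarray, voxel_size_mm
) -> float:
    """Gaussian-equivalent smoothness (mm FWHM, geometric mean over axes)
    of residual maps from their lag-1 spatial autocorrelation.

    For white noise smoothed with a Gaussian of sd sigma, the voxel-lag-d
    autocorrelation is exp(-d^2 / (4 sigma^2)); solving at d = 1 voxel per
    axis gives sigma and hence FWHM. Axes with non-positive lag-1
    autocorrelation contribute 0 (no smoothness).
    """
    res = np.asarray(residual_maps, dtype=float)
    if res.ndim == 2:  # (subjects, voxels) -> reassemble into the grid
        vols = np.zeros((res.shape[0],) + mask.shape)
        vols[:, mask] = res
    else:
        vols = res
    fwhms = []
    vox = np.asarray(voxel_size_mm, dtype=float)
    for axis in range(3):
        r1s = []
        for v in vols:
            a = np.moveaxis(v, axis, 0)
            x0 = a[:-1][np.moveaxis(mask, axis, 0)[:-1] & np.moveaxis(mask, axis, 0)[1:]]
            x1 = a[1:][np.moveaxis(mask, axis, 0)[:-1] & np.moveaxis(mask, axis, 0)[1:]]
            if x0.size > 10 and x0.std() > 0 and x1.std() > 0:
                r1s.append(np.corrcoef(x0, x1)[0, 1])
        r1 = float(np.mean(r1s)) if r1s else 0.0
        if r1 <= 0:
            fwhms.append(0.0)
            continue
        d = vox[axis]
        sigma = np.sqrt(-(d**2) / (4.0 * np.log(r1)))
        fwhms.append(sigma * np.sqrt(8.0 * np.log(2.0)))
    fwhms = np.asarray(fwhms)
    if np.any(fwhms == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(fwhms))))


def monte_carlo_extent_threshold(
    mask: np.ndarray,
    smoothness_fwhm_mm: float,
    voxel_size_mm,
    voxel_p: float = 0.01,
    fwer: float = 0.05,
    n_iter: int = 1000,
    seed=0,
) -> int:
    """Cluster-extent threshold controlling the familywise error rate.

    Simulates ``n_iter`` smooth Gaussian null maps on the mask (white
    noise convolved to the requested smoothness, then z-scored within the
    mask), thresholds two-sided at ``voxel_p``, records each iteration's
    maximum cluster extent (26-connectivity), and returns the ceiling of
    the (1 - fwer) quantile.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not (0 < voxel_p < 1) or not (0 < fwer <= 1):
        raise ValueError("voxel_p in (0,1), fwer in (0,1]")
    mask = np.asarray(mask, dtype=bool)
    vox = np.asarray(voxel_size_mm, dtype=float)
    sigma_vox = np.array(
        [(smoothness_fwhm_mm / np.sqrt(8.0 * np.log(2.0))) / v for v in vox]
    )
    if np.any(2 * 3 * sigma_vox > np.asarray(mask.shape)):
        raise ValueError(
            f"smoothness {smoothness_fwhm_mm} mm is too wide for mask shape {mask.shape}"
        )
    zcrit = stats.norm.ppf(1.0 - voxel_p / 2.0)
    rng = np.random.default_rng(seed)
    max_extents = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        noise = rng.standard_normal(mask.shape)
        if smoothness_fwhm_mm > 0:
            noise = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="constant")
        vals = noise[mask]
        z = np.zeros(mask.shape)
        z[mask] = (vals - vals.mean()) / vals.std()
        ext = 0
        for signed in (z >= zcrit, z <= -zcrit):
            labels, n_lab = ndimage.label(signed & mask, structure=CONNECTIVITY_STRUCTURE)
            if n_lab:
                counts = np.bincount(labels.ravel())[1:]
                ext = max(ext, int(counts.max()))
        max_extents[it] = ext
    q = float(np.quantile(max_extents, 1.0 - fwer, method="higher"))
    return max(int(np.ceil(q)), 1)


def threshold_clusters(
    t_map: np.ndarray,
    df: int,
    voxel_p: float = 0.01,
    extent: int = 20,
    mask: np.ndarray | None = None,
) -> list[SurvivingCluster]:
    """Two-sided voxel thresholding plus extent filtering.

    Voxels with two-sided p < ``voxel_p`` are grouped by 26-connectivity,
    positive and negative t separately; clusters with at least ``extent``
    voxels survive, sorted by decreasing |peak t|.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    t = np.asarray(t_map, dtype=float)
    tcrit = stats.t.ppf(1.0 - voxel_p / 2.0, df)
    if mask is None:
        mask = np.ones(t.shape, dtype=bool)
    out: list[SurvivingCluster] = []
    for sign in (1, -1):
        supra = (sign * t > tcrit) & mask
        labels, n_lab = ndimage.label(supra, structure=CONNECTIVITY_STRUCTURE)
        for lab in range(1, n_lab + 1):
            vox = np.argwhere(labels == lab)
            if vox.shape[0] < extent:
                continue
            vals = t[tuple(vox.T)]
            peak_i = int(np.argmax(sign * vals))
            out.append(
                SurvivingCluster(
                    sign=sign,
                    peak_voxel=tuple(int(v) for v in vox[peak_i]),
                    peak_t=float(vals[peak_i]),
                    extent=int(vox.shape[0]),
                    voxels=vox,
                )
            )
    out.sort(key=lambda c: -abs(c.peak_t))
    return out


def severity_correlation(scalars: np.ndarray, severity: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between per-subject scalar summaries (mean
    representative z over a cluster's surviving voxels) and standardized
    severity, with the two-sided t-approximation p-value."""
    x = np.asarray(scalars, dtype=float)
    y = np.asarray(severity, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
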