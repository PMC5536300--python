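"""Preprocessing of 4D BOLD-like series.

Covers the implementable steps of a standard resting-state stream on data
already in a common grid: discarding initial non-equilibrium volumes,
detecting outlier volumes from the first-order derivative of the motion
parameters and from the global mean signal, repairing them by linear
interpolation between the nearest clean volumes, and isotropic Gaussian
spatial smoothing (default 8 mm FWHM).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cohort import SubjectSeries

__all__ = [
    "OutlierReport",
    "discard_initial_volumes",
    "detect_outliers",
    "repair_outliers",
    "smooth_gaussian",
    "preprocess_subject",
]

#: Default head radius (mm) used to convert rotations to arc displacement.
ROTATION_ARC_RADIUS_MM = 65.0


@dataclass
class OutlierReport:
    subject_id: str
    flagged_indices: list[int]
    motion_derivative_max: np.ndarray  # per-volume, mm
    global_signal_z: np.ndarray  # per-volume
    motion_threshold_mm: float
    global_z_threshold: float

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["motion_derivative_max"] = [float(v) for v in self.motion_derivative_max]
        d["global_signal_z"] = [float(v) for v in self.global_signal_z]
        return json.dumps(d, indent=2)


def _replace(series: SubjectSeries, **kw) -> SubjectSeries:
    return dataclasses.replace(series, **kw)


def discard_initial_volumes(series: SubjectSeries, n_discard: int = 6) -> SubjectSeries:
    """Drop the first ``n_discard`` volumes (signal-stabilization period),
    truncating the motion trace identically."""
    if n_discard < 0:
        raise ValueError("n_discard must be nonnegative")
    if n_discard >= series.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {series.n_volumes} volumes"
        )
    return _replace(
        series,
        data=series.data[..., n_discard:].copy(),
        motion=series.motion[n_discard:].copy(),
    )


def detect_outliers(
    series: SubjectSeries,
    motion_threshold_mm: float = 0.5,
    global_z_threshold: float = 3.0,
    include_rotations: bool = False,
) -> OutlierReport:
    """Flag volumes by motion-derivative and global-signal criteria.

    Volume t is flagged iff the maximum absolute successive difference of
    the translation parameters exceeds ``motion_threshold_mm`` (volume 0
    has derivative 0 by convention), or the z-scored global mean signal at
    t exceeds ``global_z_threshold`` in absolute value. With
    ``include_rotations``, rotations are converted to arc displacement at a
    65 mm radius and enter the same derivative statistic.
    """
    if series.motion.shape[0] != series.n_volumes:
        raise ValueError("motion trace length must match data time length")
    params = series.motion[:, :3]
    if include_rotations:
        arc = np.deg2rad(series.motion[:, 3:6]) * ROTATION_ARC_RADIUS_MM
        params = np.concatenate([params, arc], axis=1)
    deriv = np.zeros(series.n_volumes)
    deriv[1:] = np.max(np.abs(np.diff(params, axis=0)), axis=1)

    gs = series.data[series.mask].mean(axis=0)
    sd = gs.std()
    gz = (gs - gs.mean()) / sd if sd > 0 else np.zeros_like(gs)

    flagged = np.where((deriv > motion_threshold_mm) | (np.abs(gz) > global_z_threshold))[0]
    return OutlierReport(
        subject_id=series.subject_id,
        flagged_indices=[int(i) for i in flagged],
        motion_derivative_max=deriv,
        global_signal_z=gz,
        motion_threshold_mm=motion_threshold_mm,
        global_z_threshold=global_z_threshold,
    )


def repair_outliers(series: SubjectSeries, report: OutlierReport) -> SubjectSeries:
    """Replace flagged volumes by linear interpolation between the nearest
    earlier and later non-flagged volumes; runs at either end take the
    single nearest clean volume. Non-flagged volumes are untouched."""
    t = series.n_volumes
    flagged = sorted(set(report.flagged_indices))
    if any(i < 0 or i >= t for i in flagged):
        raise ValueError("flagged index out of range")
    good = np.array([i for i in range(t) if i not in set(flagged)])
    if good.size == 0:
        raise ValueError("cannot repair a series in which every volume is flagged")
    if not flagged:
        return _replace(series, data=series.data.copy())
    data = series.data.copy()
    for i in flagged:
        earlier = good[good < i]
        later = good[good > i]
        if earlier.size and later.size:
            lo, hi = earlier[-1], later[0]
            w = (i - lo) / (hi - lo)
            data[..., i] = (1 - w) * series.data[..., lo] + w * series.data[..., hi]
        elif later.size:
            data[..., i] = series.data[..., later[0]]
        else:
            data[..., i] = series.data[..., earlier[-1]]
    return _replace(series, data=data)


def smooth_gaussian(series: SubjectSeries, fwhm_mm: float = 8.0) -> SubjectSeries:
    """Isotropic Gaussian spatial smoothing of every volume.

    The kernel sd is ``fwhm / sqrt(8 ln 2)`` per axis, converted to voxel
    units; edges are handled with a renormalized truncated kernel (radius
    3 sd) so each volume's global mean is preserved.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm_mm == 0:
        return _replace(series, data=series.data.copy())
    sigma_vox = [
        (fwhm_mm / np.sqrt(8.0 * np.log(2.0))) / v for v in series.voxel_size_mm
    ]
    data = series.data
    # Mass-preserving edge handling: each voxel's kernel is renormalized
    # over its in-grid support, which is equivalent to dividing the input
    # by the smoothed all-ones volume before convolving.
    norm = ndimage.gaussian_filter(
        np.ones(data.shape[:3]), sigma=sigma_vox, mode="constant", truncate=3.0
    )
    out = np.empty_like(data, dtype=float)
    for t in range(data.shape[-1]):
        sm = ndimage.gaussian_filter(
            data[..., t].astype(float) / norm, sigma=sigma_vox,
            mode="constant", truncate=3.0,
        )
        out[..., t] = sm
    return _replace(series, data=out)


def preprocess_subject(
    series: SubjectSeries,
    n_discard: int = 6,
    motion_threshold_mm: float = 0.5,
    global_z_threshold: float = 3.0,
    fwhm_mm: float = 8.0,
) -> tuple[SubjectSeries, OutlierReport]:
    """Discard, detect, repair, smooth — the full per-subject stream."""
    s = discard_initial_volumes(series, n_discard)
    report = detect_outliers(s, motion_threshold_mm, global_z_threshold)
    s = repair_outliers(s, report)
    s = smooth_gaussian(s, fwhm_mm)
    return s, report
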