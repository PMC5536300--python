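"""Synthetic resting-state fMRI cohort generator with known ground truth.

Builds multi-subject 4D BOLD-like datasets in a common voxel grid. Each
subject's data are a linear mixture of K spatially smooth Gaussian sources,
whose time courses follow a group-specific stationary vector-autoregressive
(VAR) model, plus i.i.d. Gaussian noise. The generator plants, and records
in a :class:`GroundTruth`, every systematic effect downstream stages are
meant to recover:

* directed lagged (Granger-causal) dependencies between sources, including
  a mediated chain A -> M -> B;
* group differences in source amplitude and in selected VAR coefficients
  (the patient-like group is weakened on designated edges);
* a symptom-severity score correlated with one source's realized amplitude;
* occasional motion-corrupted outlier volumes.

The default emulates a two-group resting-state design: 146 volumes at a
repetition time of 2.2 s on a 16 x 16 x 12 grid (a desk-scale stand-in for
a 64 x 64 x 34 acquisition over a 24 cm field of view with 3.5 mm slices).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "SubjectSeries",
    "generate_cohort",
    "make_source_maps",
    "generate_severity",
    "companion_spectral_radius",
    "default_spec",
    "write_cohort",
    "load_cohort",
]

PATIENT = "patient"
CONTROL = "control"
GROUPS = (PATIENT, CONTROL)


def _fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / np.sqrt(8.0 * np.log(2.0))


def companion_spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the companion matrix of VAR coefficients.

    Parameters
    ----------
    coeffs : ndarray, shape (p, K, K)
        Lag matrices A_1..A_p; entry ``A_l[i, j]`` couples source j at lag
        l into source i.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    p, k, k2 = coeffs.shape
    if k != k2:
        raise ValueError("VAR coefficient matrices must be square")
    companion = np.zeros((p * k, p * k))
    companion[:k, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        companion[k:, : k * (p - 1)] = np.eye(k * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(companion))))


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; identical spec + seed gives
    bit-identical output.

    ``var_coefficients`` maps group name to an array of shape
    ``(var_order, K, K)``; ``amplitude_scale`` maps group name to a length-K
    vector of per-source amplitude multipliers.
    """

    grid_dims: tuple[int, int, int] = (16, 16, 12)
    voxel_size_mm: tuple[float, float, float] = (3.75, 3.75, 3.5)
    n_volumes: int = 146
    tr_seconds: float = 2.2
    n_per_group: tuple[int, int] = (20, 20)  # (patients, controls)
    n_sources: int = 4
    source_fwhm_mm: float = 12.0
    subject_jitter_mm: float = 1.0
    var_order: int = 1
    var_coefficients: Mapping[str, np.ndarray] = field(default_factory=dict)
    amplitude_scale: Mapping[str, np.ndarray] = field(default_factory=dict)
    noise_sd: float = 1.5
    severity_target_r: float = -0.30
    severity_source: int = 0
    outlier_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.grid_dims) or len(self.grid_dims) != 3:
            raise ValueError("grid_dims must be 3 positive integers")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be positive")
        if self.n_volumes <= self.var_order + 10:
            raise ValueError("n_volumes must exceed var_order + 10")
        if self.n_sources >= self.n_volumes:
            raise ValueError(
                f"n_sources ({self.n_sources}) must be < n_volumes ({self.n_volumes})"
            )
        if int(np.prod(self.grid_dims)) < 10 * self.n_sources:
            raise ValueError("grid voxel count must be >= 10 x n_sources")
        if not (0.0 <= self.outlier_rate < 1.0):
            raise ValueError("outlier_rate must lie in [0, 1)")
        if abs(self.severity_target_r) > 1.0:
            raise ValueError("severity_target_r must lie in [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        # Fill structural defaults, then enforce stationarity.
        coeffs = dict(self.var_coefficients)
        amps = dict(self.amplitude_scale)
        for g in GROUPS:
            if g not in coeffs:
                coeffs[g] = _default_var(self.var_order, self.n_sources, g)
            coeffs[g] = np.asarray(coeffs[g], dtype=float)
            if coeffs[g].shape != (self.var_order, self.n_sources, self.n_sources):
                raise ValueError(
                    f"var_coefficients[{g!r}] must have shape "
                    f"({self.var_order}, {self.n_sources}, {self.n_sources})"
                )
            if g not in amps:
                amps[g] = _default_amplitudes(self.n_sources, g)
            amps[g] = np.asarray(amps[g], dtype=float)
            if amps[g].shape != (self.n_sources,) or np.any(amps[g] <= 0):
                raise ValueError(f"amplitude_scale[{g!r}] must be K positive reals")
            rho = companion_spectral_radius(coeffs[g])
            if rho >= 1.0:
                raise ValueError(
                    f"VAR model for group {g!r} is non-stationary: "
                    f"companion spectral radius {rho:.3f} >= 1"
                )
        object.__setattr__(self, "var_coefficients", coeffs)
        object.__setattr__(self, "amplitude_scale", amps)

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_group))


def _default_var(p: int, k: int, group: str) -> np.ndarray:
    """Default planted causal structure.

    Control group, lag 1: every source is AR(0.3); directed edges
    2 -> 0 (0.5) and 0 -> 3 (0.5), forming a chain 2 -> 0 -> 3 mediated by
    source 0 with no direct 2 -> 3 link. The patient-like group carries
    the same edges at half strength. Source 1 (the amplitude-strengthened
    one) receives no planted input, so its time-course variance is
    identical across groups and amplitude is the only group effect on it.
    """
    a = np.zeros((p, k, k))
    a[0] += np.eye(k) * 0.3
    strength = 0.5 if group == CONTROL else 0.25
    if k >= 3:
        a[0, 0, 2] = strength
    if k >= 4:
        a[0, 3, 0] = strength
    return a


def _default_amplitudes(k: int, group: str) -> np.ndarray:
    """Patient-like group: sources 0 and 2 weakened (x0.7), source 1
    strengthened (x1.3); controls at unit amplitude."""
    amps = np.ones(k)
    if group == PATIENT:
        if k >= 1:
            amps[0] = 0.7
        if k >= 3:
            amps[2] = 0.7
        if k >= 2:
            amps[1] = 1.3
    return amps


def default_spec(**overrides) -> CohortSpec:
    """The default study conditions used throughout the test-bench."""
    return CohortSpec(**overrides)


@dataclass
class SubjectSeries:
    """One subject's 4D BOLD-like data plus covariates and motion trace."""

    subject_id: str
    group: str
    age: float
    sex: str
    severity: float | None
    data: np.ndarray  # (x, y, z, t)
    mask: np.ndarray  # (x, y, z) boolean
    tr_seconds: float
    voxel_size_mm: tuple[float, float, float]
    motion: np.ndarray  # (t, 6): 3 translations mm, 3 rotations deg

    def __post_init__(self) -> None:
        if self.data.shape[-1] != self.motion.shape[0]:
            raise ValueError("data time length must equal motion trace length")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match spatial dims")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[-1])


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream recovery checks."""

    source_maps: np.ndarray  # (K, x, y, z) canonical, pre-jitter
    subject_source_maps: dict[str, np.ndarray]  # id -> (K, x, y, z)
    timecourses: dict[str, np.ndarray]  # id -> (K, T) amplitude-scaled
    var_adjacency: dict[str, list[tuple]]  # group -> [(src, dst, lag, coef)]
    mediated_chains: list[tuple[int, int, int]]  # (src, mediator, dst)
    group_effects: dict[str, list]
    severity_scores: dict[str, float]
    subject_amplitudes: dict[str, np.ndarray]  # id -> (K,) realized scales
    outlier_indices: dict[str, list[int]]

    def to_jsonable(self) -> dict:
        """JSON-safe summary (omits the dense arrays)."""
        return {
            "var_adjacency": {g: [list(e) for e in v] for g, v in self.var_adjacency.items()},
            "mediated_chains": [list(c) for c in self.mediated_chains],
            "group_effects": self.group_effects,
            "severity_scores": self.severity_scores,
            "outlier_indices": self.outlier_indices,
        }


def make_source_maps(
    grid_dims: Sequence[int],
    voxel_size_mm: Sequence[float],
    n_sources: int,
    source_fwhm_mm: float,
    subject_jitter_mm: float,
    seed,
    subject_ids: Sequence[str] | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Canonical Gaussian-blob source maps plus per-subject jittered copies.

    Centers are placed on a deterministic lattice chosen so pairwise center
    distance exceeds the FWHM; each map is a unit-peak Gaussian. Subject
    maps are the canonical maps translated by a random (spectral-shift)
    offset of magnitude <= ``subject_jitter_mm``.

    Returns ``(canonical, per_subject)`` with canonical of shape
    (K, x, y, z).
    """
    grid = tuple(int(d) for d in grid_dims)
    vox = np.asarray(voxel_size_mm, dtype=float)
    rng = np.random.default_rng(seed)
    centers = _place_centers(grid, vox, n_sources, source_fwhm_mm)
    sigma_mm = _fwhm_to_sigma(source_fwhm_mm)

    coords = np.stack(
        np.meshgrid(*[np.arange(d) * v for d, v in zip(grid, vox)], indexing="ij"),
        axis=-1,
    )  # (x, y, z, 3) physical mm coordinates

    def blob(center_mm: np.ndarray) -> np.ndarray:
        d2 = np.sum((coords - center_mm) ** 2, axis=-1)
        return np.exp(-d2 / (2.0 * sigma_mm**2))

    canonical = np.stack([blob(c) for c in centers])
    # Guard: distinct canonical sources must stay spatially dissimilar.
    flat = canonical.reshape(n_sources, -1)
    if n_sources > 1:
        cc = np.corrcoef(flat)
        off = cc[~np.eye(n_sources, dtype=bool)]
        if np.any(off >= 0.3):
            raise ValueError(
                "source placement produced overlapping maps "
                f"(max pairwise correlation {off.max():.2f})"
            )

    if subject_ids is None:
        subject_ids = []
    per_subject: dict[str, np.ndarray] = {}
    for sid in subject_ids:
        maps = []
        for k in range(n_sources):
            if subject_jitter_mm > 0:
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                offset = direction * rng.uniform(0, subject_jitter_mm)
            else:
                offset = np.zeros(3)
            maps.append(blob(centers[k] + offset))
        per_subject[sid] = np.stack(maps)
    return canonical, per_subject


def _place_centers(
    grid: tuple[int, int, int], vox: np.ndarray, n_sources: int, fwhm_mm: float
) -> np.ndarray:
    """Deterministic center placement on an interior lattice.

    Candidate sites sit at 1/4 and 3/4 of each axis extent (8 octant
    sites), taken in an order that maximizes spread; rejects if the grid
    cannot hold the requested sources at pairwise distance > FWHM.
    """
    extent = (np.asarray(grid) - 1) * vox
    lo, hi = extent * 0.25, extent * 0.75
    octants = [
        (0, 0, 0), (1, 1, 1), (1, 0, 0), (0, 1, 1),
        (0, 1, 0), (1, 0, 1), (0, 0, 1), (1, 1, 0),
    ]
    sites = np.array([[hi[a] if o[a] else lo[a] for a in range(3)] for o in octants])
    if n_sources > len(sites):
        raise ValueError(f"cannot place {n_sources} sources on this grid (max 8)")
    centers = sites[:n_sources]
    if n_sources > 1:
        dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        mind = dists[~np.eye(n_sources, dtype=bool)].min()
        if mind <= fwhm_mm:
            raise ValueError(
                f"grid too small: minimum center distance {mind:.1f} mm "
                f"does not exceed source FWHM {fwhm_mm:.1f} mm"
            )
    return centers


def generate_severity(amplitudes: np.ndarray, target_r: float, seed) -> np.ndarray:
    """Severity scores with population correlation ``target_r`` to the
    supplied amplitudes.

    severity = r * z(amplitude) + sqrt(1 - r^2) * independent N(0,1) noise,
    then standardized to mean 0, sd 1.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.size < 3:
        raise ValueError("need at least 3 subjects for severity generation")
    if np.allclose(amplitudes, amplitudes[0]):
        raise ValueError("amplitudes must not be all equal")
    if abs(target_r) > 1.0:
        raise ValueError("|target_r| must be <= 1")
    rng = np.random.default_rng(seed)
    z = (amplitudes - amplitudes.mean()) / amplitudes.std()
    noise = rng.standard_normal(amplitudes.size)
    sev = target_r * z + np.sqrt(1.0 - target_r**2) * noise
    sd = sev.std()
    if sd == 0:  # only at |target_r| == 1 with degenerate z; z has sd 1 here
        sd = 1.0
    return (sev - sev.mean()) / sd


def simulate_var(
    coeffs: np.ndarray, n_steps: int, rng: np.random.Generator, burn_in: int = 100
) -> np.ndarray:
    """Simulate a stationary VAR(p) with unit-variance Gaussian innovations.

    Returns array of shape (K, n_steps).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    p, k, _ = coeffs.shape
    total = n_steps + burn_in
    x = np.zeros((total, k))
    eps = rng.standard_normal((total, k))
    for t in range(total):
        acc = eps[t].copy()
        for lag in range(1, p + 1):
            if t - lag >= 0:
                acc += coeffs[lag - 1] @ x[t - lag]
        x[t] = acc
    return x[burn_in:].T


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectSeries], GroundTruth]:
    """Generate the full cohort described by ``spec``.

    Each subject's data are
    ``sum_k amp_k(subject) * map_k(subject, voxel) * tc_k(t) + noise`` with
    time courses drawn from the subject's group VAR model. Outlier volumes
    (rate ``spec.outlier_rate``) receive a translation jump in the motion
    trace and a global intensity spike.
    """
    root = np.random.SeedSequence(spec.seed)
    seeds = root.spawn(5)
    rng_maps_seed = seeds[0]
    rng_demo = np.random.default_rng(seeds[1])
    rng_subject_root = seeds[2]
    rng_sev_seed = seeds[3]
    rng_amp = np.random.default_rng(seeds[4])

    n_pat, n_con = spec.n_per_group
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n_pat + n_con)]
    groups = [PATIENT] * n_pat + [CONTROL] * n_con

    canonical, per_subject_maps = make_source_maps(
        spec.grid_dims,
        spec.voxel_size_mm,
        spec.n_sources,
        spec.source_fwhm_mm,
        spec.subject_jitter_mm,
        rng_maps_seed,
        subject_ids=subject_ids,
    )
    mask = np.ones(spec.grid_dims, dtype=bool)

    # Group-matched demographics: ages uniform over the emulated 8-49 y
    # range, sexes assigned proportionally within each group.
    ages = rng_demo.uniform(8.0, 49.0, size=len(subject_ids))
    sexes: list[str] = []
    for g, n in ((PATIENT, n_pat), (CONTROL, n_con)):
        n_male = int(round(n * 0.6))  # male-skewed, as in stuttering samples
        sx = ["M"] * n_male + ["F"] * (n - n_male)
        sexes.extend(sx)

    subject_seeds = rng_subject_root.spawn(len(subject_ids))
    series: list[SubjectSeries] = []
    timecourses: dict[str, np.ndarray] = {}
    subject_amplitudes: dict[str, np.ndarray] = {}
    outlier_indices: dict[str, list[int]] = {}
    t = spec.n_volumes

    for i, sid in enumerate(subject_ids):
        g = groups[i]
        rng = np.random.default_rng(subject_seeds[i])
        tc = simulate_var(spec.var_coefficients[g], t, rng)
        # Per-subject amplitude: group scale times lognormal jitter; the
        # jitter is what a severity score can correlate with.
        jitter = np.exp(rng_amp.normal(0.0, 0.25, size=spec.n_sources))
        amps = spec.amplitude_scale[g] * jitter
        tc_scaled = tc * amps[:, None]
        maps = per_subject_maps[sid]
        data = np.tensordot(maps, tc_scaled, axes=(0, 0))  # (x,y,z,t)
        if spec.noise_sd > 0:
            data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)

        motion = np.zeros((t, 6))
        drift = rng.normal(0.0, 0.02, size=(t, 6)).cumsum(axis=0)
        motion += drift
        flagged: list[int] = []
        if spec.outlier_rate > 0:
            n_out = rng.binomial(t - 1, spec.outlier_rate)
            if n_out > 0:
                flagged = sorted(
                    rng.choice(np.arange(1, t), size=n_out, replace=False).tolist()
                )
            for idx in flagged:
                motion[idx, :3] += rng.choice([-1, 1], size=3) * rng.uniform(1.0, 3.0, 3)
                data[..., idx] += rng.uniform(3.0, 6.0) * spec.noise_sd + 1.0

        series.append(
            SubjectSeries(
                subject_id=sid,
                group=g,
                age=float(ages[i]),
                sex=sexes[i],
                severity=None,
                data=data,
                mask=mask,
                tr_seconds=spec.tr_seconds,
                voxel_size_mm=spec.voxel_size_mm,
                motion=motion,
            )
        )
        timecourses[sid] = tc_scaled
        subject_amplitudes[sid] = amps
        outlier_indices[sid] = flagged

    # Severity: patients only, driven by the realized amplitude of the
    # designated source.
    pat_ids = [s.subject_id for s in series if s.group == PATIENT]
    severity_scores: dict[str, float] = {}
    if len(pat_ids) >= 3:
        amp_vec = np.array(
            [subject_amplitudes[sid][spec.severity_source] for sid in pat_ids]
        )
        sev = generate_severity(amp_vec, spec.severity_target_r, rng_sev_seed)
        for sid, v in zip(pat_ids, sev):
            severity_scores[sid] = float(v)
            for s in series:
                if s.subject_id == sid:
                    s.severity = float(v)

    var_adjacency = {
        g: [
            (int(j), int(i), int(lag + 1), float(spec.var_coefficients[g][lag, i, j]))
            for lag in range(spec.var_order)
            for i in range(spec.n_sources)
            for j in range(spec.n_sources)
            if i != j and spec.var_coefficients[g][lag, i, j] != 0.0
        ]
        for g in GROUPS
    }
    mediated = _find_mediated_chains(var_adjacency[CONTROL])
    amp_effects = [
        (int(k), float(spec.amplitude_scale[PATIENT][k] / spec.amplitude_scale[CONTROL][k]))
        for k in range(spec.n_sources)
        if not np.isclose(spec.amplitude_scale[PATIENT][k], spec.amplitude_scale[CONTROL][k])
    ]
    coef_effects = []
    for g_edge in var_adjacency[CONTROL]:
        src, dst, lag, c_con = g_edge
        c_pat = float(spec.var_coefficients[PATIENT][lag - 1, dst, src])
        if not np.isclose(c_pat, c_con):
            coef_effects.append((src, dst, lag, c_pat - c_con))
    truth = GroundTruth(
        source_maps=canonical,
        subject_source_maps=per_subject_maps,
        timecourses=timecourses,
        var_adjacency=var_adjacency,
        mediated_chains=mediated,
        group_effects={
            "amplitude_ratio": amp_effects,
            "coefficient_difference": coef_effects,
        },
        severity_scores=severity_scores,
        subject_amplitudes=subject_amplitudes,
        outlier_indices=outlier_indices,
    )
    return series, truth


def _find_mediated_chains(edges: Iterable[tuple]) -> list[tuple[int, int, int]]:
    """Chains (a, m, b) with planted a->m and m->b but no direct a->b."""
    direct = {(e[0], e[1]) for e in edges}
    chains = []
    for a, m in direct:
        for m2, b in direct:
            if m2 == m and b != a and (a, b) not in direct:
                chains.append((a, m, b))
    return sorted(chains)


# ---------------------------------------------------------------------------
# I/O: NIfTI volumes, phenotype TSV, motion text, ground-truth JSON.

def write_cohort(series: list[SubjectSeries], truth: GroundTruth, out_dir) -> None:
    """Write one 4D NIfTI per subject, a phenotype TSV, per-subject motion
    traces and a JSON ground-truth summary."""
    import nibabel as nib
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in series:
        affine = np.diag(list(s.voxel_size_mm) + [1.0])
        img = nib.Nifti1Image(s.data.astype(np.float32), affine)
        img.header.set_zooms(tuple(s.voxel_size_mm) + (s.tr_seconds,))
        nib.save(img, out / f"{s.subject_id}_bold.nii")
        np.savetxt(out / f"{s.subject_id}_motion.txt", s.motion, fmt="%.6f")
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": round(s.age, 2),
                "sex": s.sex,
                "severity": "" if s.severity is None else round(s.severity, 4),
            }
        )
    pd.DataFrame(rows).to_csv(out / "phenotype.tsv", sep="\t", index=False)
    mask_img = nib.Nifti1Image(
        series[0].mask.astype(np.uint8), np.diag(list(series[0].voxel_size_mm) + [1.0])
    )
    nib.save(mask_img, out / "mask.nii")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=2)


def load_cohort(in_dir) -> list[SubjectSeries]:
    """Read a cohort previously written by :func:`write_cohort`."""
    import nibabel as nib
    import pandas as pd

    src = Path(in_dir)
    pheno = pd.read_csv(src / "phenotype.tsv", sep="\t")
    mask = np.asarray(nib.load(src / "mask.nii").dataobj).astype(bool)
    series = []
    for _, row in pheno.iterrows():
        sid = row["subject_id"]
        img = nib.load(src / f"{sid}_bold.nii")
        data = np.asarray(img.dataobj, dtype=float)
        zooms = img.header.get_zooms()
        motion = np.loadtxt(src / f"{sid}_motion.txt")
        sev = row["severity"]
        series.append(
            SubjectSeries(
                subject_id=sid,
                group=row["group"],
                age=float(row["age"]),
                sex=row["sex"],
                severity=None if pd.isna(sev) else float(sev),
                data=data,
                mask=mask,
                tr_seconds=float(zooms[3]) if len(zooms) > 3 else 2.2,
                voxel_size_mm=tuple(float(z) for z in zooms[:3]),
                motion=motion,
            )
        )
    return series
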