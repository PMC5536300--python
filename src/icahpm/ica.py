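"""PCA reduction and single-subject spatial ICA.

The decomposition treats each time point as an observation over voxels:
the T' x M data matrix is reduced to N x M by projecting onto the top N
temporal principal components (whitened), and a fixed-point ICA then
rotates the whitened rows to maximize non-Gaussianity of the spatial maps.
Each recovered component is a z-scored spatial map over the mask together
with its associated time course.

Model orders are enumerated over a configurable range; the full-scale
enumeration 20..130 in steps of 10 yields 12 component sets per subject,
while a desk-scale grid uses a lower range (130 components are degenerate
on a toy grid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "ICMap",
    "ICSet",
    "PCAReduction",
    "enumerate_model_orders",
    "reduce_pca",
    "extract_spatial_ics",
    "decompose_subject",
]


def enumerate_model_orders(lower: int = 20, upper: int = 130, step: int = 10) -> list[int]:
    """Arithmetic sequence of ICA model orders, inclusive of ``upper`` when
    it lies on the grid (the full-scale default 20..130 gives 12 orders)."""
    if step <= 0:
        raise ValueError("step must be positive")
    if lower > upper:
        raise ValueError("lower bound must not exceed upper bound")
    return list(range(lower, upper + 1, step))


@dataclass
class ICMap:
    """One spatial independent component: z-scored map plus time course."""

    subject_id: str
    model_order: int
    component_index: int
    spatial_z: np.ndarray  # over mask voxels, mean 0 sd 1
    timecourse: np.ndarray  # length T'
    convergence_flag: bool = True


@dataclass
class ICSet:
    subject_id: str
    model_order: int
    components: list[ICMap]
    pca_explained_variance: float

    def __post_init__(self) -> None:
        if len(self.components) != self.model_order:
            raise ValueError("ICSet must hold exactly model_order components")


@dataclass
class PCAReduction:
    """Whitening record for a T' x M -> N x M reduction."""

    reduced: np.ndarray  # (N, M) whitened: reduced @ reduced.T / M = I
    basis: np.ndarray  # (N, T') rows project centered data to whitened space
    eigenvalues: np.ndarray  # all T' temporal eigenvalues, descending
    row_means: np.ndarray  # per-time-point voxel means removed
    explained_variance: float = field(init=False)
    reconstruction_error: float = field(init=False)

    def __post_init__(self) -> None:
        n = self.reduced.shape[0]
        total = float(self.eigenvalues.sum())
        kept = float(self.eigenvalues[:n].sum())
        self.explained_variance = kept / total if total > 0 else 1.0
        self.reconstruction_error = max(total - kept, 0.0)


def reduce_pca(x: np.ndarray, n_components: int) -> PCAReduction:
    """Reduce a T' x M matrix to its top-N whitened temporal components.

    Rows (time points) are centered over voxels; the temporal covariance
    ``X X^T / M`` is eigendecomposed and the top-N eigenvectors, scaled to
    unit variance, form the reduced N x M matrix. The discarded eigenvalue
    sum equals the voxel-averaged squared reconstruction error.
    """
    x = np.asarray(x, dtype=float)
    t, m = x.shape
    if n_components >= t:
        raise ValueError(
            f"requested {n_components} components but only {t} time points"
        )
    row_means = x.mean(axis=1)
    xc = x - row_means[:, None]
    cov = xc @ xc.T / m
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    top = evals[:n_components]
    if np.any(top <= 0):
        raise ValueError("data rank is below the requested component count")
    basis = (evecs[:, :n_components] / np.sqrt(top)).T  # (N, T')
    reduced = basis @ xc
    return PCAReduction(reduced=reduced, basis=basis, eigenvalues=evals, row_means=row_means)


def extract_spatial_ics(
    reduction: PCAReduction,
    n_components: int,
    seed,
    subject_id: str = "",
    data: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> ICSet:
    """Fixed-point spatial ICA on whitened data.

    Finds an orthonormal unmixing of the whitened rows maximizing
    non-Gaussianity (log-cosh contrast). Maps are z-scored over voxels and
    sign-fixed so each map's skewness is nonnegative (time course flipped
    together with the map). Time courses are the least-squares projection
    of the original data onto the maps when ``data`` (T' x M, uncentered)
    is supplied, otherwise the unmixed whitened rows' pseudo-time courses.
    """
    y = reduction.reduced
    if y.shape[0] != n_components:
        raise ValueError("reduction dimension must equal the requested order")
    rng = np.random.default_rng(seed)
    w_init = rng.standard_normal((n_components, n_components))
    def make_ica():
        return FastICA(
            algorithm="parallel",
            whiten=False,
            fun="logcosh",
            max_iter=max_iter,
            tol=tol,
            w_init=w_init,
        )

    ica = make_ica()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ica.fit(y.T)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ica = make_ica()
                ica.fit(y.T)
    w = ica.components_  # (N, N), orthonormal on whitened input
    maps = w @ y  # (N, M) spatial sources

    if data is not None:
        xc = np.asarray(data, dtype=float) - reduction.row_means[:, None]
        # Least-squares mixing: time course per map from the full data.
        tcs, *_ = np.linalg.lstsq(maps.T, xc.T, rcond=None)  # (N, T')
    else:
        # Whitened-space mixing only: A = basis^+ W^T, columns are courses.
        tcs = (np.linalg.pinv(reduction.basis) @ w.T).T
    components = []
    for k in range(n_components):
        m = maps[k]
        tc = np.asarray(tcs[k], dtype=float)
        if stats.skew(m) < 0:
            m, tc = -m, -tc
        z = (m - m.mean()) / m.std()
        components.append(
            ICMap(
                subject_id=subject_id,
                model_order=n_components,
                component_index=k,
                spatial_z=z,
                timecourse=tc,
                convergence_flag=converged,
            )
        )
    return ICSet(
        subject_id=subject_id,
        model_order=n_components,
        components=components,
        pca_explained_variance=reduction.explained_variance,
    )


def decompose_subject(
    series, model_orders: list[int], seed
) -> dict[int, ICSet]:
    """Run PCA + spatial ICA at every requested model order for one subject.

    The 4D data are flattened to T' x M over the mask; each order gets its
    own child seed so the set is reproducible order by order.
    """
    x = series.data[series.mask].T  # (T', M)
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child = root.spawn(len(model_orders))
    out: dict[int, ICSet] = {}
    for s, n in zip(child, model_orders):
        red = reduce_pca(x, n)
        out[n] = extract_spatial_ics(
            red, n, s, subject_id=series.subject_id, data=x
        )
    return out
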