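"""Subject classification from connectivity features.

Features are per-subject scalars: regional strength (mean representative
z over a significant cluster's surviving voxels) and directed causal
indices (GCIs of significant edges). Classifiers are a Gaussian-kernel
soft-margin SVM — kernel K(u, v) = exp(-||u - v||^2 / (2 w^2)) with width
w = 0.5 on standardized features — evaluated under leave-one-out and
stratified k-fold cross-validation, and a maximum-uncertainty LDA (MLDA)
whose pooled covariance eigenvalues below their mean are raised to the
mean, making the discriminant well-defined when features outnumber
subjects. Standardization and imputation statistics are always computed
inside the training fold only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "FeatureMatrix",
    "ClassificationReport",
    "build_features",
    "svm_crossval",
    "mlda_fit_loo",
    "repeated_loo",
]

PATIENT = "patient"


@dataclass
class FeatureMatrix:
    subjects: list[str]
    labels: list[str]
    features: np.ndarray  # (n, d), raw (standardization happens per fold)
    feature_names: list[str]

    def __post_init__(self) -> None:
        if self.features.ndim != 2 or self.features.shape[1] < 1:
            raise ValueError("need at least one feature")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if np.isnan(self.features).all(axis=1).any():
            raise ValueError("a subject with no features should have been excluded")

    def subset(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            subjects=list(self.subjects),
            labels=list(self.labels),
            features=self.features[:, idx].copy(),
            feature_names=list(names),
        )


@dataclass
class ClassificationReport:
    scheme: str
    accuracy: float
    sensitivity: float | None = None
    specificity: float | None = None
    contributions: dict[str, float] | None = None
    n_trials: int = 1
    accuracy_sd: float = 0.0
    predictions: list[str] = field(default_factory=list)


def build_features(
    subjects: list[str],
    regional: dict[str, dict[str, float]] | None = None,
    edge_gcis: dict[str, dict[str, float | None]] | None = None,
) -> FeatureMatrix:
    """Assemble the subjects x d feature matrix.

    ``regional`` maps feature name (e.g. ``"z:cluster3"``) to per-subject
    scalars; ``edge_gcis`` maps edge names (e.g. ``"gci:c1->c2"``) to
    per-subject GCIs, possibly missing (None). Missing values stay NaN
    here and are imputed with the training-fold median inside each CV
    fold. Constant features are dropped with a warning; subjects missing
    every feature are excluded with a warning.
    """
    regional = regional or {}
    edge_gcis = edge_gcis or {}
    names = list(regional) + list(edge_gcis)
    if not names:
        raise ValueError("need at least one significant cluster or edge")
    cols = []
    for name in names:
        src = regional.get(name, edge_gcis.get(name))
        col = np.array(
            [np.nan if src.get(s) is None else float(src.get(s)) for s in subjects]
        )
        cols.append(col)
    x = np.column_stack(cols)
    keep_feat = []
    for j, name in enumerate(names):
        col = x[:, j]
        finite = col[~np.isnan(col)]
        if finite.size == 0 or np.all(finite == finite[0]):
            warnings.warn(f"dropping constant or empty feature {name!r}")
            continue
        keep_feat.append(j)
    if not keep_feat:
        raise ValueError("all features constant or empty")
    x = x[:, keep_feat]
    names = [names[j] for j in keep_feat]
    keep_subj = ~np.isnan(x).all(axis=1)
    if not keep_subj.all():
        dropped = [s for s, k in zip(subjects, keep_subj) if not k]
        warnings.warn(f"excluding subjects with no features: {dropped}")
    return FeatureMatrix(
        subjects=[s for s, k in zip(subjects, keep_subj) if k],
        labels=[],
        features=x[keep_subj],
        feature_names=names,
    )


def _fold_standardize(train: np.ndarray, test: np.ndarray, rng=None, jitter=0.0):
    """Impute (training-fold median) and standardize (training-fold
    moments) — no statistic touches the held-out subjects."""
    med = np.nanmedian(train, axis=0)
    tr = train.copy()
    te = test.copy()
    for j in range(tr.shape[1]):
        mj = np.isnan(tr[:, j])
        fill = med[j]
        if rng is not None and jitter > 0 and mj.any():
            tr[mj, j] = fill + rng.normal(0.0, jitter, size=mj.sum())
        else:
            tr[mj, j] = fill
        mjt = np.isnan(te[:, j])
        te[mjt, j] = fill
    mu = tr.mean(axis=0)
    sd = tr.std(axis=0)
    sd[sd == 0] = 1.0
    return (tr - mu) / sd, (te - mu) / sd


def _check_labels(labels: list[str]) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need at least 2 subjects per class")
    return y


def _sens_spec(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float | None, float | None]:
    pos = y_true == PATIENT
    neg = ~pos
    sens = float((y_pred[pos] == PATIENT).mean()) if pos.any() else None
    spec = float((y_pred[neg] != PATIENT).mean()) if neg.any() else None
    return sens, spec


def svm_crossval(
    fm: FeatureMatrix,
    labels: list[str],
    scheme: str = "loo",
    k: int = 5,
    kernel_width: float = 0.5,
    c: float = 1.0,
    seed: int = 0,
) -> ClassificationReport:
    """Gaussian-kernel SVM under LOO or stratified k-fold CV.

    The kernel is exp(-||u-v||^2 / (2 width^2)) on features standardized
    within each training fold; gamma = 1/(2 width^2). k-fold splits are
    stratified and seeded; LOO is deterministic.
    """
    y = _check_labels(labels)
    x = fm.features
    gamma = 1.0 / (2.0 * kernel_width**2)
    n = x.shape[0]
    if scheme == "loo":
        folds = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    elif scheme == "kfold":
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(skf.split(x, y))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    preds = np.empty(n, dtype=y.dtype)
    for train, test in folds:
        xtr, xte = _fold_standardize(x[train], x[test])
        clf = SVC(kernel="rbf", gamma=gamma, C=c)
        clf.fit(xtr, y[train])
        preds[test] = clf.predict(xte)
    acc = float((preds == y).mean())
    sens, spec = _sens_spec(y, preds)
    return ClassificationReport(
        scheme=f"svm_{scheme}",
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        predictions=list(preds),
    )


def _mlda_direction(xtr: np.ndarray, ytr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Maximum-uncertainty discriminant direction.

    Pooled within-class covariance is eigendecomposed; eigenvalues below
    the eigenvalue mean are replaced by the mean, and
    w = Sigma_reg^{-1} (mu1 - mu2). Always finite, even for d > n.
    """
    classes = np.unique(ytr)
    mus = [xtr[ytr == cl].mean(axis=0) for cl in classes]
    n = xtr.shape[0]
    pooled = np.zeros((xtr.shape[1], xtr.shape[1]))
    for cl, mu in zip(classes, mus):
        xc = xtr[ytr == cl] - mu
        pooled += xc.T @ xc
    pooled /= max(n - len(classes), 1)
    evals, evecs = np.linalg.eigh(pooled)
    lam = evals.mean()
    evals_reg = np.where(evals < lam, lam, evals)
    sigma_inv = (evecs / evals_reg) @ evecs.T
    w = sigma_inv @ (mus[0] - mus[1])
    return w, mus[0], mus[1]


def mlda_fit_loo(fm: FeatureMatrix, labels: list[str]) -> ClassificationReport:
    """MLDA with leave-one-out CV and hyperplane feature contributions.

    Classification projects onto w and assigns the nearest class mean
    (midpoint threshold). Contributions are |w_i| from a fit on all
    subjects, normalized by the largest |w_i|.
    """
    y = _check_labels(labels)
    x = fm.features
    n = x.shape[0]
    preds = np.empty(n, dtype=y.dtype)
    classes = np.unique(y)
    for i in range(n):
        train = np.delete(np.arange(n), i)
        xtr, xte = _fold_standardize(x[train], x[i : i + 1])
        ytr = y[train]
        w, mu0, mu1 = _mlda_direction(xtr, ytr)
        proj = float((xte @ w)[0])
        mid = float((mu0 + mu1) @ w) / 2.0
        # mu0 belongs to classes[0]; above-midpoint side is the class whose
        # mean projects higher.
        hi = classes[0] if float(mu0 @ w) >= float(mu1 @ w) else classes[1]
        lo = classes[1] if hi == classes[0] else classes[0]
        preds[i] = hi if proj >= mid else lo
    xall, _ = _fold_standardize(x, x[:0])
    w_all, *_ = _mlda_direction(xall, y)
    wmax = np.abs(w_all).max()
    contributions = {
        name: float(abs(wi) / wmax) if wmax > 0 else 0.0
        for name, wi in zip(fm.feature_names, w_all)
    }
    acc = float((preds == y).mean())
    sens, spec = _sens_spec(y, preds)
    return ClassificationReport(
        scheme="mlda_loo",
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        contributions=contributions,
        predictions=list(preds),
    )


def repeated_loo(
    fm: FeatureMatrix,
    labels: list[str],
    feature_subset: list[str],
    n_trials: int = 1000,
    kernel_width: float = 0.5,
    c: float = 1.0,
    seed: int = 0,
    imputation_jitter: float = 0.05,
) -> ClassificationReport:
    """Repeated leave-one-out evaluation of a named feature subset.

    Each trial reruns LOO with trial-specific stochastic elements (the
    imputation jitter applied to training-fold fills). With complete data
    and a deterministic solver all trials coincide and the sd is 0.
    Reports the mean accuracy and its standard deviation across trials.
    """
    if not feature_subset:
        raise ValueError("feature subset must be nonempty")
    sub = fm.subset(feature_subset)
    y = _check_labels(labels)
    x = sub.features
    n = x.shape[0]
    gamma = 1.0 / (2.0 * kernel_width**2)
    has_missing = np.isnan(x).any()
    root = np.random.SeedSequence(seed)
    trial_seeds = root.spawn(n_trials)
    accs = np.empty(n_trials)
    for tr_i in range(n_trials):
        rng = np.random.default_rng(trial_seeds[tr_i])
        preds = np.empty(n, dtype=y.dtype)
        for i in range(n):
            train = np.delete(np.arange(n), i)
            xtr, xte = _fold_standardize(
                x[train], x[i : i + 1], rng=rng if has_missing else None,
                jitter=imputation_jitter,
            )
            clf = SVC(kernel="rbf", gamma=gamma, C=c)
            clf.fit(xtr, y[train])
            preds[i] = clf.predict(xte)[0]
        accs[tr_i] = (preds == y).mean()
        if not has_missing:
            # Deterministic: every remaining trial is identical.
            accs[tr_i:] = accs[tr_i]
            break
    sens, spec = _sens_spec(y, preds)
    return ClassificationReport(
        scheme="repeated_loo",
        accuracy=float(accs.mean()),
        sensitivity=sens,
        specificity=spec,
        n_trials=n_trials,
        accuracy_sd=float(accs.std()),
        predictions=list(preds),
    )
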