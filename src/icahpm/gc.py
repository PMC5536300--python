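"""Granger causality indices between cluster time courses.

The index of x on y at order p is the Geweke-style log ratio
``GCI = ln(RSS_restricted / RSS_full)`` where the restricted model regresses
y_t on its own p lags (plus intercept) and the full model adds p lags of x.
Nesting guarantees GCI >= 0. The mediated index of x on y through m is the
drop in GCI when m's past is conditioned on in both models:
``max(0, GCI(x->y) - GCI(x->y | m))`` — large when x's influence on y is
carried by m, near zero when the influence is direct.

Group inference is nonparametric: per-group Wilcoxon signed-rank tests of
the median index against zero, and a two-sided Wilcoxon rank-sum test (with
normal approximation and tie correction; exact enumeration for small
tie-free samples) between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .hpm import ReproducibleCluster

__all__ = [
    "GCIRecord",
    "GCIGroupComparison",
    "subject_timecourse",
    "gci",
    "gci_conditional",
    "gci_via",
    "select_order",
    "group_compare",
    "rank_sum_test",
    "cohort_gci_records",
]


@dataclass
class GCIRecord:
    subject_id: str
    source_cluster: int | str
    target_cluster: int | str
    mediator_cluster: int | str | None
    var_order: int
    gci: float

    def __post_init__(self) -> None:
        if self.gci < 0:
            raise ValueError("GCI must be nonnegative")
        if self.mediator_cluster is not None and self.mediator_cluster in (
            self.source_cluster,
            self.target_cluster,
        ):
            raise ValueError("mediator must differ from source and target")


@dataclass
class GCIGroupComparison:
    edge: tuple
    group_medians: dict[str, float]
    group_iqrs: dict[str, tuple[float, float]]
    signed_rank_p: dict[str, float]
    rank_sum_z: float
    rank_sum_p: float
    n_per_group: dict[str, int]


def subject_timecourse(cluster: ReproducibleCluster, subject_id: str,
                       ic_lookup=None) -> np.ndarray | None:
    """Standardized time course of a subject's contribution to a cluster.

    A single member component gives its standardized time course; multiple
    members (pooled across orders) give the first principal component of
    their time courses, sign-aligned to the member mean. Returns None when
    the subject has no member in the cluster (missing-data marker).
    """
    tcs = [m.timecourse for m in cluster.members if m.subject_id == subject_id]
    if not tcs:
        return None
    if len(tcs) == 1:
        return _standardize(tcs[0])
    x = np.stack([_standardize(t) for t in tcs])  # (k, T)
    # PC1 over members: dominant eigenvector of the k x k Gram matrix.
    gram = x @ x.T
    evals, evecs = np.linalg.eigh(gram)
    v = evecs[:, -1]
    pc1 = v @ x
    mean_tc = x.mean(axis=0)
    if pc1 @ mean_tc < 0:
        pc1 = -pc1
    return _standardize(pc1)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("constant time course")
    return (x - x.mean()) / sd


def _lag_matrix(series: list[np.ndarray], p: int) -> tuple[np.ndarray, int]:
    """Design of lagged regressors [1, s1(t-1..t-p), s2(...), ...]."""
    t = series[0].size
    cols = [np.ones(t - p)]
    for s in series:
        for lag in range(1, p + 1):
            cols.append(s[p - lag : t - lag])
    return np.column_stack(cols), t - p


def _rss(y: np.ndarray, x: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


def gci(x: np.ndarray, y: np.ndarray, p: int = 1,
        conditioning: list[np.ndarray] | None = None) -> float:
    """Granger causality index of x on y at VAR order p.

    Optionally conditions both the restricted and full models on the past
    of additional series. Scale-invariant and nonnegative by construction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if p < 1:
        raise ValueError("order p must be >= 1")
    if y.size <= 10 * p:
        raise ValueError(f"series length {y.size} too short for order {p}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant series: regression is singular")
    cond = [np.asarray(c, dtype=float) for c in (conditioning or [])]
    target = y[p:]
    x_restricted, _ = _lag_matrix([y] + cond, p)
    x_full, _ = _lag_matrix([y] + cond + [x], p)
    rss_r = _rss(target, x_restricted)
    rss_f = _rss(target, x_full)
    if rss_f <= 0:
        return 0.0 if rss_r <= 0 else np.inf
    return max(float(np.log(rss_r / rss_f)), 0.0)


def gci_conditional(x, y, m, p: int = 1) -> float:
    """GCI of x on y given the past of mediator m."""
    return gci(x, y, p=p, conditioning=[np.asarray(m, dtype=float)])


def gci_via(x: np.ndarray, y: np.ndarray, m: np.ndarray, p: int = 1) -> float:
    """Mediated causal index of x on y through m: the conditioning drop
    ``max(0, GCI(x->y) - GCI(x->y|m))``."""
    direct = gci(x, y, p=p)
    conditional = gci(x, y, p=p, conditioning=[np.asarray(m, dtype=float)])
    return max(0.0, direct - conditional)


def gci_via_path_product(x, y, m, p: int = 1) -> float:
    """Alternative mediated index: the weaker leg of the x->m->y path."""
    return min(gci(x, m, p=p), gci(m, y, p=p))


def select_order(timecourses: list[np.ndarray], max_p: int = 3,
                 criterion: str = "bic") -> int:
    """VAR order minimizing an information criterion over a joint fit.

    All candidate orders are scored on the common effective sample (the
    last T - max_p observations) so criteria are comparable; ties break
    toward the smallest order.
    """
    if max_p < 1:
        raise ValueError("max_p must be >= 1")
    series = [np.asarray(s, dtype=float) for s in timecourses]
    t = series[0].size
    k = len(series)
    if t - max_p <= k * max_p + 1:
        raise ValueError("series too short for the requested max order")
    y_all = np.column_stack([s[max_p:] for s in series])  # (T_eff, k)
    t_eff = y_all.shape[0]
    best = (np.inf, None)
    for p in range(1, max_p + 1):
        cols = [np.ones(t_eff)]
        for s in series:
            for lag in range(1, p + 1):
                cols.append(s[max_p - lag : t - lag])
        x = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(x, y_all, rcond=None)
        resid = y_all - x @ beta
        sigma = resid.T @ resid / t_eff
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        n_params = k * x.shape[1]
        if criterion == "bic":
            score = logdet + n_params * np.log(t_eff) / t_eff
        elif criterion == "aic":
            score = logdet + 2.0 * n_params / t_eff
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        if score < best[0]:
            best = (score, p)
    if best[1] is None:
        raise ValueError("no VAR order could be scored")
    return best[1]


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of a vs b.

    Returns (z, p). z uses the normal approximation with tie correction
    and is positive when the first sample tends larger. For small tie-free
    samples (both n <= 25) the p-value is replaced by the exact
    enumeration value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    nn = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((nn) * (nn - 1))
    var = n1 * n2 / 12.0 * ((nn + 1) - tie_term)
    z = 0.0 if var == 0 else (w - mu) / np.sqrt(var)
    has_ties = np.any(tie_counts > 1)
    if not has_ties and n1 <= 25 and n2 <= 25:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        p = float(res.pvalue)
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return float(z), p


def group_compare(
    values: dict[str, float | None],
    labels: dict[str, str],
    edge: tuple = (),
    group_order: tuple[str, str] = ("patient", "control"),
) -> GCIGroupComparison:
    """Nonparametric group comparison of one edge's per-subject indices.

    Subjects with missing values are excluded listwise. Per group: median,
    interquartile range and signed-rank p against zero. Across groups: the
    rank-sum z (positive when the first-named group is larger) and its
    two-sided p.
    """
    by_group: dict[str, list[float]] = {g: [] for g in group_order}
    for sid, v in values.items():
        if v is None:
            continue
        g = labels[sid]
        if g in by_group:
            by_group[g].append(float(v))
    for g in group_order:
        if len(by_group[g]) == 0:
            raise ValueError(f"group {g!r} has no non-missing values for edge {edge}")
        if len(by_group[g]) < 5:
            raise ValueError(f"group {g!r} has fewer than 5 subjects for edge {edge}")
    medians, iqrs, signed_p = {}, {}, {}
    for g in group_order:
        v = np.asarray(by_group[g])
        medians[g] = float(np.median(v))
        q1, q3 = np.percentile(v, [25, 75])
        iqrs[g] = (float(q1), float(q3))
        if np.allclose(v, 0):
            signed_p[g] = 1.0
        else:
            signed_p[g] = float(stats.wilcoxon(v, alternative="two-sided").pvalue)
    z, p = rank_sum_test(np.asarray(by_group[group_order[0]]),
                         np.asarray(by_group[group_order[1]]))
    return GCIGroupComparison(
        edge=tuple(edge),
        group_medians=medians,
        group_iqrs=iqrs,
        signed_rank_p=signed_p,
        rank_sum_z=z,
        rank_sum_p=p,
        n_per_group={g: len(by_group[g]) for g in group_order},
    )


def cohort_gci_records(
    clusters: list[ReproducibleCluster],
    subjects: list,
    var_order: int | None = None,
    max_p: int = 3,
    edges: list[tuple] | None = None,
    mediated_edges: list[tuple] | None = None,
) -> tuple[list[GCIRecord], int]:
    """Per-subject GCIs for all (or the named) directed cluster pairs.

    A shared VAR order is selected by BIC on the first subject with
    complete time courses unless ``var_order`` is given. ``edges`` are
    (source_id, target_id) cluster-id pairs; ``mediated_edges`` are
    (source_id, target_id, mediator_id) triples.
    """
    by_id = {c.cluster_id: c for c in clusters}
    ids = sorted(by_id)
    if edges is None:
        edges = [(a, b) for a in ids for b in ids if a != b]
    if mediated_edges is None:
        mediated_edges = []

    tc_cache: dict[tuple, np.ndarray | None] = {}

    def tc(cid, sid):
        key = (cid, sid)
        if key not in tc_cache:
            tc_cache[key] = subject_timecourse(by_id[cid], sid)
        return tc_cache[key]

    if var_order is None:
        var_order = 1
        for s in subjects:
            courses = [tc(c, s.subject_id) for c in ids]
            if all(c is not None for c in courses):
                var_order = select_order(courses, max_p=max_p)
                break
    records: list[GCIRecord] = []
    for s in subjects:
        sid = s.subject_id
        for a, b in edges:
            xa, yb = tc(a, sid), tc(b, sid)
            if xa is None or yb is None:
                continue
            records.append(
                GCIRecord(sid, a, b, None, var_order, gci(xa, yb, p=var_order))
            )
        for a, b, m in mediated_edges:
            xa, yb, mm = tc(a, sid), tc(b, sid), tc(m, sid)
            if xa is None or yb is None or mm is None:
                continue
            records.append(
                GCIRecord(sid, a, b, m, var_order, gci_via(xa, yb, mm, p=var_order))
            )
    return records, var_order
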