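"""Hierarchical partner matching of independent components.

Stage 1 matches components across participants within one model order:
pairs of components from two subjects are partners when each is the
other's best Tanimoto match (bidirectional matching), and connected
components of the resulting graph — restricted to those spanning a minimum
fraction of subjects — form clusters. A one-sample t test over member
z-maps gives each cluster a map, and Cronbach's alpha over members
(items = maps, observations = voxels) scores its internal consistency.

Stage 2 repeats bidirectional matching on the cluster t-maps across model
orders and retains order-spanning, high-alpha groups as reproducible
clusters, each with per-subject representative maps (mean of the subject's
member components pooled across orders) and a final t-map recomputed from
those representatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .ica import ICMap, ICSet

__all__ = [
    "MatchEdge",
    "WithinOrderCluster",
    "ReproducibleCluster",
    "tanimoto_similarity",
    "tanimoto_distance",
    "similarity_matrix",
    "bidirectional_match",
    "form_clusters_within_order",
    "cluster_t_map",
    "cronbach_alpha",
    "match_across_orders",
    "run_hpm",
]

DEGENERATE_T_CAP = 1e6


@dataclass(frozen=True)
class MatchEdge:
    ic_a: tuple  # (subject_id or order key, component index)
    ic_b: tuple
    similarity: float


def tanimoto_similarity(
    map_a: np.ndarray,
    map_b: np.ndarray,
    mode: str = "continuous",
    z_threshold: float = 2.0,
) -> float:
    """Tanimoto spatial similarity of two maps on the same mask.

    Continuous mode computes <a,b> / (<a,a> + <b,b> - <a,b>) on the maps
    clipped to nonnegative values; binary mode is intersection-over-union
    of the supra-threshold voxel sets (z >= ``z_threshold``). Both are
    symmetric, lie in [0, 1], and equal 1 only for identical inputs (after
    clipping or thresholding). Empty maps give 0 with a warning.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must live on the same mask")
    if mode == "continuous":
        a = np.clip(a, 0.0, None)
        b = np.clip(b, 0.0, None)
        ab = float(a @ b)
        denom = float(a @ a) + float(b @ b) - ab
        if denom <= 0:
            warnings.warn("both maps empty after clipping; similarity set to 0")
            return 0.0
        return ab / denom
    elif mode == "binary":
        sa = a >= z_threshold
        sb = b >= z_threshold
        union = np.count_nonzero(sa | sb)
        if union == 0:
            warnings.warn("both maps empty after thresholding; similarity set to 0")
            return 0.0
        return np.count_nonzero(sa & sb) / union
    raise ValueError(f"unknown mode {mode!r}")


def tanimoto_distance(map_a, map_b, **kw) -> float:
    """1 - Tanimoto similarity (exposed for completeness)."""
    return 1.0 - tanimoto_similarity(map_a, map_b, **kw)


def similarity_matrix(
    maps_a: np.ndarray, maps_b: np.ndarray, mode: str = "continuous",
    z_threshold: float = 2.0,
) -> np.ndarray:
    """All-pairs Tanimoto similarities between two stacks of maps
    (vectorized equivalent of calling :func:`tanimoto_similarity`)."""
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if mode == "continuous":
        a = np.clip(a, 0.0, None)
        b = np.clip(b, 0.0, None)
        ab = a @ b.T
        aa = np.sum(a * a, axis=1)[:, None]
        bb = np.sum(b * b, axis=1)[None, :]
        denom = aa + bb - ab
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(denom > 0, ab / denom, 0.0)
        return sim
    elif mode == "binary":
        sa = a >= z_threshold
        sb = b >= z_threshold
        inter = sa.astype(float) @ sb.T.astype(float)
        union = (
            np.count_nonzero(sa, axis=1)[:, None]
            + np.count_nonzero(sb, axis=1)[None, :]
            - inter
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(union > 0, inter / union, 0.0)
    raise ValueError(f"unknown mode {mode!r}")


def bidirectional_match(
    set_a: ICSet | list[np.ndarray],
    set_b: ICSet | list[np.ndarray],
    mode: str = "continuous",
    z_threshold: float = 2.0,
    key_a=None,
    key_b=None,
) -> list[MatchEdge]:
    """Mutual-best-match pairs between two component sets.

    Component i of A pairs with component j of B exactly when j is A-i's
    best match in B and i is B-j's best match in A. Ties break toward the
    lowest component index (argmax returns the first maximum).
    """
    maps_a, ka = _as_map_stack(set_a, key_a)
    maps_b, kb = _as_map_stack(set_b, key_b)
    if len(maps_a) == 0 or len(maps_b) == 0:
        raise ValueError("both sets must be nonempty")
    sim = similarity_matrix(maps_a, maps_b, mode=mode, z_threshold=z_threshold)
    best_b = np.argmax(sim, axis=1)  # per A component
    best_a = np.argmax(sim, axis=0)  # per B component
    edges = []
    for i, j in enumerate(best_b):
        if best_a[j] == i:
            edges.append(
                MatchEdge(ic_a=(ka, int(i)), ic_b=(kb, int(j)), similarity=float(sim[i, j]))
            )
    return edges


def _as_map_stack(s, key):
    if isinstance(s, ICSet):
        return np.stack([c.spatial_z for c in s.components]), (
            key if key is not None else s.subject_id
        )
    arr = np.stack([np.asarray(m, dtype=float) for m in s])
    return arr, key


@dataclass
class WithinOrderCluster:
    model_order: int
    members: list[ICMap]
    alpha: float = np.nan
    t_map: np.ndarray | None = None
    degenerate_voxels: np.ndarray | None = None

    @property
    def subject_ids(self) -> list[str]:
        return [m.subject_id for m in self.members]


@dataclass
class ReproducibleCluster:
    cluster_id: int
    members: list[ICMap]
    alpha: float
    t_map: np.ndarray
    subject_representatives: dict[str, np.ndarray]
    orders: list[int] = field(default_factory=list)

    @property
    def subject_ids(self) -> list[str]:
        return sorted(self.subject_representatives)


def form_clusters_within_order(
    ic_sets: list[ICSet],
    min_subject_fraction: float = 0.5,
    mode: str = "continuous",
    z_threshold: float = 2.0,
) -> list[WithinOrderCluster]:
    """Stage-1 clusters at one model order.

    Nodes are every subject's components; edges are bidirectional matches
    for every subject pair; clusters are connected components spanning at
    least ``min_subject_fraction`` of subjects. Within a cluster each
    subject keeps at most one component (the one with the highest mean
    similarity to the other members).
    """
    if len(ic_sets) < 2:
        raise ValueError("need at least 2 subjects to form clusters")
    order = ic_sets[0].model_order
    if any(s.model_order != order for s in ic_sets):
        raise ValueError("all ICSets must share the model order")
    n_subjects = len(ic_sets)
    g = nx.Graph()
    comp_lookup: dict[tuple, ICMap] = {}
    for s in ic_sets:
        for c in s.components:
            node = (s.subject_id, c.component_index)
            g.add_node(node)
            comp_lookup[node] = c
    for i in range(n_subjects):
        for j in range(i + 1, n_subjects):
            for e in bidirectional_match(
                ic_sets[i], ic_sets[j], mode=mode, z_threshold=z_threshold
            ):
                g.add_edge(e.ic_a, e.ic_b, similarity=e.similarity)

    clusters: list[WithinOrderCluster] = []
    floor = min_subject_fraction * n_subjects
    for nodes in nx.connected_components(g):
        nodes = sorted(nodes)
        subs = {n[0] for n in nodes}
        if len(nodes) < 2 or len(subs) < floor:
            continue
        members = _dedup_subjects(nodes, comp_lookup, mode, z_threshold)
        clusters.append(WithinOrderCluster(model_order=order, members=members))
    if not clusters:
        warnings.warn("no cluster passed the subject-membership floor")
    for cl in clusters:
        if len(cl.members) >= 2:
            cl.alpha = cronbach_alpha(np.stack([m.spatial_z for m in cl.members]))
        if len(cl.members) >= 3:
            cl.t_map, cl.degenerate_voxels = cluster_t_map(
                np.stack([m.spatial_z for m in cl.members])
            )
    clusters.sort(key=lambda c: (-len(c.members), c.members[0].component_index))
    return clusters


def _dedup_subjects(nodes, comp_lookup, mode, z_threshold) -> list[ICMap]:
    """Keep one component per subject: highest mean similarity to the
    members owned by *other* subjects."""
    maps = np.stack([comp_lookup[n].spatial_z for n in nodes])
    sim = similarity_matrix(maps, maps, mode=mode, z_threshold=z_threshold)
    subjects = [n[0] for n in nodes]
    keep: dict[str, int] = {}
    for idx, (node, sub) in enumerate(zip(nodes, subjects)):
        others = [k for k, s2 in enumerate(subjects) if s2 != sub]
        score = float(np.mean(sim[idx, others])) if others else 0.0
        best = keep.get(sub)
        if best is None or score > best[1]:
            keep[sub] = (idx, score)
    chosen = sorted(v[0] for v in keep.values())
    return [comp_lookup[nodes[i]] for i in chosen]


def cluster_t_map(member_maps: np.ndarray, cap: float = DEGENERATE_T_CAP) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise one-sample t over the k member z-maps.

    t = mean / (sd / sqrt(k)), sd with k-1 degrees of freedom. Voxels with
    zero variance and zero mean give t = 0; zero variance with nonzero
    mean gives the cap value (sign of the mean) and is flagged.
    """
    x = np.asarray(member_maps, dtype=float)
    k = x.shape[0]
    if k < 3:
        raise ValueError("cluster t-map needs at least 3 members")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    degenerate = (sd == 0) & (mean != 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(k))
    t[(sd == 0) & (mean == 0)] = 0.0
    t[degenerate] = np.sign(mean[degenerate]) * cap
    return t, degenerate


def cronbach_alpha(member_maps: np.ndarray) -> float:
    """Cronbach's alpha with member maps as items and voxels as
    observations: (k/(k-1)) * (1 - sum(item variances)/variance(sum))."""
    x = np.asarray(member_maps, dtype=float)
    k = x.shape[0]
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    item_vars = x.var(axis=1, ddof=1)
    total_var = x.sum(axis=0).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance across voxels")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def match_across_orders(
    per_order_clusters: dict[int, list[WithinOrderCluster]],
    alpha_threshold: float = 0.7,
    min_orders_fraction: float = 0.5,
    mode: str = "continuous",
    z_threshold: float = 2.0,
) -> list[ReproducibleCluster]:
    """Stage-2 matching of cluster t-maps across model orders.

    Bidirectional matching is applied to every order pair; connected
    components over the order-level graph that span at least
    ``min_orders_fraction`` of orders and reach ``alpha_threshold`` are
    retained. Per-subject representatives are the mean of the subject's
    member components pooled across orders; the final t-map is recomputed
    from those representatives.
    """
    orders = sorted(o for o, cl in per_order_clusters.items() if cl)
    if len(orders) < 2:
        raise ValueError("need clusters from at least 2 model orders")
    usable = {
        o: [c for c in per_order_clusters[o] if c.t_map is not None]
        for o in orders
    }
    orders = [o for o in orders if usable[o]]
    if len(orders) < 2:
        raise ValueError("need t-maps from at least 2 model orders")

    g = nx.Graph()
    for o in orders:
        for i in range(len(usable[o])):
            g.add_node((o, i))
    for a_idx in range(len(orders)):
        for b_idx in range(a_idx + 1, len(orders)):
            oa, ob = orders[a_idx], orders[b_idx]
            maps_a = [c.t_map for c in usable[oa]]
            maps_b = [c.t_map for c in usable[ob]]
            for e in bidirectional_match(
                maps_a, maps_b, mode=mode, z_threshold=z_threshold, key_a=oa, key_b=ob
            ):
                g.add_edge((oa, e.ic_a[1]), (ob, e.ic_b[1]))

    results: list[ReproducibleCluster] = []
    floor = min_orders_fraction * len(orders)
    cid = 0
    for nodes in sorted(nx.connected_components(g), key=lambda ns: sorted(ns)[0]):
        spanned = {o for o, _ in nodes}
        if len(spanned) < floor or len(nodes) < 2:
            continue
        members: list[ICMap] = []
        for o, i in sorted(nodes):
            members.extend(usable[o][i].members)
        by_subject: dict[str, list[np.ndarray]] = {}
        for m in members:
            by_subject.setdefault(m.subject_id, []).append(m.spatial_z)
        reps = {s: np.mean(np.stack(v), axis=0) for s, v in by_subject.items()}
        rep_stack = np.stack(list(reps.values()))
        if rep_stack.shape[0] < 3:
            continue
        alpha = cronbach_alpha(rep_stack)
        if alpha < alpha_threshold:
            continue
        t_map, _ = cluster_t_map(rep_stack)
        results.append(
            ReproducibleCluster(
                cluster_id=cid,
                members=members,
                alpha=alpha,
                t_map=t_map,
                subject_representatives=reps,
                orders=sorted(spanned),
            )
        )
        cid += 1
    if not results:
        warnings.warn("no reproducible cluster survived the alpha/order thresholds")
    return results


def run_hpm(
    ic_sets_by_order: dict[int, list[ICSet]],
    min_subject_fraction: float = 0.5,
    alpha_threshold: float = 0.7,
    min_orders_fraction: float = 0.5,
    mode: str = "continuous",
    z_threshold: float = 2.0,
) -> list[ReproducibleCluster]:
    """Both HPM stages: within-order clustering then across-order matching."""
    per_order = {
        o: form_clusters_within_order(
            sets, min_subject_fraction=min_subject_fraction, mode=mode,
            z_threshold=z_threshold,
        )
        for o, sets in ic_sets_by_order.items()
    }
    return match_across_orders(
        per_order,
        alpha_threshold=alpha_threshold,
        min_orders_fraction=min_orders_fraction,
        mode=mode,
        z_threshold=z_threshold,
    )
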