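"""Support for scripts/acceptance.py: a minimal series factory and an
independent brute-force construction of bidirectional-match clusters
(mirrors the oracle used in the test suite)."""

from __future__ import annotations

import numpy as np

from icahpm.cohort import SubjectSeries


def make_series(n_volumes=146, shape=(6, 6, 4), seed=0):
    rng = np.random.default_rng(seed)
    return SubjectSeries(
        subject_id="sub-001",
        group="control",
        age=25.0,
        sex="F",
        severity=None,
        data=rng.normal(size=shape + (n_volumes,)),
        mask=np.ones(shape, dtype=bool),
        tr_seconds=2.2,
        voxel_size_mm=(3.75, 3.75, 3.5),
        motion=np.zeros((n_volumes, 6)),
    )


def brute_force_clusters(ic_sets, min_subject_fraction=0.5):
    """Exhaustive pairwise mutual-best matching + union-find, with the
    subject floor and one-member-per-subject rule applied explicitly."""

    def sim(u, v):
        a = np.clip(u, 0, None)
        b = np.clip(v, 0, None)
        ab = a @ b
        den = a @ a + b @ b - ab
        return ab / den if den > 0 else 0.0

    nodes = [
        (s.subject_id, c.component_index, c.spatial_z)
        for s in ic_sets
        for c in s.components
    ]
    key = {(n[0], n[1]): i for i, n in enumerate(nodes)}
    parent = list(range(len(nodes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(len(ic_sets)):
        for j in range(len(ic_sets)):
            if i >= j:
                continue
            a_set, b_set = ic_sets[i], ic_sets[j]
            for ca in a_set.components:
                sims_b = [sim(ca.spatial_z, cb.spatial_z) for cb in b_set.components]
                jb = int(np.argmax(sims_b))
                sims_a = [
                    sim(b_set.components[jb].spatial_z, cx.spatial_z)
                    for cx in a_set.components
                ]
                if int(np.argmax(sims_a)) == ca.component_index:
                    union(key[(a_set.subject_id, ca.component_index)],
                          key[(b_set.subject_id, jb)])

    groups = {}
    for idx in range(len(nodes)):
        groups.setdefault(find(idx), []).append(idx)
    n_subj = len(ic_sets)
    out = []
    for g in groups.values():
        if len(g) < 2:
            continue
        subs = {nodes[i][0] for i in g}
        if len(subs) < min_subject_fraction * n_subj:
            continue
        chosen = {}
        for i in g:
            sid = nodes[i][0]
            others = [j for j in g if nodes[j][0] != sid]
            score = (
                np.mean([sim(nodes[i][2], nodes[j][2]) for j in others])
                if others
                else 0.0
            )
            if sid not in chosen or score > chosen[sid][1]:
                chosen[sid] = (i, score)
        out.append(frozenset((nodes[i][0], nodes[i][1]) for i, _ in chosen.values()))
    return set(out)
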