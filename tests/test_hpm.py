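"""Hierarchical partner matching: similarity, matching, clusters, alpha."""

import numpy as np
import pytest

from icahpm.hpm import (
    bidirectional_match,
    cluster_t_map,
    cronbach_alpha,
    form_clusters_within_order,
    match_across_orders,
    run_hpm,
    similarity_matrix,
    tanimoto_distance,
    tanimoto_similarity,
)
from icahpm.ica import ICMap, ICSet


def _icset(subject_id, maps, order=None):
    maps = [np.asarray(m, dtype=float) for m in maps]
    order = order if order is not None else len(maps)
    comps = [
        ICMap(
            subject_id=subject_id,
            model_order=order,
            component_index=i,
            spatial_z=(m - m.mean()) / m.std(),
            timecourse=np.zeros(5),
        )
        for i, m in enumerate(maps)
    ]
    return ICSet(subject_id=subject_id, model_order=order, components=comps,
                 pca_explained_variance=1.0)


def _blob(m, center, width, amp=5.0):
    x = np.arange(m)
    return amp * np.exp(-((x - center) ** 2) / (2 * width**2))


class TestTanimoto:
    def test_identical_maps_give_one(self):
        a = np.array([0.0, 1.0, 2.0, -1.0])
        assert tanimoto_similarity(a, a) == pytest.approx(1.0)
        assert tanimoto_similarity(a, a, mode="binary", z_threshold=0.5) == 1.0

    def test_disjoint_supports_give_zero(self):
        a = np.array([3.0, 0.0, 0.0, 0.0])
        b = np.array([0.0, 0.0, 3.0, 0.0])
        assert tanimoto_similarity(a, b) == 0.0
        assert tanimoto_similarity(a, b, mode="binary") == 0.0

    def test_binary_counts_match_set_oracle(self):
        """|A| = 30, |B| = 20, overlap 10 -> 10 / 40."""
        a = np.zeros(100)
        b = np.zeros(100)
        a[:30] = 3.0
        b[20:40] = 3.0  # overlap 20..29 (10 voxels), union 40
        assert tanimoto_similarity(a, b, mode="binary") == pytest.approx(10 / 40)

    def test_negative_values_clipped_in_continuous_mode(self):
        a = np.array([1.0, -5.0, 2.0])
        b = np.array([1.0, 0.0, 2.0])
        assert tanimoto_similarity(a, b) == pytest.approx(1.0)

    def test_symmetry_and_distance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 50))
        s1 = tanimoto_similarity(a, b)
        s2 = tanimoto_similarity(b, a)
        assert s1 == pytest.approx(s2)
        assert tanimoto_distance(a, b) == pytest.approx(1.0 - s1)

    def test_empty_maps_warn_and_return_zero(self):
        a = np.full(4, -1.0)
        with pytest.warns(UserWarning):
            assert tanimoto_similarity(a, a) == 0.0

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            tanimoto_similarity(np.ones(3), np.ones(4))

    def test_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(3, 40))
        b = rng.normal(size=(4, 40))
        mat = similarity_matrix(a, b)
        for i in range(3):
            for j in range(4):
                assert mat[i, j] == pytest.approx(tanimoto_similarity(a[i], b[j]))


class TestBidirectionalMatch:
    def test_self_match_pairs_every_component(self):
        s = _icset("a", [_blob(60, c, 3) + np.random.default_rng(c).normal(0, 0.1, 60)
                         for c in (10, 30, 50)])
        edges = bidirectional_match(s, s)
        assert len(edges) == 3
        for e in edges:
            assert e.ic_a[1] == e.ic_b[1]

    def test_constructed_trio_yields_single_edge(self):
        """A1 and B1 are mutual best matches; A2's best is also B1, so only
        the (A1, B1) edge appears for that trio (verified against the full
        3 x 3 similarity table)."""
        base = _blob(80, 20, 3)
        a_maps = [base, base + _blob(80, 60, 3, amp=2.0), _blob(80, 45, 2)]
        b_maps = [base + np.random.default_rng(0).normal(0, 0.05, 80),
                  _blob(80, 70, 2), _blob(80, 5, 2)]
        sa, sb = _icset("a", a_maps), _icset("b", b_maps)
        sim = similarity_matrix(
            np.stack([c.spatial_z for c in sa.components]),
            np.stack([c.spatial_z for c in sb.components]),
        )
        assert sim[0].argmax() == 0 and sim[1].argmax() == 0  # A1, A2 -> B1
        assert sim[:, 0].argmax() == 0  # B1 -> A1
        edges = bidirectional_match(sa, sb)
        pairs = {(e.ic_a[1], e.ic_b[1]) for e in edges}
        assert (0, 0) in pairs
        assert (1, 0) not in pairs

    def test_orientation_independence(self):
        rng = np.random.default_rng(2)
        sa = _icset("a", rng.normal(size=(3, 50)) + 3)
        sb = _icset("b", rng.normal(size=(3, 50)) + 3)
        ab = {(e.ic_a[1], e.ic_b[1]) for e in bidirectional_match(sa, sb)}
        ba = {(e.ic_b[1], e.ic_a[1]) for e in bidirectional_match(sb, sa)}
        assert ab == ba


def _brute_force_clusters(ic_sets, min_subject_fraction=0.5):
    """Independent re-implementation: explicit pairwise loops over all
    subject pairs and components, mutual-best edges, union-find, subject
    floor, and the one-member-per-subject rule."""

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
        # one member per subject: highest mean similarity to other-subject members
        chosen = {}
        for i in g:
            sid = nodes[i][0]
            others = [j for j in g if nodes[j][0] != sid]
            score = np.mean([sim(nodes[i][2], nodes[j][2]) for j in others]) if others else 0.0
            if sid not in chosen or score > chosen[sid][1]:
                chosen[sid] = (i, score)
        out.append(frozenset((nodes[i][0], nodes[i][1]) for i, _ in chosen.values()))
    return set(out)


class TestClusterFormation:
    def _noisy_sets(self, n_subjects, centers, seed=0, noise=0.4):
        rng = np.random.default_rng(seed)
        sets = []
        for i in range(n_subjects):
            maps = [
                _blob(120, c + rng.integers(-2, 3), 4) + rng.normal(0, noise, 120)
                for c in centers
            ]
            sets.append(_icset(f"s{i}", maps))
        return sets

    def test_single_shared_source_forms_one_cluster(self):
        rng = np.random.default_rng(3)
        sets = []
        planted = _blob(120, 60, 5)
        for i in range(4):
            maps = [planted + rng.normal(0, 0.3, 120), rng.normal(0, 1.0, 120)]
            sets.append(_icset(f"s{i}", maps))
        clusters = form_clusters_within_order(sets)
        big = [c for c in clusters if len(c.members) == 4]
        assert len(big) == 1
        pz = (planted - planted.mean()) / planted.std()
        for m in big[0].members:
            assert np.corrcoef(pz, m.spatial_z)[0, 1] > 0.8

    def test_two_disjoint_sources_two_clusters(self):
        sets = self._noisy_sets(4, [25, 90], seed=4, noise=0.2)
        clusters = form_clusters_within_order(sets)
        full = [c for c in clusters if len(c.members) == 4]
        assert len(full) == 2
        m0 = {m.subject_id for m in full[0].members}
        m1 = {m.subject_id for m in full[1].members}
        assert m0 == m1 == {f"s{i}" for i in range(4)}
        # no IC appears in both clusters
        k0 = {(m.subject_id, m.component_index) for m in full[0].members}
        k1 = {(m.subject_id, m.component_index) for m in full[1].members}
        assert not (k0 & k1)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            form_clusters_within_order(self._noisy_sets(1, [20]))

    @pytest.mark.parametrize("n_subjects,n_comp_centers,seed", [
        (3, [20, 60, 100], 5),
        (4, [15, 45, 75, 105, 118], 6),
        (4, [30, 90], 7),
    ])
    def test_matches_brute_force_oracle(self, n_subjects, n_comp_centers, seed):
        """Cluster membership equals an exhaustive brute-force construction
        of all bidirectional pairs (independent union-find implementation)."""
        sets = self._noisy_sets(n_subjects, n_comp_centers, seed=seed)
        got = {
            frozenset((m.subject_id, m.component_index) for m in c.members)
            for c in form_clusters_within_order(sets)
        }
        expected = _brute_force_clusters(sets)
        assert got == expected

    def test_permutation_invariance(self):
        """Shuffling component order within every ICSet leaves retained
        member sets unchanged (up to component relabeling)."""
        sets = self._noisy_sets(4, [25, 90], seed=8, noise=0.2)
        perm_sets = []
        rng = np.random.default_rng(9)
        perms = {}
        for s in sets:
            p = rng.permutation(len(s.components))
            perms[s.subject_id] = p
            comps = []
            for new_idx, old_idx in enumerate(p):
                c = s.components[old_idx]
                comps.append(ICMap(c.subject_id, c.model_order, new_idx,
                                   c.spatial_z, c.timecourse))
            perm_sets.append(ICSet(s.subject_id, s.model_order, comps, 1.0))
        base = {
            frozenset((m.subject_id, int(perms[m.subject_id][m.component_index]))
                      for m in c.members)
            for c in form_clusters_within_order(perm_sets)
        }
        orig = {
            frozenset((m.subject_id, m.component_index) for m in c.members)
            for c in form_clusters_within_order(sets)
        }
        assert base == orig


class TestClusterStatistics:
    def test_t_map_hand_computed(self):
        maps = np.array([[1.0], [2.0], [3.0]])
        t, flag = cluster_t_map(maps)
        assert t[0] == pytest.approx(2.0 / (1.0 / np.sqrt(3)), rel=1e-12)
        assert not flag.any()

    def test_t_zero_when_all_zero(self):
        t, flag = cluster_t_map(np.zeros((4, 3)))
        np.testing.assert_array_equal(t, 0.0)

    def test_degenerate_variance_capped_and_flagged(self):
        maps = np.tile(np.array([[2.0, 0.0]]), (4, 1))
        t, flag = cluster_t_map(maps, cap=100.0)
        assert t[0] == 100.0 and flag[0]
        assert t[1] == 0.0 and not flag[1]

    def test_fewer_than_three_members_rejected(self):
        with pytest.raises(ValueError):
            cluster_t_map(np.ones((2, 5)))

    def test_alpha_identical_maps_is_one(self):
        m = np.tile(np.random.default_rng(0).normal(size=80), (4, 1))
        assert cronbach_alpha(m) == pytest.approx(1.0)

    def test_alpha_two_item_closed_form(self):
        """k = 2: alpha = 2 (1 - (v1+v2)/(v1+v2+2c))."""
        rng = np.random.default_rng(1)
        a = rng.normal(size=500)
        b = 0.6 * a + rng.normal(0, 0.8, 500)
        v1, v2 = a.var(ddof=1), b.var(ddof=1)
        c = np.cov(a, b, ddof=1)[0, 1]
        expected = 2 * (1 - (v1 + v2) / (v1 + v2 + 2 * c))
        assert cronbach_alpha(np.stack([a, b])) == pytest.approx(expected, rel=1e-10)

    def test_alpha_independent_maps_near_zero(self):
        vals = []
        for seed in range(20):
            m = np.random.default_rng(seed).normal(size=(5, 1000))
            vals.append(cronbach_alpha(m))
        assert abs(np.mean(vals)) < 0.1

    def test_alpha_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.zeros((3, 10)))


class TestMatchAcrossOrders:
    def _per_order(self, orders, n_subjects=4, seed=0):
        rng = np.random.default_rng(seed)
        per_order = {}
        centers = [30, 90]
        for o in orders:
            sets = []
            for i in range(n_subjects):
                maps = [
                    _blob(120, c + rng.integers(-2, 3), 4) + rng.normal(0, 0.3, 120)
                    for c in centers
                ]
                while len(maps) < o:
                    maps.append(rng.normal(0, 1.0, 120))
                sets.append(_icset(f"s{i}", maps, order=o))
            per_order[o] = form_clusters_within_order(sets)
        return per_order

    def test_planted_sources_reproduce_across_orders(self):
        per_order = self._per_order([2, 3, 4])
        clusters = match_across_orders(per_order)
        assert len(clusters) == 2
        for cl in clusters:
            assert cl.alpha >= 0.7
            assert len(cl.subject_representatives) == 4
            assert set(cl.orders) == {2, 3, 4}

    def test_unattainable_alpha_threshold_empties_retention(self):
        per_order = self._per_order([2, 3])
        with pytest.warns(UserWarning):
            assert match_across_orders(per_order, alpha_threshold=1.01) == []

    def test_single_order_rejected(self):
        per_order = self._per_order([2])
        with pytest.raises(ValueError):
            match_across_orders(per_order)

    def test_subject_relabeling_permutes_clusters_only(self):
        """Relabeling subjects yields the same clusters with renamed
        members."""
        per_order = self._per_order([2, 3], seed=3)
        clusters = match_across_orders(per_order)
        relabel = {f"s{i}": f"t{(i + 1) % 4}" for i in range(4)}
        per_order2 = {}
        for o, cls in per_order.items():
            new_cls = []
            for c in cls:
                members = [
                    ICMap(relabel[m.subject_id], m.model_order, m.component_index,
                          m.spatial_z, m.timecourse)
                    for m in c.members
                ]
                new_c = type(c)(model_order=c.model_order, members=members,
                                alpha=c.alpha, t_map=c.t_map,
                                degenerate_voxels=c.degenerate_voxels)
                new_cls.append(new_c)
            per_order2[o] = new_cls
        clusters2 = match_across_orders(per_order2)
        sets1 = {
            frozenset(relabel[s] for s in c.subject_representatives)
            for c in clusters
        }
        sets2 = {frozenset(c.subject_representatives) for c in clusters2}
        assert sets1 == sets2


def test_run_hpm_end_to_end_on_constructed_sets():
    """Both stages chained on constructed component sets recover the two
    planted blobs as exactly two reproducible clusters."""
    rng = np.random.default_rng(12)
    by_order = {}
    for o in (2, 3):
        sets = []
        for i in range(4):
            maps = [
                _blob(150, 35 + rng.integers(-2, 3), 5) + rng.normal(0, 0.3, 150),
                _blob(150, 110 + rng.integers(-2, 3), 5) + rng.normal(0, 0.3, 150),
            ]
            while len(maps) < o:
                maps.append(rng.normal(0, 1, 150))
            sets.append(_icset(f"s{i}", maps, order=o))
        by_order[o] = sets
    clusters = run_hpm(by_order)
    assert len(clusters) == 2
    for cl in clusters:
        assert cl.alpha > 0.7
        assert cl.t_map.shape == (150,)
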