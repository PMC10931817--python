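"""Colocalization: gap metric and one-to-one matching."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ihcsynapse.coloc import colocalize, component_gap

SPACING = (0.3, 0.08, 0.08)


def _punctum(voxels, role="presynaptic", pid=1):
    """An arbitrary voxel set as one punctum (components need not be
    connected for gap/matching tests)."""
    from ihcsynapse.detect import _punctum_from_voxels

    idx = np.asarray(voxels, dtype=int)
    spacing = np.asarray(SPACING)
    return _punctum_from_voxels(
        idx, spacing, float(np.prod(spacing)), role, pid
    )


def brute_force_gap(p, q, spacing):
    """O(n*m) oracle: zero when overlapping/26-adjacent, else the minimum
    pairwise physical distance."""
    spacing = np.asarray(spacing)
    best = np.inf
    touching = False
    for a, b in itertools.product(p.voxels, q.voxels):
        if np.max(np.abs(a - b)) <= 1:
            touching = True
        d = np.linalg.norm((a - b) * spacing)
        best = min(best, d)
    return 0.0 if touching else best


def test_identical_sets_have_zero_gap():
    p = _punctum([(1, 1, 1), (1, 1, 2)])
    q = _punctum([(1, 1, 1), (1, 1, 2)], role="postsynaptic")
    assert component_gap(p, q, SPACING) == 0.0


def test_diagonal_adjacency_is_touching():
    p = _punctum([(1, 1, 1)])
    q = _punctum([(1, 2, 2)], role="postsynaptic")  # x-y diagonal neighbour
    assert component_gap(p, q, SPACING) == 0.0


def test_separated_voxels_have_positive_gap():
    p = _punctum([(1, 1, 1)])
    q = _punctum([(1, 1, 4)], role="postsynaptic")
    assert component_gap(p, q, SPACING) == pytest.approx(3 * 0.08)


def test_gap_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    for _ in range(30):
        a = rng.integers(0, 10, size=(rng.integers(1, 8), 3))
        b = rng.integers(0, 10, size=(rng.integers(1, 8), 3))
        p = _punctum(np.unique(a, axis=0))
        q = _punctum(np.unique(b, axis=0), role="postsynaptic")
        got = component_gap(p, q, SPACING)
        want = brute_force_gap(p, q, SPACING)
        assert got == pytest.approx(want)
        assert component_gap(q, p, SPACING) == pytest.approx(got)  # symmetry


def test_overlapping_pair_matches_with_no_orphans():
    p = _punctum([(1, 1, 1), (1, 1, 2)])
    q = _punctum([(1, 1, 2), (1, 1, 3)], role="postsynaptic")
    res = colocalize([p], [q], SPACING)
    assert len(res.pairs) == 1
    assert res.orphan_pre == [] and res.orphan_post == []


def test_zero_distance_rule_rejects_separated_elements():
    p = _punctum([(2, 2, 2)])
    q = _punctum([(2, 2, 4)], role="postsynaptic")  # one empty voxel between
    res = colocalize([p], [q], SPACING, max_gap_um=0.0)
    assert res.pairs == []
    assert res.orphan_pre == [p.id] and res.orphan_post == [q.id]


def _random_scene(rng, n_pre, n_post):
    pre = [
        _punctum(
            np.unique(rng.integers(0, 14, size=(rng.integers(1, 5), 3)), axis=0),
            pid=i + 1,
        )
        for i in range(n_pre)
    ]
    post = [
        _punctum(
            np.unique(rng.integers(0, 14, size=(rng.integers(1, 5), 3)), axis=0),
            role="postsynaptic", pid=i + 1,
        )
        for i in range(n_post)
    ]
    return pre, post


def test_matching_cardinality_equals_optimal():
    """Greedy one-to-one matching reaches maximum-cardinality matching
    (Hopcroft–Karp oracle) at max_gap = 0."""
    rng = np.random.default_rng(1)
    for _ in range(15):
        pre, post = _random_scene(rng, rng.integers(1, 12), rng.integers(1, 12))
        res = colocalize(pre, post, SPACING, max_gap_um=0.0)
        g = nx.Graph()
        g.add_nodes_from((f"a{i}" for i in range(len(pre))), bipartite=0)
        g.add_nodes_from((f"b{j}" for j in range(len(post))), bipartite=1)
        for i, p in enumerate(pre):
            for j, q in enumerate(post):
                if brute_force_gap(p, q, SPACING) == 0.0:
                    g.add_edge(f"a{i}", f"b{j}")
        opt = nx.bipartite.maximum_matching(
            g, top_nodes=[f"a{i}" for i in range(len(pre))]
        )
        assert len(res.pairs) == len(opt) // 2


def test_no_punctum_used_twice_and_symmetry():
    rng = np.random.default_rng(2)
    pre, post = _random_scene(rng, 10, 10)
    res = colocalize(pre, post, SPACING)
    pre_ids = [p.pre_id for p in res.pairs]
    post_ids = [p.post_id for p in res.pairs]
    assert len(pre_ids) == len(set(pre_ids))
    assert len(post_ids) == len(set(post_ids))
    swapped = colocalize(post, pre, SPACING)
    assert {(p.post_id, p.pre_id) for p in swapped.pairs} == {
        (p.pre_id, p.post_id) for p in res.pairs
    }


def test_pair_count_monotone_in_max_gap():
    rng = np.random.default_rng(3)
    pre, post = _random_scene(rng, 8, 8)
    counts = [
        len(colocalize(pre, post, SPACING, max_gap_um=g).pairs)
        for g in (0.0, 0.1, 0.3, 1.0)
    ]
    assert counts == sorted(counts)


def test_noise_free_pair_count_equals_planted(small_stack, small_result):
    _, truth = small_stack
    assert len(small_result.pairs) == int((truth.kind == "synapse").sum())
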