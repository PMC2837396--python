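"""Comparison-tree constructions against independent oracles."""

import itertools

import numpy as np
import pytest
from scipy.sparse import csgraph
from scipy.spatial.distance import pdist, squareform

from arborcost.core import VertexSet
from arborcost.trees import (
    last_tree,
    minimum_spanning_tree,
    mst_with_nodes,
    random_spanning_tree,
    star_tree,
    steiner_minimal_tree,
)
from arborcost.economy import path_lengths


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def prufer_decode(seq, n):
    """Edges of the labelled tree with Prüfer sequence ``seq`` on n nodes."""
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = []
    leaves = sorted(v for v in range(n) if degree[v] == 1)
    for v in seq:
        leaf = leaves.pop(0)
        edges.append((leaf, v))
        degree[v] -= 1
        if degree[v] == 1:
            import bisect

            bisect.insort(leaves, v)
    edges.append((leaves[0], leaves[1]))
    return edges


def brute_force_mst_length(points):
    """Minimum over all n^(n-2) labelled spanning trees (Cayley)."""
    n = len(points)
    D = squareform(pdist(points))
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        cost = sum(D[a, b] for a, b in prufer_decode(seq, n))
        best = min(best, cost)
    return best


# ---------------------------------------------------------------------------
# MST
# ---------------------------------------------------------------------------

def test_single_bouton_mst_is_one_edge():
    vs = VertexSet(root=[0, 0, 0], boutons=[[5, 0, 0]])
    t = minimum_spanning_tree(vs)
    assert len(t.edges) == 1
    assert t.total_length == pytest.approx(5.0)


def test_prim_matches_exhaustive_enumeration(rng):
    for _ in range(5):
        pts = rng.uniform(0, 1, size=(6, 3))
        vs = VertexSet(root=pts[0], boutons=pts[1:])
        t = minimum_spanning_tree(vs)
        assert t.total_length == pytest.approx(
            brute_force_mst_length(pts), rel=1e-12
        )


def test_prim_matches_scipy_complete_graph(rng):
    pts = rng.uniform(0, 500, size=(120, 3))
    vs = VertexSet(root=pts[0], boutons=pts[1:])
    t = minimum_spanning_tree(vs)
    ref = csgraph.minimum_spanning_tree(squareform(pdist(pts))).sum()
    assert t.total_length == pytest.approx(float(ref), rel=1e-12)


class TestMSTWithNodes:
    def test_coincident_extra_changes_nothing(self, cloud_vs):
        vs = VertexSet(cloud_vs.root, cloud_vs.boutons,
                       extra_nodes=cloud_vs.boutons[:1])
        assert mst_with_nodes(vs).total_length == pytest.approx(
            minimum_spanning_tree(cloud_vs).total_length
        )

    def test_collinear_extra_changes_nothing(self):
        vs0 = VertexSet(root=[0, 0, 0], boutons=[[10, 0, 0], [20, 0, 0]])
        vs = VertexSet(vs0.root, vs0.boutons, extra_nodes=[[5, 0, 0]])
        assert mst_with_nodes(vs).total_length == pytest.approx(
            minimum_spanning_tree(vs0).total_length
        )

    def test_far_extra_strictly_longer(self, cloud_vs):
        vs = VertexSet(cloud_vs.root, cloud_vs.boutons,
                       extra_nodes=[[0, 0, 900.0]])
        assert (mst_with_nodes(vs).total_length
                > minimum_spanning_tree(cloud_vs).total_length + 100)

    def test_empty_extras_rejected(self, cloud_vs):
        with pytest.raises(ValueError):
            mst_with_nodes(cloud_vs)


# ---------------------------------------------------------------------------
# star
# ---------------------------------------------------------------------------

def test_star_ring_wire_and_paths(ring8):
    t = star_tree(ring8)
    assert t.total_length == pytest.approx(800.0)
    prof = path_lengths(t)
    assert np.allclose(prof.path_um, 100.0)
    assert np.allclose(prof.ratio, 1.0)


def test_star_of_single_bouton_equals_mst():
    vs = VertexSet(root=[0, 0, 0], boutons=[[3, 4, 0]])
    assert star_tree(vs).total_length == pytest.approx(
        minimum_spanning_tree(vs).total_length
    )


# ---------------------------------------------------------------------------
# Steiner heuristic
# ---------------------------------------------------------------------------

def steiner_angles(tree):
    out = []
    for s in tree.steiner_indices:
        nbrs = [b for a, b in tree.edges if a == s]
        nbrs += [a for a, b in tree.edges if b == s]
        assert len(nbrs) == 3
        units = []
        for v in nbrs:
            d = tree.positions[v] - tree.positions[s]
            units.append(d / np.linalg.norm(d))
        for i in range(3):
            for j in range(i + 1, 3):
                out.append(np.degrees(
                    np.arccos(np.clip(units[i] @ units[j], -1, 1))))
    return np.asarray(out)


def test_equilateral_triangle_fermat_point():
    vs = VertexSet(root=[0, 0, 0],
                   boutons=[[1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
    t = steiner_minimal_tree(vs)
    assert len(t.steiner_indices) == 1
    assert t.total_length == pytest.approx(np.sqrt(3), rel=1e-6)
    assert minimum_spanning_tree(vs).total_length == pytest.approx(2.0)
    assert np.allclose(steiner_angles(t), 120.0, atol=1e-3)


def test_collinear_points_gain_no_steiner_points():
    vs = VertexSet(root=[0, 0, 0], boutons=[[5, 0, 0], [11, 0, 0], [20, 0, 0]])
    t = steiner_minimal_tree(vs)
    assert len(t.steiner_indices) == 0
    assert t.total_length == pytest.approx(
        minimum_spanning_tree(vs).total_length
    )


def test_steiner_never_longer_than_mst_and_ratio_bounded(rng):
    for _ in range(5):
        pts = rng.uniform(0, 100, size=(25, 3))
        vs = VertexSet(root=pts[0], boutons=pts[1:])
        t = steiner_minimal_tree(vs)
        l_mst = minimum_spanning_tree(vs).total_length
        assert t.total_length <= l_mst + 1e-9
        assert t.total_length / l_mst > 0.5  # Steiner ratio bound
        angles = steiner_angles(t)
        if angles.size:
            assert np.all(np.abs(angles - 120.0) < 0.5)


# ---------------------------------------------------------------------------
# LAST
# ---------------------------------------------------------------------------

def test_last_alpha_one_is_a_star(cloud_vs):
    t = last_tree(cloud_vs, 1.0)
    prof = path_lengths(t)
    assert np.allclose(prof.ratio, 1.0, rtol=1e-12)


def test_last_huge_alpha_is_the_mst(cloud_vs):
    t = last_tree(cloud_vs, 1e9)
    assert t.total_length == pytest.approx(
        minimum_spanning_tree(cloud_vs).total_length, rel=1e-12
    )


def test_last_ratio_bound_500_points(rng):
    pts = rng.uniform(0, 1, size=(500, 3))
    vs = VertexSet(root=np.full(3, 0.5), boutons=pts)
    t = last_tree(vs, 2.0)
    prof = path_lengths(t)
    assert prof.ratio.max() < 2.0
    assert prof.ratio.min() >= 1.0 - 1e-12


def test_last_alpha_below_one_rejected(cloud_vs):
    with pytest.raises(ValueError):
        last_tree(cloud_vs, 0.9)


def test_last_between_star_and_mst_wire(cloud_vs):
    l_mst = minimum_spanning_tree(cloud_vs).total_length
    l_star = star_tree(cloud_vs).total_length
    l_last = last_tree(cloud_vs, 2.0).total_length
    assert l_mst - 1e-9 <= l_last <= l_star + 1e-9


# ---------------------------------------------------------------------------
# Wilson random spanning trees
# ---------------------------------------------------------------------------

def test_random_tree_spans_everything(cloud_vs):
    t = random_spanning_tree(cloud_vs, seed=5)
    assert len(t.edges) == cloud_vs.n
    assert t.n_vertices == cloud_vs.n + 1
    t.validate()


def test_random_tree_reproducible(cloud_vs):
    a = random_spanning_tree(cloud_vs, seed=77)
    b = random_spanning_tree(cloud_vs, seed=77)
    ea = {tuple(sorted(e)) for e in a.edges.tolist()}
    eb = {tuple(sorted(e)) for e in b.edges.tolist()}
    assert ea == eb


def test_random_tree_never_shorter_than_mst(cloud_vs):
    l_mst = minimum_spanning_tree(cloud_vs).total_length
    for seed in range(5):
        assert random_spanning_tree(cloud_vs, seed).total_length >= l_mst


# ---------------------------------------------------------------------------
# isometry invariance
# ---------------------------------------------------------------------------

def test_constructions_invariant_under_similarity(rng, cloud_vs):
    from scipy.stats import special_ortho_group

    R = special_ortho_group.rvs(3, random_state=1234)
    k = 2.5
    moved = cloud_vs.transformed(scale=k, rotation=R,
                                 translation=(40, -10, 7))
    for build in (minimum_spanning_tree,
                  lambda v: last_tree(v, 1.7),
                  star_tree):
        a = build(cloud_vs).total_length
        b = build(moved).total_length
        assert b == pytest.approx(k * a, rel=1e-9)
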