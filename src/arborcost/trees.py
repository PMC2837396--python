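"""Comparison arbors over a fixed vertex set.

Given the fixed vertices of an axon arbor (axon origin as root plus the N
bouton positions, optionally supplemented with the bifurcation set X), this
module builds the artificial trees the economy analysis compares against:

* :func:`minimum_spanning_tree` -- exact Euclidean MST (Prim on the
  complete graph; Delaunay-accelerated for large N), the wire-length
  optimum over the fixed vertices.
* :func:`mst_with_nodes` -- exact MST spanning root, boutons *and* the
  bifurcation set X ("MST nodes"), testing whether real branch points
  shorten wire.
* :func:`star_tree` -- a dedicated direct branch from root to every
  bouton; the path-length (conduction delay) optimum.
* :func:`steiner_minimal_tree` -- heuristic upper bound on the Euclidean
  Steiner minimal tree obtained by iterated local Steinerization of the
  MST (Fermat-Torricelli point insertion with geometric-median
  relaxation).  Exact ESMT is NP-hard.
* :func:`last_tree` -- light-approximate spanning tree: a hybrid that
  keeps total length near the MST while bounding every bouton's
  root-path-length ratio below a balance parameter alpha.
* :func:`random_spanning_tree` -- uniform random spanning tree of the
  complete graph by Wilson's loop-erased random walk, the chance baseline.

All constructions return a :class:`ConstructedTree` whose vertex rows are
ordered root (0), boutons (1..N), extra fixed vertices, then any inserted
Steiner points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.spatial import Delaunay, QhullError

from .core import VertexSet

#: above this many vertices the MST is computed on the 3D Delaunay graph
#: (the Euclidean MST is a subgraph of the Delaunay triangulation in any
#: dimension); degenerate inputs fall back to Prim on the complete graph.
DELAUNAY_THRESHOLD = 1200

TREE_KINDS = ("mst", "mst_nodes", "star", "esmt", "last", "random")


@dataclass
class ConstructedTree:
    """An artificial comparison arbor over a fixed vertex set."""

    kind: str
    positions: np.ndarray            # (n, 3)
    edges: np.ndarray                # (m, 2) int
    weights: np.ndarray              # (m,)
    root_index: int = 0
    n_boutons: int = 0               # boutons occupy rows 1..n_boutons
    n_fixed: int = 0                 # fixed vertices (root+boutons+extras)
    parameters: dict = field(default_factory=dict)

    @property
    def n_vertices(self) -> int:
        return int(self.positions.shape[0])

    @property
    def bouton_indices(self) -> np.ndarray:
        return np.arange(1, self.n_boutons + 1)

    @property
    def steiner_indices(self) -> np.ndarray:
        return np.arange(self.n_fixed, self.n_vertices)

    @property
    def total_length(self) -> float:
        return float(self.weights.sum())

    def adjacency(self) -> sparse.csr_matrix:
        n = self.n_vertices
        i, j = self.edges[:, 0], self.edges[:, 1]
        w = self.weights
        return sparse.coo_matrix(
            (np.concatenate([w, w]),
             (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(n, n),
        ).tocsr()

    def validate(self) -> "ConstructedTree":
        n, m = self.n_vertices, len(self.edges)
        if m != n - 1:
            raise ValueError(f"not a spanning tree: {n} vertices, {m} edges")
        ncomp, _ = csgraph.connected_components(self.adjacency(),
                                                directed=False)
        if ncomp != 1:
            raise ValueError("constructed tree is disconnected")
        return self


def _finalize(kind, points, edges, n_boutons, n_fixed=None, steiner=None,
              **params) -> ConstructedTree:
    pts = points if steiner is None or not len(steiner) else np.vstack(
        [points, steiner])
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    weights = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    return ConstructedTree(
        kind=kind,
        positions=pts,
        edges=edges,
        weights=weights,
        root_index=0,
        n_boutons=n_boutons,
        n_fixed=len(points) if n_fixed is None else n_fixed,
        parameters=params,
    ).validate()


# ---------------------------------------------------------------------------
# exact Euclidean MST
# ---------------------------------------------------------------------------

def _prim_edges(points: np.ndarray) -> np.ndarray:
    """Exact MST of the complete Euclidean graph, O(n^2) lazy Prim.

    Ties in candidate edge weights are broken toward the lowest vertex
    index (numpy argmin), making the output deterministic.
    """
    n = len(points)
    if n < 2:
        return np.zeros((0, 2), dtype=int)
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best_dist = np.linalg.norm(points - points[0], axis=1)
    best_from = np.zeros(n, dtype=int)
    best_dist[0] = np.inf
    edges = np.empty((n - 1, 2), dtype=int)
    for k in range(n - 1):
        j = int(np.argmin(best_dist))
        edges[k] = best_from[j], j
        in_tree[j] = True
        best_dist[j] = np.inf
        d = np.linalg.norm(points - points[j], axis=1)
        upd = (d < best_dist) & ~in_tree
        best_dist[upd] = d[upd]
        best_from[upd] = j
    return edges


def _delaunay_edges(points: np.ndarray) -> np.ndarray:
    tri = Delaunay(points)
    s = tri.simplices
    pairs = np.vstack([s[:, [a, b]] for a in range(s.shape[1])
                       for b in range(a + 1, s.shape[1])])
    pairs = np.sort(pairs, axis=1)
    return np.unique(pairs, axis=0)


def _mst_edges(points: np.ndarray) -> np.ndarray:
    n = len(points)
    if n <= DELAUNAY_THRESHOLD:
        return _prim_edges(points)
    try:
        cand = _delaunay_edges(points)
    except QhullError:
        return _prim_edges(points)
    w = np.linalg.norm(points[cand[:, 0]] - points[cand[:, 1]], axis=1)
    g = sparse.coo_matrix((w, (cand[:, 0], cand[:, 1])), shape=(n, n))
    t = csgraph.minimum_spanning_tree(g).tocoo()
    return np.column_stack([t.row, t.col])


def minimum_spanning_tree(vs: VertexSet) -> ConstructedTree:
    """Exact Euclidean MST over {root} ∪ boutons."""
    pts = vs.points()
    return _finalize("mst", pts, _mst_edges(pts), vs.n)


def mst_with_nodes(vs: VertexSet) -> ConstructedTree:
    """Exact MST spanning root, boutons and the bifurcation set X.

    All extra vertices are spanned (they are not optional Steiner points);
    if real branch points shortened wire, this tree would be shorter than
    the plain MST -- in cortex it is reliably longer.
    """
    if vs.extra_nodes is None or len(vs.extra_nodes) == 0:
        raise ValueError("mst_with_nodes requires a non-empty extra_nodes set")
    pts = vs.points(include_extras=True)
    return _finalize("mst_nodes", pts, _mst_edges(pts), vs.n)


def star_tree(vs: VertexSet) -> ConstructedTree:
    """Parallel direct branch from root to every bouton (path optimum)."""
    pts = vs.points()
    edges = np.column_stack([np.zeros(vs.n, dtype=int),
                             np.arange(1, vs.n + 1)])
    return _finalize("star", pts, edges, vs.n)


# ---------------------------------------------------------------------------
# Steiner minimal tree heuristic
# ---------------------------------------------------------------------------

def _fermat_point(tri_pts: np.ndarray, tol: float = 1e-9):
    """Fermat-Torricelli point of a 3-point set (closed form).

    Returns ``(point, interior)``.  When every interior angle is below
    120 deg the minimizer of the summed distance to the three points is
    interior with three 120 deg incident angles (``interior=True``) and
    is the first isogonic point, computed here from its trilinear
    coordinates ``csc(angle + 60 deg)``.  Otherwise it coincides with
    the wide-angle (or coincident) vertex and a Steiner point there is
    degenerate (``interior=False``).
    """
    a, b, c = tri_pts
    sa = float(np.linalg.norm(b - c))
    sb = float(np.linalg.norm(c - a))
    sc = float(np.linalg.norm(a - b))
    if sb == 0 or sc == 0:
        return a.copy(), False
    if sa == 0:
        return b.copy(), False
    cos = np.array([
        (sb * sb + sc * sc - sa * sa) / (2 * sb * sc),
        (sa * sa + sc * sc - sb * sb) / (2 * sa * sc),
        (sa * sa + sb * sb - sc * sc) / (2 * sa * sb),
    ])
    if cos.min() <= -0.5:  # some interior angle >= 120 deg
        return tri_pts[int(np.argmin(cos))].copy(), False
    ang = np.arccos(np.clip(cos, -1.0, 1.0))
    w = np.array([sa, sb, sc]) / np.sin(ang + np.pi / 3.0)
    return (w[:, None] * tri_pts).sum(axis=0) / w.sum(), True


def _splice_degenerate(tree: "_MutableTree", scale: float) -> int:
    """Remove Steiner points that collapsed onto a neighbor or lost
    degree 3; returns the number spliced."""
    n = 0
    for s in range(len(tree.pts) - 1, tree.n_fixed - 1, -1):
        ns = sorted(tree.adj[s])
        merged = None
        for u in ns:
            if tree.dist(s, u) < 1e-9 * scale:
                merged = u
                break
        if merged is not None:
            for u in ns:
                tree.disconnect(s, u)
                if u != merged:
                    tree.connect(merged, u)
            n += 1
        elif len(ns) == 2:
            tree.disconnect(s, ns[0])
            tree.disconnect(s, ns[1])
            tree.connect(ns[0], ns[1])
            n += 1
        elif len(ns) == 1:
            tree.disconnect(s, ns[0])
            n += 1
    return n


class _MutableTree:
    """Edit-friendly adjacency used while Steinerizing."""

    def __init__(self, points: np.ndarray, edges: np.ndarray, n_fixed: int):
        self.pts: list[np.ndarray] = [p for p in points]
        self.adj: list[set[int]] = [set() for _ in range(len(points))]
        self.n_fixed = n_fixed
        for a, b in edges:
            self.adj[int(a)].add(int(b))
            self.adj[int(b)].add(int(a))

    def dist(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.pts[i] - self.pts[j]))

    def total_length(self) -> float:
        return 0.5 * sum(self.dist(i, j) for i in range(len(self.pts))
                         for j in self.adj[i])

    def add_vertex(self, p: np.ndarray) -> int:
        self.pts.append(p)
        self.adj.append(set())
        return len(self.pts) - 1

    def connect(self, i: int, j: int) -> None:
        self.adj[i].add(j)
        self.adj[j].add(i)

    def disconnect(self, i: int, j: int) -> None:
        self.adj[i].discard(j)
        self.adj[j].discard(i)


def _min_angle_pair(tree: _MutableTree, v: int):
    """Neighbor pair with the smallest incident angle at v (max cosine)."""
    ns = sorted(tree.adj[v])
    best = None
    best_cos = -np.inf
    pv = tree.pts[v]
    units = {}
    for u in ns:
        d = tree.pts[u] - pv
        n = np.linalg.norm(d)
        units[u] = d / n if n > 0 else None
    for i in range(len(ns)):
        for j in range(i + 1, len(ns)):
            a, b = ns[i], ns[j]
            if units[a] is None or units[b] is None:
                continue
            cos = float(units[a] @ units[b])
            if cos > best_cos:
                best_cos = cos
                best = (a, b)
    return best, best_cos


def steiner_minimal_tree(
    vs: VertexSet,
    tol: float = 1e-9,
    angle_tol: float = 1e-6,
    max_passes: int = 150,
) -> ConstructedTree:
    """Heuristic Euclidean Steiner minimal tree (upper bound on the SMT).

    Starting from the exact MST, every vertex whose sharpest incident edge
    pair meets at less than 120 deg is a candidate for local improvement:
    the Fermat-Torricelli point of the vertex and that neighbor pair is
    inserted (degree 3) and the two edges re-routed through it whenever
    this shortens the tree.  Steiner point positions are then relaxed to
    the geometric median of their neighbors, and degenerate Steiner points
    (degree < 3, or collapsing onto another vertex) are spliced out.
    Passes repeat until the relative improvement drops below ``tol``.

    The result is guaranteed no longer than the MST; every surviving
    Steiner point has degree exactly 3 with incident angles of 120 deg
    (within ``angle_tol`` radians).  N >= 2 boutons are required.
    """
    if vs.n < 2:
        raise ValueError("steiner_minimal_tree requires at least 2 boutons")
    mst = minimum_spanning_tree(vs)
    tree = _MutableTree(mst.positions, mst.edges, n_fixed=mst.n_vertices)
    scale = max(1.0, float(np.abs(mst.positions).max()))
    cos_thresh = np.cos(np.deg2rad(120.0)) + 1e-12

    converged = False
    for _ in range(max_passes):
        n_inserted = 0
        for v in range(len(tree.pts)):
            if len(tree.adj[v]) < 2:
                continue
            pair, cos = _min_angle_pair(tree, v)
            if pair is None or cos <= cos_thresh:
                continue
            a, b = pair
            tri = np.asarray([tree.pts[v], tree.pts[a], tree.pts[b]])
            s_pos, interior = _fermat_point(tri, tol)
            if not interior:
                continue
            old = tree.dist(v, a) + tree.dist(v, b)
            new = sum(np.linalg.norm(s_pos - q) for q in tri)
            gain = old - new
            if gain <= tol * scale:
                continue
            s = tree.add_vertex(s_pos)
            tree.disconnect(v, a)
            tree.disconnect(v, b)
            tree.connect(s, v)
            tree.connect(s, a)
            tree.connect(s, b)
            n_inserted += 1

        # alternate relaxation (Steiner positions -> Fermat point of
        # their neighbors, iterated to stationarity because neighboring
        # points interact) with splicing of degenerate points, until the
        # configuration is clean: every surviving Steiner point then sits
        # exactly at an interior Fermat point, i.e. all angles are 120 deg
        stationary = False
        for _ in range(len(tree.pts) + 1):
            for _ in range(2000):
                max_move = 0.0
                for s in range(tree.n_fixed, len(tree.pts)):
                    ns = sorted(tree.adj[s])
                    if len(ns) != 3:
                        continue
                    p, _ = _fermat_point(
                        np.asarray([tree.pts[n] for n in ns]), tol)
                    max_move = max(max_move,
                                   float(np.linalg.norm(p - tree.pts[s])))
                    tree.pts[s] = p
                if max_move < 1e-10 * scale:
                    stationary = True
                    break
            if _splice_degenerate(tree, scale) == 0:
                break

        if n_inserted == 0 and stationary:
            converged = True
            break
    if not converged:
        warnings.warn("Steiner heuristic hit the pass cap before converging; "
                      "returning best tree so far", RuntimeWarning)

    # compact: drop disconnected (spliced) Steiner vertices
    keep = [i for i in range(len(tree.pts))
            if i < tree.n_fixed or len(tree.adj[i]) > 0]
    remap = {old: new for new, old in enumerate(keep)}
    pts = np.asarray([tree.pts[i] for i in keep])
    edges = sorted(
        {(remap[i], remap[j]) if remap[i] < remap[j] else (remap[j], remap[i])
         for i in keep for j in tree.adj[i]}
    )
    out = _finalize("esmt", pts[: tree.n_fixed], edges, vs.n,
                    n_fixed=tree.n_fixed, steiner=pts[tree.n_fixed:],
                    tol=tol, angle_tol=angle_tol)
    if out.total_length > mst.total_length + 1e-9 * scale:  # pragma: no cover
        return mst
    return out


# ---------------------------------------------------------------------------
# light-approximate spanning tree (LAST)
# ---------------------------------------------------------------------------

def last_tree(
    vs: VertexSet,
    alpha: float,
    _mst: ConstructedTree | None = None,
) -> ConstructedTree:
    """Wire/path hybrid with every bouton's path ratio bounded by alpha.

    A depth-first traversal of the exact MST carries the cumulative tree
    path length from the root; whenever a vertex's accumulated path would
    exceed ``alpha`` times its straight-line root distance, the direct
    root edge is added instead (in a complete Euclidean graph the
    single-source shortest path is the direct edge).  The shortest-path
    tree of the resulting subgraph is returned, so every bouton's
    root-path ratio lies in ``[1, alpha]`` -- and strictly below alpha for
    vertices in general position.  ``alpha = 1`` reproduces the star tree;
    ``alpha >> 1`` leaves the MST untouched.

    Children are visited nearest-first; the ratio guarantee holds for any
    visit order.
    """
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    mst = minimum_spanning_tree(vs) if _mst is None else _mst
    n = mst.n_vertices
    pts = mst.positions
    euclid = np.linalg.norm(pts - pts[0], axis=1)

    nbrs: list[list[tuple[float, int]]] = [[] for _ in range(n)]
    for (a, b), w in zip(mst.edges, mst.weights):
        nbrs[int(a)].append((float(w), int(b)))
        nbrs[int(b)].append((float(w), int(a)))
    for lst in nbrs:
        lst.sort()  # nearest child first

    d = np.zeros(n)
    visited = np.zeros(n, dtype=bool)
    visited[0] = True
    shortcuts: list[int] = []
    stack = [(w, v, 0) for w, v in reversed(nbrs[0])]
    while stack:
        w, v, u = stack.pop()
        if visited[v]:
            continue
        visited[v] = True
        cand = d[u] + w
        if cand > alpha * euclid[v]:
            d[v] = euclid[v]
            shortcuts.append(v)
        else:
            d[v] = cand
        stack.extend((wc, c, v) for wc, c in reversed(nbrs[v])
                     if not visited[c])

    rows = np.concatenate([mst.edges[:, 0],
                           np.zeros(len(shortcuts), dtype=int)])
    cols = np.concatenate([mst.edges[:, 1], np.asarray(shortcuts, dtype=int)])
    w_all = np.concatenate([mst.weights, euclid[shortcuts]])
    g = sparse.coo_matrix(
        (np.concatenate([w_all, w_all]),
         (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    ).tocsr()
    _, pred = csgraph.dijkstra(g, indices=0, return_predecessors=True)
    verts = np.arange(1, n)
    edges = np.column_stack([pred[verts], verts])
    return _finalize("last", pts, edges, vs.n, alpha=alpha)


# ---------------------------------------------------------------------------
# uniform random spanning tree (Wilson)
# ---------------------------------------------------------------------------

def random_spanning_tree(vs: VertexSet, seed) -> ConstructedTree:
    """Uniform random spanning tree of the complete graph on root+boutons.

    Wilson's algorithm: from each unspanned vertex, run a loop-erased
    random walk (each step uniform over all other vertices) until it hits
    the current tree, then graft the erased path.  Deterministic given the
    seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    pts = vs.points()
    n = len(pts)
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    succ = np.full(n, -1, dtype=int)
    buf: list[int] = []

    def steps():
        while True:
            if not buf:
                buf.extend(rng.integers(0, n - 1, size=512).tolist())
            yield buf.pop()

    draw = steps()
    for start in range(1, n):
        u = start
        while not in_tree[u]:
            r = next(draw)
            succ[u] = r + 1 if r >= u else r  # uniform over vertices != u
            u = succ[u]
        u = start
        while not in_tree[u]:
            in_tree[u] = True
            u = succ[u]

    verts = np.arange(1, n)
    edges = np.column_stack([verts, succ[verts]])
    return _finalize("random", pts, edges, vs.n,
                     seed=None if isinstance(seed, np.random.Generator)
                     else seed)
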