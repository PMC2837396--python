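"""Domain types and graph construction for axon arbor analysis.

An axon arbor is represented at two levels:

* :class:`ArborReconstruction` -- the raw digitized morphology: a rooted tree
  of 3D points with radii.  Each point is either a morphological landmark
  (axon origin, bifurcation, bouton, branch tip) or a routing point tracing
  the curvilinear course of the axon between landmarks.

* :class:`ArborGraph` -- the analysis graph ``T = (V, E, c)``: landmarks
  only, connected by straight edges weighted with the Euclidean distance
  between their endpoints.  Using direct rather than curvilinear distance
  makes biological arbors commensurable with geometric comparison trees
  (MST, Steiner, star, ...), which are necessarily built from straight
  segments; it also removes the lengthening effect of axonal tortuosity
  caused by obstacles in the neuropil.

The graph is an undirected tree; the root (axon origin) only defines path
orientation.  After conversion the root is re-centred at the coordinate
origin.  All lengths are in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import sparse

NODE_KINDS = (
    "origin",
    "soma",
    "routing",
    "bifurcation",
    "bouton",
    "tip",
    "white_matter",
)

#: kinds retained as vertices of the analysis graph (routing chains collapse)
LANDMARK_KINDS = ("origin", "soma", "bifurcation", "bouton", "tip")

#: maximum number of children a node may have (three-way junctions occur in
#: real arbors; anything bushier is treated as a digitization error)
MAX_CHILDREN = 3


class MorphologyError(ValueError):
    """A reconstruction violates a structural invariant (cycle, no root...)."""


class ParseError(MorphologyError):
    """A morphology file could not be parsed; the message names the line."""


@dataclass(frozen=True)
class ReconNode:
    """One digitized point of a reconstruction.

    Parameters
    ----------
    id : int
        Unique positive identifier (SWC sample number).
    kind : str
        One of :data:`NODE_KINDS`.
    position : tuple of float
        ``(x, y, z)`` in micrometres.
    radius : float
        Local axon radius in micrometres (>= 0).
    parent_id : int or None
        Identifier of the parent node; ``None`` exactly once (the root).
    """

    id: int
    kind: str
    position: tuple[float, float, float]
    radius: float
    parent_id: int | None

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise MorphologyError(f"unknown node kind {self.kind!r}")


@dataclass
class ArborReconstruction:
    """A validated single-axon reconstruction (rooted node table)."""

    nodes: list[ReconNode]
    cell_class: str = "unspecified"
    metadata: dict = field(default_factory=dict)

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[ReconNode]:
        return iter(self.nodes)

    def node_map(self) -> dict[int, ReconNode]:
        return {n.id: n for n in self.nodes}

    def children_map(self) -> dict[int, list[int]]:
        children: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id is not None:
                children[n.parent_id].append(n.id)
        for ids in children.values():
            ids.sort()
        return children

    def root(self) -> ReconNode:
        roots = [n for n in self.nodes if n.parent_id is None]
        if len(roots) != 1:
            raise MorphologyError(
                f"expected exactly one root node, found {len(roots)}"
            )
        return roots[0]

    def positions(self) -> np.ndarray:
        return np.asarray([n.position for n in self.nodes], dtype=float)

    # -- validation --------------------------------------------------------
    def validate(self) -> "ArborReconstruction":
        """Check structural invariants; raise :class:`MorphologyError`."""
        if not self.nodes:
            raise MorphologyError("empty reconstruction")
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise MorphologyError("node ids are not unique")
        if min(ids) < 1:
            raise MorphologyError("node ids must be >= 1")
        nm = self.node_map()
        root = self.root()
        for n in self.nodes:
            if n.parent_id is not None and n.parent_id not in nm:
                raise MorphologyError(
                    f"node {n.id} references missing parent {n.parent_id}"
                )
            if not np.all(np.isfinite(n.position)):
                raise MorphologyError(f"node {n.id} has non-finite position")
            if not np.isfinite(n.radius) or n.radius < 0:
                raise MorphologyError(f"node {n.id} has invalid radius")
        # cycle check: walk every parent chain with memoised reachability
        ok: set[int] = {root.id}
        for n in self.nodes:
            chain = []
            cur: int | None = n.id
            while cur is not None and cur not in ok:
                chain.append(cur)
                if len(chain) > len(self.nodes):
                    raise MorphologyError("cyclic parent links detected")
                cur = nm[cur].parent_id
            if cur is None and chain and chain[-1] != root.id:
                raise MorphologyError("multiple roots / disconnected nodes")
            ok.update(chain)
        for nid, kids in self.children_map().items():
            if len(kids) > MAX_CHILDREN:
                raise MorphologyError(
                    f"node {nid} has out-degree {len(kids)} > {MAX_CHILDREN}"
                )
        return self

    # -- geometry ----------------------------------------------------------
    def curvilinear_length(self) -> float:
        """Total traced length: sum of parent-link segment lengths (µm)."""
        nm = self.node_map()
        total = 0.0
        for n in self.nodes:
            if n.parent_id is not None:
                p = nm[n.parent_id]
                total += float(
                    np.linalg.norm(
                        np.subtract(n.position, p.position)
                    )
                )
        return total

    def transformed(
        self,
        scale: float = 1.0,
        rotation: np.ndarray | None = None,
        translation: Sequence[float] = (0.0, 0.0, 0.0),
    ) -> "ArborReconstruction":
        """Return a copy under a similarity transform ``x -> s·R·x + t``.

        Radii are multiplied by ``scale``.  Used to check that downstream
        economy measures are invariant under rigid motion and uniform
        scaling.
        """
        if scale <= 0:
            raise ValueError("scale must be positive")
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.asarray(translation, float)
        out = []
        for n in self.nodes:
            p = scale * (R @ np.asarray(n.position)) + t
            out.append(
                ReconNode(n.id, n.kind, tuple(p.tolist()), n.radius * scale,
                          n.parent_id)
            )
        return ArborReconstruction(out, self.cell_class, dict(self.metadata))


@dataclass
class VertexSet:
    """Fixed vertices for tree construction: root + N boutons (+ extras).

    ``extra_nodes`` carries the axon bifurcation set X when building the
    "MST nodes" variant.  Duplicate coordinates are permitted (coincident
    boutons are biologically meaningful) but flagged.
    """

    root: np.ndarray
    boutons: np.ndarray
    extra_nodes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.root = np.asarray(self.root, dtype=float).reshape(3)
        self.boutons = np.atleast_2d(np.asarray(self.boutons, dtype=float))
        if self.boutons.shape[0] < 1 or self.boutons.shape[1] != 3:
            raise ValueError("need at least one bouton with 3D coordinates")
        if self.extra_nodes is not None:
            self.extra_nodes = np.atleast_2d(
                np.asarray(self.extra_nodes, dtype=float)
            )

    @property
    def n(self) -> int:
        """Number of boutons N."""
        return int(self.boutons.shape[0])

    @property
    def has_duplicates(self) -> bool:
        pts = self.points()
        return len(np.unique(np.round(pts, 9), axis=0)) < len(pts)

    def points(self, include_extras: bool = False) -> np.ndarray:
        """Stacked coordinates: row 0 the root, rows 1..N the boutons,
        then any extra nodes."""
        parts = [self.root[None, :], self.boutons]
        if include_extras and self.extra_nodes is not None:
            parts.append(self.extra_nodes)
        return np.vstack(parts)

    def transformed(self, scale=1.0, rotation=None, translation=(0, 0, 0)):
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.asarray(translation, float)
        f = lambda a: scale * (a @ R.T) + t  # noqa: E731
        return VertexSet(
            f(self.root[None, :])[0],
            f(self.boutons),
            None if self.extra_nodes is None else f(self.extra_nodes),
        )


@dataclass
class ArborGraph:
    """Rooted undirected weighted tree over morphological landmarks.

    Every edge weight equals the Euclidean distance between its endpoint
    positions; the root sits at the coordinate origin.
    """

    positions: np.ndarray          # (n, 3) float, µm
    kinds: np.ndarray              # (n,) str
    edges: np.ndarray              # (m, 2) int vertex indices
    weights: np.ndarray            # (m,) float, µm
    root_index: int = 0
    node_ids: np.ndarray | None = None   # source reconstruction ids
    trimmed_tip_length: float = 0.0      # µm removed distal to last boutons
    excluded_wm_length: float = 0.0      # µm of white-matter segment removed
    meta: dict = field(default_factory=dict)

    # -- size / composition ------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_boutons(self) -> int:
        return int(np.count_nonzero(self.kinds == "bouton"))

    @property
    def bouton_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kinds == "bouton")

    @property
    def total_length(self) -> float:
        return float(self.weights.sum())

    # -- adjacency ---------------------------------------------------------
    def adjacency(self) -> sparse.csr_matrix:
        n = self.n_vertices
        if len(self.edges) == 0:
            return sparse.csr_matrix((n, n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        w = self.weights
        m = sparse.coo_matrix(
            (np.concatenate([w, w]),
             (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(n, n),
        )
        return m.tocsr()

    def neighbor_lists(self) -> list[list[tuple[int, float]]]:
        nbrs: list[list[tuple[int, float]]] = [[] for _ in range(self.n_vertices)]
        for (a, b), w in zip(self.edges, self.weights):
            nbrs[int(a)].append((int(b), float(w)))
            nbrs[int(b)].append((int(a), float(w)))
        return nbrs

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=int)
        if len(self.edges):
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    # -- invariants --------------------------------------------------------
    def validate(self, rtol: float = 1e-9) -> "ArborGraph":
        n, m = self.n_vertices, len(self.edges)
        if m != n - 1:
            raise MorphologyError(f"not a tree: {n} vertices, {m} edges")
        # connectivity via union-find
        parent = np.arange(n)

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in self.edges:
            ra, rb = find(int(a)), find(int(b))
            if ra == rb:
                raise MorphologyError("cycle detected in arbor graph")
            parent[ra] = rb
        d = np.linalg.norm(
            self.positions[self.edges[:, 0]] - self.positions[self.edges[:, 1]],
            axis=1,
        )
        scale = max(1.0, float(np.abs(self.weights).max(initial=0.0)))
        if np.any(np.abs(d - self.weights) > rtol * scale):
            raise MorphologyError("edge weights do not match Euclidean distances")
        return self

    # -- export ------------------------------------------------------------
    def vertex_set(self, include_bifurcations: bool = False) -> VertexSet:
        """Fixed vertices for comparison-tree construction."""
        boutons = self.positions[self.bouton_indices]
        extras = None
        if include_bifurcations:
            bif = np.flatnonzero(self.kinds == "bifurcation")
            if len(bif) == 0:
                raise ValueError("arbor graph has no bifurcation vertices")
            extras = self.positions[bif]
        return VertexSet(self.positions[self.root_index], boutons, extras)


# ---------------------------------------------------------------------------
# reconstruction -> graph
# ---------------------------------------------------------------------------

def _structural_kind(node: ReconNode, n_children: int, is_root: bool) -> str:
    """Landmark kind of a node given its (post-pruning) out-degree."""
    if is_root:
        return "origin"
    if node.kind in ("bouton", "white_matter"):
        return node.kind
    if n_children >= 2:
        return "bifurcation"
    if n_children == 0:
        return "tip"
    return node.kind


def to_graph(
    recon: ArborReconstruction,
    exclude_white_matter: bool = False,
    trim_tips: bool = False,
) -> ArborGraph:
    """Convert a reconstruction into the direct-distance landmark graph.

    Chains of routing points between landmarks are collapsed to a single
    edge weighted by the straight-line distance between the landmark
    endpoints.  With ``exclude_white_matter`` the myelinated segment
    descending into the white matter (flagged nodes and their descendants)
    is removed and its curvilinear length recorded; it forms no synapses in
    the cortical volume of the parent cell.  With ``trim_tips`` the wire
    distal to the last bouton of every terminal branch is removed (see
    :func:`trim_terminal_tips`).
    """
    recon.validate()
    nm = recon.node_map()
    children = recon.children_map()
    root = recon.root()

    removed: set[int] = set()
    excluded_wm = 0.0
    if exclude_white_matter:
        stack = [n.id for n in recon.nodes if n.kind == "white_matter"]
        while stack:
            nid = stack.pop()
            if nid in removed:
                continue
            removed.add(nid)
            stack.extend(children[nid])
        if root.id in removed:
            raise MorphologyError("cannot exclude the axon origin")
        for nid in removed:
            n = nm[nid]
            p = nm[n.parent_id]
            excluded_wm += float(
                np.linalg.norm(np.subtract(n.position, p.position))
            )

    kept_children = {
        nid: [c for c in kids if c not in removed]
        for nid, kids in children.items()
        if nid not in removed
    }

    # landmarks: root, boutons, branch points, leaves
    landmark_ids = []
    for n in recon.nodes:
        if n.id in removed:
            continue
        deg_out = len(kept_children[n.id])
        if (
            n.id == root.id
            or n.kind == "bouton"
            or deg_out >= 2
            or deg_out == 0
        ):
            landmark_ids.append(n.id)
    index = {nid: i for i, nid in enumerate(landmark_ids)}

    positions = np.asarray([nm[i].position for i in landmark_ids], float)
    kinds = np.asarray(
        [
            _structural_kind(
                nm[i], len(kept_children[i]), i == root.id
            )
            for i in landmark_ids
        ],
        dtype=object,
    )

    edges: list[tuple[int, int]] = []
    stack = [root.id]
    while stack:
        u = stack.pop()
        for c in kept_children[u]:
            cur = c
            while cur not in index:
                nxt = kept_children[cur]
                if len(nxt) != 1:  # pragma: no cover - landmarks catch these
                    raise MorphologyError(
                        f"routing chain through node {cur} is not reducible"
                    )
                cur = nxt[0]
            edges.append((index[u], index[cur]))
            stack.append(cur)

    edges_arr = np.asarray(edges, dtype=int).reshape(-1, 2)
    weights = np.linalg.norm(
        positions[edges_arr[:, 0]] - positions[edges_arr[:, 1]], axis=1
    ) if len(edges_arr) else np.zeros(0)

    positions = positions - positions[index[root.id]]

    graph = ArborGraph(
        positions=positions,
        kinds=kinds.astype(object),
        edges=edges_arr,
        weights=weights,
        root_index=index[root.id],
        node_ids=np.asarray(landmark_ids, dtype=int),
        excluded_wm_length=excluded_wm,
        meta={"cell_class": recon.cell_class, **recon.metadata},
    ).validate()

    if trim_tips:
        graph, _ = trim_terminal_tips(graph)
    return graph


def trim_terminal_tips(graph: ArborGraph) -> tuple[ArborGraph, float]:
    """Remove the wire distal to the last bouton of every terminal branch.

    The short tapering segment between the most distal bouton and the
    anatomical branch tip forms no synapses, so it is excess wire for the
    purposes of economy comparison.  Leaf vertices that are neither boutons
    nor the origin are stripped iteratively; the bouton set is unchanged and
    the removed length is returned exactly.  The operation is idempotent.
    """
    deg = graph.degrees()
    nbrs = graph.neighbor_lists()
    alive = np.ones(graph.n_vertices, dtype=bool)
    trimmed = 0.0
    stack = [
        v
        for v in range(graph.n_vertices)
        if deg[v] <= 1
        and v != graph.root_index
        and graph.kinds[v] not in ("bouton",)
    ]
    while stack:
        v = stack.pop()
        if not alive[v]:
            continue
        alive[v] = False
        for u, w in nbrs[v]:
            if alive[u]:
                trimmed += w
                deg[u] -= 1
                if (
                    deg[u] <= 1
                    and u != graph.root_index
                    and graph.kinds[u] not in ("bouton",)
                ):
                    stack.append(u)

    if trimmed == 0.0:
        return graph, 0.0

    new_index = -np.ones(graph.n_vertices, dtype=int)
    new_index[alive] = np.arange(int(alive.sum()))
    keep_edge = alive[graph.edges[:, 0]] & alive[graph.edges[:, 1]]
    out = ArborGraph(
        positions=graph.positions[alive],
        kinds=graph.kinds[alive],
        edges=new_index[graph.edges[keep_edge]],
        weights=graph.weights[keep_edge],
        root_index=int(new_index[graph.root_index]),
        node_ids=None if graph.node_ids is None else graph.node_ids[alive],
        trimmed_tip_length=graph.trimmed_tip_length + trimmed,
        excluded_wm_length=graph.excluded_wm_length,
        meta=dict(graph.meta),
    ).validate()
    return out, trimmed
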