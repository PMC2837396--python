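"""Branch topology and morphometrics of axon arbor graphs.

Strahler's centripetal ordering labels terminal branches first-order
(k = 1); a parent branch takes ``max(child orders) + 1`` when at least two
children attain the maximum, otherwise the maximum itself (the tie rule is
generalized to occasional three-way junctions).  The root branch carries
the arbor's maximum order, its Strahler number.  A *branch* is the
internodal section between consecutive branch points (or a branch point
and a tip), possibly spanning several graph edges through en passant
boutons.

Branches directly supporting at least one bouton are *bouton-laden*;
internodal sections with none are *bouton-free* (in cortex the latter are
candidates for myelination).  Interbouton interval and density statistics
are computed from laden sections only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import ArborGraph, ArborReconstruction
from .trees import _mst_edges

logger = logging.getLogger(__name__)

__all__ = [
    "Branch",
    "OrderProfile",
    "JunctionRecord",
    "strahler_orders",
    "branch_statistics",
    "subtree_economy",
    "branch_angles",
    "junction_volume_analysis",
    "junction_angle_report",
    "steiner_colocation",
]


@dataclass
class Branch:
    """One internodal branch of the arbor graph."""

    id: int
    order: int                 # Strahler order k >= 1
    vertices: list[int]        # graph indices, proximal -> distal
    length: float              # µm
    n_boutons: int
    parent: int | None         # id of the parent branch
    is_root_branch: bool = False

    @property
    def laden(self) -> bool:
        return self.n_boutons > 0

    @property
    def proximal(self) -> int:
        return self.vertices[0]

    @property
    def distal(self) -> int:
        return self.vertices[-1]


def _rooted_children(graph: ArborGraph) -> list[list[tuple[int, float]]]:
    """Children adjacency (with edge weights) of the rooted tree."""
    nbrs = graph.neighbor_lists()
    n = graph.n_vertices
    children: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    seen = np.zeros(n, dtype=bool)
    seen[graph.root_index] = True
    stack = [graph.root_index]
    while stack:
        u = stack.pop()
        for v, w in sorted(nbrs[u]):
            if not seen[v]:
                seen[v] = True
                children[u].append((v, w))
                stack.append(v)
    return children


def strahler_orders(graph: ArborGraph) -> list[Branch]:
    """Decompose the rooted graph into branches and Strahler-order them."""
    children = _rooted_children(graph)
    root = graph.root_index
    kinds = graph.kinds

    branches: list[Branch] = []
    child_branches: dict[int, list[int]] = {}
    # walk branch by branch: a branch ends at a branch point (>= 2 children)
    # or a tip (0 children)
    stack: list[tuple[int, int | None]] = [(root, None)]
    while stack:
        start, parent_branch = stack.pop()
        for first, w0 in children[start]:
            verts = [start, first]
            length = w0
            cur = first
            while len(children[cur]) == 1:
                nxt, w = children[cur][0]
                verts.append(nxt)
                length += w
                cur = nxt
            bid = len(branches)
            n_boutons = sum(1 for v in verts[1:] if kinds[v] == "bouton")
            branches.append(
                Branch(bid, 0, verts, length, n_boutons, parent_branch,
                       is_root_branch=(start == root))
            )
            child_branches.setdefault(parent_branch, []).append(bid)
            if len(children[cur]) >= 2:
                stack.append((cur, bid))

    # order bottom-up: children were always created after their parent
    for b in reversed(branches):
        kids = child_branches.get(b.id, [])
        if not kids:
            b.order = 1
        else:
            orders = [branches[k].order for k in kids]
            m = max(orders)
            b.order = m + 1 if orders.count(m) >= 2 else m
    return branches


@dataclass
class OrderProfile:
    """Per-Strahler-order morphometrics.

    ``table`` columns: order, length_um, length_pct, n_boutons,
    bouton_pct, laden_length_um, density_per_um (laden sections only),
    interbouton_interval_um, bouton_free_pct (share of the order's length
    in branches carrying no bouton).
    """

    table: pd.DataFrame
    strahler_number: int
    total_length_um: float
    total_boutons: int

    def fraction_boutons_orders(self, *orders: int) -> float:
        sel = self.table[self.table["order"].isin(orders)]
        return float(sel["bouton_pct"].sum() / 100.0)


def branch_statistics(graph: ArborGraph,
                      branches: list[Branch] | None = None) -> OrderProfile:
    """Aggregate branch morphometrics by Strahler order.

    Apply to a tip-trimmed graph so terminal overhangs do not inflate
    first-order length.
    """
    if branches is None:
        branches = strahler_orders(graph)
    total_len = sum(b.length for b in branches)
    total_b = sum(b.n_boutons for b in branches)
    rows = []
    for k in range(1, max(b.order for b in branches) + 1):
        sel = [b for b in branches if b.order == k]
        length = sum(b.length for b in sel)
        nb = sum(b.n_boutons for b in sel)
        laden_len = sum(b.length for b in sel if b.laden)
        laden_b = sum(b.n_boutons for b in sel if b.laden)
        free_len = sum(b.length for b in sel if not b.laden)
        density = laden_b / laden_len if laden_len > 0 else np.nan
        rows.append(
            dict(
                order=k,
                length_um=length,
                length_pct=100.0 * length / total_len if total_len else np.nan,
                n_boutons=nb,
                bouton_pct=100.0 * nb / total_b if total_b else np.nan,
                laden_length_um=laden_len,
                density_per_um=density,
                interbouton_interval_um=1.0 / density if density and density > 0
                else np.nan,
                bouton_free_pct=100.0 * free_len / length if length else np.nan,
            )
        )
    return OrderProfile(
        table=pd.DataFrame(rows),
        strahler_number=max(b.order for b in branches),
        total_length_um=total_len,
        total_boutons=total_b,
    )


def subtree_economy(graph: ArborGraph,
                    branches: list[Branch] | None = None) -> pd.DataFrame:
    """Wire economy of every branch-rooted subtree, grouped by order.

    For each branch (root branch excluded) the subtree comprises the
    branch and all its descendants; its wire economy is the exact MST
    length over {subtree origin} ∪ {subtree boutons} divided by the
    subtree's wire length.  Subtrees without boutons are skipped.

    Returns a frame with one row per evaluated branch
    (branch_id, order, n_boutons, wire_um, mst_um, epsilon); aggregate
    with e.g. ``df.groupby("order")["epsilon"].mean()``.
    """
    if branches is None:
        branches = strahler_orders(graph)
    kids: dict[int, list[int]] = {}
    for b in branches:
        if b.parent is not None:
            kids.setdefault(b.parent, []).append(b.id)

    rows = []
    for b in branches:
        if b.is_root_branch:
            continue
        stack = [b.id]
        wire = 0.0
        bouton_vs: list[int] = []
        while stack:
            cur = branches[stack.pop()]
            wire += cur.length
            bouton_vs.extend(v for v in cur.vertices[1:]
                             if graph.kinds[v] == "bouton")
            stack.extend(kids.get(cur.id, []))
        if not bouton_vs or wire <= 0:
            logger.debug("skipping boutonless subtree at branch %d", b.id)
            continue
        pts = np.vstack([graph.positions[b.proximal][None, :],
                         graph.positions[bouton_vs]])
        e = _mst_edges(pts)
        mst_len = float(
            np.linalg.norm(pts[e[:, 0]] - pts[e[:, 1]], axis=1).sum()
        )
        rows.append(dict(branch_id=b.id, order=b.order,
                         n_boutons=len(bouton_vs), wire_um=wire,
                         mst_um=mst_len, epsilon=mst_len / wire))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# branch-node geometry
# ---------------------------------------------------------------------------

@dataclass
class JunctionRecord:
    """Local geometry of one axon bifurcation."""

    node_id: int
    angles_deg: list[float] = field(default_factory=list)
    trunk_radius_um: float | None = None
    daughter_radii_um: list[float] = field(default_factory=list)
    volume_class: str = "ambiguous"   # equal | unequal | ambiguous
    offset_truncated: bool = False    # a daughter was shorter than the offset


def _daughter_direction(nm, children, nid, first_child, offset):
    """Unit vector from a junction toward the point at arc-length
    ``offset`` along the daughter; truncated at the next landmark chain
    end if the daughter is shorter."""
    origin = np.asarray(nm[nid].position, float)
    prev = origin
    cur = first_child
    travelled = 0.0
    truncated = False
    while True:
        p = np.asarray(nm[cur].position, float)
        seg = np.linalg.norm(p - prev)
        if travelled + seg >= offset and seg > 0:
            t = (offset - travelled) / seg
            target = prev + t * (p - prev)
            break
        travelled += seg
        nxt = children[cur]
        if len(nxt) != 1:
            target = p
            truncated = True
            break
        prev = p
        cur = nxt[0]
    d = target - origin
    norm = np.linalg.norm(d)
    return (d / norm if norm > 0 else None), truncated


def branch_angles(
    recon: ArborReconstruction,
    offset_um: float = 5.0,
) -> tuple[list[JunctionRecord], dict]:
    """Aperture angles between daughter branches at every bifurcation.

    The direction of each daughter is taken from the junction to the point
    at arc length ``offset_um`` along its polyline (default 5 µm, within
    the 1-10 µm window that defines "local" geometry); pairwise angles are
    recorded at three-way junctions.  The summary includes the sample
    mean/sd, a maximum-likelihood Gaussian fit, and the fraction of angles
    inside the 120 ± 10 deg Steiner window.
    """
    if not 1.0 <= offset_um <= 10.0:
        raise ValueError("offset must lie in the 1-10 µm local window")
    nm = recon.node_map()
    children = recon.children_map()
    root_id = recon.root().id
    records: list[JunctionRecord] = []
    for nid, kids in children.items():
        if len(kids) < 2 or nid == root_id:
            continue
        dirs = []
        truncated = False
        for c in kids:
            u, trunc = _daughter_direction(nm, children, nid, c, offset_um)
            truncated |= trunc
            if u is not None:
                dirs.append(u)
        rec = JunctionRecord(node_id=nid, offset_truncated=truncated)
        for i in range(len(dirs)):
            for j in range(i + 1, len(dirs)):
                cosang = float(np.clip(dirs[i] @ dirs[j], -1.0, 1.0))
                rec.angles_deg.append(float(np.degrees(np.arccos(cosang))))
        records.append(rec)

    angles = np.asarray([a for r in records for a in r.angles_deg])
    summary = {
        "n_angles": int(angles.size),
        "mean_deg": float(angles.mean()) if angles.size else np.nan,
        "sd_deg": float(angles.std(ddof=1)) if angles.size > 1 else np.nan,
        "gaussian_mu_deg": float(angles.mean()) if angles.size else np.nan,
        "gaussian_sd_deg": float(angles.std(ddof=0)) if angles.size else np.nan,
        "fraction_in_steiner_window": float(
            np.mean((angles >= 110.0) & (angles <= 130.0))
        ) if angles.size else np.nan,
    }
    return records, summary


def _window_radii(nm, step_fn, start_id, window):
    """Radii of nodes whose arc distance from the junction lies in the
    window; walks ``step_fn`` (towards parent or along a daughter)."""
    lo, hi = window
    radii = []
    prev = np.asarray(nm[start_id].position, float)
    travelled = 0.0
    cur = step_fn(start_id)
    while cur is not None:
        p = np.asarray(nm[cur].position, float)
        travelled += np.linalg.norm(p - prev)
        if travelled > hi:
            break
        if travelled >= lo:
            radii.append(nm[cur].radius)
        prev = p
        cur = step_fn(cur)
    return radii


def junction_volume_analysis(
    recon: ArborReconstruction,
    window: tuple[float, float] = (1.0, 10.0),
    area_tol: float = 0.05,
    convention: str = "daughter",
) -> list[JunctionRecord]:
    """Local volume-cost classification of every bifurcation.

    Cross-sectional areas (pi r^2, circular profile assumed) are compared
    within the 1-10 µm local window.  A junction is *ambiguous* when any
    trunk/daughter diameter varies inside the window or radii are missing;
    otherwise it is *equal* when the compared areas agree within
    ``area_tol`` (relative), else *unequal*.  ``convention="daughter"``
    compares the daughter areas with each other;
    ``convention="trunk"`` compares the trunk area against the summed
    daughter areas.
    """
    if convention not in ("daughter", "trunk"):
        raise ValueError("convention must be 'daughter' or 'trunk'")
    nm = recon.node_map()
    children = recon.children_map()
    root_id = recon.root().id

    records = []
    for nid, kids in children.items():
        if len(kids) < 2 or nid == root_id:
            continue
        rec = JunctionRecord(node_id=nid)

        def towards_parent(i):
            return nm[i].parent_id

        trunk_radii = _window_radii(nm, towards_parent, nid, window)
        segs = [trunk_radii]
        for c in kids:
            def along(i, _first=c):
                if i == nid:
                    return _first
                nxt = children[i]
                return nxt[0] if len(nxt) == 1 else None

            segs.append(_window_radii(nm, along, nid, window))

        def constant(radii):
            if not radii:
                return None
            r0 = radii[0]
            ref = max(abs(r0), 1e-12)
            return r0 if all(abs(r - r0) <= 1e-6 * ref for r in radii) else None

        values = [constant(s) for s in segs]
        rec.trunk_radius_um = values[0]
        rec.daughter_radii_um = values[1:]
        if any(v is None for v in values):
            rec.volume_class = "ambiguous"
        else:
            areas = [np.pi * v ** 2 for v in values]
            trunk_area, d_areas = areas[0], areas[1:]
            if convention == "daughter":
                lo, hi = min(d_areas), max(d_areas)
                equal = hi - lo <= area_tol * hi
            else:
                s = sum(d_areas)
                equal = abs(trunk_area - s) <= area_tol * max(trunk_area, s)
            rec.volume_class = "equal" if equal else "unequal"
        records.append(rec)
    return records


def junction_angle_report(
    volume_records: list[JunctionRecord],
    angle_records: list[JunctionRecord],
    window_deg: tuple[float, float] = (110.0, 130.0),
) -> pd.DataFrame:
    """Joint table of volume class × Steiner-angle-window membership."""
    ang = {r.node_id: r.angles_deg for r in angle_records}
    rows = []
    for r in volume_records:
        angles = ang.get(r.node_id, [])
        in_window = any(window_deg[0] <= a <= window_deg[1] for a in angles)
        rows.append(dict(node_id=r.node_id, volume_class=r.volume_class,
                         angle_in_window=in_window,
                         angles_deg=angles))
    return pd.DataFrame(rows)


def steiner_colocation(
    bifurcations: np.ndarray,
    steiner_points: np.ndarray,
    radius: float = 2.5,
) -> float:
    """Fraction of Steiner points co-located with a real bifurcation.

    Greedy one-to-one matching by increasing pairwise distance; a Steiner
    point is matched when an unclaimed bifurcation lies within ``radius``
    µm (default 2.5 µm).
    """
    bif = np.atleast_2d(np.asarray(bifurcations, float))
    stn = np.atleast_2d(np.asarray(steiner_points, float))
    if bif.size == 0 or stn.size == 0:
        raise ValueError("both point sets must be non-empty")
    d = cdist(stn, bif)
    si, bi = np.unravel_index(np.argsort(d, axis=None), d.shape)
    used_s = np.zeros(len(stn), bool)
    used_b = np.zeros(len(bif), bool)
    matched = 0
    for s, b in zip(si, bi):
        if d[s, b] > radius:
            break
        if used_s[s] or used_b[b]:
            continue
        used_s[s] = used_b[b] = True
        matched += 1
    return matched / len(stn)
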