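"""Synthetic axon arbors with cortical branching statistics.

Real intracortical axon reconstructions of the kind this package analyses
(adult cat visual cortex, biocytin-labelled spiny and basket cells) are
not publicly deposited, so this module generates stand-in arbors that
reproduce their *measured summary statistics*: total length of tens of
millimetres, thousands of boutons, Strahler numbers of 5-7, first-order
interbouton intervals of ~14 µm (spiny) and ~5.7 µm (basket), boutons
concentrated on first/second-order branches, bouton-free proximal
collaterals, Gaussian branch-angle distributions near 80-85 deg, and a
few-µm bouton-free overhang at every branch tip.

The generator is phenomenological: a main descending trunk emits radial
primary collaterals which branch recursively (mostly interstitially, the
dominant mode in cortex); Strahler orders are then computed on the grown
skeleton and boutons are laid down per order.  It makes no claim about
developmental mechanism and deliberately omits features such as axonal
tortuosity, laminar anisotropy and terminal clustering around functional
domains -- see the methods note for what this does and does not allow
tests on synthetic populations to conclude.

All randomness flows from one seed: ``generate_arbor(params, seed)`` is
deterministic, and :func:`arbor_population` derives per-arbor seeds by
``numpy`` seed-sequence spawning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ArborReconstruction, ReconNode, VertexSet

__all__ = [
    "SyntheticParams",
    "ring_arbor",
    "default_params",
    "generate_arbor",
    "arbor_population",
]


def ring_arbor(n_boutons: int, r: float) -> VertexSet:
    """Planar ring of boutons around a central cell body.

    The classic worked geometry for contrasting wire and path cost: N
    boutons equally spaced on a circle of radius ``r`` (µm) in the z = 0
    plane, root at the centre.  Neighbouring boutons are separated by the
    chord ``d = 2 r sin(pi / N)``.
    """
    if n_boutons < 1:
        raise ValueError("need at least one bouton")
    if r <= 0:
        raise ValueError("radius must be positive")
    ang = 2.0 * np.pi * np.arange(n_boutons) / n_boutons
    pts = np.column_stack([r * np.cos(ang), r * np.sin(ang),
                           np.zeros(n_boutons)])
    return VertexSet(root=np.zeros(3), boutons=pts)


@dataclass
class SyntheticParams:
    """Growth and bouton-placement parameters for one cell class.

    Length units µm, angles degrees.  ``ibi_by_order`` and
    ``bouton_free_prob`` are indexed by Strahler order (first entry =
    order 1); the last entry is reused for higher orders.
    """

    cell_class: str
    trunk_length: float
    n_primary: float              # expected primary collaterals on the trunk
    primary_length_mean: float
    primary_length_sd: float
    interstitial_rate: float      # side branches per µm on primaries
    rate_decay: float             # rate multiplier per extra depth level
    length_decay: float           # child length scale per extra depth level
    length_sd_frac: float
    min_branch_length: float
    max_depth: int
    angle_mu: float               # daughter-daughter aperture angle, deg
    angle_sd: float
    ibi_by_order: tuple[float, ...]
    bouton_free_prob: tuple[float, ...]
    tip_overhang_mean: float
    tip_overhang_sd: float
    axon_radius: float
    wm_tail_length: float         # myelinated descending segment (spiny)

    def __post_init__(self) -> None:
        if not 0.0 < self.angle_mu < 180.0:
            raise ValueError("angle_mu must lie in (0, 180) degrees")
        if self.angle_sd <= 0:
            raise ValueError("angle_sd must be positive")
        for name in ("trunk_length", "n_primary", "primary_length_mean",
                     "interstitial_rate", "rate_decay", "length_decay",
                     "min_branch_length", "tip_overhang_mean", "axon_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(v <= 0 for v in self.ibi_by_order):
            raise ValueError("interbouton intervals must be positive")
        if any(not 0 <= p <= 1 for p in self.bouton_free_prob):
            raise ValueError("bouton_free_prob entries must lie in [0, 1]")


def default_params(cell_class: str) -> SyntheticParams:
    """Class defaults calibrated to published cortical arbor statistics.

    Spiny (excitatory) cells: sparser boutons (first-order interbouton
    interval ~14 µm), maximum Strahler order mostly 5-6, a myelinated
    tail descending into the white matter, little bouton-free wire at low
    orders.  Basket (inhibitory) cells: dense bouton strings on terminal
    branches (~5.7 µm interval), deeper branching (order ~7), and a much
    larger share of bouton-free (myelinated) internodal wire.  Branch
    aperture angles are Gaussian with class means near 80-85 deg.
    Primary collaterals reach out on the order of a millimetre.
    """
    if cell_class == "spiny":
        return SyntheticParams(
            cell_class="spiny",
            trunk_length=650.0,
            n_primary=5.0,
            primary_length_mean=850.0,
            primary_length_sd=250.0,
            interstitial_rate=0.0045,
            rate_decay=0.95,
            length_decay=0.62,
            length_sd_frac=0.35,
            min_branch_length=45.0,
            max_depth=9,
            angle_mu=80.3,
            angle_sd=35.7,
            ibi_by_order=(14.1, 17.0, 32.0, 70.0, 160.0, 400.0),
            bouton_free_prob=(0.0, 0.06, 0.35, 0.70, 0.95, 1.0),
            tip_overhang_mean=3.5,
            tip_overhang_sd=1.5,
            axon_radius=0.4,
            wm_tail_length=500.0,
        )
    if cell_class == "basket":
        return SyntheticParams(
            cell_class="basket",
            trunk_length=550.0,
            n_primary=5.0,
            primary_length_mean=620.0,
            primary_length_sd=200.0,
            interstitial_rate=0.0072,
            rate_decay=0.92,
            length_decay=0.60,
            length_sd_frac=0.35,
            min_branch_length=35.0,
            max_depth=10,
            angle_mu=84.8,
            angle_sd=34.5,
            ibi_by_order=(5.7, 7.5, 16.0, 45.0, 120.0, 300.0),
            bouton_free_prob=(0.0, 0.26, 0.55, 0.85, 1.0, 1.0),
            tip_overhang_mean=3.5,
            tip_overhang_sd=1.5,
            axon_radius=0.5,
            wm_tail_length=0.0,
        )
    raise ValueError(f"unknown cell class {cell_class!r}; use spiny or basket")


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

class _Seg:
    """Straight internodal section of the growing skeleton."""

    __slots__ = ("start", "direction", "length", "depth", "children",
                 "order", "wm")

    def __init__(self, start, direction, length, depth, wm=False):
        self.start = start
        self.direction = direction
        self.length = length
        self.depth = depth
        self.children: list["_Seg"] = []
        self.order = 0
        self.wm = wm

    @property
    def end(self):
        return self.start + self.direction * self.length


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_direction(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _rotate_from(parent_dir: np.ndarray, angle_deg: float, rng) -> np.ndarray:
    """Direction at ``angle_deg`` from ``parent_dir``, uniform azimuth."""
    a = np.deg2rad(angle_deg)
    # orthonormal frame around the parent direction
    helper = np.array([1.0, 0.0, 0.0])
    if abs(parent_dir @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(parent_dir, helper))
    w = np.cross(parent_dir, u)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return _unit(math.cos(a) * parent_dir
                 + math.sin(a) * (math.cos(phi) * u + math.sin(phi) * w))


def _draw_angle(params: SyntheticParams, rng) -> float:
    """Aperture angle from the Gaussian truncated to (0, 180) deg."""
    for _ in range(100):
        a = rng.normal(params.angle_mu, params.angle_sd)
        if 0.0 < a < 180.0:
            return float(a)
    return params.angle_mu


def _grow_collateral(params, rng, start, direction, length, depth):
    """Grow one straight collateral, splitting it into segments at the
    interstitial side-branch points; recurses into the side branches.

    Returns ``(first_segment, last_segment)`` of the straight chain.  On
    the trunk (depth 0) the most distal side branch attaches exactly at
    the trunk's end, so the trunk terminates in a branch point rather
    than a bare tip.
    """
    if depth == 0:
        k = max(0, int(rng.poisson(params.n_primary)) - 1)
        attach = sorted(
            rng.uniform(0.15 * length, length, size=k).tolist()
        ) + [length]
        end_attach = True
    elif depth < params.max_depth:
        rate = params.interstitial_rate * params.rate_decay ** (depth - 1)
        k = int(rng.poisson(rate * length))
        attach = sorted(
            rng.uniform(0.05 * length, 0.98 * length, size=k).tolist()
        )
        end_attach = False
    else:
        attach = []
        end_attach = False

    cuts = [0.0] + attach + ([] if end_attach else [length])
    attach_set = set(attach)
    first: _Seg | None = None
    prev: _Seg | None = None
    for a, b in zip(cuts[:-1], cuts[1:]):
        seg = _Seg(start + direction * a, direction, b - a, depth)
        if prev is None:
            first = seg
        else:
            prev.children.append(seg)
        prev = seg
        if b in attach_set:
            child_len = _child_length(params, rng, depth + 1)
            if child_len is not None:
                if depth == 0:
                    d = _random_direction(rng)
                else:
                    d = _rotate_from(direction, _draw_angle(params, rng), rng)
                child, _ = _grow_collateral(params, rng, seg.end, d,
                                            child_len, depth + 1)
                seg.children.append(child)
    return first, prev


def _child_length(params, rng, depth) -> float | None:
    if depth > params.max_depth:
        return None
    if depth == 1:
        mean, sd = params.primary_length_mean, params.primary_length_sd
    else:
        mean = params.primary_length_mean * params.length_decay ** (depth - 1)
        sd = params.length_sd_frac * mean
    if mean < params.min_branch_length:
        return None
    val = rng.normal(mean, sd)
    return float(max(val, params.min_branch_length))


def _all_segments(root_seg: _Seg) -> list[_Seg]:
    out = []
    stack = [root_seg]
    while stack:
        s = stack.pop()
        out.append(s)
        stack.extend(s.children)
    return out


def _assign_strahler(root_seg: _Seg) -> None:
    order = []
    stack = [(root_seg, False)]
    while stack:
        seg, done = stack.pop()
        if done:
            if not seg.children:
                seg.order = 1
            else:
                ks = [c.order for c in seg.children]
                m = max(ks)
                seg.order = m + 1 if ks.count(m) >= 2 else m
            order.append(seg)
        else:
            stack.append((seg, True))
            stack.extend((c, False) for c in seg.children)


def _per_order(values: tuple[float, ...], k: int) -> float:
    return values[min(k - 1, len(values) - 1)]


def generate_arbor(params: SyntheticParams, seed) -> ArborReconstruction:
    """Grow one synthetic arbor; deterministic given ``seed``.

    Growth happens in three phases: (1) the branch skeleton (trunk,
    primaries, recursive interstitial side branches); (2) Strahler
    ordering of the skeleton; (3) bouton placement per branch order
    (gamma-distributed interbouton gaps with the configured mean, whole
    sections left bouton-free with the per-order probability, and a
    bouton-free overhang of a few µm appended beyond every terminal's
    last bouton).  Raises if the parameters yield no boutons at all.
    """
    rng = np.random.default_rng(seed)
    trunk_dir = _unit(np.array([0.0, 0.0, -1.0])
                      + 0.15 * rng.normal(size=3))
    trunk, trunk_last = _grow_collateral(params, rng, np.zeros(3), trunk_dir,
                                         params.trunk_length, depth=0)
    if params.wm_tail_length > 0:
        # myelinated continuation descending into the white matter
        trunk_last.children.append(
            _Seg(trunk_last.end, np.array([0.0, 0.0, -1.0]),
                 params.wm_tail_length, 0, wm=True)
        )
    _assign_strahler(trunk)

    nodes: list[ReconNode] = []
    next_id = [0]

    def add(kind, pos, parent_id, radius=None):
        next_id[0] += 1
        nodes.append(ReconNode(
            next_id[0], kind, tuple(float(x) for x in pos),
            params.axon_radius if radius is None else radius, parent_id,
        ))
        return next_id[0]

    root_id = add("origin", np.zeros(3), None)
    total_boutons = 0

    # trunk and every segment carry at most: a 5 µm routing marker (local
    # geometry for angle/diameter windows), the boutons, and the end node
    stack = [(trunk, root_id)]
    while stack:
        seg, parent = stack.pop()
        marks: list[tuple[float, str]] = []
        if seg.length > 6.0:
            marks.append((5.0, "white_matter" if seg.wm else "routing"))
        terminal = not seg.children
        if not seg.wm:
            free_p = _per_order(params.bouton_free_prob, seg.order)
            laden = rng.uniform() >= free_p
            if laden:
                ibi = _per_order(params.ibi_by_order, seg.order)
                stop = seg.length - 0.5
                if terminal:
                    overhang = max(
                        0.5, rng.normal(params.tip_overhang_mean,
                                        params.tip_overhang_sd))
                    stop = seg.length - overhang
                pos = 0.0
                placed = []
                while True:
                    pos += rng.gamma(4.0, ibi / 4.0)
                    if pos > stop:
                        break
                    placed.append(pos)
                if terminal and stop > 1.0:
                    # the most distal bouton sits right at the overhang
                    # stop, leaving only the few-µm tip beyond it
                    if placed and stop - placed[-1] < 0.5:
                        placed[-1] = stop
                    else:
                        placed.append(stop)
                marks.extend((p, "bouton") for p in placed)
                total_boutons += len(placed)
        marks.sort()

        cur = parent
        for dist, kind in marks:
            cur = add(kind, seg.start + seg.direction * dist, cur)
        end_kind = ("white_matter" if seg.wm
                    else "tip" if terminal
                    else "bifurcation" if len(seg.children) >= 2
                    else "routing")
        end_id = add(end_kind, seg.end, cur)
        for child in seg.children:
            stack.append((child, end_id))

    if total_boutons == 0:
        raise ValueError(
            "parameter combination produced an arbor without boutons"
        )

    recon = ArborReconstruction(
        nodes,
        cell_class=params.cell_class,
        metadata={"generator": "arborcost.synthetic",
                  **({"seed": int(seed)} if isinstance(seed, (int, np.integer))
                     else {})},
    )
    return recon.validate()


def arbor_population(params: SyntheticParams | str, n: int,
                     seed: int = 0) -> list[ArborReconstruction]:
    """Generate ``n`` arbors with independent seeds spawned from ``seed``."""
    if isinstance(params, str):
        params = default_params(params)
    children = np.random.SeedSequence(seed).spawn(n)
    return [generate_arbor(params, s) for s in children]
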