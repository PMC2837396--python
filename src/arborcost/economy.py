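"""Wire-length and path-length economy measures, latency and dispersion.

Definitions (all lengths in micrometres):

* wire length ``L`` -- sum of tree edge weights, each edge counted once
  regardless of how many root-to-bouton paths share it.
* path length ``d_T(r, v)`` -- sum of edge weights on the unique tree path
  from the root to bouton v.
* wire economy  ``epsilon = L_MST / L``        (1 = wire-optimal)
* path economy  ``gamma = P_STAR / P``         (1 = delay-optimal), where
  ``P`` is by default the *mean* root-to-bouton path length and ``P_STAR``
  the mean straight-line root distance (the star tree's path length).
* path ratio ``rho = d_T / d_Euclid >= 1``; defined as 1 for a bouton
  coincident with the root.

Latencies divide path length by a uniform conduction velocity; the
temporal dispersion ``sigma_t`` is the standard deviation of latencies
about the ordinary least-squares regression of path length on Euclidean
root distance, which makes it independent of any intercept/slope offset
shared by all boutons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats
from scipy.sparse import csgraph

__all__ = [
    "wire_length",
    "path_lengths",
    "economy_measures",
    "distance_latency_analysis",
    "PathProfile",
    "EconomyReport",
    "LatencyAnalysis",
]

#: paper-calibrated default conduction velocities for adult cat visual
#: cortex intracortical axons, m s^-1
DEFAULT_VELOCITIES = (0.15, 0.30)


def wire_length(tree) -> float:
    """Total wire of a tree (µm): each edge counted once."""
    return float(np.asarray(tree.weights).sum())


@dataclass
class PathProfile:
    """Per-bouton spatial/temporal cost records for one tree."""

    bouton_index: np.ndarray   # vertex indices of the boutons
    euclid_um: np.ndarray      # straight-line root distance
    path_um: np.ndarray        # tree path length d_T(root, v)
    ratio: np.ndarray          # rho = path / euclid (1 where euclid == 0)

    @property
    def n(self) -> int:
        return len(self.bouton_index)

    def latency_ms(self, velocity: float) -> np.ndarray:
        """Latencies at a uniform conduction velocity (m s^-1)."""
        if velocity <= 0:
            raise ValueError("velocity must be positive")
        return self.path_um * 1e-3 / velocity

    def mean_path(self) -> float:
        return float(self.path_um.mean())

    def total_path(self) -> float:
        return float(self.path_um.sum())

    def fraction_ratio_below(self, bound: float = 2.0) -> float:
        return float(np.mean(self.ratio < bound))


def path_lengths(tree) -> PathProfile:
    """Root-to-bouton tree path lengths (Dijkstra on the tree).

    ``tree`` may be an :class:`~arborcost.core.ArborGraph` or a
    :class:`~arborcost.trees.ConstructedTree`; both expose positions,
    weighted edges, a root index and their bouton indices.
    """
    dist = csgraph.dijkstra(tree.adjacency(), indices=tree.root_index)
    if np.any(np.isinf(dist)):
        raise ValueError("tree is disconnected: unreachable vertices")
    boutons = np.asarray(tree.bouton_indices, dtype=int)
    pts = tree.positions
    euclid = np.linalg.norm(pts[boutons] - pts[tree.root_index], axis=1)
    path = dist[boutons]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(euclid > 0, path / euclid, 1.0)
    return PathProfile(boutons, euclid, path, ratio)


@dataclass
class EconomyReport:
    """Economy of one arbor against its comparison trees.

    ``wire`` and ``mean_path`` map tree labels (``axon``, ``mst``,
    ``mst_nodes``, ``esmt``, ``star``, ...) to totals; epsilon/gamma
    variants are named after the tree in the denominator, e.g.
    ``epsilon["axon"] = L_MST / L_AXON`` and
    ``gamma["mst"] = P_STAR / P_MST``.
    """

    n_boutons: int
    wire: dict = field(default_factory=dict)        # L_* µm
    mean_path: dict = field(default_factory=dict)   # P_* µm (per bouton)
    total_path: dict = field(default_factory=dict)
    epsilon: dict = field(default_factory=dict)
    gamma: dict = field(default_factory=dict)
    fraction_ratio_below_2: float = float("nan")
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"n_boutons": self.n_boutons,
               "fraction_ratio_below_2": self.fraction_ratio_below_2}
        for name, d in (("L", self.wire), ("P", self.mean_path),
                        ("P_total", self.total_path),
                        ("epsilon", self.epsilon), ("gamma", self.gamma)):
            for k, v in d.items():
                out[f"{name}_{k}"] = v
        out.update(self.meta)
        return out


def economy_measures(
    axon,
    comparisons: Mapping[str, object],
    use_total_path: bool = False,
) -> EconomyReport:
    """Compute epsilon/gamma variants for one arbor.

    ``axon`` is the biological arbor graph; ``comparisons`` maps labels
    (``"mst"`` required for epsilon; ``"star"`` recommended for gamma,
    otherwise the star is implied by the bouton geometry) to constructed
    trees sharing the same bouton set and root.
    """
    profile = path_lengths(axon)
    n = profile.n
    for label, tree in comparisons.items():
        t_n = len(np.asarray(tree.bouton_indices))
        if t_n != n:
            raise ValueError(
                f"comparison {label!r} spans {t_n} boutons, axon has {n}"
            )

    wire = {"axon": wire_length(axon)}
    meanp = {"axon": profile.mean_path()}
    totp = {"axon": profile.total_path()}
    p_star = float(profile.euclid_um.mean())
    t_star = float(profile.euclid_um.sum())
    profiles = {"axon": profile}
    for label, tree in comparisons.items():
        wire[label] = wire_length(tree)
        pr = path_lengths(tree)
        profiles[label] = pr
        meanp[label] = pr.mean_path()
        totp[label] = pr.total_path()
    meanp.setdefault("star", p_star)
    totp.setdefault("star", t_star)
    if "star" not in wire:
        wire["star"] = t_star  # star wire = sum of direct root distances

    if "mst" not in wire:
        raise ValueError("comparisons must include an 'mst' tree")
    l_mst = wire["mst"]
    p_ref = totp if use_total_path else meanp
    star_ref = p_ref["star"]

    eps = {k: l_mst / v for k, v in wire.items() if v > 0 and k != "mst"}
    eps["mst"] = 1.0
    gam = {k: star_ref / v for k, v in p_ref.items()
           if v > 0 and k != "star"}
    gam["star"] = 1.0

    return EconomyReport(
        n_boutons=n,
        wire=wire,
        mean_path=meanp,
        total_path=totp,
        epsilon=eps,
        gamma=gam,
        fraction_ratio_below_2=profile.fraction_ratio_below(2.0),
        meta=dict(getattr(axon, "meta", {}) or {}),
    )


@dataclass
class LatencyAnalysis:
    """Distance-path regression and temporal dispersion for one tree."""

    velocity: float            # m s^-1
    slope: float               # path per unit distance (dimensionless)
    intercept_um: float
    r_squared: float
    sigma_um: float            # residual sd about the regression, µm
    sigma_t_ms: float          # the same expressed as latency sd
    latency_ms: np.ndarray
    histogram: tuple[np.ndarray, np.ndarray]

    @property
    def intercept_mm(self) -> float:
        return self.intercept_um * 1e-3


def distance_latency_analysis(
    profile: PathProfile,
    velocity: float,
    bins: int = 50,
) -> LatencyAnalysis:
    """OLS fit of path length on Euclidean root distance, plus dispersion.

    ``sigma_t`` is the standard deviation of residuals about the fitted
    line (ddof = 2), divided by the conduction velocity.  Requires at
    least three boutons and non-degenerate distances.
    """
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    if profile.n < 3:
        raise ValueError("need at least 3 boutons for a regression")
    x, y = profile.euclid_um, profile.path_um
    if np.ptp(x) <= 1e-9 * max(float(np.abs(x).max()), 1.0):
        raise ValueError("zero-variance root distances: cannot fit")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    sigma_um = float(np.sqrt((resid ** 2).sum() / max(profile.n - 2, 1)))
    latency = profile.latency_ms(velocity)
    hist = np.histogram(latency, bins=bins)
    return LatencyAnalysis(
        velocity=velocity,
        slope=float(fit.slope),
        intercept_um=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        sigma_um=sigma_um,
        sigma_t_ms=sigma_um * 1e-3 / velocity,
        latency_ms=latency,
        histogram=hist,
    )
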