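"""Wire/path economy trade-off analysis.

Sweeping the LAST balance parameter alpha from 1 upward traces a
continuous trade-off curve in the (epsilon, gamma) economy plane: at
alpha = 1 the construction is the star tree (gamma = 1, epsilon small);
as alpha grows it relaxes toward the MST (epsilon -> 1, gamma falling).
The *equilibrium* is the alpha at which wire and path economy curves
cross.  Uniform random spanning trees provide the chance baseline, and
nonparametric population statistics compare arbor groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import VertexSet
from .economy import path_lengths, wire_length
from .trees import last_tree, minimum_spanning_tree, random_spanning_tree

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "TradeoffCurve",
    "last_sweep",
    "equilibrium",
    "randomized_baseline",
    "compare_populations",
    "compare_variances",
    "rank_association",
]

#: default alpha grid: fine steps through the biologically relevant range
#: plus sparse large values to reach the MST limit
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(1.0, 3.01, 0.1), 2)) + (
    4.0, 6.0, 10.0, 100.0,
)


@dataclass
class TradeoffCurve:
    """Economy curves epsilon(alpha), gamma(alpha) for one vertex set."""

    alphas: np.ndarray
    epsilon: np.ndarray
    gamma: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, float)
        self.epsilon = np.asarray(self.epsilon, float)
        self.gamma = np.asarray(self.gamma, float)
        if np.any(np.diff(self.alphas) <= 0):
            raise ValueError("alpha grid must be strictly increasing")
        if self.alphas[0] < 1:
            raise ValueError("alpha grid must start at >= 1")


def last_sweep(vs: VertexSet, alphas=DEFAULT_ALPHA_GRID) -> TradeoffCurve:
    """Build a LAST tree per alpha and record its wire and path economy.

    epsilon(alpha) = L_MST / L_LAST(alpha);
    gamma(alpha) = P_STAR / P_LAST(alpha) with mean path lengths.
    """
    alphas = np.asarray(sorted(alphas), float)
    mst = minimum_spanning_tree(vs)
    l_mst = mst.total_length
    euclid = np.linalg.norm(vs.boutons - vs.root, axis=1)
    p_star = float(euclid.mean())
    eps = np.empty(len(alphas))
    gam = np.empty(len(alphas))
    for i, a in enumerate(alphas):
        t = last_tree(vs, float(a), _mst=mst)
        eps[i] = l_mst / wire_length(t)
        gam[i] = p_star / path_lengths(t).mean_path()
    return TradeoffCurve(alphas, eps, gam, meta={"n_boutons": vs.n})


def equilibrium(curve: TradeoffCurve) -> tuple[float, float] | None:
    """Locate the alpha where the epsilon and gamma curves cross.

    The crossing is interpolated linearly in alpha between the adjacent
    grid points; returns ``(alpha_star, economy_star)`` or ``None`` (and
    logs) when the curves do not cross within the grid.
    """
    f = curve.epsilon - curve.gamma
    for i in range(len(f) - 1):
        if f[i] == 0.0:
            return float(curve.alphas[i]), float(curve.epsilon[i])
        if f[i] < 0.0 <= f[i + 1]:
            t = -f[i] / (f[i + 1] - f[i])
            a = curve.alphas[i] + t * (curve.alphas[i + 1] - curve.alphas[i])
            e = curve.epsilon[i] + t * (curve.epsilon[i + 1] - curve.epsilon[i])
            return float(a), float(e)
    if f[-1] == 0.0:
        return float(curve.alphas[-1]), float(curve.epsilon[-1])
    logger.info("economy curves do not cross within the alpha grid")
    return None


def randomized_baseline(vs: VertexSet, n_trees: int = 250, seed=0) -> dict:
    """Economy of uniform random spanning trees on the same vertex set.

    Generates ``n_trees`` Wilson trees (default 250) and returns their
    epsilon/gamma values with mean ± sd summaries.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    mst = minimum_spanning_tree(vs)
    l_mst = mst.total_length
    euclid = np.linalg.norm(vs.boutons - vs.root, axis=1)
    p_star = float(euclid.mean())
    eps = np.empty(n_trees)
    gam = np.empty(n_trees)
    for i in range(n_trees):
        t = random_spanning_tree(vs, rng)
        eps[i] = l_mst / wire_length(t)
        gam[i] = p_star / path_lengths(t).mean_path()
    return {
        "epsilon": eps,
        "gamma": gam,
        "epsilon_mean": float(eps.mean()),
        "epsilon_sd": float(eps.std(ddof=1)) if n_trees > 1 else 0.0,
        "gamma_mean": float(gam.mean()),
        "gamma_sd": float(gam.std(ddof=1)) if n_trees > 1 else 0.0,
        "n_trees": n_trees,
    }


@dataclass
class TestResult:
    test: str
    statistic: float
    pvalue: float
    significance: float
    alternative: str

    @property
    def significant(self) -> bool:
        return bool(self.pvalue < self.significance)


def compare_populations(
    x,
    y,
    design: str = "unpaired",
    alternative: str = "two-sided",
    significance: float = 0.01,
) -> TestResult:
    """Nonparametric location comparison of two arbor populations.

    Paired designs use the Wilcoxon signed-rank test, unpaired the
    Mann-Whitney U test; significance defaults to the 1% level.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if design == "paired":
        if len(x) != len(y):
            raise ValueError("paired design requires equal-length samples")
        if np.allclose(x, y):
            return TestResult("wilcoxon", 0.0, 1.0, significance, alternative)
        stat, p = stats.wilcoxon(x, y, alternative=alternative)
        return TestResult("wilcoxon", float(stat), float(p), significance,
                          alternative)
    if design == "unpaired":
        stat, p = stats.mannwhitneyu(x, y, alternative=alternative)
        return TestResult("mannwhitneyu", float(stat), float(p), significance,
                          alternative)
    raise ValueError("design must be 'paired' or 'unpaired'")


def compare_variances(x, y, significance: float = 0.01) -> TestResult:
    """Brown-Forsythe (median-centred Levene) test of equal variability."""
    stat, p = stats.levene(np.asarray(x, float), np.asarray(y, float),
                           center="median")
    return TestResult("brown-forsythe", float(stat), float(p), significance,
                      "two-sided")


def rank_association(
    x,
    y,
    alternative: str = "two-sided",
    significance: float = 0.01,
) -> dict:
    """Spearman rank correlation with an OLS line for display."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    rho = stats.spearmanr(x, y, alternative=alternative)
    fit = stats.linregress(x, y)
    return {
        "spearman_r": float(rho.statistic),
        "pvalue": float(rho.pvalue),
        "significant": bool(rho.pvalue < significance),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
    }
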