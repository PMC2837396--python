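# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `arborcost`. All lengths are micrometres, angles degrees,
velocities m s⁻¹ unless stated.

## Graph representation of an arbor

A reconstruction is a rooted node table (SWC). Conversion to the analysis
graph keeps only morphological landmarks — the axon origin, bifurcations,
boutons and branch tips — and joins consecutive landmarks with a single
straight edge weighted by the Euclidean distance between them. This
*direct-distance* convention removes the tortuosity that the neuropil
imposes on real axons and makes biological wire commensurable with the
straight-segment comparison trees; consequently the graph's total length
is a lower bound on the traced curvilinear length (equal only for
perfectly straight reconstructions). The root is recentred to (0, 0, 0);
the tree is undirected and the root defines path orientation only.

Two preprocessing steps mirror how the biology is scored:

* **White-matter exclusion** (spiny cells): the myelinated segment
  descending into the white matter forms no local synapses; nodes flagged
  as white matter (and their descendants) are removed and their
  curvilinear length is recorded separately.
* **Tip trimming**: the short tapering segment beyond the most distal
  bouton of each terminal branch is synapse-free excess; leaf vertices
  that are not boutons are stripped iteratively (idempotent, bouton
  conserving, removed length recorded exactly). All economy and per-order
  statistics are intended to run on tip-trimmed graphs.

Boutons are treated as on-path vertices of the skeleton (the alternative
— off-path marker coordinates — is not representable in SWC without a
custom convention). Three-way junctions are allowed; out-degree > 3 is
rejected as a digitization error. Coincident boutons stay distinct
vertices; zero-weight edges are legal.

### SWC dialects

`swc_typed` encodes landmark kinds in the SWC type column (1 soma/origin,
2 routing, 5 bifurcation, 7 bouton, 8 white matter; tips are type-2
leaves). `swc_plus_annotations` accepts vanilla SWC plus a JSON sidecar
listing bouton/white-matter node ids. Writing uses `repr` floats, so a
written file re-reads bit-identically.

## Comparison trees

* **MST** — Prim on the implicit complete graph, O(N²) time / O(N)
  memory, ties broken toward the lowest vertex index. Above 1200 vertices
  the candidate edges are restricted to the 3D Delaunay graph (the
  Euclidean MST is a subgraph of the Delaunay triangulation in any
  dimension) and extracted with scipy's sparse MST; degenerate inputs
  (e.g. coplanar points) fall back to Prim. Tests cross-check Prim
  against exhaustive Prüfer-sequence enumeration and against scipy on
  the dense matrix.
* **MST with nodes** — the same algorithm over root ∪ boutons ∪
  bifurcation set X; all extra vertices are spanned.
* **Star** — one direct edge per bouton; by construction γ = 1 and its
  wire equals the summed root distances.
* **Steiner heuristic** — iterated local Steinerization of the MST.
  Any vertex whose sharpest incident edge pair meets below 120° is a
  candidate: the Fermat–Torricelli point of the vertex and that pair is
  inserted (only if it shortens the tree by more than `tol`·scale,
  default 1e-9 relative) and the two edges re-route through it. The
  Fermat point is computed in closed form from its trilinear coordinates
  csc(angle + 60°); when an interior angle reaches 120° the minimizer
  degenerates onto that vertex and no insertion happens. After each
  insertion pass, Steiner positions are relaxed (coordinate descent,
  each point to the Fermat point of its three neighbours) to
  stationarity, alternating with splicing of degenerate points (degree
  < 3, or collapsed onto a neighbour within 1e-9·scale) until the
  configuration is clean — this guarantees every surviving Steiner point
  has degree exactly 3 with 120° incident angles, and total length never
  exceeds the MST's. Marginal configurations (pairs asymptotically
  approaching 120°) can churn insert/collapse cycles with geometrically
  vanishing gains; the pass cap (default 150) then triggers a warning
  and returns the best tree so far, which still satisfies the angle
  property because cleanup always ends in a relaxed, spliced state. The
  result is an upper bound on the (NP-hard) Euclidean Steiner minimal
  tree; the Steiner ratio guarantees it lies within (0.5, 1] of the MST.
* **LAST** — depth-first traversal of the exact MST carrying the
  accumulated tree-path length from the root; when a vertex's
  accumulated length strictly exceeds α times its Euclidean root
  distance, the direct root edge is added (in a complete Euclidean graph
  the single-source shortest path is the direct edge) and the
  accumulation resets. The shortest-path tree (Dijkstra) of MST ∪
  shortcuts is returned, so every ratio lies in [1, α] — strictly below
  α except for measure-zero boundary geometries. α = 1 reproduces the
  star exactly (every non-collinear vertex is relaxed); large α leaves
  the MST untouched. Children are visited nearest-first; the guarantee
  holds for any visit order.
* **Wilson random trees** — loop-erased random walks on the unweighted
  complete graph, giving exactly uniform random spanning trees
  (verified on K₄ by chi-square against the 16 labelled trees);
  deterministic per seed.

## Economy, latency, dispersion

ε variants divide L_MST by the wire of the tree named in the subscript;
γ variants divide the star's mean path by the named tree's mean path
(total-path versions are provided and behave similarly). ρ at a
root-coincident bouton is defined as 1. Latency = path length / uniform
velocity; no biophysical propagation is modelled, so latencies are
proportional to path length by construction and σ_t is reported both as
a velocity-free length (µm) and in ms at the configured velocity.
The distance–path regression is unweighted OLS of path length on
Euclidean root distance (per arbor; pool inputs across arbors for a
population fit); σ_t uses the residual sd with ddof = 2. Distances with
relative spread below 1e-9 raise rather than fit.

Because ε and γ are ratios of lengths built from the same coordinates,
they are invariant under rigid motion and uniform scaling; this is
enforced by tests at 1e-9 relative tolerance.

A subtlety: whole-arbor and subtree ε may slightly exceed 1, because the
biological tree passes through bifurcation points that the boutons-only
MST cannot use — a well-placed (near-Steiner) bifurcation shortens the
arbor below the MST. The inverse Steiner ratio 2/√3 bounds the excess.

## Strahler ordering and per-order morphometrics

A *branch* is the internodal section between consecutive branch points
(or a branch point and a tip). Terminal branches get order 1; a parent
takes max(child orders) + 1 when at least two children attain the
maximum, else the maximum — the tie rule generalizes unchanged to
three-way junctions. Per order the package reports length share, bouton
share, bouton density on bouton-laden sections only (reciprocal:
interbouton interval), and the share of the order's length in entirely
bouton-free sections (interbouton gaps on laden sections do not count).
Subtree economy roots the MST of each branch's subtree at the branch's
proximal node and divides by subtree wire, excluding the root branch;
boutonless subtrees are skipped and logged.

Branch (aperture) angles are measured between daughter direction vectors
taken at 5 µm arc length along each daughter (configurable within the
1–10 µm "local" window; daughters shorter than the offset use their
endpoint and are flagged). Angles operate on the reconstruction, not the
collapsed graph, because the offset walk needs the routing points.
Junction volume cost assumes circular cross-sections; a junction is
*ambiguous* unless every trunk/daughter diameter is constant within the
local window, and *equal* when the daughter areas agree within 5%
relative (the trunk-vs-summed-daughters convention is switchable; results
should state which was used). Steiner/bifurcation co-location uses greedy
one-to-one matching by increasing distance with a 2.5 µm radius.

## Trade-off analysis

The default α grid is 1.0–3.0 in steps of 0.1 plus {4, 6, 10, 100};
equilibrium (ε = γ) is located by linear interpolation in α between the
adjacent grid points and lies strictly between the star and MST corners
when the curves cross. The random baseline defaults to 250 Wilson trees
per vertex set. Population comparisons use Wilcoxon signed-rank (paired),
Mann-Whitney U (unpaired), Brown–Forsythe (median-centred Levene) for
variability and Spearman rank correlation, all at a 1% default
significance level.

## Synthetic arbors

The generator is a phenomenological stand-in for undeposited cortical
reconstructions: it reproduces measured summary statistics, not a
developmental mechanism. Growth has three phases:

1. **Skeleton** — a descending trunk (no boutons; for spiny cells it
   continues into a 500 µm white-matter tail) emits ~5 radial primary
   collaterals (mean length 850 µm spiny / 620 µm basket, reflecting the
   ~1 mm radial reach of real primaries); each collateral adds
   interstitial side branches by a per-µm Poisson rate that decays with
   depth, with daughter aperture angles drawn from a Gaussian truncated
   to (0°, 180°) — means/sds (80.3°, 35.7°) spiny and (84.8°, 34.5°)
   basket — and lengths decaying geometrically with depth until a 35–45
   µm floor or the depth cap (9 spiny / 10 basket).
2. **Strahler ordering** of the grown skeleton.
3. **Boutons per order** — gamma-distributed interbouton gaps (shape 4)
   with per-order means anchored at the first-order interbouton
   intervals 14.1 µm (spiny) and 5.7 µm (basket) and growing with order;
   whole sections are left bouton-free with a per-order probability
   (higher for basket, reaching 1 by order 5, matching the prevalence of
   myelinated internodes); terminal branches carry their most distal
   bouton a few µm (3.5 ± 1.5) short of the tip.

All randomness flows from one seed through numpy's `SeedSequence`
spawning, so populations are reproducible arbor-by-arbor. Default
populations land at ~40–50 mm total wire and ~2,500 (spiny) / ~5,000
(basket) boutons per arbor, median Strahler numbers ~5 (spiny) and 5–7
(basket), ≥ 95% of boutons on orders 1–2, and tip-trim fractions of
1–2% of total wire. Emergent (uncalibrated) pipeline outputs fall close
to published values for real arbors — ε ≈ 0.87 (spiny) with basket lower,
γ ≈ 0.56–0.61, star ε ≈ 0.02, ~82% of path ratios < 2, trade-off
equilibrium near α ≈ 2 at economy ≈ 0.74, random-tree economies ≈ 0.02 —
which is the package's main internal consistency check.

What the generator does **not** emulate: axonal tortuosity (branches are
straight, so direct-vs-curvilinear corrections are exercised only by
dedicated fixtures), laminar anisotropy and patchy terminal clustering,
diameter tapering (radii are constant per class), correlated bouton
clustering beyond gamma renewal, and any activity- or growth-factor-
dependent remodelling. Tests passing on synthetic populations therefore
show that the *pipeline* reproduces the directional phenomena given
arbors with these summary statistics — not that the statistics fully
characterise real axons.

## Problem sizes used by the test suite

Calibration and directional tests use 100 fixed-seed arbors per class
for the calibration bands and economy orderings, 40 per class for the
subtree-economy gradient, and 20 per class × 2 trees for the random
baseline; the LAST guarantee is checked on twenty 500-point clouds and
the MST oracle on fifty 6–7-point sets (exhaustive enumeration over all
labelled trees). These sizes keep the full suite to a few minutes while
leaving all statistical checks far below the 1% significance thresholds
they are tested at.
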