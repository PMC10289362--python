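# Methods

## Trees, splits, and the root convention

Input trees are rooted, with non-negative branch lengths in expected
substitutions per site. All distances and geodesics operate on the
unrooted split decomposition: each edge contributes the bipartition of the
leaf set below/above it, and the two edges incident to a degree-2 root
induce the same bipartition, so their lengths are summed into one split
weight. Splits are bitmasks over the sorted taxon list, canonically
oriented to the side not containing the first taxon; pendant splits
(single leaf versus the rest) are trivial for topology comparisons but
carry length for the weighted distances.

Trees rebuilt from a split set (pathtrees, and the root-invariance checks)
are rooted at the attachment point of the first taxon. This is a
convention, not a claim about the original rooting: intermediate
topologies on a geodesic need not contain either endpoint's root split, so
"the" root cannot in general be carried along; every split-based quantity
(RF, wRF, BHV, topology keys, likelihood under a reversible model) is
unaffected.

Newick serialization writes branch lengths with `repr` (shortest exact
round-trip), so parse∘write preserves split weights bit-for-bit.
Zero-length edges are legal and preserved; for topology identity and for
geodesic supports, edges with length ≤ `tol = 1e-9` (configurable) are
treated as absent. Relaxed PHYLIP (whitespace-delimited names, sequential
or interleaved, autodetected) is accepted for alignments; gaps, `N`, and
ambiguity codes are fully missing data.

## BHV geodesics (successive refinement)

The geodesic support starts as the single cone-path leg
(A₁, B₁) = (splits only in T₁, splits only in T₂) after removing splits at
or below the contraction tolerance (they would otherwise create 0/0 ratio
comparisons; their ≤1e-9 length contribution is discarded). A leg (A, B)
is refined whenever the minimum-weight vertex cover of its bipartite
incompatibility graph — nodes weighted |e|²/‖A‖² and |e|²/‖B‖², an edge
wherever two splits have all four bipartition intersection cells nonempty —
has weight < 1: with cover C_A ∪ C_B, the leg becomes
(C_A, B∖C_B), (A∖C_A, C_B), which preserves orthant validity because the
cover removes every incompatible pair between A∖C_A and B∖C_B. Refinement
recurses until every leg's minimum cover weighs ≥ 1. Legs are finally
sorted by ‖Aᵢ‖/‖Bᵢ‖ (ties broken lexicographically on canonical split
encodings; empty-sided legs sort to the ends with ratio 0 or ∞; such legs
arise when the two exclusive split sets are mutually compatible and the
geodesic cuts straight across the shared orthant).

The cover is solved exactly as a max-flow/min-cut on the standard bipartite
construction. Two numerical details matter. The cut partition is derived
by breadth-first search over the residual network using a residual
threshold of 1e-10 rather than exact saturation, because float flows leave
~1e-15 residuals on saturated edges; and the cover weight used for the
split/stop decision is recomputed exactly from the returned cover sets,
with the refinement threshold at 1 − 1e-12. A whole-side cover (weight
exactly 1 up to noise) is treated as unsplittable.

An exhaustive reference (`bhv_distance_bruteforce`) enumerates every
ordered partition pair satisfying both support invariants — orthant
compatibility and nondecreasing ‖Aᵢ‖/‖Bᵢ‖ — and minimizes the length
formula. The ratio-ordering condition is essential: without it, supports
like ((A,∅),(∅,B)) would score √(‖A‖²+‖B‖²), which is not the length of
any traversable path. The refinement algorithm agrees with this reference
to machine precision on batteries of 5/6-leaf tree pairs (including pairs
with shared splits).

## Weighted Robinson-Foulds, and how it relates to BHV

`wrf_distance` is the L1 distance over the union of all splits, pendants
included, with splits absent from one tree contributing their full length;
`rf_distance` is the size of the symmetric difference of nontrivial split
sets. wRF is the L1 length of the cone path, hence an upper bound on the
BHV (L2 geodesic) distance — that inequality is asserted throughout the
test suite and holds everywhere.

A fixed multiplicative cap of wRF below 2×BHV, sometimes quoted for these
metrics, does **not** hold under the definitions above: for two trees of
the same topology whose k splits each differ by the same amount, wRF/BHV
is exactly √k, which is unbounded. The acceptance battery (200 random
8-leaf pairs, exponential(0.1) lengths) measures a maximum ratio of ≈3.2
and a mean of ≈2.6; `scripts/acceptance.py` recomputes this number. The
corresponding bound assertion in the acceptance tests is left failing
rather than weakened, since the measured value is the honest outcome under
the stated conditions.

## Pathtrees

`tree_at(g, λ)` applies the support formulas directly. λ = 0 and λ = 1
return copies of the endpoints (exact, by construction rather than by
evaluation, so degenerate empty-sided legs cannot inject zero-length
splits into an endpoint). A λ exactly at a leg boundary
‖Aᵢ‖/(‖Aᵢ‖+‖Bᵢ‖) is assigned to orthant i: the vanished Aᵢ splits are
dropped and the Bᵢ splits are retained at length 0, so boundary pathtrees
are multifurcating. Formula values in [−1e-12, 0) are clamped to 0; more
negative values would indicate a support bug and raise. "Equally spaced"
sampling uses λⱼ = j/(m+1), j = 1..m — uniform in λ, which under this
parameterization is uniform in distance traveled; endpoints are excluded,
so s starting trees and m samples per pair yield m·s(s−1)/2 pathtrees.

## JC69 likelihood and branch-length optimization

The substitution model is Jukes-Cantor: equal base frequencies, one rate,
P(same) = 1/4 + 3/4·e^(−4t/3). Likelihoods are computed by Felsenstein
pruning over compressed site patterns with per-node rescaling (log-scale
accumulators), natural log throughout. The model is reversible, so root
placement does not affect the likelihood; the suite checks this by
rebuilding trees from their split sets. Keeping the model this simple is a
deliberate scope choice: one fitness function, no rate heterogeneity, no
extra free parameters; the interface would admit other reversible models
but none are implemented.

Optimization is coordinate ascent: bounded Brent on each edge over
[1e-8, 10] substitutions/site (`xatol` 1e-10), sweeping all edges until
the per-sweep gain drops below 1e-6 log units or 50 sweeps. An edge update
is only accepted if it improves the likelihood, so the per-sweep trace is
non-decreasing and the result is never worse than the start.
Multifurcating topologies (boundary pathtrees) are optimized as-is.

On data simulated from a fixed 6-leaf tree with split lengths spanning
[0.05, 1.0] (100k sites), optimized lengths land within 5% of the
generating values from both the true start and an all-0.5 start. Recovery
is assessed in split space: the two root-incident edges of a rooted tree
are identifiable only through their sum under a reversible model, so
per-rooted-edge comparisons would be ill-posed.

## Landscapes

MDS is classical (Torgerson): double-center −½JD²J, top-2 eigenpairs,
coordinates scaled by √eigenvalue. BHV and wRF matrices are generally
non-Euclidean; negative eigenvalues are truncated to zero, and the Shepard
correlations (Pearson, Spearman, Kendall over the strict upper triangle)
quantify the distortion. Each axis is flipped so its largest-magnitude
coordinate is positive, making the embedding deterministic; a seeded
SMACOF variant (scikit-learn) is available behind a flag for comparison
with stress-minimizing MDS.

Starting trees are the convex-hull vertices (counter-clockwise, qhull) of
the embedded sample; collinear configurations raise a degenerate-hull
error. Surfaces are interpolated on a grid over the coordinate bounding
box — default 300×300 for standalone use, 150×150 in the pipeline to keep
iteration cost low — by either Clough-Tocher piecewise cubics on a
Delaunay triangulation or a thin-plate-spline RBF with zero smoothing
(which reproduces affine fields exactly); cells outside the hull polygon
are masked. Plots show the contour or 3-D surface with trees colored by
log-likelihood, starting trees as triangles, selected/optimized trees on a
purple spectrum ranked by likelihood (lighter = lower), and the best tree
as a red square.

## Pipeline

One iteration: embed the (burn-in/stride-thinned) sample, take hull trees
as starting trees, generate pathtrees for every pair, score everything,
select the n best by *unoptimized* log-likelihood (scoring precedes
optimization in the iteration; optimized scores are used for reporting and
coloring only), cluster by topology key, optimize one representative per
cluster — the highest-likelihood member, a deterministic and warm start —
and render. Later iterations zoom in by re-embedding only the previous
iteration's optimized trees and taking their hull; they default to the
cheaper wRF metric (overridable). If fewer than three distinct topologies
remain, there is no region left to zoom into and the run stops early,
recording the reason in `runlog.json`. The best tree over all iterations
is reported separately. Since the current sample per iteration is hull
trees + pathtrees (not the full input sample), the guaranteed monotonicity
is best-optimized ≥ best current-sample tree; an interior input tree can
legitimately out-score every hull-derived topology.

Runs are deterministic for a fixed configuration and seed: tree files and
TSVs are byte-identical across repeats (the run log contains wall-clock
timings and is exempt). All randomness flows through
`numpy.random.default_rng` seeded from the configuration.

## The synthetic-data generator

Fixtures emulate what a user would bring from a Bayesian MCMC run: a cloud
of topologically similar trees plus the alignment they were sampled
against. Topologies come from uniform sequential attachment (each new leaf
attaches to a uniformly chosen edge or above the root), which is uniform
over rooted binary leaf-labeled shapes; branch lengths are i.i.d.
exponential with mean 0.1 substitutions/site by default (a moderate
within-gene divergence), or uniform on a given range. Clouds apply a given
number of NNI moves per tree — implemented so that a move across the
merged root edge swaps subtrees *between* the two root children, since
swapping within one side would only rotate the rooted shape — plus
multiplicative log-normal length jitter (σ = 0.1 default, 0 to disable).
Alignments evolve site-independently under JC69 from uniform root states;
simulated pairwise mismatch fractions match the closed form
¾(1 − e^(−4t/3)) within Monte-Carlo error.

What the generator does not emulate: autocorrelation of MCMC samples,
rate variation across sites, indels/alignment error, non-uniform base
composition, and model misspecification. Passing tests therefore
demonstrate geometric and algorithmic correctness and internal
consistency, not robustness of the landscape picture on real data.

## Problem sizes and tolerances used in the checks

Geodesic-versus-enumeration: 105 pairs among 15 five-leaf trees plus 20
independent six-leaf pairs, tolerance 1e-9. Metric batteries: 200
eight-leaf pairs. Telescoping additivity along geodesics: 1e-8. Pruning
versus exhaustive marginalization: 50 instances of 4–5 leaves × 20 sites,
1e-10. Pipeline fixtures: 8 taxa, 300 sites, 30-tree clouds, two
iterations. These sizes keep the full suite under a minute apart from the
option-heavy recovery and pipeline tests, while covering every branch of
the refinement (shared splits, multi-leg supports, empty-sided legs,
boundary multifurcations).

## Known limitations

- Geodesic computation is exact but quartic-ish in practice via repeated
  max-flow; distance matrices for thousands of trees should use wRF (as
  the pipeline's later iterations do by default).
- The 2-D embedding can place distant trees nearby (non-Euclidean
  distortion); always read the Shepard correlations next to a landscape.
- JC69 only; relative likelihoods of topologies under richer models may
  order differently.
- The convex hull in MDS space approximates, but is not, a hull in
  treespace; trees outside the embedded hull are invisible to the zoom.
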