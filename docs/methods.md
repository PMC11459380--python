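# Methods

## The question and the model

A differentiation trajectory that unfolds a single transcriptional
programme travels through expression space in a roughly constant
direction; a trajectory that initiates a *new* programme changes its
direction of travel.  `trajdir` makes this notion quantitative.  A
direction in N-dimensional attribute space (principal components or
log-normalized genes) is a point on the unit sphere S^(N−1).  Given an
ordered path p_0, …, p_m, every later point is projected to the unit
vector (p_j − p_0)/‖p_j − p_0‖.  If the path has a well-defined
directionality these projections cluster tightly; the tightness is
summarized by an optimal **center** ĉ and its **radius** — the minimized
mean (or maximum) geodesic distance arccos⟨ĉ, x_j⟩ from the center to the
projections.  A small radius means strong directionality; ĉ *is* the
direction and can be decomposed into gene-level contributions.

Assumptions worth stating explicitly:

* pseudotime is an input (from Slingshot or any other tool), never
  inferred here, and is treated as a valid ordering of the cells;
* directionality is assessed relative to the *first point* of the
  (sub)path — sub-trajectories are selected either by index bounds on a
  path or by a pseudotime threshold on the ensemble;
* the analysis is invariant under translation, positive rescaling and
  rotation of the attribute space, so the absolute scale of the input
  coordinates never matters.

## Finding the center

Two summary statistics are supported.

**mean** (default) — the spherical geometric median, minimizing the mean
geodesic distance.  Solved by a damped Riemannian Weiszfeld iteration:
the update is the 1/distance-weighted mean of the tangent-space
logarithms of the projections, retracted to the sphere along the
exponential map, halving the step while the objective fails to decrease,
and stopping when the mean distance improves by < 1e−12 (max 300
iterations).

**max** — the center of the minimal enclosing spherical cap, minimizing
the maximum geodesic distance.  A geodesic Badoiu–Clarkson descent
(step toward the current farthest point with a 1/(k+1) schedule) is
polished by an SLSQP solve of the equivalent convex program
(maximize t subject to Xc ≥ t, ‖c‖ ≤ 1), which is exact whenever the
optimal cap is smaller than a hemisphere, with a softmax fallback
otherwise.

Both objectives become non-convex when the projections spread beyond a
hemisphere, so each solver refines several starts — the normalized
Euclidean mean plus every data point — and keeps the best; exact ties
are resolved in favor of the normalized-mean start, which makes
degenerate cases (e.g. two projections, whose median set is a whole
geodesic arc) deterministic.  On random point sets the solvers match a
2° brute-force grid search (the test suite's independent oracle) to
better than 1e−3 radians, and reach simple closed-form optima to ~1e−9.
Geodesic distances are evaluated as 2·arcsin(chord/2) rather than
arccos of the inner product, which would lose about eight digits for
nearly coincident directions.

If even the optimal center lies more than π/2 from the farthest
projection the result carries a `low_confidence` flag: the points spread
over more than a hemisphere and a single "direction" is not meaningful.
(The mean radius can never exceed π/2, since the mean distances from c
and −c sum to π.)

## Null models and the P-value

An observed radius is calibrated against randomized versions of the same
path:

* **byPermutation** (package default): each attribute column is permuted
  independently across the path's rows; per-coordinate value multisets
  are exactly preserved.
* **bySteps**: the path is rebuilt from its own ordered step lengths
  with i.i.d. uniform step directions (normalized Gaussian vectors);
  step lengths are preserved exactly.

Randomized paths are analysed over the same index range with the same
statistic, and the P-value is the add-one rank
(1 + #{null ≤ observed}) / (n_null + 1) — never exactly zero, ties
counted conservatively.  Testing paths generated by the null mechanism
itself yields uniformly distributed P-values (Kolmogorov–Smirnov check
in the test suite).

The two schemes probe different nulls and behave differently on
low-dimensional, nearly linear data.  A column permutation preserves
each coordinate's values, so when one coordinate dominates the geometry
about 1/m of permutations (base point landing at an extreme) reproduce a
directional-looking path; the permutation null therefore has a heavy
lower tail on synthetic tube-like ensembles, while on real embeddings
with signal spread across components it is a stringent, widely-used
choice.  The step-randomization null asks a sharper question — "is this
path more directional than a random walk with identical step lengths?" —
and is the scheme used in the synthetic recovery studies below; the
scheme is always recorded in the output as part of the provenance.

## From cells to trajectories

A pseudotemporally ordered ensemble is sampled into discrete paths: the
pseudotime range is split into `n_windows` (default 10) equal-width
windows and one cell is drawn uniformly from each non-empty window
(minimum 3 usable windows).  Each sampled path is tested against its own
nulls; `analyse_trajectory` (default 1000 paths, 1000 nulls each)
retains the full radius and P-value distributions, reports the median
per-path P-value as the aggregate, and averages the per-path centers
(renormalized) into the trajectory's direction.  Two trajectories are
compared by a two-sided Mann–Whitney rank-sum test on their sampled
radius distributions.

`branch_point_scan` re-runs the analysis from successively later
pseudotime starts (default fractions 0 to 0.5 in steps of 0.05),
recomputing the windows on the restricted range so path lengths stay
comparable.  The operational signatures:

* **default arm** — directional everywhere: aggregate P at the floor
  1/(n_null+1) at every start;
* **branch arm** — median radius decreases and −log10 aggregate P
  increases as the start approaches the departure point (Spearman trend
  across the scan);
* **symmetric bifurcation** — both arms' radius distributions are
  statistically indistinguishable and neither arm satisfies the
  default-arm criterion: the branching signature is absent.

## Gene-level scores

When the analysis runs in PC space, a gene × component loading matrix
maps the fitted direction back to genes: score(g) = ⟨loading row g, ĉ⟩,
the expression change of g per unit of travel along the trajectory
direction.  Scores are plain inner products by default (unit-norm
directions against unit-norm loadings give the small raw magnitudes
typical of such analyses); an optional `component_weights` argument
rescales by per-component variances.  Identity loadings reproduce the
center itself, which is the gene-space case.  Ranked lists use a
deterministic lexicographic tie-break.

## The synthetic generators

`make_branching` / `make_bifurcation` build piecewise-linear backbones
with isotropic Gaussian noise; pseudotime is each cell's ground-truth
normalized arc-length position along its own backbone, never re-inferred.
Directions are oblique to the coordinate axes (u = 1/√N·(1,…,1)), as a
real embedding's trajectory would be — an axis-aligned backbone is a
degenerate special case in which the permutation null collapses
(off-axis columns become constant).

Key default choices, all recorded in the output spec:

* `arm_length = 7.0`, `noise_sd = 0.1` — a 70:1 span-to-noise ratio,
  i.e. tight tubes around long arms.  Only this ratio matters (the
  analysis is scale invariant).  At much lower ratios the within-stage
  scatter dominates the windows near the path start and no trajectory —
  not even a perfectly straight one — can distinguish itself from nulls
  at the rank-test floor.
* the post-departure leg spans a full `arm_length`
  (the branching fate unfolds a complete new programme), placing the
  departure at own-pseudotime dp/(dp+1) = 1/3 for the default
  dp_fraction = 0.5.  With equal-length legs the branch arm's
  radius-versus-start curve is hump-shaped: just before the corner the
  post-corner points subtend steeper and steeper angles from the base,
  so the radius rises before it collapses.  The long post-leg removes
  the hump and yields the monotone decline that defines the branching
  signature.
* `branch_region_width = 0.0` — a single decision point.  A positive
  width draws per-cell departure points from a region (the more
  biologically suggestive variant); note that because every departing
  cell then travels along the *same* direction v from a *different*
  trunk point, a wide region spreads the branch arm into a fan whose
  sampled paths never become tightly directional, weakening the
  scan signature.  The region variant is retained for studying exactly
  that effect.
* `angle_between_arms = π/2`, documented as a visually clean arbitrary
  default.

What the generators do **not** emulate: count noise (library size,
dropout), anisotropic or expression-dependent dispersion, curvature of
real manifolds, multifurcations, or confounding programmes such as the
cell cycle.  Passing the synthetic recovery tests therefore shows the
geometry pipeline is correct and calibrated, not that any particular
real dataset will show these signatures.

## Numerical and reporting choices

* Angles are radians everywhere internally; the CLI prints degrees
  alongside.
* Points coincident with the projection base (< 1e−12) are dropped and
  counted, not errors: sampled single-cell paths can repeat a cell.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical inputs and seeds give
  bit-identical results, and `results.json` contains no timestamps (and
  no output-directory paths), so repeated runs are byte-identical.
* Skipped scan starts (too few cells) are reported with reasons rather
  than failing the scan.
* The synthetic recovery studies in the test suite and acceptance script
  use 100 sampled paths × 99 nulls per start — sizes at which the
  signatures are decisive while a full two-model, four-arm study runs in
  minutes on a single core.

## Known limitations

* The direction is anchored at the sub-path's first point; a trajectory
  that curves smoothly everywhere has no distinguished direction and
  will simply report a large radius.
* The permutation null is conservative for tube-like, low-dimensional
  geometries (see above); for such data the step-length null is the
  informative one.
* The minimal-cap solver's convex polish is exact only for caps smaller
  than a hemisphere; beyond that the result is a best-effort local
  optimum flagged `low_confidence`.
* Aggregating per-path P-values by their median is robust but has no
  exact finite-sample guarantee; the full distributions are retained and
  reported for inspection.
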