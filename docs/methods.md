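# Methods

This note documents the models and procedures implemented in `basinselect`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data experiments do and do not show.

## Problem setting

Template-free protein structure prediction produces large ensembles of
candidate 3D structures (*decoys*), each scored by a semi-empirical energy
function. Decoy selection asks which of these are near-native. Energies are
unreliable pointwise — in-silico energy surfaces are rugged, with many false
minima — but the *landscape* they induce over the ensemble still carries
signal: near-native decoys tend to congregate in coherent, funnel-like
basins, while non-native regions fragment into many shallow or deceptive
wells. The package operationalizes that idea as a pipeline:

1. embed the ensemble in an ε nearest-neighbor graph under pairwise
   Cα least-RMSD,
2. decompose the graph plus per-decoy energies into basins of attraction,
3. select basins by unsupervised criteria (size) or by supervised,
   difficulty-conditioned purity prediction followed by purification,
4. select one decoy from the chosen basin by weighted ranking.

## Geometry

Distances between decoys (and to the native) are least RMSDs over Cα atoms:
RMSD after optimal rigid superposition, computed by the Kabsch algorithm
with a determinant correction so reflections are never applied. Single-pair
calls build the explicit rotation and measure residuals (exact at machine
precision for self-comparison). Full pairwise matrices use an equivalent
closed form — singular values of the 3×3 cross-covariance obtained from a
vectorized trigonometric eigen-solution of its Gram matrix, with the
determinant sign correcting the smallest one — which avoids per-pair LAPACK
dispatch and agrees with the explicit route to ~1e-7 Å. Pairwise matrices
can be cached on disk keyed by a hash of ids and coordinates; repeated
analyses of the same ensemble then skip the quadratic recomputation.

## The nn-graph

Vertices are decoys; an edge joins u, v when d(u, v) ≤ ε. Defaults: ε₀ = 1 Å,
growing additively by 0.5 Å up to 10 times while the graph is disconnected.
The growth step and cap are conventions chosen to match the 1 Å scale of
ε₀. Density is controlled by keeping at most `max_nn = 100` nearest
neighbors per vertex (ascending distance, ties by id); an edge survives only
if both endpoints keep it, so the graph stays undirected. A graph still
disconnected after the growth budget is used as-is: decomposition and
community detection operate per component. The cap is applied after the
final ε is fixed.

## Basin decomposition

A vertex is a local minimum when its energy is no higher than all its
neighbors'. Taken literally this makes every vertex of a flat plateau a
minimum, so minima, descent targets and plateaus are all resolved under the
lexicographic key (energy, id): exactly one deterministic minimum per
plateau, and every descent step strictly decreases the key, which makes
cycles impossible by construction (a cycle aborts with an internal error).
Each non-minimum vertex follows the out-edge maximizing the discrete
negative gradient [e(u) − e(v)] / d(u, v), ties to the smaller id, until a
minimum is reached; vertices reaching the same minimum form one basin.
Edge distances of zero (duplicate decoys) are clamped to a tiny positive
value in the ratio.

Persistence measures basin shallowness by sublevel-set filtration with a
union-find: vertices enter in ascending (energy, id); when a vertex first
connects two components, the component whose minimum is lexicographically
younger dies, with persistence equal to the energy gap between the merge
level and its focal energy. The surviving minimum of each graph component
takes the component's full energy range rather than an infinite sentinel, so
downstream features stay finite.

Each basin is also re-embedded in its own nn-graph with ε = pdist + 1 Å
(pdist = mean pairwise member RMSD, no growth, no cap); the number of
connected components of that graph is a feature of how geometrically
coherent the basin is. Size-1 basins count as one component.

## Unsupervised baselines

**K-means selection.** Decoys are vectorized by Kabsch-superposing every
decoy onto the first and flattening the Cα coordinates; Euclidean distance
in that space approximates pairwise RMSD times √(residue count). For a
given k, k-means runs with centroids initialized from k uniformly drawn
decoys, 10 restarts, retaining the restart with the smallest within-cluster
scatter L(C) = ½ Σ_l Σ_{i,j∈C_l, i≠j} D(x_i, x_j). The number of clusters is
the knee of the SSE-vs-k curve: the k maximizing perpendicular distance to
the chord joining (1, SSE(1)) and (k_max, SSE(k_max)); ties resolve to the
smaller k and a flat or linear curve returns 1 with a warning. The
prediction is the largest cluster (ties: lower mean energy, then id).
`k_max` defaults to 25; the desk-scale evaluation protocol uses 10.

**Community selection.** Louvain modularity optimization (resolution 1.0,
edges unweighted, seeded) on the nn-graph; the prediction is the largest
community with the same tie rules. An edgeless graph degenerates to
singleton communities and returns a single vertex with a warning.

## Supervised selection

All learners are XGBoost ensembles with fixed hyperparameters — 100 trees,
depth 3, learning rate 0.1, no subsampling, `min_child_weight = 0`, seeded —
chosen once for reproducibility; `min_child_weight = 0` is required because
the difficulty classifier trains on a handful of rows (one per decoy set)
whose logloss Hessians would otherwise forbid any split.

**Difficulty prediction.** A decoy set's landscape summary — min/max basin
size, min/max focal energy, min/max persistence, and a 5-bin histogram of
basin component counts (1, 2, 3–5, 6–10, >10) — feeds a classifier of the
set's difficulty (easy/medium/hard, or binary with medium collapsed into
hard). A leave-one-target-out protocol helper trains one model per held-out
set.

**Phase 1: purity regression.** Basins are ranked by predicted purity from
three features: Pareto rank, Pareto count, and component count. Dominance is
over (size, group energy): a dominates b when a is at least as large and at
least as low-energy, strictly better in one. Rank is the number of
dominators (0 = non-dominated front) — monotone with the front-peeling
level, which is available as an option — and count the number dominated.
Group energy defaults to the focal (minimum) energy; the member average is
selectable. Because raw dominance counts scale with how many basins an
ensemble fragments into, the pipeline feeds the regressor rank/count as
fractions of (n_basins − 1); that normalization is what lets a model
trained on one decoy set transfer to another. Predictions are clamped to
[0, 1]; the top n basins (default n = 5, ties by size then id) pass to
Phase 2.

**Phase 2: purification.** A per-decoy RMSD regressor over knowledge-based
potential feature columns (pluggable; 20 by default) predicts each member's
distance to the native. Decoys whose predicted RMSD *exceeds*
dist_thresh·(1 + τ) are removed — the only reading under which purification
"may eliminate a near-native decoy" as an occasional error mitigated by
relaxing the threshold; τ ∈ {0, 0.10, 0.20, 0.25} relaxes by default and may
be negative to tighten. Emptied basins are dropped (an error if all empty,
advising a larger τ). Survivors are re-ranked by post-purification
*predicted* purity (the fraction of kept members predicted under
dist_thresh — true labels are unavailable at selection time) and the top l
(default 1) are returned. A removed focal is replaced by the kept
minimum-energy member.

The end-to-end pipeline keys a model library by difficulty level: the
predicted level selects the purity regressor, RMSD regressor and
dist_thresh trained on sets of that difficulty.

## Weighted decoy selection

Within a selected basin, each decoy gets a weight and the highest-weight
decoy (ties: lower energy, then id) is the prediction.

- Predicted-RMSD scheme: w_i = 1/(rmsd_i + ζ), ζ = 1e-6 (any small positive
  guard works; the weight is order-reversing in the prediction).
- Density scheme: S_i = Σ_{j≠i} r_ij / m over the basin, normalized
  piecewise about the median into [−1, 1] (min → −1, median → 0, max → +1;
  a degenerate side maps to 0, so an all-equal basin is uniform), then
  w_i = exp(−k·S′_i) with k = 5.

Weighted purity wp(B) = Σ w_i g_i / Σ w_i (g_i = 1 iff near-native) equals
the probability of drawing a near-native under weight-proportional
selection; it is invariant to rescaling the weights and reduces to TP/|B|
under uniform weights. The uniform-random baseline draws 10 decoys with
replacement and averages the loss.

## Ground truth and difficulty rules

A decoy is near-native iff its least RMSD to the native is strictly under
dist_thresh. The threshold follows the difficulty of the set: easy
(min_dist < 1 Å) uses 2 Å; medium (1 ≤ min_dist < 3 Å) uses 2.5 Å, escalated
to 3 Å when fewer than 10 near-natives exist; hard starts at min_dist + 1 Å
rounded up to the next 0.5 Å and escalates by 0.5 Å until at least one
near-native exists. An easy or medium set still scarce (fewer than 10) at
its final threshold moves to the next harder category. Two conventions are
this package's own: the interval 2 ≤ min_dist < 3 belongs to medium (the
scarcity rule, not the interval boundary, is what pushes borderline sets to
hard), and the hard-case escalation is data-level (at least one near-native
in the ensemble) rather than conditioned on what any particular selection
method accumulates, which would be circular for a library; the
method-dependent variant can be emulated by passing a custom counter.

Selections are scored by purity TP(S)/|S| and individually selected decoys
by RMSD loss: RMSD(selected, native) − RMSD(best decoy, native).

## Synthetic landscapes

The molecular generator emulates the study conditions the pipeline is meant
for, at desk scale (hundreds to thousands of decoys instead of tens of
thousands):

- **Native**: a self-avoiding random Cα walk, 3.8 Å virtual bonds, no
  non-bonded pair under 3.5 Å, with directional persistence to keep the
  chain open.
- **Decoys**: Cartesian Gaussian perturbations of a base structure,
  iteratively rescaled to hit a target least RMSD. The near-native component
  (mass = `near_native_fraction`) targets RMSDs strictly inside dist_thresh,
  with one decoy planted at `min_dist` exactly (realized within 5% + 0.02 Å
  or the generator raises). The far component congregates around
  `n_false_minima` attractor structures (5–10 Å from the native, local
  spread ~1 Å) plus a scattered background (15% of non-natives, up to 12 Å).
- **Energies**: a funnel term `funnel_strength`·RMSD (3 energy units/Å)
  minus a Gaussian well at each false attractor with depth 0.9× the funnel
  value at its center — deep enough that false minima rival or beat the
  near-native region, the premise that defeats purely energy-based
  selection — plus N(0, 0.5) observation noise.
- **Pseudo-potentials**: 20 feature columns standing in for knowledge-based
  potentials; 16 are fixed linear maps of true RMSD with N(0, 0.5 Å) noise
  on the RMSD scale, 4 are pure noise so regressors must implicitly select
  features. The linear maps are drawn from a *separate* fixed seed shared
  across ensembles, because real potentials are the same functions for every
  target; without that, a regressor trained on one target could not
  transfer to another.

Difficulty presets fix (min_dist, dist_thresh, near-native fraction) at
(0.7 Å, 2 Å, 0.25) for easy, (1.5 Å, 2.5 Å, 0.08) for medium and
(3.5 Å, 4.5 Å, 0.02) for hard — near-native abundances patterned on what
template-free pipelines achieve on targets of those difficulties.

The abstract generator drops molecular geometry entirely: points around m
planted well centers on a circle in 2D, radially increasing energy per well,
planted labels exported for recovery tests, and an optional high-energy
ridge joining wells so that merge-based persistence is exercised in a single
component (with the ridge the global maximum, the persistence gap of two
wells equals their planted depth difference).

What the synthetic data does *not* emulate: real decoy geometry (fragment
assembly, secondary structure), realistic energy functions (only the rank
structure of a funnel plus deceptive wells), correlated potential features,
or ensembles of 50,000+ decoys. Passing tests therefore show that the
machinery is correct and that the supervised pipeline exploits landscape
structure when it exists — not that it will reach any particular accuracy
on real Rosetta or CASP data.

## Evaluation protocol at desk scale

The method-comparison experiments (test suite and acceptance script) train
the model library on ensembles drawn at the *same* scale as the test
ensembles — basin geometry features (notably component counts) depend on
sampling density, so train/test scale mismatch degrades transfer, mirroring
how the original study trains and tests on same-sized decoy sets. Five
training sets per difficulty level are used in the test suite: the
difficulty classifier sees one feature row per training set, and with fewer
rows its greedy tree splits latch onto features that do not generalize (the
minimum focal energy, an extreme-value statistic) instead of the
basin-count and basin-size signals that actually separate the levels. The
test suite uses 15 training + 30 test ensembles of ~2000 decoys; the
acceptance script uses 9 + 9 at 1500 decoys. `k_max = 10` for the k-means
baseline at these sizes.

## Numerical choices and degenerate inputs

- Ties everywhere resolve lexicographically (documented per operation);
  fixed seeds make every stage bit-reproducible.
- Distance-0 edges are clamped to 1e-300 in descent ratios.
- Degenerate density normalizations (median equals an extreme) map that
  branch to 0 — the continuous limit of the formula.
- A flat SSE curve returns k = 1 with a warning rather than an arbitrary
  knee.
- Collinear or rank-deficient coordinate sets still superpose (the
  determinant correction handles the zero singular value).

## Known limitations

- The steepest-descent assignment is sensitive to ε: too small fragments
  basins, too large merges them; no automatic ε selection is attempted
  beyond the connectivity-driven growth.
- Pareto features are coarse: basins of similar size and energy are
  indistinguishable to Phase 1, which then leans on Phase 2 purification to
  separate them.
- The difficulty classifier trains on one row per decoy set; with few sets
  it memorizes rather than generalizes, exactly as a 6-set training regime
  would in the original protocol.
- Persistence of the global survivor uses the component energy range, which
  grows with ensemble size; it is a ranking feature, not a calibrated
  physical quantity.
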