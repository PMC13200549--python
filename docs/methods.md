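# Methods

## The alignment model

flowalign treats a peak-picked spectrum as a discrete measure: peak *i*
sits at position $x_i \in \mathbb{R}^D$ (ppm per NMR axis; Th and seconds
for an LC–MS feature map) and carries normalized intensity $w_i \ge 0$,
$\sum_i w_i = 1$. Two spectra $\rho$ and $\nu$ are compared by optimal
transport under a truncated ground cost

$$
W_{\mathrm{tr}}(\rho,\nu) \;=\; \min_{\gamma \in \Gamma(\rho,\nu)}
  \int \hat d(x,y)\, \mathrm d\gamma(x,y),
\qquad
\hat d(x,y) =
\begin{cases}
 d(x-y) & d(x-y) \le d_{\max} \\
 \delta_{\max} & \text{otherwise,}
\end{cases}
$$

with $d$ the Euclidean (default) or $\ell_1$ norm. The truncation encodes
two physical priors: corresponding signals never drift farther than
$d_{\max}$, and signal present in only one spectrum (noise, sample-specific
compounds) should stay unmatched at a bounded price $\delta_{\max}$ per
unit mass rather than being dragged onto a distant stranger.

The problem is solved exactly as integer min-cost flow on a sparse
network: a source node feeds one node per peak of the first spectrum (arc
capacity = quantized intensity, cost 0), matching arcs join cross-spectrum
peak pairs at cost equal to their distance, second-spectrum nodes drain
into a sink, and one direct source→sink "mismatch" arc carries all
unmatched mass at cost $\delta_{\max}$. Matching arcs with cost above
$\delta_{\max}$ can never carry flow in an optimum, so candidate pairs are
generated only inside radius $\min(d_{\max}, \delta_{\max})$ with a k-d
tree (`scipy.spatial.cKDTree.sparse_distance_matrix`); the result equals
the exhaustive pair set but the network stays sparse, which is what makes
the solve near-linear in peak count in practice. Pairs with
$d_{\max} < d \le \delta_{\max}$ would cost exactly $\delta_{\max}$ —
identical to the mismatch route — so pruning them changes no cost, only
the (arbitrary) attribution of mismatch mass.

## Integer quantization

Network Simplex needs integer data for exact, cycle-free arithmetic, so:

* intensities are mapped to integers by **largest-remainder rounding** at
  `intensity_scale` (default $10^6$, minimum $10^4$) units per unit mass —
  both sides then sum to exactly `intensity_scale`, keeping the instance
  balanced without a slack arc;
* distances are rounded to the nearest integer at `cost_scale` (default
  $10^6$) units per unit distance.

The reported $W_{\mathrm{tr}}$ is the de-quantized integer optimum. Per
peak, matched + unmatched mass equals normalized intensity to within
$2/\texttt{intensity\_scale}$; $W_{\mathrm{tr}}$ can exceed
$\delta_{\max}$ by at most $1/\texttt{cost\_scale}$ (the rounding of the
mismatch cost itself). Because the quantization is order-independent and
the network mirror-symmetric, $W_{\mathrm{tr}}(a,b) = W_{\mathrm{tr}}(b,a)$
holds exactly, not approximately.

## The Network Simplex solver

`netsimplex.solve` is a from-scratch primal Network Simplex on Python
integers (no overflow, no floating error):

* **Initial basis** — an artificial root joined to every node by a big-M
  arc, $M = 1 + \sum_a c_a \min(u_a, U)$ with $U$ the total supply; always
  feasible, no phase-one. Positive artificial flow at termination means
  the instance is infeasible.
* **Entering arc** — cyclic block search (block ≈ √m), taking the most
  negative reduced-cost violation in the block; the standard practical
  rule.
* **Leaving arc / anti-cycling** — among blocking arcs, the *last* one
  met when traversing the pivot cycle in its push direction from the
  apex. This maintains strongly feasible trees and guarantees finite
  termination under degeneracy.
* **Tree updates** — parent/parent-arc/depth arrays plus per-node tree-arc
  sets; after a pivot the cut-off subtree is re-rooted at the entering
  arc's endpoint and its depths/potentials recomputed by traversal.

Optimality is certified, not assumed: `verify_optimality` checks
conservation, capacities and complementary slackness of the returned
potentials, and `reference_solve` — an independent successive-shortest-
paths solver (Dijkstra with Johnson potentials on the residual network,
sharing no code with the simplex) — must agree on the optimal cost
integer-for-integer. The test suite enforces this on hundreds of random
instances; `to_dimacs` exports instances for external cross-checks.

## Front-ends

**LC–MS.** RT shifts dwarf m/z shifts, so the m/z axis is rescaled by
`max_rt_shift / max_mz_shift` and a single radius
$d_{\max} = \delta_{\max} = \texttt{max\_rt\_shift}$ bounds both
dimensions at once (a feature can move at most `max_mz_shift` Th *and*
`max_rt_shift` s to remain matchable). The plan is reduced to consensus
pairs by **principal matching**: a feature asserts a pair only if at least
`match_fraction` (default 0.5 — a feature whose majority mass is
unmatched should not claim a consensus partner) of its mass was matched,
and its partner is the feature receiving its largest flow; flow ties break
to the nearer peak, then the lower id. Principal matching is many-to-one
by default; a `strict_one_to_one` flag keeps, per contested target, only
the strongest source.

**NMR.** Axes are compressed per-axis before transport so shifts are
commensurate: by default 0.1 on the nitrogen axis of 2D (¹H, ¹⁵N) lists
and on the two carbon axes of 4D lists (assumed at positions 1 and 2 —
a package convention, overridable per axis), identity elsewhere.
$d_{\max}$ and $\delta_{\max}$ are stated in scaled ppm (defaults 0.05 and
0.09 work well for 2D amide-region series). For a spectral series,
consecutive pairwise principal matches are concatenated into **chains**
that track one resonance across conditions; when two chains converge on
one peak, the larger incoming flow wins, then the smaller distance, then
the lower id, and the loser terminates — this keeps every peak in at most
one chain, which downstream per-chain shift trajectories require.
`shift_report` emits the per-axis coordinate differences (in original,
unscaled ppm) along each chain, e.g. temperature coefficients per
dimension. Peak lists without intensities (assignment-derived 7D lists)
are read with unit intensities.

## Evaluation

*Pairing precision/recall* scores consensus pairs against reliable labels
(peptide identities). TP: both features share a reliable label. FP: labels
differ, or exactly one feature is labeled and that label has a reliable
partner in the other run (the match stole a feature that belongs
elsewhere). Pairs touching no reliable feature are excluded. FN: truth
pairs not recovered, so TP + FN always equals the number of ground-truth
pairs. Precision is an explicit `None` (undefined), never 0, when no pair
was evaluable.

*Extended confusion matrix* for class-labeled peak lists: predicted class
of a first-spectrum peak = class of its matched partner; the K×K matrix
gains a column for unmatched first-spectrum peaks and a row for unmatched
second-spectrum peaks, so a lost peak costs exactly as much as a
misassigned one. Accuracy = trace over grand total; per-class precision
and recall use column/row sums including the unmatched cells in the
denominators only. Aggregation is macro over classes with nonzero
denominators (the counting unit is peaks, not intensity); per-class values
are also reported so any other convention is recoverable. `grid_search`
evaluates the full Cartesian $d_{\max} \times \delta_{\max}$ grid.

## Synthetic data

`synthgen` provides the ground-truthed inputs the tests and the
acceptance script run on. `generate_series` emulates a
variable-temperature ¹H-¹⁵N HSQC series in shape: D = 2, ¹H 6–10 ppm ×
¹⁵N 100–130 ppm, 6 conditions, 5 clusters × 11 peaks (cluster centers on
a jittered grid, members rejection-sampled around them), log-normal
intensities, minimum inter-peak spacing 0.2 scaled units, and an
independent per-peak uniform shift of at most 0.02 scaled units per axis
per step. The shift law is uniform and bounded (not Gaussian) so
truncation-radius contracts are exactly testable, and the constructor
*enforces* max shift < spacing/2 — under that invariant the nearest
cross-spectrum neighbour is always the true counterpart, so ground truth
(identical peak ids across the series) is recoverable by construction.
`shift_replicate` builds single replicates in any dimension;
`tile_spectrum` grows problem size by translating copies along axis 1
far enough apart that the alignment decomposes into independent blocks.
All randomness flows through one seeded `numpy.random.Generator`.

What this generator does **not** emulate: peak overlap, spurious/noise
peaks, intensity variation between replicates, correlated (systematic)
shift fields, or missing peaks. Passing the recovery tests therefore
demonstrates correctness of the transport machinery and of the
truncation/plateau behaviour, not robustness to the full noise structure
of real spectra; on real data the balance of matched vs. mismatch mass is
governed by the user's choice of $\delta_{\max}$, which should sit near
the expected maximum inter-replicate shift.

## Numerical choices and problem sizes

* Quantization defaults as above; both can be raised where the ~1e-6
  relative error matters.
* Threshold ties: noise filtering keeps intensities *strictly* above
  `fraction × max` (computed after discarding non-positive intensities;
  configurable).
* Degenerate equal-cost optima: any optimal plan is accepted; all
  downstream contracts (cost, conservation, principal-match reduction)
  are stated against cost, never against a unique plan.
* The test and acceptance workloads use ≤ 15 peaks/side for
  solver-vs-oracle checks (hundreds of instances), the 55-peak synthetic
  series for recovery, and tiled spectra up to 220 peaks/side for the
  decomposition check — sizes chosen so the whole suite runs in seconds
  while exercising every code path; the solver itself has no small-size
  assumption.

## Known limitations

* Pure-Python Network Simplex: exact and dependency-free, but not tuned
  for the multi-million-peak regime; the algorithmic scaling (sparse
  candidate graphs, near-linear arc counts) is what the package
  demonstrates.
* Pairwise alignment only; multi-run consensus beyond chaining, warping
  functions for systematic RT drift, and entropy-regularized approximate
  transport are out of scope.
* featureXML ingestion reads centroid position and intensity only; convex
  hulls and quality scores are ignored.
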