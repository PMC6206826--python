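# Methods

## Model and assumptions

The package models a collection of M ≥ 2 undirected, non-negatively weighted
networks over a shared node universe as a multi-layer network. A *conserved
module* is a node set that is (a) densely interconnected and (b) so in many
layers at once. Both properties are per-edge summaries, which motivates the
central modelling step: the M-layer stack is compressed into two symmetric
N×N feature matrices — connection strength (average weight) and participation
coefficient (uniformity of the weight's distribution over layers) — and all
clustering happens on those two matrices only. The cost of detection is
therefore essentially independent of M; the price is that any structure not
visible in these two per-edge summaries (e.g. a module dense in two disjoint
halves of the layers with different memberships) is invisible to the method.

Node alignment uses the union of all layers' node labels, sorted
lexicographically; a node absent from a layer is an all-zero row/column
there. Self-loops are dropped on input and asymmetric adjacency input is
symmetrized by `max(A, Aᵀ)` (conservative retention of evidence for an
undirected model), both with logged warnings.

## Feature transform for weighted inputs

Weighted layers are first normalized into [0, 1] by dividing by the layer
maximum (per-layer by default; a global-maximum option exists for inputs
whose absolute scale is comparable across layers). Max-division preserves
zeros and relative order. Each positive weight is then squashed with the
logistic `L(w) = 1/(1+exp(cw+d))`. The calibration anchors `L(0) = 0.0001`,
giving `d = log 9999` and `c = −2 log 9999`, so `L(0.5) = 0.5` and
`L(1) = 0.9999`: the transform is a smooth soft threshold at half the layer
maximum. Its purpose is to stop the mass of weak edges from scoring as
perfectly conserved — an edge of weight 0.01 in every layer has participation
1 by definition but carries no module signal. Structural zeros are never
transformed (an absent edge stays absent; applying L to true zeros would
densify every layer with 10⁻⁴ entries), and transformed values below L(0)
are truncated to zero — with the default calibration this is a floor rather
than an active filter, since L is increasing and no positive weight maps
below L(0). Unweighted inputs (all weights in {0, 1}) are detected
automatically and used directly.

## Factorization

The two feature matrices are two views of one latent structure, factorized
jointly:

F = Σ_v ‖X⁽ᵛ⁾ − H⁽ᵛ⁾H⁽ᵛ⁾ᵀ‖²_F + Σ_v λ_v ‖H⁽ᵛ⁾ − H_c‖²_F,  H⁽ᵛ⁾, H_c ≥ 0,

alternating a multiplicative update of each view factor with the exact
consensus solution H_c = (Σ λ_v H⁽ᵛ⁾)/(Σ λ_v). Defaults λ_s = 0.01,
λ_p = 0.05: the participation view is weighted more because cross-layer
uniformity is the defining property of a conserved (as opposed to merely
dense) module. Accuracy is insensitive to these values below ~0.1.

Numerical choices, all configurable:

* **Initialization** — factor entries uniform on (0, 1) scaled by
  √(mean(X)/k), so the initial reconstruction is on the data's magnitude;
  each restart draws from an independent seeded stream, and a fixed seed
  gives bit-identical results.
* **Consensus initialization** — H_c starts as the consensus of the initial
  view factors, so the first view update sees a consistent consensus.
* **Stopping** — relative objective change < 1e-6 or 500 sweeps; 10 restarts
  by default, keeping the restart with the smallest final objective.
* **ε = 1e-10** added to the update denominator against 0/0.
* **Monotonicity** — the plain multiplicative update for the *symmetric*
  factorization is not a guaranteed-descent step and can overshoot into a
  damped period-2 oscillation on strongly structured inputs. The solver
  therefore guarantees final ≤ initial objective per restart (checked in
  tests over seeded instances) rather than per-sweep descent, and logs once
  per restart if a sweep raises the objective by more than 1%.

The rank k is the number of candidate modules and must be chosen by the
user; `scan_k` runs the pipeline over several k with a shared seed and
tabulates scores against a reference (planted truth or gene-set collection)
so an elbow can be picked. Overshooting k is fairly benign: duplicate
columns select overlapping candidates that the merge step collapses.

## Module selection

Columns of H_c are standardized with their own mean and *sample* (N−1)
standard deviation; node i joins column j's candidate when z_ij > θ. The
selection is soft: nodes can join several candidates or none. θ defaults to
3.5 for real data and 2 for synthetic benchmarks (θ > 2 corresponds to a
one-sided normal tail below 0.05). Note the geometry this implies: a clean
binary-like column whose module holds a fraction f of all nodes gives its
members z ≈ √((1−f)/f), so θ = 2 requires module fractions below ~1/5.

Candidates with overlap ratio |C_x ∩ C_y| / min(|C_x|, |C_y|) > 0.5 are
merged. The merge order is not prescribed by the criterion itself; the
implementation is greedy highest-overlap-first, iterated to a fixpoint
(transitively: a merged module can absorb further candidates), with ties
broken by smaller union then lexicographically smallest member tuple — fully
deterministic and insensitive to candidate order. Merged modules are plain
set unions; no re-scoring against H_c is attempted (a member's recorded
z-score is its maximum over the contributing columns). Modules smaller than
five nodes are removed last.

## Validation

Cluster quality of module C in layer t is the ratio of the mean edge weight
over unordered pairs inside C to the mean weight over all other pairs
("density" is taken as mean pair weight so the same definition serves
weighted and unweighted layers). An empty outside with a non-empty inside
yields +∞ (which sorts above every finite quality in the permutation
comparison); 0/0 yields 0. The permutation null draws node sets of identical
size uniformly from the global node universe — not per-layer non-isolated
nodes — so qualities are comparable across layers. The p-value uses add-one
smoothing, p = (1 + #{q_rand ≥ q_t})/(1 + n_perm) (never exactly zero, ties
counted conservatively), with n_perm = 1000 by default. All module × layer
tests are Benjamini–Hochberg corrected jointly — the stricter and more
reproducible choice — and adjusted p < 0.01 defines presence. Modules
present in no more than half of the layers (strict inequality) are removed.

## Synthetic benchmarks

Two generators emulate the study conditions under which this kind of method
is evaluated, with exact ground truth:

* **common_blocks** (defaults M = 30, N = 500, five disjoint 80-node blocks
  planted into 25/20/15/10/5 randomly chosen layers): within a layer,
  intra-block pairs connect with probability α, all other pairs with
  probability β < α (experiments typically use α ∈ {0.1, 0.3, 0.5, 0.7},
  β = 0.05). For unweighted output, an intra-module pair planted in m of M
  layers has expected connection strength mα/M — a closed-form check used in
  tests.
* **overlapping_cores** (defaults M = 15, N = 500, conserved cores of 50 and
  40 nodes): in every layer each core is embedded in a larger layer-specific
  module by adding 30 layer-private nodes drawn disjointly from the non-core
  universe; only the cores — the intersections of the per-layer modules —
  are conserved.

With `weighted=True`, present module edges draw weights from N(0.8,
noise_sd²) and present background edges from N(0.2, noise_sd²), clipped to
[0, 1], noise_sd = 0.1 by default; means and spread are exposed as module
constants/parameters so other noise models can be emulated. What the
generators deliberately do not emulate: degree heterogeneity, overlapping
planted memberships within a layer, and weight correlation between layers.
Passing the recovery tests therefore shows the pipeline separates
planted-partition-style structure at realistic noise, not that it handles
scale-free degree sequences or correlated real-data noise.

## Evaluation

Pair-counting over all unordered node pairs: related = sharing ≥ 1 truth
module, assigned together = sharing ≥ 1 predicted module (the natural
extension of the pair rules to overlapping soft modules); unassigned nodes
are singletons. TPR, FPR and the Matthews correlation coefficient follow the
standard confusion-count formulas; a zero MCC denominator returns 0 with a
warning. Gene-set scoring tests each module × reference-set overlap with a
one-sided Fisher's exact test over a configurable universe (default: the
network's node count; the appropriate background is dataset-specific),
BH-corrects across all tests and calls significance at adjusted p < 0.05.
Precision = fraction of modules enriched in ≥ 1 set, recall = fraction of
sets covered by ≥ 1 module, f-score their harmonic mean.

## Problem sizes in the test suite

The bundled tests and examples run the full pipeline on scaled-down
benchmarks — e.g. three 30-node modules planted in 8/6/4 of M = 10 layers
over N = 200 nodes, five restarts, five benchmark seeds — which preserves
the member fractions and α/β regime of the full-size designs while keeping
the suite fast. Null-calibration checks use a 100-node complete layer with
i.i.d. uniform weights, 200 query modules and 999 permutations.

## Known limitations

* The two features cannot distinguish a module conserved across layers from
  one whose total weight happens to be spread evenly; the logistic transform
  mitigates but does not eliminate this for weighted data.
* The multiplicative update can oscillate (see above); restarts and the
  final-objective selection make this benign in practice, but per-sweep
  monotone descent is not guaranteed.
* k and θ are user choices; no automatic model selection is built in beyond
  the `scan_k` table.
* The permutation null (uniform node sets) ignores degree structure; on
  networks with heavy-tailed degrees it is anti-conservative for hub-rich
  modules.
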