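# Methods

This note documents the models and procedures implemented in `netfilters`,
the parameter choices that matter, what the synthetic benchmarks do and do
not emulate, and the numerical conventions adopted where a design choice was
genuinely open.

## Network filters

A network filter maps a vector of node measurements to denoised values using
each node's immediate neighborhood, applied synchronously: every output is a
function of the same input vector, so no denoised value feeds back into
another within one pass.

- **Mean filter** — x̂_i = (x_i + Σ_{j∈ν_i} w_ij x_j)/(1 + k_i). Weights
  default to 1; the mean filter is the only shipped filter that honors
  non-unit weights (the median has no natural weighting, and the sharp
  filter is defined through the mean filter with unit weights). Degree-0
  nodes pass through unchanged.
- **Median filter** — the median of the closed neighborhood multiset; even
  cardinalities take the midpoint of the two central values (the numpy
  convention; the choice only matters for even neighborhoods and is not
  observable in aggregate benchmark behavior).
- **Sharp filter** — x̂_i = α(x_i − mean_i) + x̄, the network analogue of
  unsharp masking. α defaults to 0.8, a cross-validated value appropriate
  for the data scales used here; it is exposed as a parameter. x̄ is the
  global mean of the input values unless a baseline override is supplied.
- **Patchwork filter** — partition, drop between-module edges, then per
  module apply the sharp filter if the module's internal value
  assortativity r_s is negative, else the mean filter. Two conventions:
  (1) the sharp branch recenters on the **module-local** mean, not the
  global mean — sharpening around the global mean misrepresents every
  module's center when module value distributions differ, which is exactly
  the regime the patchwork filter exists for (the benchmark's
  `sharp_global` arm quantifies how badly that fails); (2) a module with
  constant values (undefined r_s) falls to the smoothing branch, where
  smoothing is a no-op — the conservative default. One global α serves all
  sharpened modules. Nodes isolated inside their module subgraph, and whole
  modules without internal edges, pass through unchanged.

## Assortativity

The numeric assortativity coefficient is computed in closed form from three
sums (Σ over edges of x_i x_j, Σ k_i x_i, Σ k_i x_i²), equivalent to the
Pearson correlation of values over the 2m directed edge stubs; the tests
verify this equivalence against an O(n²) literal double sum to 1e−10.
Constant values give a zero denominator and raise a dedicated error;
callers that must proceed (the patchwork filter) treat that case as r ≥ 0.

## Diffusion-kernel baselines

- **Laplacian exponential kernel** S_β = e^{−βL} with L = D − A: symmetric
  and doubly stochastic, so it preserves the mean of the data exactly.
  Dense matrix exponential up to n = 2000, `expm_multiply` beyond.
- **Personalized-PageRank kernel** K_α = (1−α)(I−αB)^{-1} with
  B_ij = 1/k_j on edges (column-stochastic). The PPR weight vector of node
  i is the i-th *column* of K, so denoising combines values along columns:
  x̂ = Kᵀx, a row-stochastic mixing that preserves constants. Applying the
  matrix on the left of x without transposition would rescale values by
  degree-dependent row sums and is not a denoiser; the kernel matrix itself
  and its columns-sum-to-1 invariant are kept exactly as defined.
- **Smoothing-parameter selection** scans a grid (default 0.1…0.9 in steps
  of 0.1, spanning the conventional low/high extremes), denoises every
  sample column, embeds samples by 2-component PCA (column-centered,
  unscaled — the samples share units), bins the embedding into a 4×4
  equal-width grid between each component's min and max (right-closed last
  bin so the max point counts), and keeps the smallest parameter maximizing
  the Shannon entropy of cell occupancy. Natural logarithm; the base only
  rescales entropies and cannot change the argmax. Ties go to the smallest
  parameter (less smoothing for equal dispersion).

## Synthetic benchmarks

The generators define controlled conditions under which every denoised value
can be scored against known truth.

**Non-modular graphs.** Chung-Lu random graphs with n = 100 nodes and
expected degrees drawn i.i.d. from a power-law density ∝ k^(−3) on k ≥ 1;
any sequence containing a draw above 17 is redrawn whole (suppressing
star-like hubs). Expected degrees are real-valued — the classical Chung-Lu
weight formulation, under which realized degrees follow the weights in
expectation (mean expected degree ≈ 2.0 after truncation). Edges are
independent with p_ij = min(1, k_i k_j / Σk). Only the largest connected
component is kept (ties broken toward the lexicographically smallest
member), which avoids the bias of isolated low-degree nodes; components
average ~65 nodes with mean degree ~2.5.

**Node values with target assortativity.** Values are drawn i.i.d. from
N(μ, σ²) (non-modular: μ = σ² = 100) and then driven to a target r* by
hill climbing: redraw one uniformly chosen node's value i.i.d., accept iff
the distance |r − r*| does not increase, stop when it is within β = 0.009.
Acceptance-only-on-improvement keeps the marginals exactly i.i.d. draws
from the distribution. Incremental O(degree) updates make each proposal
cheap; the running sums are recomputed exactly at convergence to guard
against float drift. A proposal budget (default 2×10⁵) turns pathological
targets into an explicit error advising a fresh seed; the experiment
harness retries such replicates with derived seeds.

**Modular graphs.** A planted-partition degree-corrected SBM with κ = 5
modules of n_r = 100 nodes, the same degree distribution, and mixing matrix
ω_rs = λ·ω_planted + (1−λ)·ω_random with λ = 0.85, ω_planted diagonal
(each module's degree mass internal) and ω_random_rs = K_r K_s/2m, the
standard forms. λ = 1 gives perfectly separated modules, λ = 0 recovers
Chung-Lu. Module values come from module-specific Normals (means
{110, 80, 60, 40, 20}, σ² = 25); a chosen number of modules get a target
assortativity drawn uniformly from [0.4, 0.7], the rest from
[−0.7, −0.4], each converged on the largest component of the module's
induced subgraph (module-disconnected stragglers are filled i.i.d. with a
warning — the value chain needs a connected support).

**Corruption models.** Measurement noise permutes the values of exactly
⌊0.25·n⌋ uniformly chosen nodes (per module on modular graphs), conserving
the value multiset; the permutation is uniform, so fixed points can occur
and the effective noise rate is marginally below nominal. Network noise
deletes ⌊f·m⌋ uniformly chosen edges and places the same number of new
edges between uniformly chosen pairs, rejecting self-loops and duplicates —
edge count and node set are conserved exactly.

**Error metric.** Mean absolute error between true and denoised values on
the permuted nodes only, averaged over replicates, with 99% percentile
bootstrap confidence intervals on the replicate means. All method arms in a
replicate share the same graph, values and noise, so comparisons are
paired; per-replicate seeds derive deterministically from a master seed, so
a results table is bit-reproducible.

**Replication scale.** Default replicate counts are 200 (non-modular,
per assortativity level) and 50 (modular, per assortative-fraction
setting), chosen so a full study completes in minutes on one CPU while the
bootstrap CIs on every reported percent reduction stay within a few points;
both are flags.

## Community detection

The patchwork filter accepts any partitioner through one interface.
Shipped: Louvain-class greedy modularity maximization (chooses its own
module count); spectral partitioning as k-means (10 restarts, seeded) on
the row-normalized leading κ eigenvectors of the normalized Laplacian; and
a degree-corrected SBM fit by greedy single-node moves maximizing the
Karrer–Newman degree-corrected log-likelihood at fixed κ, initialized from
a spectral partition. The metadata-aware variant treats a supplied node
labeling as a prior through a block-given-metadata confusion matrix
re-estimated after every sweep (hard-assignment EM, pseudocount 0.01 as a
numerical log floor): with metadata that genuinely aligns with the edge
structure the confusion matrix converges toward the identity and the fit
recovers that structure almost exactly; with uninformative metadata the
likelihood term dominates. A `planted` passthrough supplies ground truth
for controlled experiments. All partitioners are deterministic given
(graph, seed).

## Expression-change prediction (KNN task)

Given a proteins × tissues panel in two paired states (healthy/cancer,
values on a continuous 0–3 scale), the task predicts each tissue's delta
vector (cancer − healthy) from its healthy profile under leave-one-out
cross validation: PCA on the training healthy profiles (observations =
tissues, column-centered by the training mean, unscaled); project the
held-out profile; K nearest training tissues by Euclidean distance on the
first 4 components (ties broken by tissue order); PCA on the training
deltas (also 4 components); average the neighbors' delta scores with
weights ∝ 1/distance (an exact match takes all the weight, shared equally
among exact matches); back-project adding the training-delta mean — the
standard PCA reconstruction — and score the MAE against the true delta.
A denoiser bound to a network over the proteins may be applied to the
healthy matrix and the delta matrix separately before training, since the
two have different distributions; diffusion denoisers select their
smoothing parameter on each matrix separately. Preprocessing averages
duplicate protein rows and imputes an entry missing in at most 2 tissues
from the same protein's observed values in a uniformly random other tissue
of the same state.

**Synthetic panel.** Because the real atlas-scale data cannot ship with the
package, a generator produces panels with the features the task exploits:
healthy profiles are module-level tissue signatures plus a node effect
smoothed along the network (so neighbors correlate and smoothing can
help); deltas share a low-rank structure across tissues plus tissue-specific
perturbations; everything is clipped to [0, 3]; i.i.d. Gaussian noise
(default sd 0.5, roughly one ordinal step of the 0–3 scale) is added before
clipping, and the clean panel is returned alongside for scoring. What it
does **not** emulate: ordinal quantization of the raw scores, missingness
patterns, antibody-specific biases, or the true topology of a protein
interaction network — so passing tests demonstrate the machinery and the
direction of the denoising benefit, not effect sizes on real data.

## Known limitations

- At the benchmark's printed density (mean degree ≈ 2.5 in the largest
  component) the modular graphs sit near the community-detectability
  limit: spectral and modularity partitions recover the planted structure
  only partially, so patchwork margins that depend on partition quality
  are compressed relative to denser regimes, and module subgraphs contain
  pass-through nodes with no internal edges.
- Filters are strictly one-hop; low-degree nodes pool few measurements and
  retain more residual noise. Iterated or multi-hop filtering is out of
  scope.
- The value-assignment chain is a hill climb, not a sampler of a defined
  ensemble: it returns *some* value configuration with the target
  assortativity and i.i.d. marginals, which is sufficient for the
  benchmarks but does not define a unique distribution over configurations.
- Weighted and signed networks are accepted by the data model, but only
  the mean filter uses weights; no shipped generator produces them.
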