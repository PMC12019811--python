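# Methods

## Problem and data model

A networked time series (NTS) couples a multivariate time series — `T` time
steps, `N` entities, `D` features — with a sequence of weighted undirected
graphs on the same entities. Observations are partial on both sides: a
binary mask `Mˣ ∈ {0,1}^{T×N×D}` marks observed feature entries, and a mask
`Mᴬ ∈ {0,1}^{T×N×N}` marks observed edge slots. Values stored under mask 0
are sentinels (NaN by convention) and must not influence any computation;
this is enforced by construction (all model inputs are multiplied by the
mask) and asserted by tests that perturb masked entries and require
identical losses, metrics and validation reports.

Time and node indices are 0-based. Bundles are directories of CSV tables
plus a JSON manifest. The manifest distinguishes two readings of an entry
absent from the edge list: `absent_edges: zero` (the default — an absent
pair is an observed non-edge, with a separate list of missing entries) and
`absent_edges: missing`. The default reflects the sensor-network setting in
which the static topology is known but dynamic weights can drop out.
Floats are written with `%.17g` and parsed with round-trip precision, so a
save/load cycle is lossless.

## Position embeddings

For anchor `a`, the random-walk-with-restart score vector is the unique
fixed point of `r = (1−c) W r + c e_a`, with restart probability `c = 0.15`
and `W` column-stochastic over weighted degree, so `Σr = 1` is an invariant
(checked to `10·ε`). Dangling nodes (zero observed degree) restart to the
anchor, which keeps `W` column-stochastic on degenerate graphs; on an empty
graph the scores collapse to the anchor indicator. Power iteration stops
when successive iterates differ by less than `ε = 1e-8` in max norm (at
most 10,000 iterations; the contraction factor is `1−c` in L1). The
implementation iterates all anchors jointly as one `(N×N)(N×L)` product per
sweep; a dense linear solve `r = c (I − (1−c) W)⁻¹ e` serves as the
independent oracle in tests (agreement ≤ 1e-8 over random weighted graphs).

Anchors are fixed per dataset: the `L = min(N, ⌈log₂N⌉²)` nodes of largest
total observed weighted degree (ties to the smaller index), following the
anchor-set sizing of position-aware GNNs; a seeded uniform strategy is also
available. Positions are computed once from the observed graphs before
training and are not updated from imputed graphs.

The expressiveness rationale is testable: on the unit-weight 6-cycle,
1-WL colour refinement assigns every node one colour, while RWR scores
against a single anchor take at least three distinct values and order nodes
by cycle distance.

## Architecture

One *direction* of the model consists of:

* **Encoder** — 2-layer GRU over `[x̃ ⊙ m ‖ m ‖ R]` per node per step
  (missing features enter as zeros); two linear heads on the final state
  give the posterior mean and log-variance (latent width `d_z`); sampling
  is by seeded reparameterization. At impute time the posterior mean is
  used, making imputation deterministic given a checkpoint.
* **Stage 1** — linear map of the previous hidden state to an initial
  feature prediction, blended with observations by the filler
  `m ⊙ x̃ + (1−m) ⊙ ŷ`.
* **Stage 2** — node embeddings `U_t` from a linear map of
  `[O_t ‖ m ‖ R_t ‖ H_{t−1}]`; a two-layer MLP over `[U_t ‖ H_{t−1} ‖ f(t)]`
  produces per-node link embeddings whose scaled inner products, through a
  softplus, give the predicted weighted adjacency (diagonal zeroed,
  symmetrised). A per-node MLP emitting `N` columns directly would break
  permutation equivariance, which the pairwise score preserves (asserted by
  permutation tests). `f(t)` is the unit-norm Bochner encoding
  `(1/√k)[cos w₁t, sin w₁t, …]` with `k` learnable frequencies initialised
  log-spaced over `[1/T, 1]` cycles; it satisfies the rescaling identity
  `f_w(αt) = f_{αw}(t)` exactly. One round of degree-normalised message
  passing on the predicted graph, `φ(D̂⁻¹ A U W₁ + U W₂)` with `D̂`
  clamped at 1 and `φ = ReLU`, yields structural embeddings.
* **Stage 3** — one scaled-dot-product self-attention layer (2 heads) over
  the nodes of the step, input `[z ‖ H_{t−1} ‖ H_graph ‖ O_t ‖ m]`,
  followed by MLPs; the refined prediction is filled against observations
  again. A single-layer GRU cell on `[z ‖ X_out ‖ m ‖ H_graph]` updates the
  hidden state.

The initial decoder state `H₀ ~ N(0, 1/d_h)` is drawn once per direction at
model initialisation and stored as a buffer, so it travels with checkpoints
and with copied parameters. The backward direction is an independent
parameter set applied to the time-reversed window (configurable to share
parameters); an MLP over the six per-step representations of both
directions produces the merged imputation. The per-node latent `z` is
window-level (the final encoder state) and is broadcast to every decoder
step.

Defaults: `d_h = 64`, `d_z = 32`, `k = 8`, 2 attention heads,
`mlp_hidden = 64`. The recovery experiment uses a half-width model
(`d_h = 32`, `d_z = 16`, `k = 4`, `mlp_hidden = 32`), ample for a
12-node fixture.

## Objective and training

The loss of one window sums nine nonnegative terms: masked MAE of the
merged output; masked MAEs of the raw stage-1 and stage-3 predictions of
both directions; `γ`-weighted link errors of both directions; and
`β`-weighted KL divergences of both posteriors from the standard normal
(closed form, averaged per element). The stage losses compare the raw
predictions — not the filler outputs, which agree with observations by
construction and would contribute nothing. The link error is the Frobenius
error normalised per observed edge slot, `sqrt(Σ Mᴬ (Ã − A_out)² / ΣMᴬ)`,
so it shares the per-entry scale of the MAE terms; `β = 0.05`, `γ = 1`
by default. Training uses all observed entries as supervision (no
additional input re-masking); held-out evaluation entries are produced by
the generator and never seen.

Optimisation is Adam at `lr = 1e-3` over sliding windows (length 24,
stride 24 in the recovery setting), all windows in one batch per step,
features standardised per feature on observed entries (the scaler is stored
in the checkpoint and inverted on output). Every random draw — parameter
init, `H₀`, reparameterization noise — flows from explicit seeds, so two
runs agree bit-for-bit. Non-finite losses abort with the epoch index.
Optional early stopping monitors the training total with a patience
counter.

At impute time, covering windows (a tail window is appended when the stride
leaves a remainder) are run bidirectionally; window predictions at a
missing entry are averaged, the two directions' adjacency predictions are
averaged, the result is symmetrised with a zero diagonal, and observed
entries are copied from the input verbatim — an exact conservation law that
holds for arbitrary (including untrained) parameters.

## Autodiff engine

No GPU tensor library is part of this package's dependency set; the model
runs on a purpose-built reverse-mode engine over numpy float64
(`ntsvae.autodiff`): a `Tensor` wrapper records a tape of closures and
`backward()` walks it in reverse topological order. Correctness is
guarded two ways: per-op tests against central finite differences, and an
end-to-end check that the gradient of the full training loss matches finite
differences to 1e-4 relative at randomly chosen parameters. The engine
keeps everything in float64, which makes the determinism guarantees above
cheap.

## Synthetic data generator

The generator emulates the statistical structure of sensor-network data:

* **Base graph** — by default a geometric sensor layout in the unit square
  with thresholded-Gaussian-kernel weights (Erdős–Rényi and grid layouts
  are available); isolated nodes are reconnected to a neighbour.
* **Signals** — `r = 3` latent temporal factors (Gaussian-smoothed noise,
  smoothing length 8 steps, unit variance) mixed by per-node loadings that
  are diffused twice along the base graph with coupling 0.5, plus N(0,
  0.1²) observation noise. The diffusion makes neighbouring nodes more
  correlated than random pairs — the property that makes joint
  feature/edge imputation non-degenerate — and a test asserts exactly that.
* **Dynamic edges** — a base edge `(u,v)` is present at time `t` iff the
  RBF similarity `exp(−‖x_t^u − x_t^v‖²/(2σ²))` of the endpoint signals
  exceeds the threshold `k = 0.3` (σ = 1), in which case it carries the
  static base weight.
* **Masking** — feature entries are hidden i.i.d. with probability
  `p = 0.25`; edge slots on base edges are hidden by the *endpoint rule*
  (an edge is unobserved whenever either endpoint has a hidden feature at
  that step; expected hidden fraction `1 − (1−p)² = 43.75%` at `p = 0.25`)
  or, as a variant, with a flat 70% probability for such slots. Hidden
  entries form the held-out evaluation masks, disjoint from the observation
  masks by construction.

The recovery fixture is `N = 12`, `T = 200`, `D = 1`, `p = 0.25`, endpoint
rule, generator seed 0 — small enough that the full experiment (300 epochs)
runs in under two minutes on one CPU core while leaving ~600 held-out
feature entries and ~3000 held-out edge slots to score on.

What the generator does *not* emulate: mechanistic epidemic or traffic
dynamics, heavy-tailed marginals, regime changes, block (sensor-outage)
missingness patterns, or directed flows. Passing the recovery experiment
therefore shows that the architecture can exploit smooth temporal structure
and graph-correlated signals — not that it matches any particular
real-world benchmark number.

## Evaluation

Metrics are computed only at held-out entries: MAE, MSE and
MRE = `Σ|err| / Σ|label|` for features, and the Frobenius norm of the
adjacency error (dataset aggregate) for edges. Overlap between evaluation
and observation masks is a contract error. The reference points are the
per-node mean imputer (features) and the all-zeros predictor (edges); the
recovery experiment requires the trained model to beat both on the same
held-out entries.

## Known limitations

* Dense `N×N` link scoring and attention limit practical graph sizes to a
  few hundred nodes; no sparse or low-rank attention variants are provided.
* The RWR solver is exact power iteration; no approximate push/local
  solvers for large graphs.
* Directed graphs are loadable (`undirected: false`) but the decoder's
  symmetrisation targets undirected data; directed link decoding is out of
  scope.
* Forecasting beyond the observed window is not exposed, although the time
  encoding generalises to unseen timestamps.
* Streaming data, irregular per-node sampling grids, multigraphs and
  categorical features are out of scope.
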