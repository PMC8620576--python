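# Methods

## Data model

A DTI dataset is a binary interaction matrix `Y` (drugs × targets) plus
optional square, symmetric similarity matrices `S_d` (drug–drug) and
`S_t` (target–target) with entries in [0, 1] and unit diagonal.  The
canonical in-memory orientation is drugs × targets; the public
gold-standard files store targets as rows, so the reader's `auto`
orientation transposes when every row identifier carries the `hsa`
protein prefix.  Similarity files are symmetrized by averaging with
their transpose, clipped to [0, 1], and diagonal-forced to 1 on
ingestion, because real chemical-similarity exports can be slightly
asymmetric; the largest correction applied is logged.  Interaction
entries are one-class: 1 means experimentally verified, 0 means
unobserved.

## Shared network

All three ranking variants use the same five-layer scorer: one-hot drug
and target inputs, embedding matrices `P` (n × k) and `Q` (m × k), the
element-wise product `h0 = p_d ⊙ q_t` as interaction layer, a ReLU
tower of `L` hidden layers, and a linear prediction head giving a raw
score `x_dt`.  The tower shape defaults to constant width `k` per layer;
only the depth is usually varied.  Initialization is zero-mean normal
with sd √(2/fan-in) for hidden weights (the standard choice for ReLU
stacks), sd 0.01 for embeddings, zero biases.

The loss heads:

* point-wise: `Σ (y − σ(x))²` over sampled cells;
* pair-wise: `Σ softplus(−(x_pos − x_neg))` over sampled triples.  The
  difference is taken between **raw** scores with a single sigmoid on
  the gap; squashing each score through its own sigmoid first would
  double-saturate the gradient.  The literal double-sigmoid form remains
  available (`pairwise_squash`) for comparison;
* list-wise: for a list of one positive and K negatives, softmax the
  K+1 scores into top-one probabilities and charge
  `−[ln p(positive) + Σ ln(1 − p(negative))]`.  Both the positive and
  negative terms are kept even though softmax normalization couples
  them.

Every head adds `λ · Ω(Θ)` where `Ω` sums squared entries of **all**
parameters (embeddings, weights, biases) — one regularization knob, so
hyperparameter grids stay one-dimensional in λ.

Similarity information enters as
`λ_d ‖S_d − P Pᵀ‖²_F + λ_t ‖S_t − Q Qᵀ‖²_F`:
the Gram matrix of the embeddings should reproduce the precomputed
similarities.  Because the penalty touches embedding rows regardless of
interaction data, it is the only channel through which cold-start drugs
learn.

## Gradients and numerics

Backpropagation is written directly in numpy (batched matrix algebra,
scatter-add into embedding gradients).  Sigmoid and softplus use
branch/shift forms and inputs are clamped to ±709 before
exponentiation, so no overflow occurs for |x| ≤ 1e4 and predictions
stay strictly inside (0, 1); softmax is max-shifted.  Central finite
differences (step 1e-5, relative error < 1e-4) validate every parameter
gradient of all three total losses on a small instance whose
pre-activations are pushed away from the ReLU kinks — at a kink the
two-sided difference quotient is simply not the derivative, so the test
instance avoids them by construction.

The exact similarity-penalty gradient `−4λ (S − PPᵀ)P` needs an n × n
product per step; that is the default (`sim_mode: exact`) up to
n = 1000.  Beyond that a per-batch row-block estimator is used, scaled
by n/|block|, with one exact full-matrix pass per epoch
(`sim_mode: stochastic`).

## Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) throughout, for the neural models
and the MF baselines alike.  Negatives are resampled fresh every epoch —
per drug, uniformly from its unobserved targets, in numbers
proportional to its positives (`neg_ratio`, default 1.0 balanced;
`per_positive` triples for the pair-wise head, default 1; list size
K = 4 by default).  Epochs default to 100 and are a free parameter.
All randomness descends from one integer seed through named
sub-streams, so runs are bit-reproducible.

Cold-start (CV_nd) drugs are excluded from every sampler; their
embedding rows receive gradients **only** from the drug-similarity term,
so with λ_d = 0 they provably keep their initial values.  An
alternative inference rule, the similarity-weighted average
`p_d = Σ_j S_d[d,j] p_j / Σ_j S_d[d,j]` over training drugs, is
available as `cold_start: sim_avg`.

## Baselines

PMF minimizes squared error on sampled cells with inner-product scores.
The classical objective sums over verified pairs only, under which the
constant predictor 1 is optimal; sampling negatives like the point-wise
neural model is our one-class adaptation.  CMF adds the two similarity
penalties; with both weights zero it runs the identical code path and
reproduces PMF step for step.  BPR-MF applies the pair-wise loss to
inner-product scores.

CMF supports a spectral initialization (`init: spectral`, chosen
automatically when both similarity matrices are present and a
similarity weight is positive): each similarity matrix is factored by
its top-k eigenpairs — the closed-form minimizer of its penalty — and
the rotation ambiguity between the two factor bases is resolved by a
k × k bilinear least-squares fit to the training cells, split
symmetrically through its SVD.  Rationale: the CMF landscape has a
strong local attractor in which the Gram terms are satisfied but the
interaction term settles into a memorizing solution; starting from the
spectral estimate, a small Adam learning rate (1e-4, within the
standard grid) refines the interaction fit without leaving the
similarity-consistent region.  Random initialization remains the
default whenever no similarity information is used.

## Evaluation

AUC uses the tie-aware Mann–Whitney formulation and AUPR the
non-interpolated step summation (average precision); both delegate to
scikit-learn and are tested against brute-force pair-enumeration and
threshold-enumeration oracles.  Fold plans are random partitions into
10 near-equal test sets of cells (CV_dt) or drugs (CV_nd).  CV_dt test
cells are masked entirely from training — their zeros are not usable as
sampled negatives, preventing a leakage path the protocol description
leaves implicit.  Metrics are micro-averaged over the pooled test cells
of each fold and then averaged across folds (a pooled-across-folds mode
is not provided; per-fold averaging matches the protocol's wording).
Folds whose test labels are single-class are skipped with a warning and
excluded from means — small datasets can produce them.  Grid search
evaluates every point by cross-validation (or a single validation fold
in `fast` mode) and breaks AUC ties toward smaller k, then smaller
depth.

## Synthetic data generator

The generator plants standard-normal factors `P*` (n × k_true), `Q*`
(m × k_true).  Latent scores are the inner products (linear link) or a
tanh of a fixed random projection of the element-wise product
(nonlinear link).  Exactly ⌈density · n · m⌉ cells — the top scores —
become 1, so positive counts are exact and the positive set is
deterministic per seed.  Similarities are the factor Gram matrices,
min–max mapped to [0, 1] over off-diagonal entries (mimicking the range
of normalized chemical/sequence similarity scores), diagonal 1, plus
symmetric Gaussian noise of sd `sim_noise`, re-clipped.

Default study conditions are n = 100 drugs, m = 80 targets,
k_true = 8, density 0.08, sim_noise 0.05 — the sparsity regime of the
mid-sized public DTI datasets at a desk-scale matrix size.  What the
generator does *not* emulate: the heavy degree skew of real interaction
data (hub drugs, promiscuous targets), block structure in chemical
series, or realistic similarity score distributions.  Passing recovery
tests therefore demonstrates that the estimators identify planted
low-rank structure under the model's own assumptions, not performance
on real pharmacology.

## Problem sizes used in the shipped checks

The recovery and cold-start analyses run 10-fold CV on the 100 × 80
default conditions: three seeds for CV_dt recovery (neural variants
with λ_d = λ_t = 0.01, k = 32, τ = 0.005, 200 epochs; CMF with
k = k_true on noiseless linear data, τ = 1e-4, 100 epochs), and five
seeds for the CV_nd similarity contrast (k = 16, 80 epochs,
λ_d = λ_t ∈ {0, 0.05}).  These sizes keep a full run around ten
minutes on one CPU while leaving wide margins on the qualitative
findings: similarity regularization lifts cold-start AUC from chance
(≈ 0.5) to above 0.9.

## Known limitations

* Per-cell probability calibration is not attempted; scores are for
  ranking only.
* The stochastic similarity-gradient mode is an approximation;
  its scale factor is heuristic and it is exercised at desk scale only
  for correctness, not accuracy.
* Hidden-layer widths beyond "constant width k" are configurable but
  untuned.
* The MF baselines use Adam rather than alternating least squares; with
  aggressive learning rates from random starts CMF can settle into the
  memorizing attractor described above.
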