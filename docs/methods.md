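# Methods

## Model

`gmvae` fits a variational autoencoder to a cells × genes matrix `X` of
log-normalized expression. The generative assumption is that expression
arises from latent gene-module activities through a single linear map,

    x ≈ θ z + b,      z ~ N(0, I),

where the weight matrix θ (genes × latent) is constrained in two ways that
give the latent space its interpretation:

* **Masking.** A binary mask `M` restricts θ to the support of the
  user-supplied gene modules: `θ[i, j]` may be nonzero only if gene `i`
  belongs to module `j`. The latent coordinate `z_j` therefore can only
  explain the genes of module `j`, and is read out directly as that
  module's activity (a gene-module variable, GMV).
* **Nonnegativity.** `θ ≥ 0` elementwise, so a larger activity can only
  increase the predicted expression of the module's genes; the sign of an
  activity difference between cell groups is then directly interpretable.

Three node kinds share the latent space: one GMV node per gene module;
optional fully-connected (FC) nodes whose mask column is all-ones, which
absorb variance the modules cannot explain (keeping 16 or fewer preserves
the module nodes' biological signal — more than that triggers a warning);
and covariate nodes, one per level of a categorical covariate such as
batch. Covariate coordinates are overwritten with the cell's one-hot label
before decoding, conditioning the generative process on the label; the
label is known, so nothing is inferred for these coordinates (the encoded
posterior reports the code itself with a nominal 1e-6 standard deviation).
This deterministic overwrite is a design choice — the alternative of
treating covariate nodes as ordinary inferred latents would leave the
decoder free to ignore the label.

The variational posterior is a diagonal Gaussian `q(z|x) = N(μ(x),
diag σ²(x))` from a ReLU MLP encoder (default: 2 hidden layers of 800
units, dropout 0.2 — the defaults match a published configuration of this
model family; tests and the acceptance runs use 64–128 units, which is the
problem size this package's CPU-only NumPy implementation handles
comfortably at desk scale). Training maximizes the ELBO

    L(x) = E_q[log p(x|z)] − KL(q(z|x) || N(0, I)),

with a unit-variance Gaussian observation model (reconstruction = squared
error up to constants, summed over genes), a single reparameterized draw
per cell per step, and the closed-form KL. Optimization is Adam
(lr 5e-4, batch 128 by default), up to 300 epochs with early stopping on
validation ELBO (80/20 split, patience 20). After every optimizer step the
decoder is projected back onto the constraint set: masked entries to exact
zero, negative entries to zero. Enforcement is doubled — θ is multiplied
by M in the forward pass *and* re-projected after updates — so the
invariants hold regardless of optimizer momentum.

A dropout layer on the sampled `z` (default rate 0.3, training only)
counteracts the diagonal prior's tendency to silence all but one of a set
of overlapping modules: randomly removing a module's node forces the
model to keep redundant modules informative.

### Numerical choices

* **Input centering / bias warm start.** The encoder subtracts a stored
  per-gene offset (the training-split mean), and the decoder bias starts
  at the same vector. Both are fit once at the start of training and saved
  in the checkpoint. Without them the shared mean-expression direction
  dominates the encoder input, and Adam — whose per-step movement is
  bounded by the learning rate — spends essentially the whole run fitting
  the offset; module recovery fails entirely.
* **Log-variance clamping** to [−12, 10] in the encoder head, with
  gradients zeroed at the clamp, keeps early training finite.
* **Decoder init**: Xavier-uniform draw clamped to ≥ 0 (masked entries
  exactly zero). Entries clamped to zero at init can re-grow — a zero
  weight does not block its own gradient.
* Non-finite loss terms raise immediately, naming the term and epoch.

## Differential module activity

For module `k` and groups A, B, the test contrasts the one-sided
hypotheses `H0: E[z_a^k] > E[z_b^k]` against its complement. `p(H0)` is
estimated by direct Monte Carlo: sample `n_pairs` cell pairs (default
5000) with replacement — which realizes abundance weighting over cells
within each group — draw `n_mc` (default 10) reparameterized samples from
each cell's posterior, and count `z_a > z_b`, ties as one half (ties have
measure zero for the Gaussian posteriors; the convention keeps the
group-swap antisymmetry exact). The log-Bayes factor is the log-odds
`K = ln p(H0)/(1 − p(H0))` with `p` clamped to `[ε, 1−ε]`,
`ε = 1/(n_pairs · n_mc)`, so `K` is always finite. The conventional call
is `|K| > 3` (posterior odds ≈ 20), optionally gated on the effect size
MD = |mean_A(μ_k) − mean_B(μ_k)| (default threshold 0, i.e. off; a floor
of 5 is the convention used for volcano plots on real pathway analyses).
MD uses posterior means, not sampled draws, so it is deterministic.
One-vs-rest testing derives independent per-category seeds from one root
seed via `SeedSequence.spawn`.

## Evaluation metrics

* **Silhouette**: mean of `(b − a)/max(a, b)` with Euclidean distance,
  delegated to scikit-learn; exact up to 10⁴ cells, seeded subsampling
  above. The test suite checks it against a brute-force evaluation of the
  definition to 1e-10.
* **Mean-expression R²**: the squared Pearson correlation between per-gene
  means of the real and reconstructed matrices (a correlation, not a
  regression coefficient of determination).
* **Top-k overlap**: `|top-k(A) ∩ top-k(B)|/k` between two module
  rankings; under independent random rankings its expectation is `k/N`.
* A repeated-subsampling harness (default 100 seeded repetitions) produces
  the mean ± sd error bars used with these metrics.

## Synthetic data

The generator mirrors the model's own assumptions with known ground truth:
activities `Z*` drawn per condition from normal priors (std 1), sparse
nonnegative loadings `W*` (uniform 0.3–1.0 on each module's support) whose
support defines the emitted GMT, a per-gene baseline level (std 1.0 —
real log-normalized data has strong gene-to-gene mean differences, and
without them the mean-expression R² metric would degenerate), optional
per-gene batch offsets, Gaussian observation noise (std 0.5), and a global
shift to a nonnegative log-normalized-like scale. Unannotated genes carry
baseline plus noise only. Consecutive modules share a configured fraction
of genes (default 10%), exercising the latent-dropout rationale.
Condition effects are planted by shifting a module's activity mean
(`plant_differential`).

The default study is 2,000 cells (two conditions × 1,000), 1,000 genes,
20 modules of 45 genes. What passing tests on these data do **not** show:
robustness to count noise, zero inflation, library-size variation, or
module annotations that are wrong for the tissue — the generator's
modules are exactly correct by construction, so recovery rates here are an
upper bound on real-data behavior.

## Problem sizes and runtime

The implementation is pure NumPy with hand-written gradients (a
finite-difference check in the suite guards the backward pass), and all
shipped analyses run on one CPU: the default synthetic study trains in
~20 s with a 128-unit encoder; the repeated planted-effect study (20
seeded runs at 600 cells × 300 genes) takes ~30 s.

## Known limitations

* The single-layer nonnegative decoder trades generative capacity for
  interpretability; it cannot express interactions between modules.
* Gene matching is exact string equality (an explicit uppercase helper is
  provided); no ortholog or identifier mapping.
* Out-of-sample projection assumes comparably normalized input; missing
  genes are zero-filled and projection refuses below 50% gene overlap.
* No count-data (negative binomial) observation model.
* No multiple-testing correction across modules: the fixed `|K| > 3`
  convention is used, as is standard for this test.
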