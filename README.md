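# gmvae

Interpretable variational autoencoder for single-cell transcriptomics:
the decoder is a single **masked, nonnegative linear layer** wired to
user-supplied gene modules (pathways, regulons, marker sets), so every
latent variable reads out directly as one module's per-cell activity —
no post-hoc enrichment needed. On top of the model, the package provides
a Monte-Carlo **Bayes-factor test** for differential module activity
between cell groups, out-of-sample projection, the matching evaluation
metrics, and a synthetic-data generator with planted ground truth.

## Model

For log-normalized expression `x` (cells × genes) and gene modules encoded
as a binary mask `M` (genes × latent nodes, `M[i,j] = 1` iff gene `i`
belongs to module `j`):

```
x ≈ θ z + b,   θ ⊙ (1 − M) = 0,   θ ≥ 0,   z ~ N(0, I)
q(z | x) = N(μ_φ(x), diag σ²_φ(x))        (MLP encoder)
```

trained by maximizing the ELBO
`E_q[log p(x|z)] − KL(q(z|x) ‖ N(0, I))` with Adam, early stopping on
validation ELBO, and projection of `θ` back onto the constraint set after
every step. Because module `j`'s latent node can only reconstruct module
`j`'s genes, and only positively, `z_j` is interpretable as that module's
activity. Extra fully-connected nodes absorb unannotated variance and
covariate nodes condition the decoder on batch labels.

Differential activity between groups A and B is scored per module by the
natural-log Bayes factor `K = ln p(H0)/(1 − p(H0))` for
`H0: E[z_A] > E[z_B]`, estimated by Monte-Carlo sampling of cell pairs
from the variational posteriors; `|K| > 3` (posterior odds ≈ 20) is the
conventional significance call.

The implementation is pure NumPy (hand-written gradients, verified by
finite differences in the test suite) and runs all shipped analyses on a
single CPU. See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

`examples/02_differential_activity.py` plants a +3σ shift on
`module_03` and a −2σ shift on `module_07` in a 600-cell synthetic study,
trains, and tests perturbed vs control:

```
      gmv      K    MD  p_h0  significant
module_03  3.154 2.636 0.959         True
module_07 -1.942 1.846 0.125        False
module_02  0.424 0.440 0.605        False
...
module_05 -0.004 0.001 0.499        False
```

The two planted modules take the top ranks with K signs matching the
planted directions (+3σ → K > 0 for the perturbed-vs-control contrast);
`module_03` clears the `|K| > 3` bar, the weaker −2σ effect ranks second,
and unperturbed modules sit near `K = 0`, `p(H0) = 0.5`. The other
examples cover training and activity recovery (`01`, median planted-vs-
inferred |r| = 0.97 on the default 2,000-cell study), out-of-sample
projection of a held-out condition (`03`, effect-rank correlation 0.84),
regulon-defined modules (`04`), and the evaluation metrics (`05`).

A thin CLI wraps the same pipeline for file-based runs
(`gmvae simulate / train / project / dgmv`, each writing a JSON run
manifest); `gmvae --help` lists the options.

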