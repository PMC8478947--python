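"""Differential module activity between two conditions, with known truth.

Plants a +3 sigma shift on one module and a -2 sigma shift on another,
trains, and runs the Monte-Carlo Bayes-factor test.  K > 0 favors higher
activity in the first group; |K| > 3 (posterior odds ~ 20) is the
conventional significance call, MD the effect size in latent space.
"""

from gmvae import (
    EncoderSpec,
    SimulationConfig,
    TrainConfig,
    bayes_factor,
    build_mask,
    init_model,
    plant_differential,
    rank_and_call,
    simulate,
    train,
)

cfg = SimulationConfig(
    n_cells_per_group=300, n_genes=300, n_modules=10, genes_per_module=28,
    n_unannotated_genes=20, seed=7,
)
cfg = plant_differential(cfg, ["module_03"], 3.0)
cfg = plant_differential(cfg, ["module_07"], -2.0)
adata, modules, truth = simulate(cfg)

mask = build_mask(modules, list(adata.var_names), n_fc=2)
model = init_model(mask, encoder_spec=EncoderSpec(n_hidden=64, seed=0))
model, _ = train(model, adata, TrainConfig(max_epochs=120, patience=20, seed=0))

result = bayes_factor(
    model,
    adata,
    adata.obs["condition"] == "perturbed",  # group A
    adata.obs["condition"] == "control",    # group B
    n_pairs=4000,
    seed=0,
)
table = rank_and_call(result)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\nplanted: module_03 (+3 sigma), module_07 (-2 sigma); they should "
      "top the |K| ranking with K signs matching the planted directions.")
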