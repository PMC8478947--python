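"""Use a transcription-factor network as the module definition.

Modules need not be pathways: a two-column regulator -> target edge list
(ARACNe-style) defines one module per transcription factor, and each
latent node then reads out as that factor's regulon activity.
"""

import tempfile
from pathlib import Path

from gmvae import build_mask, read_regulon_table

edges = "\n".join(
    [
        "TF_A\tgene_0001", "TF_A\tgene_0002", "TF_A\tgene_0003",
        "TF_A\tgene_0004", "TF_A\tgene_0005",
        "TF_B\tgene_0004", "TF_B\tgene_0005", "TF_B\tgene_0006",
        "TF_B\tgene_0007", "TF_B\tgene_0008", "TF_B\tgene_0099",
    ]
)
with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "network.tsv"
    path.write_text(edges + "\n")
    regulons = read_regulon_table(path)

print(f"{len(regulons)} regulons parsed:")
for reg in regulons:
    print(f"  {reg.name}: {len(reg.genes)} targets")

genes = [f"gene_{i:04d}" for i in range(50)]  # dataset universe, gene_0099 absent
mask = build_mask(regulons, genes, n_fc=1, min_genes=3)
print(f"mask: {mask.n_genes} genes x {mask.n_latent} latent nodes "
      f"({mask.n_gmv} regulon + 1 fully-connected)")
print("column sums:", mask.mask.sum(axis=0).astype(int).tolist(),
      "<- targets present in the dataset per node")
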