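"""scRNA-seq input mode: count preprocessing into the model's marker space.

Simulates a Poisson gene-count matrix, then runs the standard chain:
filter genes detected in fewer than 10 cells, scale each cell to a total
of 10,000 counts, log1p, and keep the 1,000 most variable genes.  The
result is a cells x 1000 matrix that enters the pipeline exactly like a
cytometry sample (with the wider autoencoder variant).
"""

import numpy as np

import cytogpnet as cg
from cytogpnet.autoencoder import AEConfig

sim = cg.SimConfig(n_markers=1500, informative=(0, 1, 2), effect=1.0, seed=5)
counts, cell_class = cg.simulate_counts(sim, depth=2000, n_cells=400)
print(f"raw counts: {counts.shape[0]} cells x {counts.shape[1]} genes, "
      f"median depth {np.median(counts.sum(axis=1)):.0f}")

processed = cg.preprocess_scrnaseq(counts, cg.PreprocessConfig(mode="scrnaseq"))
depth = np.expm1(processed.values).sum(axis=1)
print(f"after preprocessing: {processed.values.shape[1]} HVGs; "
      f"per-cell depth spread {depth.min():.6f}..{depth.max():.6f} "
      "(partial: HVG columns only)")

ae_cfg = AEConfig.for_scrnaseq(input_dim=processed.values.shape[1])
print(f"scRNA-seq autoencoder: hidden {ae_cfg.hidden_dims}, latent {ae_cfg.latent_dim}")
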