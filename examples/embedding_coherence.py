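"""Are gene embeddings coherent with pathway membership?

Compares the mean within-pathway pairwise Pearson correlation of gene
vectors against a null in which the gene -> vector assignment is shuffled
by a derangement (no gene keeps its own vector). A positive mean delta
whose 95% CI excludes zero means the embedding places functionally related
genes close together. Two embeddings are scored: the simulator's
pathway-structured one and a pure-noise control.
"""

import numpy as np

from pertbench import EmbeddingTable, SimConfig, coherence_test, simulate_deltas, simulate_embeddings

cfg = SimConfig(n_genes=600, n_perturbations=40, n_pathways=8,
                embedding_noise=0.2, seed=2)
truth = simulate_deltas(cfg)
structured = simulate_embeddings(cfg, truth)
gene_sets = truth.pathway_gene_sets()

rng = np.random.default_rng(2)
noise = EmbeddingTable(structured.genes, rng.standard_normal(structured.vectors.shape),
                       source="noise-control")

for emb in (structured, noise):
    res = coherence_test(emb, gene_sets, n_permutations=100, min_set_size=3, seed=2)
    print(f"{emb.source:18s} mean delta {res.mean_delta:+.4f} "
          f"[95% CI {res.ci_low:+.4f}, {res.ci_high:+.4f}] over {len(res.per_set)} sets")
print("\nThe structured embedding's CI excludes 0 (pathway-coherent);")
print("the noise control straddles 0 (no association with the gene sets).")
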