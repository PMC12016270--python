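"""Simulate a Perturb-seq-like screen and benchmark baseline predictors.

Builds a synthetic screen with moderate heterogeneity (shared response
fraction 0.3), then runs the full pipeline: normalization, pseudo-bulking,
perturbation-exclusive split, featurization of perturbations from the
matched synthetic gene embeddings, model fitting and the four Pearson
metrics. Pearson Delta is the headline number: the correlation between
predicted and observed differential (post minus control) profiles on
held-out perturbations. The "dynamic range" is the Pearson Delta gap
between the best model and the Train Mean floor.
"""

from pertbench import RunConfig, SimConfig, run_benchmark

sim = SimConfig(
    n_genes=1000,
    n_perturbations=60,
    cells_per_condition=30,
    control_cells=150,
    shared_fraction=0.3,  # expected pairwise delta correlation between perturbations
    count_depth=3000,
    seed=0,
)
cfg = RunConfig(sim=sim, models=("train_mean", "rf", "knn"),
                grids={"rf": (100, 300), "knn": (1, 3, 5)},
                fractions=(0.7, 0.1, 0.2), seed=0)
run = run_benchmark(cfg)

print(run.result.aggregate.pivot(index="model", columns="metric", values="value").round(4))
print(f"\nmedian pairwise delta correlation: {run.heterogeneity.median:.3f}")
print(f"dynamic range (best - train_mean, Pearson Delta): {run.gap:.3f}")
print(
    "\nRaw-space 'pearson' is high for every model (baseline expression dominates);"
    "\n'pearson_delta' separates the feature-based models from the Train Mean floor."
)
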