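# pertbench

Benchmarking toolkit for **post-perturbation RNA-seq prediction**: given a
Perturb-seq screen (pooled CRISPR perturbations with single-cell RNA-seq
readout), how well can a model predict the expression profile of a
perturbation it has never seen? And — just as important — is the dataset
diverse enough for that benchmark to mean anything?

The package is aimed at computational biologists who evaluate perturbation-
response models (foundation models, graph networks, classical regressors)
and want a transparent, reproducible harness with honest baselines.

## What it computes

**Pipeline.** Cells are depth-normalized to 10,000 reads and log1p-
transformed; cells sharing a condition label are averaged into pseudo-bulk
profiles; each perturbation's *delta profile* is its pseudo-bulk minus the
control pseudo-bulk. Perturbations are split perturbation-exclusively into
train/validation/test (combos such as `"A+B"` assigned whole, and tagged
`combo_seen0/1/2`, `seen_single` or `unseen_single` relative to the train
set).

**Metrics.** For predicted profile ŷ, observed y and control c, per test
perturbation:

- `pearson` — r(ŷ, y), raw expression space (dominated by baseline
  magnitudes; reported but not meaningful for model comparison);
- `pearson_delta` — r(ŷ − c, y − c), the headline metric;
- `pearson_delta_de` — r(ŷ − c, y − c) restricted to the top-20
  differentially expressed genes (Welch t-test or Wilcoxon rank-sum,
  deterministic ranking);
- `pearson_delta_no_target` — the top-20 variant with the CRISPR target
  gene(s) excluded and the list refilled to 20, so trivially predicting the
  directly targeted gene earns nothing.

Undefined correlations (constant vectors) are reported as NaN and counted,
never coerced to zero.

**Baselines.** *Train Mean* predicts the mean training pseudo-bulk profile
for every query — the floor every model must beat. Random Forest, Elastic
Net and kNN regressors map perturbation features (a gene-embedding table —
binary GO membership from GMT, foundation-model embeddings from TSV, or
synthetic — reduced to ≤ 256 principal components; combo features are the
sum of component vectors) to pseudo-bulk profiles, each tuning one
hyperparameter on validation Pearson Delta.

**Diagnostics.** The pairwise Pearson correlations between all delta
profiles summarize dataset heterogeneity; their median versus the
benchmark's *dynamic range* (best model − Train Mean, Pearson Delta)
exposes the inverse relationship: homogeneous screens cannot discriminate
models.

**Embedding coherence.** For a gene-set collection (GMT), the mean
within-set pairwise correlation of embedding vectors is compared with a
derangement null (no gene keeps its own vector); per-set deltas are
summarized by their mean and a 95% t-interval.

**Simulator.** `SimConfig`/`simulate_study` generate ground-truth deltas
with an analytically controlled pairwise correlation (shared/private
mixture with mixing weight ρ = `shared_fraction`), pathway structure,
signed CRISPRi/CRISPRa target effects, Poisson (optionally overdispersed)
counts, and matched pathway-informative gene embeddings — so the whole
pipeline is testable offline.

## Worked example

```python
from pertbench import RunConfig, SimConfig, run_benchmark

sim = SimConfig(n_genes=1000, n_perturbations=60, cells_per_condition=30,
                control_cells=150, shared_fraction=0.3, count_depth=3000, seed=0)
cfg = RunConfig(sim=sim, models=("train_mean", "rf", "knn"),
                grids={"rf": (100, 300), "knn": (1, 3, 5)},
                fractions=(0.7, 0.1, 0.2), seed=0)
run = run_benchmark(cfg)
print(run.result.aggregate.pivot(index="model", columns="metric", values="value").round(4))
```

prints

```
metric      pearson  pearson_delta  pearson_delta_de  pearson_delta_no_target
model
knn          0.9325         0.6779            0.5194                   0.5940
rf           0.9381         0.6973            0.5572                   0.6394
train_mean   0.9144         0.5442            0.4605                   0.5098
```

with `run.heterogeneity.median ≈ 0.291` and `run.gap ≈ 0.153`. Read it as:
raw-space `pearson` is > 0.91 even for the trivial Train Mean predictor
(baseline expression magnitudes dominate), while `pearson_delta` separates
the feature-based models from the floor; the 0.153 gap is this synthetic
dataset's dynamic range at median inter-perturbation correlation 0.29.

The `examples/` directory has one short script per capability
(benchmarking, heterogeneity diagnostics, DE selection, embedding
coherence); each prints the numbers it computes and what they mean. A thin
CLI mirrors the library:

```bash
pertbench simulate --rho 0.3 --seed 0 --out study/
pertbench benchmark --synthetic --models train_mean,rf --seed 0 --out bench/
pertbench coherence --embeddings syn=study/embeddings.tsv --gmt study/pathways.gmt --out coh/
```

Loading the published Perturb-seq benchmark datasets through the GEARS
`cell-gears` loader is supported but opt-in (`allow_download=True`): it
needs network access and the optional `cell-gears` package.

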