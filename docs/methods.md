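# Methods

## Problem setting

Perturb-seq screens read out single-cell expression after pooled CRISPR
perturbations. A perturbation-response model is asked to predict the
post-perturbation expression profile of perturbations held out from
training (the perturbation-exclusive, PEX, setting). This package
implements the evaluation harness for that task: the preprocessing chain,
the metrics, simple baselines that any candidate model must beat, and two
diagnostics — dataset heterogeneity and gene-embedding coherence — that
determine how much a benchmark result can be trusted.

## Preprocessing and data model

Counts are normalized per cell to 10,000 reads and transformed with the
natural-log `log(1 + x)`, the single-cell ecosystem default. Cells with
zero total count cannot be rescaled; they are dropped (never imputed) and
counted in the log. Pseudo-bulk profiles are unweighted per-cell means
within a condition, computed in log space; delta profiles subtract the
control pseudo-bulk row. All control cells contribute to the control
profile (no matched subsetting).

Perturbation labels name their target gene(s); dual perturbations use the
`"A+B"` syntax with a reserved control label `ctrl` (both configurable).
Splits are made over perturbation labels, not cells: labels are sorted,
shuffled with NumPy's PCG64 generator under an explicit seed, and cut at
`round(cumsum(fractions)·n)`, so a split is reproducible across platforms.
Test combos are tagged by how many of their components appear as single
perturbations in the train set (`combo_seen0/1/2`); test singles are
`seen_single` when the gene occurs as any train-label component, else
`unseen_single`.

## Differential-expression ranking

Each perturbation's cells are tested gene-wise against control cells,
two-sided, with either a Welch (unequal-variance) t-test or a Wilcoxon
rank-sum test. The ranking key is ascending p-value, ties broken by
descending |statistic|, then lexicographic gene name — fully deterministic
where common toolkit defaults are not. Degenerate genes under the t-test
(zero variance in both groups) get a signed-infinity statistic with p = 0
when the means differ, else statistic 0 and p = 1, rather than NaN. The
Wilcoxon p-value is the exact enumeration when both groups have at most 8
cells and the data are tie-free, and the tie-corrected normal approximation
otherwise; the statistic is the U-statistic centered at `n1·n2/2` so its
sign tracks the direction of change.

Top-K selection (K = 20 by default) takes the first K ranked genes. With
target exclusion on, the perturbation's own target gene(s) are removed
before cutting and the list is refilled to K: in CRISPRi/CRISPRa screens
the target's change is trivially predictable from the perturbation label,
and a metric restricted to a list containing it rewards lookup, not
response prediction. One DE list per perturbation is computed from the
observed cells and applied to every model's predictions.

## Metrics

Per test perturbation, with predicted profile ŷ, observed y, control c:
`pearson` = r(ŷ, y); `pearson_delta` = r(ŷ−c, y−c); `pearson_delta_de`
restricts the delta correlation to the top-20 DE genes;
`pearson_delta_no_target` uses the target-excluded top-20 list. Raw-space
Pearson is reported but should not be used for model comparison: baseline
expression magnitude spreads over orders of magnitude, so any predictor
that reproduces the expression hierarchy scores > 0.9.

Correlations need at least 3 observations and are undefined when either
vector is constant — notably a Train-Mean-style constant predicted delta
offset is *not* silently scored 0; undefined values are NaN, excluded from
aggregation and counted in the result's provenance. Aggregation over test
perturbations is the unweighted mean of defined values.

Dataset heterogeneity is the distribution of Pearson correlations between
all unordered pairs of delta profiles; its median (each pair counted once,
undefined pairs excluded and counted) summarizes how similar perturbation
responses are. The benchmark's dynamic range is the best model's aggregate
Pearson Delta minus Train Mean's. Relating the two across datasets (with a
Spearman rank correlation) shows the inverse relationship: the more
homogeneous the screen, the less room any model has to beat the mean.

## Baseline models

Train Mean stores the per-gene mean over training perturbations' pseudo-
bulk rows and predicts that single vector for every query. The feature-
based regressors (Random Forest, Elastic Net, k-NN; scikit-learn) regress
pseudo-bulk profiles on perturbation features: a gene-embedding table is
reduced by PCA (full SVD) to at most 256 components, fitted on all genes'
vectors — not only perturbation targets — and a perturbation's feature is
its target gene's reduced vector, with combo features the elementwise sum
of the components. Each component's sign is fixed by forcing its largest-
magnitude loading positive, removing the LAPACK sign ambiguity so features
are identical across platforms.

One hyperparameter per regressor is tuned (RF: tree count, default grid
{100, 200, 500}; EN: L1 ratio {0.1, 0.5, 0.9}; kNN: neighbors
{1, 3, 5, 10}); the chosen value maximizes mean validation Pearson Delta —
the headline metric is also the model-selection criterion. Elastic Net
keeps scikit-learn's default regularization strength (alpha = 1.0), which
on log-space profiles shrinks coefficients heavily; it therefore tends
toward a near-constant predictor close to the Train Mean floor. Binary GO
membership matrices are built from GMT collections with sets under 3
member genes dropped (configurable).

## Embedding coherence test

For each gene set with at least `min_set_size` (default 2) members present
in the embedding table, the observed statistic is the mean pairwise Pearson
correlation between member vectors (requiring embedding dimension ≥ 3;
dimension-2 tables are flagged as degenerate). The null shuffles the
gene → vector assignment with a derangement — a permutation with no fixed
points, so no gene keeps its own vector — sampled by rejection from uniform
permutations (the draw is uniform over derangements in the limit of the
rejection scheme's acceptance; uniformity over derangements is not required
for the null's validity and rejection is the simplest correct sampler). One
global derangement per permutation draw is applied across the whole gene
universe and all sets are re-scored; the per-set null mean averages the
draws. The per-set delta (observed − null) is summarized across sets by its
mean with a 95% Student-t interval. When several embedding tables are
compared, all are first restricted to their common gene set.

## Synthetic data generator

The simulator emulates the features of a Perturb-seq benchmark that drive
evaluation behavior, with defaults chosen to sit inside the range real
screens span.

**Deltas.** For single perturbation *p* in pathway *k*:
`delta_p = delta_scale · (√ρ·s + √(1−ρ)·u_p)` with
`u_p = √w·c_k + √(1−w)·e_p`, where `s`, `c_k`, `e_p` are independent
standard-normal gene vectors. Cross-pathway pairs then correlate at exactly
ρ in expectation and same-pathway pairs at ρ + (1−ρ)·w. The pathway
component (default w = 0.5, 10 pathways) exists because the benchmark needs
embeddings whose similarity structure is informative about response
similarity — without it, no featurization could beat the Train Mean floor
and the dynamic-range analysis would be vacuous. Same-pathway pairs are a
small minority of all pairs (≈ 9% at 100 perturbations), so the median
pairwise correlation still estimates ρ; real datasets' medians (≈ 0.12 to
≈ 0.66) are covered by ρ in [0.1, 0.7]. A signed target-gene effect
(default −3 in log space, CRISPRi-like knockdown; positive values emulate
CRISPRa) overwrites the target entry by default ("additive" mode
available); a zero target effect means no modification. Combos sum their
components' deltas plus a small combo-specific deviation
(`combo_noise = 0.2`).

**Counts.** Per-gene baseline log-expression μ is drawn once from a normal
with SD 1 (a log-normal-like magnitude spread — the reason raw-space
Pearson is uninformative). Condition *p* has expected gene proportions
∝ exp(μ + delta_p); each cell's counts are Poisson around `count_depth`
(default 5,000) times those proportions, optionally Gamma-overdispersed
(negative binomial). Dropout arises naturally from low depth rather than a
separate zero-inflation knob. Defaults of 50 cells per perturbation and
200 control cells reflect the per-condition cell counts of the published
screens at a desk-friendly scale.

**Embeddings.** Target genes of perturbations sharing a pathway receive
the pathway centroid plus Gaussian noise (`embedding_noise = 0.1`); all
other genes receive independent standard-normal vectors (default dimension
32). With one pathway per perturbation the table degenerates to pure noise.

**Determinism.** Deltas, cells and embeddings draw from named sub-streams
(`default_rng([seed, k])`, k = 0, 1, 2) of the config seed; identical
config + seed yields byte-identical outputs.

What the simulator does *not* model: ambient RNA, doublets, batch effects,
cell-cycle structure, or any real dataset's gene-level moments. Passing
tests on synthetic data therefore demonstrate the correctness and the
qualitative dynamics of the harness (metric behavior, heterogeneity/
dynamic-range coupling, featurization value), not performance on any real
screen.

## Problem sizes used in tests and the acceptance script

Unit and property tests run at small sizes (hundreds of genes, ≤ 12
perturbations). The parameter-recovery check uses 2,000 genes × 100
perturbations over 10 seeds (the scale at which the median's sampling
noise is well under the ±0.05 acceptance band). The heterogeneity/dynamic-
range sweep uses 1,000 genes, 60 perturbations, 30 cells per condition at
depth 3,000, 3 seeds per ρ, with models {Train Mean, RF} and an RF grid of
{100, 300} trees: RF is the strongest baseline family here, so the
best-minus-Train-Mean gap is unchanged by adding the weaker regressors,
and these sizes keep the full sweep around a minute while leaving the
Spearman sign unambiguous. The negative control (pure-noise embeddings,
10 seeds) runs at 500 genes × 40 perturbations with one grid point per
regressor, since tuning cannot matter when features carry no signal.

## Known limitations

- Predictions are scored at pseudo-bulk level only; per-cell scoring and
  distributional metrics are out of scope.
- No significance testing between models' scores; the harness reports
  point estimates and leaves inference to the user.
- The external GEARS loader is a thin opt-in shim; it does not reproduce
  the GEARS publication's exact split lists, only the perturbation-
  exclusive property.
- The Elastic Net baseline inherits its default regularization strength;
  with strongly shrunk coefficients it is effectively a second mean-like
  baseline rather than a competitive model.
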