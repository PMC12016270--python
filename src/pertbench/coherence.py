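"""Gene-embedding coherence against curated gene sets.

Are embedding vectors of functionally related genes more similar than
chance? For each gene set (pathway, regulon, ...), the observed mean
pairwise Pearson correlation between member-gene vectors is compared with
its value under a null in which the gene -> vector assignment is shuffled
by a derangement — a permutation with no fixed points, so no gene retains
its own vector. The per-set difference (observed minus null mean) is
summarized across sets by its mean and a 95% t-interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .embeddings import EmbeddingTable, restrict_to_common_genes  # noqa: F401  (re-export)


def within_set_similarity(emb: EmbeddingTable, gene_set) -> float:
    """Mean pairwise Pearson correlation between member-gene vectors.

    Members absent from the table are ignored; fewer than 2 present
    members, or no defined pair (constant vectors), yields NaN.
    """
    members = [g for g in gene_set if g in emb]
    if len(members) < 2:
        return float("nan")
    V = np.vstack([emb.vector(g) for g in members])
    if V.shape[1] < 3:
        raise ValueError("embedding dimension must be >= 3 for non-degenerate correlations")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(V)
    iu = np.triu_indices(len(members), k=1)
    vals = corr[iu]
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def derangement(n_or_keys, rng=None, seed: int | None = None) -> np.ndarray:
    """Sample a fixed-point-free permutation by rejection.

    Accepts a count or a sequence of keys; returns the permuted index
    array (``out[i]`` is the source index assigned to position ``i``,
    with ``out[i] != i`` for all ``i``). Rejection from uniform random
    permutations keeps resampling until no fixed point remains; a single
    key admits no derangement and is an error.
    """
    n = n_or_keys if isinstance(n_or_keys, (int, np.integer)) else len(n_or_keys)
    if n < 2:
        raise ValueError("a derangement needs at least 2 keys")
    if rng is None:
        rng = np.random.default_rng(seed)
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


@dataclass
class CoherenceResult:
    """Per-set and collection-level embedding-coherence statistics.

    ``per_set`` columns: set, n_genes, observed, null_mean, delta.
    ``mean_delta`` with its 95% t-confidence interval summarizes the
    collection; ``skipped`` lists sets below the minimum-size threshold.
    """

    per_set: pd.DataFrame
    mean_delta: float
    ci_low: float
    ci_high: float
    n_permutations: int
    seed: int
    source: str = "unknown"
    skipped: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "source": self.source,
            "n_sets": int(self.per_set.shape[0]),
            "n_skipped": len(self.skipped),
            "mean_delta": self.mean_delta,
            "ci95": [self.ci_low, self.ci_high],
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def coherence_test(
    emb: EmbeddingTable,
    gene_sets: dict[str, list[str]],
    n_permutations: int = 100,
    min_set_size: int = 2,
    seed: int = 0,
) -> CoherenceResult:
    """Embedding coherence of a gene-set collection vs. a derangement null.

    For every permutation draw, one global derangement of the gene ->
    vector assignment is applied across the whole embedding table and all
    sets are re-scored; the per-set null mean averages the draws. The
    per-set delta is observed minus null mean; the collection-level mean
    delta carries a 95% t-interval over the per-set deltas.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if min_set_size < 2:
        raise ValueError("min_set_size must be >= 2")
    rng = np.random.default_rng(seed)
    present = set(emb.genes)
    usable: dict[str, list[str]] = {}
    skipped: list[str] = []
    for name in sorted(gene_sets):
        members = sorted(set(gene_sets[name]) & present)
        if len(members) >= min_set_size:
            usable[name] = members
        else:
            skipped.append(name)
    if not usable:
        raise ValueError("no usable gene set after size filtering")

    observed = {name: within_set_similarity(emb, members) for name, members in usable.items()}

    null_sums = {name: 0.0 for name in usable}
    null_counts = {name: 0 for name in usable}
    for _ in range(n_permutations):
        perm = derangement(len(emb), rng=rng)
        shuffled = EmbeddingTable(emb.genes, emb.vectors[perm], source=emb.source)
        for name, members in usable.items():
            val = within_set_similarity(shuffled, members)
            if not np.isnan(val):
                null_sums[name] += val
                null_counts[name] += 1

    rows = []
    for name, members in usable.items():
        null_mean = null_sums[name] / null_counts[name] if null_counts[name] else float("nan")
        obs = observed[name]
        rows.append(
            {
                "set": name,
                "n_genes": len(members),
                "observed": obs,
                "null_mean": null_mean,
                "delta": obs - null_mean,
            }
        )
    per_set = pd.DataFrame(rows)
    deltas = per_set["delta"].dropna().to_numpy()
    if deltas.size == 0:
        raise ValueError("no defined per-set delta")
    mean_delta = float(deltas.mean())
    if deltas.size > 1 and deltas.std(ddof=1) > 0:
        ci_low, ci_high = stats.t.interval(
            0.95, df=deltas.size - 1, loc=mean_delta, scale=stats.sem(deltas)
        )
    else:
        ci_low = ci_high = mean_delta
    return CoherenceResult(
        per_set=per_set,
        mean_delta=mean_delta,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_permutations=n_permutations,
        seed=seed,
        source=emb.source,
        skipped=skipped,
    )
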