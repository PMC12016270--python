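"""Dataset-heterogeneity diagnostics.

How diverse are a screen's transcriptional responses? The pairwise Pearson
correlations between per-perturbation delta profiles answer this: a high
median correlation means perturbations elicit similar responses (low
heterogeneity), which inflates the Train Mean baseline and compresses the
benchmark's dynamic range — the Pearson-delta gap between the best model
and Train Mean. Homogeneous screens therefore cannot discriminate between
models; heterogeneous ones can.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import BenchmarkResult


@dataclass
class HeterogeneityReport:
    """Pairwise delta-correlation structure of one dataset.

    ``correlations`` is the symmetric perturbations x perturbations Pearson
    matrix (diagonal 1); ``median`` is taken over the strict upper triangle,
    each unordered pair counted once, undefined pairs excluded.
    ``split_boundary`` optionally records the train/test separator index
    used when rows are ordered train block first.
    """

    correlations: pd.DataFrame
    median: float
    offdiag: np.ndarray
    n_pairs: int
    n_undefined: int
    split_boundary: int | None = None

    def summary(self) -> dict:
        return {
            "median_pairwise_correlation": self.median,
            "n_perturbations": int(self.correlations.shape[0]),
            "n_pairs": self.n_pairs,
            "n_undefined_pairs": self.n_undefined,
        }


def pairwise_delta_correlations(
    deltas: pd.DataFrame,
    order: list[str] | None = None,
    split_boundary: int | None = None,
) -> HeterogeneityReport:
    """Pearson correlation between every pair of delta profiles.

    ``order`` optionally reorders rows (e.g. train block then test block
    for heatmap partitioning, with ``split_boundary`` the separator index);
    the median is invariant to ordering. Zero-variance delta rows yield
    undefined pairs, which are excluded from the median and counted.
    """
    if order is not None:
        deltas = deltas.loc[order]
    P, G = deltas.shape
    if P < 2:
        raise ValueError("need at least 2 perturbations")
    if G < 3:
        raise ValueError("need at least 3 genes")
    X = deltas.to_numpy(dtype=float)
    sd = X.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(X)
    corr[np.arange(P), np.arange(P)] = 1.0
    degenerate = sd == 0
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    corr[np.arange(P), np.arange(P)] = 1.0
    iu = np.triu_indices(P, k=1)
    offdiag = corr[iu]
    defined = offdiag[~np.isnan(offdiag)]
    if defined.size == 0:
        raise ValueError("no defined perturbation pair: all delta rows are constant")
    return HeterogeneityReport(
        correlations=pd.DataFrame(corr, index=deltas.index, columns=deltas.index),
        median=float(np.median(defined)),
        offdiag=offdiag,
        n_pairs=int(offdiag.size),
        n_undefined=int(np.isnan(offdiag).sum()),
        split_boundary=split_boundary,
    )


def dynamic_range(result: BenchmarkResult, baseline: str = "train_mean",
                  metric: str = "pearson_delta") -> float:
    """Benchmark dynamic range: best model minus Train Mean, Pearson Delta.

    Positive values mean some model beats the baseline; a gap near zero
    means the dataset cannot distinguish models from the trivial mean
    predictor.
    """
    agg = result.aggregate[result.aggregate["metric"] == metric].set_index("model")["value"]
    if baseline not in agg.index:
        raise ValueError(f"baseline model {baseline!r} missing from result")
    others = agg.drop(index=baseline)
    if others.empty:
        raise ValueError("need at least one non-baseline model")
    return float(max(agg.max(), agg[baseline]) - agg[baseline])


@dataclass
class HeterogeneityRangeTable:
    """Median intra-dataset correlation vs. benchmark dynamic range."""

    table: pd.DataFrame
    spearman: float = field(default=float("nan"))


def heterogeneity_vs_range(
    entries: dict[str, tuple[HeterogeneityReport, BenchmarkResult]],
) -> HeterogeneityRangeTable:
    """Pair each dataset's median delta correlation with its dynamic range.

    Returns one row per dataset and the Spearman rank correlation between
    the two columns; a negative coefficient reproduces the inverse
    relationship between dataset homogeneity and the ability to separate
    models.
    """
    if len(entries) < 2:
        raise ValueError("need at least 2 datasets to relate heterogeneity and range")
    rows = [
        {"dataset": name, "median_correlation": rep.median, "gap": dynamic_range(res)}
        for name, (rep, res) in entries.items()
    ]
    table = pd.DataFrame(rows).set_index("dataset")
    rho = stats.spearmanr(table["median_correlation"], table["gap"]).statistic
    return HeterogeneityRangeTable(table=table, spearman=float(rho))
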