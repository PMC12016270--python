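"""Benchmark evaluation metrics on pseudo-bulk profiles.

Four Pearson-correlation metrics per test perturbation:

* ``pearson`` — raw correlation between predicted and observed
  post-perturbation pseudo-bulk expression. Dominated by baseline
  expression magnitude, reported for completeness.
* ``pearson_delta`` — correlation between predicted and observed
  differential profiles (post minus control); the headline metric.
* ``pearson_delta_de`` — pearson_delta restricted to the top-K (default
  20) differentially expressed genes of that perturbation.
* ``pearson_delta_no_target`` — the top-K variant with the CRISPR target
  gene(s) excluded from the list (refilled to K).

Undefined correlations (zero variance in either vector, e.g. a constant
predicted delta) are surfaced as NaN and counted, never coerced to 0;
aggregation is the unweighted mean over the defined per-perturbation
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PerturbDataset, SplitSpec, delta_profiles, pseudobulk
from .de import rank_genes, top_k_de

METRICS = ("pearson", "pearson_delta", "pearson_delta_de", "pearson_delta_no_target")


def pearson(x, y) -> float:
    """Pearson product-moment correlation; NaN when either side is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(xc @ xc))
    sy = float(np.sqrt(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def pearson_delta(pred, true, control) -> float:
    """Correlation of predicted vs. observed differential profiles."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    control = np.asarray(control, dtype=float)
    return pearson(pred - control, true - control)


def pearson_delta_de(pred, true, control, de_genes, gene_index: pd.Index) -> float:
    """pearson_delta restricted to the columns of ``de_genes``.

    Fewer than 3 usable genes leaves the correlation undefined (NaN).
    """
    de_genes = list(de_genes)
    missing = [g for g in de_genes if g not in gene_index]
    if missing:
        raise KeyError(f"DE genes absent from panel: {missing[:3]}")
    if len(de_genes) < 3:
        return float("nan")
    idx = gene_index.get_indexer(de_genes)
    pred = np.asarray(pred, dtype=float)[idx]
    true = np.asarray(true, dtype=float)[idx]
    control = np.asarray(control, dtype=float)[idx]
    return pearson(pred - control, true - control)


@dataclass
class BenchmarkResult:
    """Per-model, per-perturbation metric table plus aggregates.

    ``per_perturbation`` is long-format (model, perturbation, subgroup,
    metric, value); ``aggregate`` is the unweighted mean over defined
    values per (model, metric). ``provenance`` records the DE method,
    K, exclusion flag, seeds and the count of undefined correlations.
    """

    per_perturbation: pd.DataFrame
    aggregate: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def score(self, model: str, metric: str = "pearson_delta") -> float:
        sel = self.aggregate[
            (self.aggregate["model"] == model) & (self.aggregate["metric"] == metric)
        ]["value"]
        if sel.empty:
            raise KeyError(f"no aggregate for model={model!r}, metric={metric!r}")
        return float(sel.iloc[0])

    @property
    def models(self) -> list[str]:
        return sorted(self.aggregate["model"].unique())


def evaluate(
    predictions: dict[str, pd.DataFrame],
    ds: PerturbDataset,
    split: SplitSpec,
    de_method: str = "t_test",
    k: int = 20,
    provenance: dict | None = None,
) -> BenchmarkResult:
    """Score model predictions on the test perturbations of a split.

    ``predictions`` maps model name -> DataFrame of predicted post-
    perturbation pseudo-bulk profiles (rows = test perturbations, columns
    = gene names aligned with the dataset). The observed pseudo-bulk of
    the dataset provides both the ground truth and the control row; one
    top-K DE list per perturbation is computed from the observed cells
    and applied to every model, with the no-target variant excluding that
    perturbation's CRISPR target gene(s) from the list.
    """
    pb = pseudobulk(ds)
    control_row = pb.loc[ds.control].to_numpy()
    gene_index = pb.columns
    test = list(split.test)
    targets = ds.perturbation_targets

    for model, pred in predictions.items():
        missing = [p for p in test if p not in pred.index]
        if missing:
            raise ValueError(f"model {model!r} lacks predictions for: {missing}")

    de_lists: dict[str, list[str]] = {}
    de_lists_nt: dict[str, list[str]] = {}
    for p in test:
        ranking = rank_genes(ds, p, method=de_method)
        de_lists[p] = top_k_de(ranking, k=k)
        de_lists_nt[p] = top_k_de(ranking, k=k, exclude_targets=True, target_genes=targets[p])

    rows = []
    for model, pred in predictions.items():
        for p in test:
            true_row = pb.loc[p].to_numpy()
            pred_row = pred.loc[p].reindex(gene_index).to_numpy() if isinstance(pred, pd.DataFrame) else pred.loc[p]
            values = {
                "pearson": pearson(pred_row, true_row),
                "pearson_delta": pearson_delta(pred_row, true_row, control_row),
                "pearson_delta_de": pearson_delta_de(
                    pred_row, true_row, control_row, de_lists[p], gene_index
                ),
                "pearson_delta_no_target": pearson_delta_de(
                    pred_row, true_row, control_row, de_lists_nt[p], gene_index
                ),
            }
            for metric, value in values.items():
                rows.append(
                    {
                        "model": model,
                        "perturbation": p,
                        "subgroup": split.subgroups.get(p, ""),
                        "metric": metric,
                        "value": value,
                    }
                )
    per_pert = pd.DataFrame(rows)
    n_undefined = int(per_pert["value"].isna().sum())
    aggregate = (
        per_pert.groupby(["model", "metric"], sort=True)["value"]
        .mean()  # pandas mean skips NaN: undefined values are excluded, not zeroed
        .reset_index()
    )
    prov = {
        "de_method": de_method,
        "top_k": k,
        "split_seed": split.seed,
        "control": ds.control,
        "n_test": len(test),
        "n_undefined": n_undefined,
    }
    prov.update(provenance or {})
    return BenchmarkResult(per_perturbation=per_pert, aggregate=aggregate, provenance=prov)


__all__ = [
    "METRICS",
    "BenchmarkResult",
    "pearson",
    "pearson_delta",
    "pearson_delta_de",
    "evaluate",
    "delta_profiles",
]
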