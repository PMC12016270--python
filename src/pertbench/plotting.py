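"""Figure writers for the diagnostics and coherence analyses.

All functions write straight to disk with the non-interactive Agg backend;
they are conveniences over matplotlib, not a plotting API.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .coherence import CoherenceResult
from .diagnostics import HeterogeneityRangeTable, HeterogeneityReport


def heterogeneity_heatmap(report: HeterogeneityReport, path: str | Path) -> None:
    """Pairwise delta-correlation heatmap, train/test separator drawn if known."""
    corr = report.correlations
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    if report.split_boundary is not None:
        for b in (report.split_boundary - 0.5,):
            ax.axhline(b, color="black", lw=1)
            ax.axvline(b, color="black", lw=1)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"pairwise delta correlations (median {report.median:.3f})")
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def correlation_violin(reports: dict[str, HeterogeneityReport], path: str | Path) -> None:
    """Distribution of pairwise delta correlations per dataset."""
    names = list(reports)
    data = [reports[n].offdiag[~np.isnan(reports[n].offdiag)] for n in names]
    fig, ax = plt.subplots(figsize=(1.5 * len(names) + 2, 4))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(names) + 1), names, rotation=30, ha="right")
    ax.set_ylabel("pairwise Pearson r of delta profiles")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def heterogeneity_range_scatter(table: HeterogeneityRangeTable, path: str | Path) -> None:
    """Median intra-dataset correlation vs. benchmark dynamic range."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, row in table.table.iterrows():
        ax.scatter(row["median_correlation"], row["gap"], label=str(name))
    ax.set_xlabel("median intra-dataset correlation")
    ax.set_ylabel("best model − Train Mean (Pearson Delta)")
    ax.set_title(f"Spearman ρ = {table.spearman:.2f}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def coherence_bars(results: dict[str, CoherenceResult], path: str | Path) -> None:
    """Mean within-set coherence delta per embedding with 95% CI bars."""
    names = list(results)
    means = [results[n].mean_delta for n in names]
    errs = [
        (results[n].mean_delta - results[n].ci_low, results[n].ci_high - results[n].mean_delta)
        for n in names
    ]
    fig, ax = plt.subplots(figsize=(1.2 * len(names) + 2, 4))
    ax.bar(names, means, yerr=np.array(errs).T, capsize=4)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylabel("mean within-set Pearson delta (obs − null)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
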