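"""Per-perturbation differential-expression ranking and top-K selection.

Each perturbation's cells are compared with control cells gene-by-gene
using either a Welch (unequal-variance) t-test or a Wilcoxon rank-sum
test. Genes are ranked by ascending p-value, ties broken by descending
|statistic| and then lexicographic gene name, which makes the ordering
fully deterministic. The top-K list (K = 20 in the standard benchmark)
optionally excludes the CRISPR target gene(s) and is refilled from the
remaining ranking so the list keeps length K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import PerturbDataset

METHODS = ("t_test", "wilcoxon")

# Below this per-group size (and with no ties) the Wilcoxon p-value is the
# exact enumeration over rank assignments rather than the normal
# approximation with tie correction.
WILCOXON_EXACT_MAX_N = 8


@dataclass
class DERanking:
    """Ordered differential-expression table for one perturbation.

    ``table`` has one row per tested gene, sorted by the ranking key, with
    columns ``gene``, ``statistic`` (signed; positive means higher in the
    perturbed group) and ``pvalue``.
    """

    perturbation: str
    method: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        p = self.table["pvalue"].to_numpy()
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])


def _welch(pert: np.ndarray, ctrl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(pert, ctrl, axis=0, equal_var=False)
        stat, pval = np.asarray(res.statistic, dtype=float), np.asarray(res.pvalue, dtype=float)
    # Degenerate rule for zero pooled variance: means differ -> signed
    # infinity with p = 0 (maximally significant); identical constants ->
    # statistic 0, p = 1.
    bad = ~np.isfinite(stat) | ~np.isfinite(pval)
    if np.any(bad):
        diff = pert.mean(axis=0) - ctrl.mean(axis=0)
        stat = np.where(bad, np.where(diff != 0, np.sign(diff) * np.inf, 0.0), stat)
        pval = np.where(bad, np.where(diff != 0, 0.0, 1.0), pval)
    return stat, pval


def _wilcoxon(pert: np.ndarray, ctrl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n1, n2 = len(pert), len(ctrl)
    center = n1 * n2 / 2.0
    if max(n1, n2) <= WILCOXON_EXACT_MAX_N:
        stat = np.empty(pert.shape[1])
        pval = np.empty(pert.shape[1])
        for j in range(pert.shape[1]):
            a, b = pert[:, j], ctrl[:, j]
            ties = len(np.unique(np.concatenate([a, b]))) < n1 + n2
            if np.all(a == a[0]) and np.all(b == a[0]):
                stat[j], pval[j] = 0.0, 1.0
                continue
            method = "asymptotic" if ties else "exact"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            stat[j], pval[j] = res.statistic - center, res.pvalue
        return stat, pval
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.mannwhitneyu(pert, ctrl, axis=0, alternative="two-sided", method="asymptotic")
    stat = np.asarray(res.statistic, dtype=float) - center
    pval = np.asarray(res.pvalue, dtype=float)
    constant = np.all(pert == pert[:1], axis=0) & np.all(ctrl == pert[:1], axis=0)
    stat = np.where(constant, 0.0, stat)
    pval = np.where(constant | ~np.isfinite(pval), 1.0, pval)
    return stat, pval


def rank_genes(
    ds: PerturbDataset,
    perturbation: str,
    control_label: str | None = None,
    method: str = "t_test",
) -> DERanking:
    """Rank all genes by two-sided differential expression vs. control.

    Requires log-normalized data and at least two cells per group. The
    Welch t-test does not assume equal group variances; the Wilcoxon
    rank-sum test uses exact enumeration for tie-free groups of at most
    8 cells each and the tie-corrected normal approximation otherwise.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if not ds.normalized:
        raise ValueError("rank_genes expects log-normalized data")
    control_label = control_label or ds.control
    pert = ds.cells_for(perturbation)
    ctrl = ds.cells_for(control_label)
    if len(pert) < 2 or len(ctrl) < 2:
        raise ValueError(
            f"need >= 2 cells per group, got {len(pert)} perturbed / {len(ctrl)} control"
        )
    stat, pval = (_welch if method == "t_test" else _wilcoxon)(pert, ctrl)
    genes = ds.gene_names.astype(str)
    order = np.lexsort((genes, -np.abs(stat), pval))
    table = pd.DataFrame(
        {"gene": genes[order], "statistic": stat[order], "pvalue": pval[order]}
    ).reset_index(drop=True)
    return DERanking(perturbation=perturbation, method=method, table=table)


def top_k_de(
    ranking: DERanking,
    k: int = 20,
    exclude_targets: bool = False,
    target_genes=(),
) -> list[str]:
    """First ``k`` genes of a ranking, optionally excluding CRISPR targets.

    With ``exclude_targets`` the target gene(s) are removed before cutting,
    so the list is refilled to length ``k`` from the remaining ranking
    whenever enough genes exist. Asking for more genes than the panel has
    returns the full (filtered) ranking with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    genes = ranking.genes
    if exclude_targets:
        targets = set(target_genes)
        genes = [g for g in genes if g not in targets]
    if k > len(genes):
        warnings.warn(
            f"requested top {k} genes but only {len(genes)} available; returning all",
            stacklevel=2,
        )
        return genes
    return genes[:k]
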