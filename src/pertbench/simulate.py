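"""Synthetic Perturb-seq generator with controllable heterogeneity.

The generator produces three linked artifacts:

* ground-truth log-space delta profiles whose pairwise Pearson correlation
  is controlled analytically by a shared/private mixture,
* single-cell count data whose per-condition expected expression follows
  those deltas on top of a common baseline, and
* gene embeddings whose similarity structure is informative about response
  similarity through a shared pathway assignment.

Delta construction: for a single perturbation *p* in pathway *k*,

    delta_p = delta_scale * ( sqrt(rho) * s  +  sqrt(1-rho) * u_p ),
    u_p     = sqrt(w) * c_k + sqrt(1-w) * e_p,

with ``s`` (global), ``c_k`` (per pathway) and ``e_p`` (per perturbation)
independent standard-normal gene vectors. Two perturbations from different
pathways then correlate at exactly ``rho`` in expectation, while
same-pathway pairs correlate at ``rho + (1-rho)*w``; since same-pathway
pairs are a small minority, the median pairwise correlation recovers
``rho``. The pathway component is what makes pathway-informative embeddings
predictive of the response, mirroring how functional gene annotations carry
signal about perturbation outcomes in real screens.

A signed target-gene effect (negative = CRISPRi-like knockdown, positive =
CRISPRa-like activation) is imposed on each perturbation's own target gene.
Combos sum their components' deltas plus a small combo-specific deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import COMBO_SEP, CONTROL_LABEL, PerturbDataset
from .embeddings import EmbeddingTable


@dataclass
class SimConfig:
    """Parameters of one synthetic Perturb-seq study.

    Attributes
    ----------
    n_genes, n_perturbations, n_combos
        Panel size, number of single perturbations, and number of dual
        ("A+B") perturbations built from random pairs of the singles.
    cells_per_condition, control_cells
        Cells sequenced per perturbation and for the control pool.
    shared_fraction
        rho in [0, 1]: mixing weight of the shared response component;
        equals the expected cross-pathway pairwise delta correlation.
    delta_scale
        Standard deviation of per-gene log-space effects.
    target_effect
        Signed log-space shift imposed on each perturbation's target gene;
        negative mimics CRISPRi knockdown, positive CRISPRa activation.
    target_mode
        "overwrite" (default) replaces the target gene's delta entry with
        ``target_effect``; "additive" adds it instead.
    count_depth, overdispersion
        Expected reads per cell; Poisson counts when overdispersion is 0,
        otherwise negative-binomial via per-entry Gamma rate multipliers
        with variance ``overdispersion``.
    baseline_log_sd
        SD of per-gene baseline log-expression (log-normal-like spread of
        expression magnitudes; this is what makes raw-space Pearson
        uninformatively high).
    n_pathways, pathway_strength
        Number of simulated pathways and the weight ``w`` of the shared
        within-pathway response component.
    embedding_dim, embedding_noise
        Dimension of synthetic gene embeddings and the SD of the noise
        added to the pathway centroid for target genes.
    combo_noise
        Scale of the combo-specific deviation added to summed components.
    """

    n_genes: int = 2000
    n_perturbations: int = 100
    n_combos: int = 0
    cells_per_condition: int = 50
    control_cells: int = 200
    shared_fraction: float = 0.4
    delta_scale: float = 0.5
    target_effect: float = -3.0
    target_mode: str = "overwrite"
    count_depth: float = 5000.0
    overdispersion: float = 0.0
    baseline_log_sd: float = 1.0
    n_pathways: int = 10
    pathway_strength: float = 0.5
    embedding_dim: int = 32
    embedding_noise: float = 0.1
    combo_noise: float = 0.2
    control_label: str = CONTROL_LABEL
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must lie in [0, 1]")
        if not 0.0 <= self.pathway_strength <= 1.0:
            raise ValueError("pathway_strength must lie in [0, 1]")
        if min(self.n_genes, self.cells_per_condition) < 1 or self.n_perturbations < 0:
            raise ValueError("n_genes, cells_per_condition must be >= 1; n_perturbations >= 0")
        if self.count_depth <= 0:
            raise ValueError("count_depth must be positive")
        if self.n_combos and self.n_perturbations < 2:
            raise ValueError("combos require at least 2 single perturbations")
        if self.target_mode not in ("overwrite", "additive"):
            raise ValueError("target_mode must be 'overwrite' or 'additive'")
        if self.n_pathways < 1 or self.n_pathways > max(self.n_perturbations, 1):
            if self.n_pathways > self.n_genes:
                raise ValueError("n_pathways cannot exceed n_genes")

    def rng(self, stream: int) -> np.random.Generator:
        """Named sub-stream of the config seed (0=deltas, 1=cells, 2=embeddings)."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """True log-space delta profiles plus pathway and target bookkeeping."""

    deltas: pd.DataFrame  # perturbations x genes, log space
    targets: dict[str, tuple[str, ...]]
    pathways: dict[str, int]  # single-perturbation label -> pathway id
    config: SimConfig = field(repr=False, default=None)

    @property
    def labels(self) -> list[str]:
        return list(self.deltas.index)

    def pathway_gene_sets(self) -> dict[str, list[str]]:
        """Pathway id -> member target genes, as a GMT-ready mapping."""
        sets: dict[str, list[str]] = {}
        for label, k in self.pathways.items():
            sets.setdefault(f"pathway_{k}", []).append(self.targets[label][0])
        return {name: sorted(genes) for name, genes in sorted(sets.items())}


def _gene_names(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.asarray([f"G{i:0{width}d}" for i in range(n)], dtype=object)


def simulate_deltas(cfg: SimConfig) -> GroundTruth:
    """Draw ground-truth delta profiles under the shared/private mixture."""
    rng = cfg.rng(0)
    genes = _gene_names(cfg.n_genes)
    rho, w = cfg.shared_fraction, cfg.pathway_strength
    n_pathways = min(cfg.n_pathways, max(cfg.n_perturbations, 1))

    target_idx = rng.choice(cfg.n_genes, size=cfg.n_perturbations, replace=False)
    labels = [str(genes[i]) for i in target_idx]
    pathway_of = {lab: int(i % n_pathways) for i, lab in enumerate(labels)}

    s = rng.standard_normal(cfg.n_genes)
    centroids = rng.standard_normal((n_pathways, cfg.n_genes))
    rows, targets = {}, {}
    for lab, g_idx in zip(labels, target_idx):
        e = rng.standard_normal(cfg.n_genes)
        u = np.sqrt(w) * centroids[pathway_of[lab]] + np.sqrt(1.0 - w) * e
        delta = cfg.delta_scale * (np.sqrt(rho) * s + np.sqrt(1.0 - rho) * u)
        # target_effect 0 means "no target-gene modification", so a zero
        # effect never erases the gene's share of the shared response
        if cfg.target_effect != 0.0:
            if cfg.target_mode == "overwrite":
                delta[g_idx] = cfg.target_effect
            else:
                delta[g_idx] += cfg.target_effect
        rows[lab] = delta
        targets[lab] = (lab,)

    if cfg.n_combos:
        pairs = set()
        while len(pairs) < min(cfg.n_combos, len(labels) * (len(labels) - 1) // 2):
            a, b = rng.choice(len(labels), size=2, replace=False)
            pairs.add(tuple(sorted((int(a), int(b)))))
        for a, b in sorted(pairs):
            la, lb = labels[a], labels[b]
            lab = f"{la}{COMBO_SEP}{lb}"
            u_c = rng.standard_normal(cfg.n_genes)
            delta = rows[la] + rows[lb] + cfg.delta_scale * cfg.combo_noise * u_c
            if cfg.target_effect != 0.0:
                for comp in (la, lb):
                    g = int(np.where(genes == comp)[0][0])
                    if cfg.target_mode == "overwrite":
                        delta[g] = cfg.target_effect
                    else:
                        delta[g] = rows[comp][g]
            rows[lab] = delta
            targets[lab] = (la, lb)

    values = (
        np.vstack([rows[lab] for lab in rows]) if rows else np.empty((0, cfg.n_genes))
    )
    deltas = pd.DataFrame(
        values,
        index=pd.Index(list(rows), name="perturbation"),
        columns=pd.Index(genes, name="gene"),
    )
    return GroundTruth(deltas=deltas, targets=targets, pathways=pathway_of, config=cfg)


def simulate_cells(cfg: SimConfig, truth: GroundTruth) -> PerturbDataset:
    """Draw per-cell counts whose expected proportions follow the true deltas.

    A baseline log-expression ``mu`` is drawn once; condition ``p`` has
    expected gene proportions proportional to ``exp(mu + delta_p)`` and each
    cell's counts are Poisson (optionally Gamma-overdispersed) around
    ``count_depth`` times those proportions. Control cells use delta = 0.
    """
    rng = cfg.rng(1)
    genes = truth.deltas.columns.to_numpy(dtype=object)
    mu = cfg.baseline_log_sd * rng.standard_normal(cfg.n_genes)

    blocks, labels = [], []
    conditions = [(cfg.control_label, cfg.control_cells)] + [
        (lab, cfg.cells_per_condition) for lab in truth.labels
    ]
    for lab, n_cells in conditions:
        if n_cells < 1:
            continue
        log_rate = mu if lab == cfg.control_label else mu + truth.deltas.loc[lab].to_numpy()
        props = np.exp(log_rate - log_rate.max())
        props /= props.sum()
        lam = np.broadcast_to(cfg.count_depth * props, (n_cells, cfg.n_genes))
        if cfg.overdispersion > 0:
            shape = 1.0 / cfg.overdispersion
            lam = lam * rng.gamma(shape, scale=1.0 / shape, size=lam.shape)
        blocks.append(rng.poisson(lam))
        labels.extend([lab] * n_cells)
    matrix = np.vstack(blocks).astype(float)
    return PerturbDataset(
        matrix=matrix,
        conditions=np.asarray(labels, dtype=object),
        gene_names=genes,
        control=cfg.control_label,
        normalized=False,
    )


def simulate_embeddings(cfg: SimConfig, truth: GroundTruth) -> EmbeddingTable:
    """Gene embeddings that encode the simulated pathway structure.

    Target genes of perturbations sharing a pathway receive the pathway
    centroid plus ``embedding_noise`` Gaussian noise; all other genes get
    independent standard-normal vectors. With noise 0, same-pathway target
    genes share identical vectors; with one pathway per perturbation the
    table degenerates to independent vectors.
    """
    rng = cfg.rng(2)
    genes = truth.deltas.columns.to_numpy(dtype=object)
    vectors = rng.standard_normal((cfg.n_genes, cfg.embedding_dim))
    n_pathways = max(truth.pathways.values(), default=-1) + 1
    centroids = rng.standard_normal((max(n_pathways, 1), cfg.embedding_dim))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for lab, k in truth.pathways.items():
        g = gene_pos[truth.targets[lab][0]]
        vectors[g] = centroids[k] + cfg.embedding_noise * rng.standard_normal(cfg.embedding_dim)
    return EmbeddingTable(genes=genes, vectors=vectors, source="synthetic")


def simulate_study(cfg: SimConfig) -> tuple[PerturbDataset, GroundTruth, EmbeddingTable]:
    """Convenience wrapper: deltas, cells and embeddings from one config."""
    truth = simulate_deltas(cfg)
    ds = simulate_cells(cfg, truth)
    emb = simulate_embeddings(cfg, truth)
    return ds, truth, emb


def write_study(outdir: str | Path, cfg: SimConfig, fmt: str = "csv") -> dict[str, Path]:
    """Simulate a study and write all artifacts under ``outdir``.

    Writes the cell-level dataset (CSV or h5ad), the ground-truth deltas
    (CSV), the matched embeddings (TSV), the pathway gene sets (GMT), and
    the echoed config (YAML). Returns the path of each artifact.
    """
    import yaml

    from . import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds, truth, emb = simulate_study(cfg)
    paths = {}
    if fmt == "h5ad":
        paths["dataset"] = outdir / "dataset.h5ad"
        ds.to_anndata().write_h5ad(paths["dataset"])
    else:
        paths["dataset"] = outdir / "dataset.csv"
        pio.write_dataset_csv(ds, paths["dataset"])
    paths["true_deltas"] = outdir / "true_deltas.csv"
    truth.deltas.to_csv(paths["true_deltas"])
    paths["embeddings"] = outdir / "embeddings.tsv"
    pio.write_embeddings_tsv(emb, paths["embeddings"])
    paths["pathways"] = outdir / "pathways.gmt"
    pio.write_gmt(truth.pathway_gene_sets(), paths["pathways"])
    paths["config"] = outdir / "sim_config.yaml"
    paths["config"].write_text(yaml.safe_dump(cfg.__dict__, sort_keys=True))
    return paths
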