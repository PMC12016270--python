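"""End-to-end benchmark orchestration.

`run_benchmark` ties the stages together: load or simulate a dataset,
normalize, pseudo-bulk, delta profiles, perturbation-exclusive split,
per-perturbation DE lists, baseline fitting and prediction, the four
metrics, and the heterogeneity diagnostics — with every seed and decision
recorded so a run is reconstructible from its output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .baselines import (
    DEFAULT_GRIDS,
    MODEL_KINDS,
    featurize,
    fit_regressor,
    fit_train_mean,
)
from .coherence import CoherenceResult, coherence_test
from .core import PerturbDataset, SplitSpec, delta_profiles, make_split, normalize_counts, pseudobulk
from .diagnostics import HeterogeneityReport, dynamic_range, pairwise_delta_correlations
from .embeddings import EmbeddingTable
from .metrics import BenchmarkResult, evaluate
from .simulate import SimConfig, simulate_cells, simulate_deltas, simulate_embeddings

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one benchmark run.

    Exactly one dataset source is used: a synthetic ``sim`` config, or a
    ``dataset_path`` (h5ad / CSV decided by suffix). Embeddings come from
    ``embedding_path`` (TSV), a GMT collection turned into a binary
    membership matrix (``gmt_path``), or the simulator's matched synthetic
    embeddings when ``sim`` is given.
    """

    sim: SimConfig | None = None
    dataset_path: str | None = None
    condition_key: str = "condition"
    dataset_normalized: bool = False
    embedding_path: str | None = None
    gmt_path: str | None = None
    models: tuple[str, ...] = ("train_mean", "rf")
    de_method: str = "t_test"
    top_k: int = 20
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    n_components: int = 256
    grids: dict = field(default_factory=dict)
    missing_policy: str = "drop"
    seed: int = 0
    outdir: str | None = None
    figures: bool = False

    def __post_init__(self) -> None:
        if self.top_k < 3:
            raise ValueError("top_k must be >= 3 for a defined correlation")
        bad = set(self.models) - set(MODEL_KINDS)
        if bad:
            raise ValueError(f"unknown models {sorted(bad)}; choose from {MODEL_KINDS}")
        if (self.sim is None) == (self.dataset_path is None):
            raise ValueError("exactly one of sim / dataset_path must be given")

    def hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = {
            k: (asdict(v) if isinstance(v, SimConfig) else v)
            for k, v in asdict(self).items()
            if k not in ("outdir", "figures")
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class BenchmarkRun:
    """Everything one benchmark run produced."""

    result: BenchmarkResult
    heterogeneity: HeterogeneityReport
    gap: float
    split: SplitSpec
    pseudobulk: pd.DataFrame
    deltas: pd.DataFrame
    config_hash: str


def _load_inputs(cfg: RunConfig) -> tuple[PerturbDataset, EmbeddingTable]:
    if cfg.sim is not None:
        truth = simulate_deltas(cfg.sim)
        ds = simulate_cells(cfg.sim, truth)
        emb = simulate_embeddings(cfg.sim, truth)
        if cfg.embedding_path:
            emb = pio.read_embeddings_tsv(cfg.embedding_path)
        return ds, emb
    path = Path(cfg.dataset_path)
    if path.suffix == ".h5ad":
        ds = pio.read_dataset_h5ad(path, condition_key=cfg.condition_key,
                                   normalized=cfg.dataset_normalized or None)
    else:
        ds = pio.read_dataset_csv(path, normalized=cfg.dataset_normalized)
    if cfg.embedding_path:
        emb = pio.read_embeddings_tsv(cfg.embedding_path)
    elif cfg.gmt_path:
        from .baselines import go_matrix_from_gmt

        emb = go_matrix_from_gmt(pio.read_gmt(cfg.gmt_path), genes=list(ds.gene_names))
    else:
        raise ValueError("embedding_path or gmt_path required for non-synthetic datasets")
    return ds, emb


def run_benchmark(cfg: RunConfig) -> BenchmarkRun:
    """Execute the full benchmark pipeline for one configuration."""
    ds, emb = _load_inputs(cfg)
    run = benchmark_dataset(ds, emb, cfg)
    if cfg.outdir:
        _write_run(cfg, run)
    return run


def benchmark_dataset(ds: PerturbDataset, emb: EmbeddingTable, cfg: RunConfig) -> BenchmarkRun:
    """Benchmark an in-memory dataset against an in-memory embedding table.

    The workhorse behind :func:`run_benchmark`; useful directly when the
    dataset or embeddings are constructed programmatically (e.g. pairing a
    simulated screen with deliberately uninformative embeddings as a
    negative control).
    """
    if not ds.normalized:
        ds = normalize_counts(ds)
    pb = pseudobulk(ds)
    deltas = delta_profiles(pb)
    split = make_split(ds.perturbations, fractions=cfg.fractions, seed=cfg.seed)

    needs_features = any(m != "train_mean" for m in cfg.models)
    features = None
    if needs_features:
        features = featurize(
            emb, ds.perturbations, n_components=cfg.n_components, missing=cfg.missing_policy
        )
        if features.dropped:
            split = _drop_unfeaturizable(split, set(features.dropped))

    train_pb = pb.loc[list(split.train)]
    val_pb = pb.loc[list(split.val)] if split.val else None
    control_row = pb.loc[ds.control].to_numpy()

    predictions: dict[str, pd.DataFrame] = {}
    chosen: dict[str, object] = {}
    for kind in cfg.models:
        if kind == "train_mean":
            model = fit_train_mean(train_pb)
            predictions[kind] = model.predict(split.test)
        else:
            model = fit_regressor(
                features,
                train_pb,
                kind=kind,
                grid=cfg.grids.get(kind, DEFAULT_GRIDS[kind]),
                val_pb=val_pb,
                control_row=control_row,
                seed=cfg.seed,
            )
            chosen[kind] = model.hyperparameter
            predictions[kind] = model.predict(split.test)

    config_hash = cfg.hash()
    result = evaluate(
        predictions,
        ds,
        split,
        de_method=cfg.de_method,
        k=cfg.top_k,
        provenance={
            "config_hash": config_hash,
            "seed": cfg.seed,
            "models": list(cfg.models),
            "chosen_hyperparameters": chosen,
            "embedding_source": emb.source,
        },
    )
    order = list(split.train) + list(split.val) + list(split.test)
    report = pairwise_delta_correlations(
        deltas, order=[p for p in order if p in deltas.index], split_boundary=len(split.train)
    )
    gap = dynamic_range(result) if len(cfg.models) > 1 and "train_mean" in cfg.models else float("nan")
    return BenchmarkRun(
        result=result,
        heterogeneity=report,
        gap=gap,
        split=split,
        pseudobulk=pb,
        deltas=deltas,
        config_hash=config_hash,
    )


def _drop_unfeaturizable(split: SplitSpec, dropped: set) -> SplitSpec:
    warnings.warn(
        f"removing {len(dropped)} unfeaturizable perturbation(s) from the split", stacklevel=2
    )
    return SplitSpec(
        train=tuple(p for p in split.train if p not in dropped),
        val=tuple(p for p in split.val if p not in dropped),
        test=tuple(p for p in split.test if p not in dropped),
        seed=split.seed,
        fractions=split.fractions,
        subgroups={p: t for p, t in split.subgroups.items() if p not in dropped},
    )


def _write_run(cfg: RunConfig, run: BenchmarkRun) -> None:
    import yaml

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = run.result.per_perturbation.copy()
    results["config_hash"] = run.config_hash
    results.to_csv(outdir / "results.csv", index=False)
    pio.write_profile_csv(run.heterogeneity.correlations, outdir / "heterogeneity.csv")
    summary = {
        "config_hash": run.config_hash,
        "seed": cfg.seed,
        "aggregate": run.result.aggregate.to_dict(orient="records"),
        "dynamic_range": None if np.isnan(run.gap) else run.gap,
        "heterogeneity": run.heterogeneity.summary(),
        "split": {
            "train": list(run.split.train),
            "val": list(run.split.val),
            "test": list(run.split.test),
            "subgroups": run.split.subgroups,
        },
        "provenance": run.result.provenance,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    payload = {k: (asdict(v) if isinstance(v, SimConfig) else v) for k, v in asdict(cfg).items()}
    (outdir / "config.yaml").write_text(yaml.safe_dump(payload, sort_keys=True))
    logger.info(
        "benchmark run %s: %d models, %d test perturbations, %d undefined correlations",
        run.config_hash,
        len(cfg.models),
        len(run.split.test),
        run.result.provenance["n_undefined"],
    )
    if cfg.figures:
        from . import plotting

        figdir = outdir / "figures"
        figdir.mkdir(exist_ok=True)
        plotting.heterogeneity_heatmap(run.heterogeneity, figdir / "heterogeneity_heatmap.png")


def run_coherence(
    embedding_paths: dict[str, str],
    gmt_path: str,
    n_permutations: int = 100,
    min_set_size: int = 2,
    seed: int = 0,
    outdir: str | None = None,
    restrict_common: bool = True,
) -> dict[str, CoherenceResult]:
    """Coherence test of one or more embedding tables against a GMT collection.

    With several tables and ``restrict_common``, all are first restricted
    to their common gene set so the comparison is like-for-like. Results
    are written per embedding as CSV (per set) plus a JSON summary.
    """
    from .embeddings import restrict_to_common_genes

    gene_sets = pio.read_gmt(gmt_path)
    tables = {name: pio.read_embeddings_tsv(path, source=name) for name, path in embedding_paths.items()}
    if restrict_common and len(tables) > 1:
        tables, common = restrict_to_common_genes(tables)
        logger.info("restricted %d embeddings to %d common genes", len(tables), len(common))
    results = {
        name: coherence_test(t, gene_sets, n_permutations=n_permutations,
                             min_set_size=min_set_size, seed=seed)
        for name, t in tables.items()
    }
    if outdir:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, res in results.items():
            res.per_set.to_csv(out / f"coherence_{name}.csv", index=False)
        (out / "coherence_summary.json").write_text(
            json.dumps({name: res.summary() for name, res in results.items()}, indent=2)
        )
    return results
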