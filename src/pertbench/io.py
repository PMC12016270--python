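"""Readers and writers for the benchmark's file formats.

Datasets travel as AnnData-on-HDF5 (h5ad) or dense CSV (first column =
condition label, remaining columns = genes); embeddings as TSV (first
column = gene name); gene-set collections as GMT. Pseudo-bulk and delta
matrices are written as CSV with a gene-name header row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import CONTROL_LABEL, PerturbDataset
from .embeddings import EmbeddingTable

# Published cardinalities (cells, distinct perturbations) of the four
# standard Perturb-seq benchmark datasets as distributed by the GEARS
# cell-gears v0.0.1 loader; used only by the opt-in download check.
GEARS_DATASET_SHAPES = {
    "adamson": (68_603, 87),
    "norman": (91_205, 284),
    "replogle_k562_essential": (162_751, 1_093),
    "replogle_rpe1_essential": (162_733, 1_544),
}


def read_dataset_h5ad(
    path: str | Path,
    condition_key: str = "condition",
    control: str = CONTROL_LABEL,
    layer: str | None = None,
    normalized: bool | None = None,
    validate_targets: bool = True,
) -> PerturbDataset:
    """Load a cells x genes dataset from an h5ad file.

    Expression is taken from ``layer`` when given, else from ``X``;
    condition labels from ``obs[condition_key]``. The normalization state
    defaults to the file's ``uns['normalized']`` flag (False if absent).
    """
    import anndata as ad

    adata = ad.read_h5ad(path)
    if condition_key not in adata.obs:
        raise KeyError(f"obs column {condition_key!r} not found in {path}")
    X = adata.layers[layer] if layer else adata.X
    if hasattr(X, "toarray"):
        X = X.toarray()
    if normalized is None:
        normalized = bool(adata.uns.get("normalized", False))
    return PerturbDataset(
        matrix=np.asarray(X, dtype=float),
        conditions=adata.obs[condition_key].astype(str).to_numpy(dtype=object),
        gene_names=adata.var_names.to_numpy(dtype=object),
        control=str(adata.uns.get("control", control)),
        normalized=normalized,
        validate_targets=validate_targets,
    )


def read_dataset_csv(
    path: str | Path,
    control: str = CONTROL_LABEL,
    normalized: bool = False,
    validate_targets: bool = True,
) -> PerturbDataset:
    """Load a dense CSV dataset: first column condition label, then genes."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("dataset CSV needs a condition column plus at least one gene column")
    return PerturbDataset(
        matrix=df.iloc[:, 1:].to_numpy(dtype=float),
        conditions=df.iloc[:, 0].astype(str).to_numpy(dtype=object),
        gene_names=np.asarray(df.columns[1:], dtype=object),
        control=control,
        normalized=normalized,
        validate_targets=validate_targets,
    )


def write_dataset_csv(ds: PerturbDataset, path: str | Path) -> None:
    df = pd.DataFrame(ds.matrix, columns=ds.gene_names)
    df.insert(0, "condition", ds.conditions)
    df.to_csv(path, index=False)


def write_profile_csv(profiles: pd.DataFrame, path: str | Path) -> None:
    """Write a pseudo-bulk or delta matrix with a gene-name header row."""
    profiles.to_csv(path, index=True)


def read_profile_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def read_embeddings_tsv(path: str | Path, source: str | None = None) -> EmbeddingTable:
    """Read a gene-embedding table: TSV with gene id followed by d columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return EmbeddingTable.from_frame(df, source=source or Path(path).stem)


def write_embeddings_tsv(emb: EmbeddingTable, path: str | Path) -> None:
    emb.to_frame().to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection: name, description, member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def load_gears_dataset(
    name: str,
    data_dir: str | Path = "data",
    allow_download: bool = False,
) -> PerturbDataset:
    """Load one of the standard Perturb-seq benchmark datasets via GEARS.

    Requires the ``cell-gears`` package and (on first use) network access
    to download the processed dataset; both are opt-in via
    ``allow_download``. Labels are re-written from the GEARS convention
    (``"A+ctrl"``, ``"A+B"``) to this package's (``"A"``, ``"A+B"``).
    """
    if name not in GEARS_DATASET_SHAPES:
        raise KeyError(f"unknown dataset {name!r}; known: {sorted(GEARS_DATASET_SHAPES)}")
    if not allow_download:
        raise RuntimeError(
            "loading external benchmark datasets requires allow_download=True "
            "(network + cell-gears package); use the synthetic generator for offline work"
        )
    try:
        from gears import PertData
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise RuntimeError(
            "the optional 'cell-gears' package is not installed; "
            "pip install cell-gears==0.0.1 to use the external loader"
        ) from exc
    pert_data = PertData(str(data_dir))
    pert_data.load(data_name=name)
    adata = pert_data.adata
    conditions = (
        adata.obs["condition"]
        .astype(str)
        .str.replace(r"\+ctrl$", "", regex=True)
        .str.replace(r"^ctrl\+", "", regex=True)
        .to_numpy(dtype=object)
    )
    X = adata.X.toarray() if hasattr(adata.X, "toarray") else np.asarray(adata.X)
    return PerturbDataset(
        matrix=np.asarray(X, dtype=float),
        conditions=conditions,
        gene_names=adata.var["gene_name"].to_numpy(dtype=object)
        if "gene_name" in adata.var
        else adata.var_names.to_numpy(dtype=object),
        control="ctrl",
        normalized=True,  # GEARS distributes 10k-normalized, log1p data
        validate_targets=False,
    )
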