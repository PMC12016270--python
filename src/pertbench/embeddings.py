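"""Gene embedding tables: gene -> fixed-length numeric vector.

An :class:`EmbeddingTable` is the common container for all perturbation
featurizations consumed by the baseline models and the coherence analysis:
binary Gene Ontology membership, foundation-model gene embeddings
(scGPT / scFoundation), language-model embeddings (scELMO), or synthetic
embeddings from the bundled simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class EmbeddingTable:
    """Mapping from gene name to a fixed-dimension numeric vector."""

    genes: np.ndarray
    vectors: np.ndarray  # (n_genes, dim)
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be 2-D (genes x dimensions)")
        if len(self.genes) != self.vectors.shape[0]:
            raise ValueError("one vector required per gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene keys must be unique")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding entries must be finite")
        if self.dim == 2:
            warnings.warn(
                "embedding dimension 2 makes pairwise Pearson correlations degenerate (always ±1)",
                stacklevel=2,
            )

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index()

    def _index(self) -> dict[str, int]:
        if not hasattr(self, "_idx"):
            self._idx = {g: i for i, g in enumerate(self.genes)}
        return self._idx

    def vector(self, gene: str) -> np.ndarray:
        try:
            return self.vectors[self._index()[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in embedding table ({self.source})") from None

    def subset(self, genes) -> "EmbeddingTable":
        """Restrict to ``genes`` (order preserved as given)."""
        idx = self._index()
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"{len(missing)} gene(s) missing from embedding table, e.g. {missing[:3]}")
        rows = [idx[g] for g in genes]
        return EmbeddingTable(np.asarray(list(genes), dtype=object), self.vectors[rows], self.source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.vectors, index=pd.Index(self.genes, name="gene"))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source: str = "unknown") -> "EmbeddingTable":
        return cls(df.index.to_numpy(dtype=object), df.to_numpy(dtype=float), source)


def restrict_to_common_genes(tables: dict[str, EmbeddingTable]) -> tuple[dict[str, EmbeddingTable], list[str]]:
    """Restrict several embedding tables to their common gene set.

    Returns the restricted tables (all keyed by the identical, sorted
    intersection) and the intersection itself. An empty intersection is an
    error: no comparison is possible.
    """
    if not tables:
        raise ValueError("at least one embedding table required")
    gene_sets = [set(t.genes) for t in tables.values()]
    common = sorted(set.intersection(*gene_sets))
    if not common:
        raise ValueError("embedding tables share no genes")
    return {name: t.subset(common) for name, t in tables.items()}, common
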