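"""Core data model for Perturb-seq style benchmark datasets.

A :class:`PerturbDataset` holds a cells x genes expression matrix together
with one condition label per cell. Labels are either the control label
(default ``"ctrl"``) or perturbation labels naming the targeted gene(s);
dual perturbations use a separator, e.g. ``"GENE1+GENE2"``.

The module provides the standard preprocessing chain used throughout the
benchmark: library-size normalization to 10,000 reads followed by log1p,
per-condition pseudo-bulk averaging, differential ("delta") profiles
relative to control, perturbation-exclusive train/validation/test splits,
and combo subgroup labelling (combo_seen0/1/2, unseen_single, seen_single).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL_LABEL = "ctrl"
COMBO_SEP = "+"

SUBGROUPS = ("combo_seen0", "combo_seen1", "combo_seen2", "unseen_single", "seen_single")


def parse_perturbation(label: str, sep: str = COMBO_SEP) -> tuple[str, ...]:
    """Split a perturbation label into its 1-2 gene components.

    Raises ``ValueError`` for labels with more than two components: the
    benchmark covers at most dual perturbations.
    """
    parts = tuple(p for p in label.split(sep) if p)
    if not 1 <= len(parts) <= 2:
        raise ValueError(
            f"perturbation label {label!r} has {len(parts)} components; expected 1 or 2"
        )
    return parts


@dataclass
class PerturbDataset:
    """Cells x genes expression matrix with per-cell condition labels.

    Parameters
    ----------
    matrix
        Dense ``(n_cells, n_genes)`` array of raw counts or log-normalized
        expression (see ``normalized``). Entries must be finite and
        nonnegative when ``normalized`` is False.
    conditions
        One label per cell: the control label or a perturbation label.
    gene_names
        Unique identifier per matrix column.
    control
        The reserved control condition label.
    normalized
        Normalization-state marker; True once counts have been depth-
        normalized and log1p-transformed (natural log).
    validate_targets
        When True (default) every perturbation-label component must be a
        known gene name.
    """

    matrix: np.ndarray
    conditions: np.ndarray
    gene_names: np.ndarray
    control: str = CONTROL_LABEL
    normalized: bool = False
    combo_sep: str = COMBO_SEP
    validate_targets: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (cells x genes)")
        n_cells, n_genes = self.matrix.shape
        if len(self.conditions) != n_cells:
            raise ValueError("one condition label required per cell")
        if len(self.gene_names) != n_genes:
            raise ValueError("one gene name required per matrix column")
        if len(set(self.gene_names)) != n_genes:
            raise ValueError("gene_names must be unique")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix entries must be finite")
        if not self.normalized and np.any(self.matrix < 0):
            raise ValueError("count matrix entries must be nonnegative")
        if self.control not in set(self.conditions):
            raise ValueError(f"no cells labelled with control label {self.control!r}")
        if self.validate_targets:
            known = set(self.gene_names)
            for label in self.perturbations:
                for comp in parse_perturbation(label, self.combo_sep):
                    if comp not in known:
                        raise ValueError(
                            f"perturbation {label!r} targets unknown gene {comp!r}"
                        )

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def perturbations(self) -> list[str]:
        """Sorted distinct non-control condition labels."""
        return sorted(set(self.conditions) - {self.control})

    @property
    def perturbation_targets(self) -> dict[str, tuple[str, ...]]:
        """Map perturbation label -> tuple of targeted gene names."""
        return {
            p: parse_perturbation(p, self.combo_sep) for p in self.perturbations
        }

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_names)

    def cells_for(self, condition: str) -> np.ndarray:
        """Row view of the cells belonging to one condition."""
        return self.matrix[self.conditions == condition]

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` with a ``condition`` column."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.matrix.copy(),
            obs=pd.DataFrame({"condition": pd.Categorical(self.conditions.astype(str))}),
            var=pd.DataFrame(index=pd.Index(self.gene_names.astype(str), name="gene")),
        )
        adata.uns["normalized"] = bool(self.normalized)
        adata.uns["control"] = self.control
        return adata


def normalize_counts(ds: PerturbDataset, target_sum: float = 1e4) -> PerturbDataset:
    """Depth-normalize raw counts to ``target_sum`` per cell, then log1p.

    Each cell is rescaled so its counts sum to ``target_sum`` (10,000 by
    default) and transformed with the natural-log ``log(1 + x)``. Cells
    with zero total count cannot be rescaled and are dropped with a
    warning; an all-zero dataset is an error.
    """
    if ds.normalized:
        raise ValueError("dataset is already log-normalized")
    totals = ds.matrix.sum(axis=1)
    keep = totals > 0
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("empty dataset after filtering: all cells have zero total count")
    if n_dropped:
        msg = f"dropped {n_dropped} zero-total cell(s) during normalization"
        warnings.warn(msg, stacklevel=2)
        logger.info(msg)
    matrix = ds.matrix[keep]
    conditions = ds.conditions[keep]
    if ds.control not in set(conditions):
        raise ValueError("all control cells were zero-total; cannot normalize")
    scaled = matrix * (target_sum / matrix.sum(axis=1, keepdims=True))
    return replace(ds, matrix=np.log1p(scaled), conditions=conditions, normalized=True)


def pseudobulk(ds: PerturbDataset) -> pd.DataFrame:
    """Per-condition mean expression profiles (conditions x genes).

    Rows are the unweighted arithmetic mean over each condition's cells,
    ordered control first then perturbations sorted lexicographically.
    Requires log-normalized input, matching the benchmark convention of
    averaging in log space.
    """
    if not ds.normalized:
        raise ValueError("pseudobulk expects a log-normalized dataset; run normalize_counts first")
    order = [ds.control] + ds.perturbations
    rows = []
    kept = []
    for cond in order:
        cells = ds.cells_for(cond)
        if len(cells) == 0:  # cannot occur for labels derived from cells; guards external lists
            warnings.warn(f"condition {cond!r} has no cells; excluded from pseudo-bulk", stacklevel=2)
            continue
        rows.append(cells.mean(axis=0))
        kept.append(cond)
    pb = pd.DataFrame(np.vstack(rows), index=pd.Index(kept, name="condition"), columns=ds.gene_index())
    pb.attrs["control"] = ds.control
    return pb


def delta_profiles(pb: pd.DataFrame, control_label: str | None = None) -> pd.DataFrame:
    """Differential profiles: each perturbation's pseudo-bulk minus control's.

    The control row itself is excluded from the output. The control label
    defaults to the one recorded by :func:`pseudobulk`.
    """
    control_label = control_label or pb.attrs.get("control")
    if control_label is None:
        raise ValueError("control_label not given and not recorded on the pseudo-bulk matrix")
    if control_label not in pb.index:
        raise ValueError(f"control label {control_label!r} missing from pseudo-bulk matrix")
    control = pb.loc[control_label]
    deltas = pb.drop(index=control_label) - control
    deltas.attrs["control"] = control_label
    return deltas


@dataclass
class SplitSpec:
    """Perturbation-exclusive partition of perturbation labels.

    Perturbation labels (combos treated as whole labels) are assigned to
    disjoint train/validation/test sets, so every test perturbation is
    unseen during training. ``subgroups`` tags each test perturbation with
    its combo subgroup relative to the train set.
    """

    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]
    seed: int
    fractions: tuple[float, ...] = (0.8, 0.1, 0.1)
    subgroups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.val), set(self.test)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("train/val/test sets must be pairwise disjoint")

    @property
    def all_labels(self) -> set[str]:
        return set(self.train) | set(self.val) | set(self.test)


def label_subgroup(test_perturbation: str, train_set, sep: str = COMBO_SEP) -> str:
    """Subgroup tag for a test perturbation given the train-set labels.

    Combos are tagged ``combo_seen{0,1,2}`` by how many of their two
    components occur as single perturbations in the train set. Singles are
    ``seen_single`` when the gene occurs as a component of any train
    perturbation, else ``unseen_single``.
    """
    train_set = set(train_set)
    components = parse_perturbation(test_perturbation, sep)
    train_singles = {
        parse_perturbation(t, sep)[0] for t in train_set if len(parse_perturbation(t, sep)) == 1
    }
    if len(components) == 2:
        seen = sum(c in train_singles for c in components)
        return f"combo_seen{seen}"
    train_components = {c for t in train_set for c in parse_perturbation(t, sep)}
    return "seen_single" if components[0] in train_components else "unseen_single"


def make_split(
    perturbations,
    fractions: tuple[float, ...] = (0.8, 0.1, 0.1),
    seed: int = 0,
    sep: str = COMBO_SEP,
) -> SplitSpec:
    """Random perturbation-exclusive split, reproducible across platforms.

    Labels are sorted, shuffled with ``numpy.random.default_rng(seed)``
    (PCG64) and cut at boundaries ``round(cumsum(fractions) * n)``, so the
    same seed always yields the same partition. Combo labels are assigned
    whole; test labels receive subgroup tags.
    """
    labels = sorted(set(perturbations))
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3:
        raise ValueError("fractions must be (train, val, test)")
    if any(f < 0 for f in fractions) or not 0 < sum(fractions) <= 1 + 1e-9:
        raise ValueError("fractions must be nonnegative and sum to at most 1")
    n_parts = sum(f > 0 for f in fractions)
    if len(labels) < n_parts:
        raise ValueError(f"{len(labels)} perturbations cannot fill {n_parts} non-empty sets")
    rng = np.random.default_rng(seed)
    shuffled = list(np.array(labels, dtype=object)[rng.permutation(len(labels))])
    bounds = [int(round(c * len(labels))) for c in np.cumsum(fractions)]
    train = tuple(shuffled[: bounds[0]])
    val = tuple(shuffled[bounds[0] : bounds[1]])
    test = tuple(shuffled[bounds[1] : bounds[2]])
    for name, part, frac in (("train", train, fractions[0]), ("val", val, fractions[1]), ("test", test, fractions[2])):
        if frac > 0 and not part:
            raise ValueError(f"{name} set is empty for fractions {fractions} on {len(labels)} labels")
    subgroups = {p: label_subgroup(p, train, sep) for p in test}
    return SplitSpec(train=train, val=val, test=test, seed=seed, fractions=fractions, subgroups=subgroups)
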