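"""Baseline predictors of post-perturbation pseudo-bulk profiles.

* Train Mean — predicts the mean of the training perturbations'
  pseudo-bulk profiles for every query; the floor any learned model must
  beat.
* Embedding regressors — Random Forest, Elastic Net and k-Nearest-
  Neighbors regressions from perturbation features to pseudo-bulk
  profiles. Features are built by reducing a gene-embedding table (binary
  GO membership, foundation-model or synthetic embeddings) to at most 256
  principal components; a perturbation's feature vector is its target
  gene's reduced vector, and combos sum their components' vectors.

One hyperparameter per regressor is tuned on validation-set Pearson
Delta, mirroring common benchmark practice (RF: number of trees, EN:
L1 ratio, kNN: neighbor count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet
from sklearn.neighbors import KNeighborsRegressor

from .core import COMBO_SEP, parse_perturbation
from .embeddings import EmbeddingTable
from .metrics import pearson_delta

MODEL_KINDS = ("train_mean", "rf", "en", "knn")

DEFAULT_GRIDS = {
    "rf": (100, 200, 500),
    "en": (0.1, 0.5, 0.9),
    "knn": (1, 3, 5, 10),
}

MAX_COMPONENTS = 256


@dataclass
class FeatureMatrix:
    """Reduced perturbation features plus the fitted reduction.

    ``features`` is perturbations x d' (d' <= 256); ``pca`` transforms
    held-out genes reproducibly; ``dropped`` lists perturbations whose
    target gene was absent from the embedding table (when the policy is
    to drop rather than error).
    """

    features: pd.DataFrame
    pca: PCA
    source: str
    dropped: list[str] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    def loc(self, labels) -> pd.DataFrame:
        missing = [p for p in labels if p not in self.features.index]
        if missing:
            raise KeyError(f"perturbations missing from feature matrix: {missing[:5]}")
        return self.features.loc[list(labels)]


def _fixed_sign_pca(vectors: np.ndarray, n_components: int) -> tuple[PCA, np.ndarray]:
    """Full-SVD PCA with each component's largest-|loading| forced positive.

    The sign convention removes the inherent sign ambiguity of singular
    vectors so features are identical across platforms and LAPACK builds.
    """
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(vectors)
    flip = np.sign(pca.components_[np.arange(n_components), np.abs(pca.components_).argmax(axis=1)])
    flip[flip == 0] = 1.0
    pca.components_ *= flip[:, None]
    scores *= flip
    return pca, scores


def featurize(
    emb: EmbeddingTable,
    perturbations,
    n_components: int = MAX_COMPONENTS,
    missing: str = "error",
    sep: str = COMBO_SEP,
) -> FeatureMatrix:
    """Perturbation feature vectors from a gene-embedding table.

    The principal-component reduction is fitted on the full gene-embedding
    matrix (all genes, not just perturbation targets), to at most
    ``n_components`` (capped by the embedding's rank bound). A single
    perturbation's feature is its target gene's reduced vector; an "A+B"
    combo's feature is the elementwise sum of its components' vectors.

    ``missing`` controls the policy for target genes absent from the
    table: ``"error"`` raises, ``"drop"`` drops the perturbation with a
    warning.
    """
    if missing not in ("error", "drop"):
        raise ValueError("missing policy must be 'error' or 'drop'")
    d_prime = int(min(n_components, emb.dim, len(emb)))
    pca, scores = _fixed_sign_pca(emb.vectors, d_prime)
    gene_scores = {g: scores[i] for i, g in enumerate(emb.genes)}

    rows, kept, dropped = [], [], []
    for p in perturbations:
        comps = parse_perturbation(p, sep)
        absent = [c for c in comps if c not in gene_scores]
        if absent:
            if missing == "error":
                raise KeyError(f"perturbation {p!r}: gene(s) {absent} absent from embedding table")
            warnings.warn(f"dropping perturbation {p!r}: {absent} absent from embeddings", stacklevel=2)
            dropped.append(p)
            continue
        rows.append(np.sum([gene_scores[c] for c in comps], axis=0))
        kept.append(p)
    if not kept:
        raise ValueError("no perturbation could be featurized")
    features = pd.DataFrame(np.vstack(rows), index=pd.Index(kept, name="perturbation"))
    return FeatureMatrix(features=features, pca=pca, source=emb.source, dropped=dropped)


@dataclass
class TrainMeanModel:
    """Predicts one fixed vector: the mean training pseudo-bulk profile."""

    mean_profile: pd.Series
    n_train: int
    kind: str = "train_mean"

    def predict(self, labels) -> pd.DataFrame:
        labels = list(labels)
        values = np.tile(self.mean_profile.to_numpy(), (len(labels), 1))
        return pd.DataFrame(values, index=pd.Index(labels, name="perturbation"),
                            columns=self.mean_profile.index)


def fit_train_mean(train_pb: pd.DataFrame, control_label: str | None = None) -> TrainMeanModel:
    """Mean of the training perturbations' pseudo-bulk rows (control excluded)."""
    rows = train_pb.drop(index=control_label, errors="ignore") if control_label else train_pb
    if rows.shape[0] == 0:
        raise ValueError("empty training set")
    return TrainMeanModel(mean_profile=rows.mean(axis=0), n_train=rows.shape[0])


@dataclass
class RegressorModel:
    """Fitted embedding-feature regressor with its tuned hyperparameter."""

    kind: str
    estimator: object
    features: FeatureMatrix
    gene_index: pd.Index
    hyperparameter: float
    validation_score: float
    seed: int

    def predict(self, labels) -> pd.DataFrame:
        X = self.features.loc(labels).to_numpy()
        Y = np.asarray(self.estimator.predict(X), dtype=float)
        if Y.ndim == 1:
            Y = Y[None, :] if len(labels) == 1 else Y[:, None]
        return pd.DataFrame(Y, index=pd.Index(list(labels), name="perturbation"),
                            columns=self.gene_index)


def _make_estimator(kind: str, value, seed: int):
    if kind == "rf":
        return RandomForestRegressor(n_estimators=int(value), random_state=seed, n_jobs=1)
    if kind == "en":
        return ElasticNet(l1_ratio=float(value), random_state=seed, max_iter=5000)
    if kind == "knn":
        return KNeighborsRegressor(n_neighbors=int(value))
    raise ValueError(f"unknown regressor kind {kind!r}")


def fit_regressor(
    features: FeatureMatrix,
    train_pb: pd.DataFrame,
    kind: str,
    grid=None,
    val_pb: pd.DataFrame | None = None,
    control_row=None,
    seed: int = 0,
) -> RegressorModel:
    """Fit a multi-output regressor of pseudo-bulk profiles on features.

    One hyperparameter is swept over ``grid`` (RF: n_estimators, EN:
    l1_ratio, kNN: n_neighbors); the chosen value maximizes the mean
    validation Pearson Delta against ``val_pb`` (with ``control_row``
    supplying the control profile). With a single-value grid, or no
    validation data, that value is used directly.
    """
    if kind not in ("rf", "en", "knn"):
        raise ValueError(f"fit_regressor handles rf/en/knn, got {kind!r}")
    grid = tuple(grid) if grid is not None else DEFAULT_GRIDS[kind]
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    train_labels = list(train_pb.index)
    X_train = features.loc(train_labels).to_numpy()
    Y_train = train_pb.to_numpy()
    if kind == "knn" and max(int(v) for v in grid) > len(train_labels):
        raise ValueError(
            f"kNN neighbor count {max(grid)} exceeds {len(train_labels)} training perturbations"
        )

    tune = val_pb is not None and len(grid) > 1
    if tune and control_row is None:
        raise ValueError("control_row is required to tune on validation Pearson Delta")

    best = (None, -np.inf, None)
    for value in grid:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # EN convergence chatter on tiny toy fits
            est = _make_estimator(kind, value, seed).fit(X_train, Y_train)
        if tune:
            X_val = features.loc(list(val_pb.index)).to_numpy()
            pred = np.atleast_2d(np.asarray(est.predict(X_val), dtype=float))
            scores = [
                pearson_delta(pred[i], val_pb.iloc[i].to_numpy(), control_row)
                for i in range(pred.shape[0])
            ]
            score = float(np.nanmean(scores)) if not np.all(np.isnan(scores)) else -np.inf
        else:
            score = float("nan")
        if best[0] is None or (tune and score > best[1]):
            best = (value, score, est)
    value, score, est = best
    return RegressorModel(
        kind=kind,
        estimator=est,
        features=features,
        gene_index=train_pb.columns,
        hyperparameter=value,
        validation_score=score,
        seed=seed,
    )


def go_matrix_from_gmt(
    gene_sets: dict[str, list[str]],
    genes=None,
    min_size: int = 3,
) -> EmbeddingTable:
    """Binary gene x set membership matrix from a GMT-style mapping.

    Sets with fewer than ``min_size`` member genes (after restricting to
    ``genes``, when given) are dropped. The resulting incidence matrix is
    the standard prior-knowledge featurization of perturbations by the
    functional annotations of their target genes.
    """
    universe = sorted({g for gs in gene_sets.values() for g in gs}) if genes is None else list(genes)
    gene_pos = {g: i for i, g in enumerate(universe)}
    columns, data = [], []
    for name in sorted(gene_sets):
        members = [g for g in gene_sets[name] if g in gene_pos]
        if len(members) < min_size:
            continue
        col = np.zeros(len(universe))
        col[[gene_pos[g] for g in members]] = 1.0
        columns.append(name)
        data.append(col)
    if not columns:
        raise ValueError(f"no gene set has >= {min_size} member genes in the universe")
    matrix = np.column_stack(data)
    return EmbeddingTable(np.asarray(universe, dtype=object), matrix, source="GO-binary")
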