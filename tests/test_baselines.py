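"""Baseline models: Train Mean, featurization, regressors."""

import numpy as np
import pandas as pd
import pytest

from pertbench import (
    EmbeddingTable,
    featurize,
    fit_regressor,
    fit_train_mean,
    go_matrix_from_gmt,
)


@pytest.fixture
def toy_embedding():
    rng = np.random.default_rng(0)
    genes = np.array([f"g{i}" for i in range(20)], dtype=object)
    return EmbeddingTable(genes=genes, vectors=rng.standard_normal((20, 6)), source="toy")


class TestTrainMean:
    def test_prediction_is_hand_mean(self):
        pb = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["pA", "pB"], columns=["g0", "g1"])
        model = fit_train_mean(pb)
        pred = model.predict(["pX", "pY"])
        np.testing.assert_allclose(pred.loc["pX"], [2.0, 3.0])
        np.testing.assert_array_equal(pred.loc["pX"], pred.loc["pY"])

    def test_single_row_identity(self):
        pb = pd.DataFrame([[5.0, 6.0, 7.0]], index=["pA"], columns=list("abc"))
        np.testing.assert_allclose(fit_train_mean(pb).predict(["q"]).loc["q"], [5.0, 6.0, 7.0])

    def test_control_row_excluded(self):
        pb = pd.DataFrame([[100.0], [1.0], [3.0]], index=["ctrl", "pA", "pB"], columns=["g"])
        model = fit_train_mean(pb, control_label="ctrl")
        assert model.predict(["x"]).iloc[0, 0] == pytest.approx(2.0)
        assert model.n_train == 2

    def test_empty_training_set_errors(self):
        pb = pd.DataFrame(columns=["g0"], dtype=float)
        with pytest.raises(ValueError, match="empty"):
            fit_train_mean(pb)

    def test_equals_bruteforce_column_mean(self, small_study):
        _, ds, _, _ = small_study
        from pertbench import normalize_counts, pseudobulk

        pb = pseudobulk(normalize_counts(ds)).drop(index="ctrl")
        model = fit_train_mean(pb)
        np.testing.assert_array_equal(
            model.predict(["q"]).iloc[0].to_numpy(), pb.to_numpy().mean(axis=0)
        )


class TestFeaturize:
    def test_combo_feature_is_sum_of_components(self, toy_embedding):
        fm = featurize(toy_embedding, ["g0", "g1", "g0+g1"], n_components=4)
        np.testing.assert_allclose(
            fm.features.loc["g0+g1"], fm.features.loc["g0"] + fm.features.loc["g1"], atol=1e-12
        )

    def test_combo_linearity_holds_for_all_pairs(self, toy_embedding):
        singles = [f"g{i}" for i in range(6)]
        combos = [f"g{i}+g{j}" for i in range(3) for j in range(3, 6)]
        fm = featurize(toy_embedding, singles + combos, n_components=5)
        for c in combos:
            a, b = c.split("+")
            np.testing.assert_allclose(
                fm.features.loc[c], fm.features.loc[a] + fm.features.loc[b], atol=1e-12
            )

    def test_dimension_capped_by_embedding_not_padded(self, toy_embedding):
        fm = featurize(toy_embedding, ["g0"], n_components=256)
        assert fm.dim == 6  # d < 256 -> d' = d

    def test_rank2_reconstruction_exact(self):
        # rank-2 embedding reduced with 2 components reconstructs exactly
        rng = np.random.default_rng(1)
        basis = rng.standard_normal((2, 8))
        weights = rng.standard_normal((15, 2))
        vectors = weights @ basis
        genes = np.array([f"g{i}" for i in range(15)], dtype=object)
        emb = EmbeddingTable(genes=genes, vectors=vectors, source="rank2")
        fm = featurize(emb, list(genes), n_components=2)
        recon = fm.features.to_numpy() @ fm.pca.components_ + fm.pca.mean_
        np.testing.assert_allclose(recon, vectors, atol=1e-10)

    def test_sign_convention_deterministic(self, toy_embedding):
        a = featurize(toy_embedding, ["g0", "g1"], n_components=3)
        b = featurize(toy_embedding, ["g0", "g1"], n_components=3)
        np.testing.assert_array_equal(a.features.to_numpy(), b.features.to_numpy())
        # largest-|loading| entry of each component is positive
        comp = a.pca.components_
        picks = np.abs(comp).argmax(axis=1)
        assert (comp[np.arange(comp.shape[0]), picks] > 0).all()

    def test_missing_gene_policies(self, toy_embedding):
        with pytest.raises(KeyError, match="absent"):
            featurize(toy_embedding, ["g0", "zz"], missing="error")
        with pytest.warns(UserWarning, match="dropping"):
            fm = featurize(toy_embedding, ["g0", "zz"], missing="drop")
        assert fm.dropped == ["zz"]
        assert list(fm.features.index) == ["g0"]


class TestRegressors:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        genes = np.array([f"g{i}" for i in range(12)], dtype=object)
        emb = EmbeddingTable(genes=genes, vectors=rng.standard_normal((12, 5)), source="toy")
        perts = [f"g{i}" for i in range(10)]
        fm = featurize(emb, perts, n_components=5)
        targets = pd.DataFrame(
            rng.standard_normal((10, 30)), index=perts,
            columns=[f"t{i}" for i in range(30)],
        )
        return fm, targets

    def test_knn_k1_returns_nearest_training_profile(self):
        fm, targets = self._setup()
        train = targets.iloc[:8]
        model = fit_regressor(fm, train, kind="knn", grid=(1,))
        query = "g9"
        X = fm.features
        dists = np.linalg.norm(
            X.loc[train.index].to_numpy() - X.loc[query].to_numpy(), axis=1
        )
        nearest = train.index[int(np.argmin(dists))]
        np.testing.assert_allclose(
            model.predict([query]).loc[query], train.loc[nearest], atol=1e-12
        )

    def test_rf_single_tree_single_sample_memorizes(self):
        fm, targets = self._setup()
        train = targets.iloc[:1]
        model = fit_regressor(fm, train, kind="rf", grid=(1,), seed=0)
        np.testing.assert_allclose(
            model.predict(["g5"]).iloc[0], train.iloc[0], atol=1e-12
        )

    def test_elastic_net_ridge_limit_symmetric_on_duplicated_features(self):
        # duplicated feature columns receive equal coefficients at the ridge limit
        from sklearn.linear_model import ElasticNet

        rng = np.random.default_rng(3)
        x = rng.standard_normal(40)
        X = np.column_stack([x, x])
        y = 3.0 * x + rng.normal(0, 0.1, size=40)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = ElasticNet(alpha=0.1, l1_ratio=0.0, max_iter=200000, tol=1e-12).fit(X, y)
        assert est.coef_[0] == pytest.approx(est.coef_[1], rel=1e-6)

    def test_hyperparameter_choice_reproducible(self, small_study):
        cfg, ds, truth, emb = small_study
        from pertbench import make_split, normalize_counts, pseudobulk

        pb = pseudobulk(normalize_counts(ds))
        split = make_split([p for p in pb.index if p != "ctrl"], (0.6, 0.2, 0.2), seed=2)
        fm = featurize(emb, list(split.train) + list(split.val))
        kw = dict(
            features=fm,
            train_pb=pb.loc[list(split.train)],
            kind="knn",
            grid=(1, 2, 3),
            val_pb=pb.loc[list(split.val)],
            control_row=pb.loc["ctrl"].to_numpy(),
            seed=5,
        )
        a, b = fit_regressor(**kw), fit_regressor(**kw)
        assert a.hyperparameter == b.hyperparameter
        assert a.validation_score == pytest.approx(b.validation_score)

    def test_empty_grid_and_oversized_k_error(self):
        fm, targets = self._setup()
        with pytest.raises(ValueError, match="empty"):
            fit_regressor(fm, targets, kind="rf", grid=())
        with pytest.raises(ValueError, match="exceeds"):
            fit_regressor(fm, targets.iloc[:3], kind="knn", grid=(5,))

    def test_prediction_gene_order_matches_training(self):
        fm, targets = self._setup()
        model = fit_regressor(fm, targets.iloc[:8], kind="rf", grid=(10,), seed=1)
        pred = model.predict(["g8", "g9"])
        assert list(pred.columns) == list(targets.columns)
        assert list(pred.index) == ["g8", "g9"]


class TestGoMatrix:
    def test_binary_incidence_and_min_size_filter(self):
        sets = {
            "big": ["g0", "g1", "g2", "g3"],
            "small": ["g0", "g1"],  # below min_size 3 -> dropped
        }
        emb = go_matrix_from_gmt(sets, genes=[f"g{i}" for i in range(5)])
        assert emb.vectors.shape == (5, 1)  # "small" dropped
        np.testing.assert_array_equal(emb.vectors[:, 0], [1.0, 1.0, 1.0, 1.0, 0.0])
        assert emb.source == "GO-binary"

    def test_all_sets_too_small_errors(self):
        with pytest.raises(ValueError, match="no gene set"):
            go_matrix_from_gmt({"s": ["g0"]}, genes=["g0", "g1", "g2"])
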