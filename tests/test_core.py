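"""Core data model: normalization, pseudo-bulk, deltas, splits, subgroups."""

import numpy as np
import pandas as pd
import pytest

from pertbench import (
    PerturbDataset,
    delta_profiles,
    label_subgroup,
    make_split,
    normalize_counts,
    parse_perturbation,
    pseudobulk,
)


def _ds(matrix, conditions, genes=None, **kw):
    matrix = np.asarray(matrix, dtype=float)
    genes = genes if genes is not None else [f"g{i}" for i in range(matrix.shape[1])]
    return PerturbDataset(
        matrix=matrix,
        conditions=np.asarray(conditions, dtype=object),
        gene_names=np.asarray(genes, dtype=object),
        validate_targets=False,
        **kw,
    )


class TestPerturbDataset:
    def test_rejects_duplicate_genes(self):
        with pytest.raises(ValueError, match="unique"):
            _ds([[1, 2], [3, 4]], ["ctrl", "p"], genes=["g", "g"])

    def test_rejects_missing_control(self):
        with pytest.raises(ValueError, match="control"):
            _ds([[1, 2]], ["p"])

    def test_rejects_negative_counts_and_nonfinite(self):
        with pytest.raises(ValueError, match="nonnegative"):
            _ds([[1, -2], [3, 4]], ["ctrl", "p"])
        with pytest.raises(ValueError, match="finite"):
            _ds([[1, np.nan], [3, 4]], ["ctrl", "p"])

    def test_targets_parsed_from_combo_syntax(self):
        ds = _ds([[1, 2], [3, 4], [1, 1]], ["ctrl", "g0+g1", "g0"])
        assert ds.perturbation_targets == {"g0": ("g0",), "g0+g1": ("g0", "g1")}

    def test_unknown_target_gene_rejected_when_validating(self):
        with pytest.raises(ValueError, match="unknown gene"):
            PerturbDataset(
                matrix=np.ones((2, 2)),
                conditions=np.array(["ctrl", "gX"], dtype=object),
                gene_names=np.array(["g0", "g1"], dtype=object),
            )

    def test_parse_rejects_more_than_two_components(self):
        with pytest.raises(ValueError, match="components"):
            parse_perturbation("a+b+c")


class TestNormalizeCounts:
    def test_rescales_to_10k_then_natural_log1p(self):
        ds = _ds([[1, 3], [5000, 5000]], ["ctrl", "p"])
        out = normalize_counts(ds)
        # totals 4 -> [2500, 7500]; total 10000 -> unchanged
        np.testing.assert_allclose(out.matrix[0], [np.log(2501), np.log(7501)], rtol=1e-12)
        np.testing.assert_allclose(out.matrix[1], [np.log(5001), np.log(5001)], rtol=1e-12)
        assert out.normalized

    def test_values_match_direct_arithmetic(self):
        np.testing.assert_allclose(
            normalize_counts(_ds([[1, 3], [1, 1]], ["ctrl", "p"])).matrix[0],
            [7.824445930877619, 8.922791480971794],
            atol=1e-9,
        )

    def test_zero_total_cell_dropped_with_warning(self):
        ds = _ds([[1, 1], [0, 0], [2, 2]], ["ctrl", "p", "p"])
        with pytest.warns(UserWarning, match="zero-total"):
            out = normalize_counts(ds)
        assert out.n_cells == 2
        assert list(out.conditions) == ["ctrl", "p"]

    def test_all_zero_dataset_errors(self):
        ds = _ds([[0, 0], [0, 0]], ["ctrl", "p"])
        with pytest.raises(ValueError, match="empty dataset"):
            normalize_counts(ds)

    def test_refuses_double_normalization(self, tiny_normalized):
        with pytest.raises(ValueError, match="already"):
            normalize_counts(tiny_normalized)


class TestPseudobulk:
    def test_mean_of_two_cells(self):
        ds = _ds([[0, 0], [1, 2], [3, 4]], ["ctrl", "p", "p"], **{"normalized": True})
        pb = pseudobulk(ds)
        np.testing.assert_allclose(pb.loc["p"], [2.0, 3.0])

    def test_single_cell_condition_is_identity(self, tiny_normalized):
        pb = pseudobulk(tiny_normalized)
        # gA has 2 cells; check a brute-force mean for every condition instead
        for cond in ["ctrl", "gA", "gC"]:
            np.testing.assert_allclose(
                pb.loc[cond], tiny_normalized.cells_for(cond).mean(axis=0), atol=1e-14
            )

    def test_matches_bruteforce_groupby(self, small_study):
        _, ds, _, _ = small_study
        from pertbench import normalize_counts as norm

        nds = norm(ds)
        pb = pseudobulk(nds)
        df = pd.DataFrame(nds.matrix, columns=nds.gene_names)
        df["cond"] = nds.conditions
        brute = df.groupby("cond").mean()
        for cond in pb.index:
            np.testing.assert_allclose(pb.loc[cond].to_numpy(),
                                       brute.loc[cond].to_numpy(), atol=1e-12)

    def test_requires_normalized_input(self, tiny_counts):
        with pytest.raises(ValueError, match="log-normalized"):
            pseudobulk(tiny_counts)

    def test_identical_cells_recovered_exactly(self):
        # every condition has identical cells -> pseudobulk returns those rows
        row_c, row_p = [0.5, 1.0, 2.0], [1.5, 0.0, 3.0]
        ds = _ds([row_c, row_c, row_p, row_p], ["ctrl", "ctrl", "p", "p"],
                 **{"normalized": True})
        pb = pseudobulk(ds)
        np.testing.assert_array_equal(pb.loc["ctrl"], row_c)
        np.testing.assert_array_equal(pb.loc["p"], row_p)


class TestDeltaProfiles:
    def test_forced_subtraction(self):
        pb = pd.DataFrame([[1.0, 1.0], [2.0, 0.0]], index=["ctrl", "p"], columns=["g0", "g1"])
        d = delta_profiles(pb, "ctrl")
        np.testing.assert_allclose(d.loc["p"], [1.0, -1.0])
        assert "ctrl" not in d.index

    def test_zero_vector_when_equal_to_control(self):
        pb = pd.DataFrame([[1.0, 2.0, 3.0]] * 2, index=["ctrl", "p"], columns=list("abc"))
        np.testing.assert_allclose(delta_profiles(pb, "ctrl").loc["p"], 0.0)

    def test_each_row_matches_independent_subtraction(self, tiny_normalized):
        pb = pseudobulk(tiny_normalized)
        d = delta_profiles(pb)
        for p in d.index:
            np.testing.assert_allclose(
                d.loc[p].to_numpy(), pb.loc[p].to_numpy() - pb.loc["ctrl"].to_numpy(), atol=1e-14
            )

    def test_delta_plus_control_reconstructs_pseudobulk(self, tiny_normalized):
        pb = pseudobulk(tiny_normalized)
        d = delta_profiles(pb)
        np.testing.assert_array_equal((d + pb.loc["ctrl"]).to_numpy(),
                                      pb.drop(index="ctrl").to_numpy())

    def test_missing_control_errors(self):
        pb = pd.DataFrame([[1.0, 2.0]], index=["p"], columns=["g0", "g1"])
        with pytest.raises(ValueError, match="missing"):
            delta_profiles(pb, "ctrl")


class TestMakeSplit:
    def test_cardinalities_and_disjointness(self):
        labels = [f"p{i}" for i in range(10)]
        split = make_split(labels, (0.8, 0.1, 0.1), seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (8, 1, 1)
        assert split.all_labels == set(labels)

    @pytest.mark.parametrize("seed", [0, 1, 12345])
    def test_deterministic_and_covering(self, seed):
        labels = [f"p{i}" for i in range(23)]
        a = make_split(labels, seed=seed)
        b = make_split(labels, seed=seed)
        assert (a.train, a.val, a.test) == (b.train, b.val, b.test)
        assert set(a.train) | set(a.val) | set(a.test) == set(labels)
        assert len(a.train) + len(a.val) + len(a.test) == len(labels)

    def test_different_seeds_differ(self):
        labels = [f"p{i}" for i in range(30)]
        assert make_split(labels, seed=0).train != make_split(labels, seed=1).train

    def test_too_few_perturbations_error(self):
        with pytest.raises(ValueError):
            make_split(["a", "b"], (0.8, 0.1, 0.1), seed=0)

    def test_combos_assigned_whole(self):
        labels = ["a", "b", "a+b", "c", "d", "e", "f", "g", "h", "i"]
        split = make_split(labels, seed=3)
        assert "a+b" in split.all_labels
        parts = [set(split.train), set(split.val), set(split.test)]
        assert sum("a+b" in s for s in parts) == 1


class TestLabelSubgroup:
    @pytest.mark.parametrize(
        "pert,train,expected",
        [
            ("A+B", {"C", "D"}, "combo_seen0"),
            ("A+B", {"A", "C"}, "combo_seen1"),
            ("A+B", {"A", "B"}, "combo_seen2"),
            ("C", {"A", "B"}, "unseen_single"),
            ("C", {"C+D"}, "seen_single"),
            ("A+B", {"A+C"}, "combo_seen0"),  # combo components count only as singles
        ],
    )
    def test_subgroup_rules(self, pert, train, expected):
        assert label_subgroup(pert, train) == expected

    def test_three_component_label_errors(self):
        with pytest.raises(ValueError):
            label_subgroup("a+b+c", {"a"})

    def test_split_tags_consistent_with_train_membership(self):
        labels = [f"s{i}" for i in range(8)] + ["s0+s1", "s2+s3", "s6+s7"]
        split = make_split(labels, (0.6, 0.2, 0.2), seed=5)
        for p, tag in split.subgroups.items():
            assert tag == label_subgroup(p, split.train)
            assert tag in ("combo_seen0", "combo_seen1", "combo_seen2",
                           "unseen_single", "seen_single")
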