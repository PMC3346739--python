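"""Imputation, hierarchical clustering vs a brute-force oracle, composition."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ctcprof import cluster_analysis as ca
from ctcprof.errors import ConfigError, DataError
from ctcprof.normalization import NormalizedMatrix

from linkage_oracle import brute_force_merges, scipy_merges


def _norm(values: pd.DataFrame, pooled_sd: float) -> NormalizedMatrix:
    return NormalizedMatrix(
        values=values,
        gene_medians=pd.Series(0.0, index=values.columns),
        reference_panel=("UBB",),
        pooled_sd=pooled_sd,
    )


class TestImputeAndTruncate:
    def test_missing_imputed_at_minus_3_sd(self):
        vals = pd.DataFrame(
            [[1.0, np.nan], [0.0, 2.0]], index=["a", "b"], columns=["g1", "g2"]
        )
        clustering, display = ca.impute_and_truncate(_norm(vals, 1.5))
        assert clustering.loc["a", "g2"] == pytest.approx(-4.5)
        assert np.isnan(display.loc["a", "g2"])  # stays black in display

    def test_display_clipped_clustering_not(self):
        vals = pd.DataFrame([[7.2], [0.0]], index=["a", "b"], columns=["g1"])
        clustering, display = ca.impute_and_truncate(_norm(vals, 1.5))
        assert display.loc["a", "g1"] == pytest.approx(4.5)
        assert clustering.loc["a", "g1"] == pytest.approx(7.2)

    def test_no_missing_values_identity(self):
        vals = pd.DataFrame([[1.0, -1.0], [0.5, 0.0]], index=["a", "b"],
                            columns=["g1", "g2"])
        clustering, _ = ca.impute_and_truncate(_norm(vals, 2.0))
        pd.testing.assert_frame_equal(clustering, vals)

    def test_constant_matrix_rejected(self):
        vals = pd.DataFrame([[0.0], [0.0]], index=["a", "b"], columns=["g1"])
        with pytest.raises(DataError):
            ca.impute_and_truncate(_norm(vals, 0.0))

    def test_imputation_floor_below_observed(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(0, 1.0, (30, 5))
        raw[rng.random((30, 5)) < 0.2] = np.nan
        vals = pd.DataFrame(raw, index=[f"c{i}" for i in range(30)],
                            columns=[f"g{i}" for i in range(5)])
        obs = vals.to_numpy()[np.isfinite(vals.to_numpy())]
        sd = float(np.std(obs, ddof=1))
        clustering, _ = ca.impute_and_truncate(_norm(vals, sd))
        if (np.abs(obs) <= 3 * sd).all():
            assert clustering.to_numpy().min() <= obs.min()


class TestHcluster:
    def test_two_tight_pairs(self):
        pts = pd.DataFrame(
            [[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]],
            index=["a", "b", "c", "d"],
        )
        result = ca.hcluster(pts)
        merges = scipy_merges(result.linkage_matrix, 4)
        assert merges[0][0] in ({0, 1}, {2, 3})
        assert merges[1][0] in ({0, 1}, {2, 3})
        labels = ca.cut_k(result, 2)
        assert labels["a"] == labels["b"] != labels["c"] == labels["d"]

    def test_duplicate_cells_merge_first_at_zero(self):
        pts = pd.DataFrame([[1.0, 1.0], [5.0, 5.0], [1.0, 1.0]],
                           index=["a", "b", "a2"])
        result = ca.hcluster(pts)
        merges = scipy_merges(result.linkage_matrix, 3)
        assert merges[0] == (frozenset({0, 2}), 0.0)

    @pytest.mark.parametrize("linkage", ["single", "complete", "average"])
    def test_matches_brute_force_oracle_small_n(self, linkage):
        rng = np.random.default_rng(42)
        for trial in range(40):
            n = int(rng.integers(2, 9))
            X = rng.normal(0, 1, (n, 3))
            df = pd.DataFrame(X, index=[f"c{i}" for i in range(n)])
            result = ca.hcluster(df, linkage=linkage)
            got = scipy_merges(result.linkage_matrix, n)
            want = brute_force_merges(X, linkage)
            assert [m for m, _ in got] == [m for m, _ in want]
            assert np.allclose([d for _, d in got], [d for _, d in want])

    def test_too_few_cells_rejected(self):
        with pytest.raises(DataError):
            ca.hcluster(pd.DataFrame([[1.0]], index=["a"]))

    def test_missing_values_rejected(self):
        df = pd.DataFrame([[1.0], [np.nan]], index=["a", "b"])
        with pytest.raises(DataError):
            ca.hcluster(df)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(0, 1, (12, 4)),
                          index=[f"c{i}" for i in range(12)])
        perm = list(rng.permutation(df.index))
        labels_a = ca.cut_k(ca.hcluster(df), 3)
        labels_b = ca.cut_k(ca.hcluster(df.loc[perm]), 3)
        # same partition: co-membership agrees for every pair
        for i in df.index:
            for j in df.index:
                assert (labels_a[i] == labels_a[j]) == (labels_b[i] == labels_b[j])


class TestCutK:
    def test_k1_and_kn(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(0, 1, (6, 3)), index=[f"c{i}" for i in range(6)])
        result = ca.hcluster(df)
        assert ca.cut_k(result, 1).nunique() == 1
        assert ca.cut_k(result, 6).nunique() == 6

    def test_smaller_cluster_is_cluster_one(self):
        pts = np.vstack(
            [np.random.default_rng(1).normal(0, 0.1, (3, 2)),
             np.random.default_rng(2).normal(8, 0.1, (9, 2))]
        )
        df = pd.DataFrame(pts, index=[f"c{i}" for i in range(12)])
        labels = ca.cut_k(ca.hcluster(df), 2)
        sizes = labels.value_counts()
        assert sizes[1] == 3 and sizes[2] == 9

    def test_bad_k_rejected(self):
        df = pd.DataFrame(np.eye(3), index=["a", "b", "c"])
        with pytest.raises(ConfigError):
            ca.cut_k(ca.hcluster(df), 0)


class TestNewick:
    def test_tree_parses_and_has_all_leaves(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.normal(0, 1, (7, 3)),
                          index=[f"cell{i}" for i in range(7)])
        nwk = ca.to_newick(ca.hcluster(df))
        import dendropy

        tree = dendropy.Tree.get(data=nwk, schema="newick")
        taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
        assert taxa == sorted(df.index)


def _composition_meta(case_of_cell, stage=None, er=None, pr=None, her2=None, age=None):
    cells = list(case_of_cell)
    cases = [case_of_cell[c] for c in cells]
    return pd.DataFrame(
        {
            "cell_id": cells,
            "source": "patient",
            "subject_id": cases,
            "sample_id": "d1",
            "stage": [(stage or {}).get(k, "metastatic") for k in cases],
            "er_status": [(er or {}).get(k, "neg") for k in cases],
            "pr_status": [(pr or {}).get(k, "neg") for k in cases],
            "her2_status": [(her2 or {}).get(k, "neg") for k in cases],
            "age_at_diagnosis": [(age or {}).get(k, 45.0) for k in cases],
        }
    )


class TestCompositionTable:
    def test_13_cases_4_primary_is_31_pct(self):
        case_of_cell = {f"c{i}": f"P{i}" for i in range(13)}
        labels = pd.Series(1, index=list(case_of_cell))
        stage = {f"P{i}": ("primary" if i < 4 else "metastatic") for i in range(13)}
        table = ca.composition_table(labels, _composition_meta(case_of_cell, stage=stage))
        row = table.per_cluster.loc[1]
        assert row["n_cases"] == 13 and row["pct_primary"] == 31
        assert row["pct_metastatic"] == 69  # 9/13 rounds half-up to 69

    def test_30_cases_13_triple_negative_is_43_pct(self):
        case_of_cell = {f"c{i}": f"P{i}" for i in range(30)}
        labels = pd.Series(2, index=list(case_of_cell))
        er = {f"P{i}": ("neg" if i < 13 else "pos") for i in range(30)}
        table = ca.composition_table(labels, _composition_meta(case_of_cell, er=er))
        assert table.per_cluster.loc[2, "pct_triple_negative"] == 43

    def test_overlap_8_of_35_is_23_pct(self):
        case_of_cell = {}
        labels = {}
        for i in range(35):
            case_of_cell[f"a{i}"] = f"P{i}"
            labels[f"a{i}"] = 2
        for i in range(8):  # eight cases also appear in cluster 1
            case_of_cell[f"b{i}"] = f"P{i}"
            labels[f"b{i}"] = 1
        table = ca.composition_table(
            pd.Series(labels), _composition_meta(case_of_cell)
        )
        assert table.n_cases_total == 35
        assert table.n_cases_in_multiple == 8
        assert table.pct_cases_in_multiple == 23

    def test_unknown_status_not_counted_positive_or_tn(self):
        case_of_cell = {"c0": "P0"}
        labels = pd.Series(1, index=["c0"])
        meta = _composition_meta(case_of_cell, er={"P0": "unknown"},
                                 pr={"P0": "unknown"}, her2={"P0": "unknown"})
        row = ca.composition_table(labels, meta).per_cluster.loc[1]
        assert row["n_er_or_pr_pos"] == 0 and row["n_triple_negative"] == 0


class TestRoundHalfUp:
    @pytest.mark.parametrize("x,expected", [(69.23, 69), (4.5, 5), (50.5, 51),
                                            (2.49, 2), (0.0, 0)])
    def test_values(self, x, expected):
        assert ca.round_half_up(x) == expected


class TestRenderHeatmap:
    def test_missing_tile_and_manifest(self, tmp_path):
        vals = pd.DataFrame([[1.0, np.nan], [0.0, 2.0], [0.2, 1.1]],
                            index=["a", "b", "c"], columns=["g1", "g2"])
        result = ca.hcluster(vals.fillna(-3.0))
        manifest = tmp_path / "order.txt"
        _, cells, genes = ca.render_heatmap(
            vals, result, path=str(tmp_path / "h.png"), manifest_path=str(manifest)
        )
        assert sorted(cells) == ["a", "b", "c"]
        assert (tmp_path / "h.png").exists()
        assert "# ordered cells" in manifest.read_text()

    def test_annotation_legend_has_one_entry_per_group(self, tmp_path):
        rng = np.random.default_rng(3)
        n_groups = 9
        vals = pd.DataFrame(rng.normal(0, 1, (n_groups * 2, 4)),
                            index=[f"c{i}" for i in range(n_groups * 2)])
        ann = pd.Series([f"grp{i % n_groups}" for i in range(n_groups * 2)],
                        index=vals.index)
        result = ca.hcluster(vals)
        manifest = tmp_path / "order.txt"
        ca.render_heatmap(vals, result, annotations=ann,
                          manifest_path=str(manifest))
        text = manifest.read_text().splitlines()
        groups = text[text.index("# annotation groups") + 1:]
        assert len(groups) == n_groups
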