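"""Differential expression: QC, size factors, NB test, summaries."""

import numpy as np
import pandas as pd
import pytest

from mapgen import diffexp as de
from mapgen import synthetic as syn
from mapgen.containers import CountMatrix


def _sc_matrix(seed=0, n_high_mito=10):
    spec = syn.ExpressionSimSpec(
        n_genes=60, base_mean=2.0, dispersion=0.4,
        n_cells_per_type={"macrophage": 40, "at2 cell": 30},
        organ="lung", mito_fraction=0.04, n_high_mito=n_high_mito, seed=seed,
    )
    return syn.simulate_counts(spec, "single_cell")


class TestQC:
    def test_permissive_thresholds_are_identity(self):
        cm = _sc_matrix()
        out = de.qc_filter_cells(cm, min_genes=0, max_pct_mito=100.0)
        assert out.counts.equals(cm.counts)

    def test_exactly_planted_high_mito_cells_removed(self):
        cm = _sc_matrix(seed=1)
        out = de.qc_filter_cells(cm, min_genes=0, max_pct_mito=20.0)
        removed = set(cm.meta.index) - set(out.meta.index)
        assert removed == set(cm.meta.index[cm.meta["high_mito_planted"]])
        assert len(removed) == 10

    def test_all_cells_removed_is_an_error(self):
        cm = _sc_matrix()
        with pytest.raises(ValueError):
            de.qc_filter_cells(cm, min_genes=10_000, max_pct_mito=0.0)


class TestSizeFactors:
    def _cm(self, counts):
        counts = pd.DataFrame(counts)
        counts.columns = [f"s{j}" for j in range(counts.shape[1])]
        meta = pd.DataFrame(index=counts.columns)
        meta["group"] = ["A", "B"] * (counts.shape[1] // 2)
        return CountMatrix(counts, meta)

    def test_identical_columns_give_unit_factors(self):
        cm = self._cm(np.tile([[10], [20], [30], [40]], (1, 2)))
        assert np.allclose(de.size_factors(cm), [1.0, 1.0])

    def test_doubled_column_gives_sqrt2_factors(self):
        col = np.array([10, 20, 30, 40])
        cm = self._cm(np.column_stack([col, 2 * col]))
        assert np.allclose(
            de.size_factors(cm), [1 / np.sqrt(2), np.sqrt(2)]
        )

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(50, size=(40, 6))
        cm = self._cm(counts)
        shuffled = self._cm(counts[rng.permutation(40)])
        assert np.allclose(de.size_factors(cm), de.size_factors(shuffled))

    def test_geometric_mean_is_one(self):
        cm = _sc_matrix(seed=2, n_high_mito=0)
        sf = de.size_factors(cm, mode="single_cell")
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)
        assert (sf > 0).all()

    def test_all_zero_column_rejected(self):
        counts = np.column_stack([[5, 5], [0, 0]])
        cm = self._cm(counts)
        with pytest.raises(ValueError):
            de.size_factors(cm)

    def test_library_size_fallback_warns(self, caplog):
        # no gene is nonzero in every column
        cm = self._cm(np.array([[5, 0], [0, 5]]))
        with caplog.at_level("WARNING"):
            sf = de.size_factors(cm)
        assert "library-size" in caplog.text
        assert np.allclose(sf, [1.0, 1.0])


def _bulk(planted, seed, n_genes=300, n=20, disp=0.1, base=100.0):
    genes = [f"G{i:04d}" for i in range(n_genes)]
    spec = syn.ExpressionSimSpec(
        n_genes=n_genes, gene_names=genes, base_mean=base, dispersion=disp,
        n_samples_per_group=n, planted_de=planted, seed=seed,
    )
    return syn.simulate_counts(spec, "bulk"), genes


class TestNBTest:
    def test_constant_gene_is_null(self):
        # identical columns: unit size factors, so a gene with identical
        # counts in both groups is an exact null
        counts = pd.DataFrame(
            np.tile([[7], [30], [120], [55]], (1, 10)),
            index=["g1", "g2", "g3", "g4"],
            columns=[f"s{j}" for j in range(10)],
        )
        meta = pd.DataFrame({"group": ["IPF"] * 5 + ["nonIPF"] * 5},
                            index=counts.columns)
        row = de.nb_de_test(CountMatrix(counts, meta)).set_index("gene").loc["g1"]
        assert row["log2FoldChange"] == pytest.approx(0.0, abs=1e-6)
        assert row["padj"] > 0.9

    def test_agrees_with_naive_normalized_ratio_for_expressed_genes(self):
        planted = [(f"G{i:04d}", 1.5 if i % 2 else -1.5) for i in range(20)]
        cm, genes = _bulk(planted, seed=5)
        result = de.nb_de_test(cm).set_index("gene")
        sf = de.size_factors(cm).to_numpy()
        normalized = cm.counts.to_numpy() / sf
        is_test = (cm.meta["group"] == "IPF").to_numpy()
        naive = np.log2(
            normalized[:, is_test].mean(axis=1)
            / normalized[:, ~is_test].mean(axis=1)
        )
        mean_ok = normalized.mean(axis=1) > 50
        big = np.abs(naive) > 0.5
        sel = mean_ok & big
        fitted = result.loc[np.array(genes)[sel], "log2FoldChange"].to_numpy()
        assert np.all(np.sign(fitted) == np.sign(naive[sel]))
        assert np.all(np.abs(fitted - naive[sel]) <= 0.1 * np.abs(naive[sel]))

    def test_group_swap_antisymmetry(self):
        planted = [(f"G{i:04d}", 2.0) for i in range(10)]
        cm, _ = _bulk(planted, seed=6, n_genes=80)
        res = de.nb_de_test(cm)
        swapped_meta = cm.meta.copy()
        swapped_meta["group"] = np.where(
            swapped_meta["group"] == "IPF", "nonIPF", "IPF"
        )
        res_swapped = de.nb_de_test(CountMatrix(cm.counts, swapped_meta))
        assert np.allclose(
            res["log2FoldChange"], -res_swapped["log2FoldChange"], atol=1e-6
        )
        assert np.allclose(res["pvalue"], res_swapped["pvalue"], atol=1e-8)

    def test_matches_deseq2_reference_implementation(self):
        """Cross-check against pydeseq2 on a small planted fixture."""
        planted = [(f"G{i:04d}", 2.0) for i in range(10)]
        cm, _ = _bulk(planted, seed=3, n_genes=60, n=12, base=200.0)
        mine = de.nb_de_test(cm).set_index("gene")

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        dds = DeseqDataSet(
            counts=cm.counts.T,
            metadata=cm.meta.rename(columns={"group": "condition"}),
            design="~condition",
            quiet=True,
        )
        dds.deseq2()
        stats = DeseqStats(
            dds, contrast=["condition", "IPF", "nonIPF"], quiet=True
        )
        stats.summary()
        ref = stats.results_df
        diff = (mine["log2FoldChange"] - ref["log2FoldChange"]).abs()
        assert diff.max() < 0.1
        ref_flags = (ref["padj"] < 0.05) & (ref["log2FoldChange"].abs() >= 1)
        assert (mine["is_degene"] == ref_flags).all()

    def test_validation_errors(self):
        cm, _ = _bulk([], seed=7, n_genes=10, n=2)
        meta = cm.meta.copy()
        meta["group"] = ["A"] * 3 + ["B"] * 1
        with pytest.raises(ValueError):
            de.nb_de_test(CountMatrix(cm.counts, meta))
        meta["group"] = ["A", "B", "C", "A"]
        with pytest.raises(ValueError):
            de.nb_de_test(CountMatrix(cm.counts, meta))


class TestSummaries:
    def test_stated_formula_on_single_cell(self):
        counts = pd.DataFrame({"c0": [10, 0]}, index=["g1", "g2"])
        meta = pd.DataFrame(
            {"cell_type": ["macrophage"], "organ": ["lung"]}, index=["c0"]
        )
        summary = de.summarize_expression(CountMatrix(counts, meta))
        g1 = summary[summary["gene"] == "g1"].iloc[0]
        assert g1["mean_log_cp10k"] == pytest.approx(np.log(10001), abs=1e-9)
        assert g1["frac_expressing"] == 1.0
        g2 = summary[summary["gene"] == "g2"].iloc[0]
        assert g2["mean_log_cp10k"] == 0.0
        assert g2["frac_expressing"] == 0.0

    def test_fractions_bounded(self):
        summary = de.summarize_expression(_sc_matrix(seed=8))
        assert summary["frac_expressing"].between(0, 1).all()
        assert (summary["mean_log_cp10k"] >= 0).all()


class TestPerCellType:
    def _pair(self, planted, seeds=(10, 11)):
        common = dict(
            n_genes=30,
            gene_names=[f"G{i:02d}" for i in range(29)] + ["TARGET"],
            base_mean=3.0, dispersion=0.4,
            n_cells_per_type={"macrophage": 40, "fibroblast": 40},
            organ="lung",
        )
        ipf = syn.simulate_counts(
            syn.ExpressionSimSpec(**common, planted_de=planted, seed=seeds[0]),
            "single_cell",
        )
        ctrl = syn.simulate_counts(
            syn.ExpressionSimSpec(**common, seed=seeds[1]), "single_cell"
        )
        return ipf, ctrl

    def test_planted_gene_flagged_only_in_its_cell_type(self):
        ipf, ctrl = self._pair([("TARGET", 10.0, "macrophage")])
        results = de.per_celltype_de(ipf, ctrl)
        mac = results["macrophage"].set_index("gene").loc["TARGET"]
        fib = results["fibroblast"].set_index("gene").loc["TARGET"]
        assert mac["is_degene"] and mac["log2FoldChange"] > 8
        assert not fib["is_degene"]

    def test_condition_swap_negates_fold_changes(self):
        ipf, ctrl = self._pair([("TARGET", 2.0, "macrophage")])
        fwd = de.per_celltype_de(ipf, ctrl)["macrophage"]
        rev = de.per_celltype_de(ctrl, ipf)["macrophage"]
        assert np.allclose(
            fwd["log2FoldChange"], -rev["log2FoldChange"], atol=1e-6
        )

    def test_one_sided_cell_type_skipped_with_warning(self, caplog):
        ipf, ctrl = self._pair([])
        keep = ctrl.meta["cell_type"] == "macrophage"
        ctrl_only_mac = ctrl.subset_cols(ctrl.meta.index[keep])
        with caplog.at_level("WARNING"):
            results = de.per_celltype_de(ipf, ctrl_only_mac)
        assert set(results) == {"macrophage"}
        assert "fibroblast" in caplog.text

    def test_no_shared_cell_types_is_an_error(self):
        ipf, ctrl = self._pair([])
        keep_mac = ipf.meta["cell_type"] == "macrophage"
        keep_fib = ctrl.meta["cell_type"] == "fibroblast"
        with pytest.raises(ValueError):
            de.per_celltype_de(
                ipf.subset_cols(ipf.meta.index[keep_mac]),
                ctrl.subset_cols(ctrl.meta.index[keep_fib]),
            )
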