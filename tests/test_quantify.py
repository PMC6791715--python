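"""RPKM arithmetic, replicate merging, and run-level sequencing statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import tempomod as tm
from tempomod.datasets import DK1622_GENOME_BP
from tempomod.errors import DesignError, UndefinedStatisticError, ValidationError


class TestSampleStats:
    def test_published_time_course_rates_and_clean_reads(self, dk1622_sheet):
        out = tm.sample_stats(dk1622_sheet, read_len_bp=100,
                              genome_len_bp=DK1622_GENOME_BP)
        assert out.loc["WT_0_1", "clean_reads"] == 1192960
        assert out.loc["WT_0_1", "rrna_rate_pct"] == 98.07
        assert out.loc["WT_0_1", "coverage_x"] == 13.05
        assert out.loc["WT_48_1", "clean_reads"] == 1296267
        assert out.loc["WT_48_1", "coverage_x"] == 14.18

    def test_zero_rrna_and_zero_mapped(self):
        sheet = pd.DataFrame({"sample_id": ["a"], "time_h": [0], "replicate": [1],
                              "mapped_reads": [1000], "rrna_reads": [0]})
        out = tm.sample_stats(sheet)
        assert out.loc["a", "clean_reads"] == 1000
        assert out.loc["a", "rrna_rate_pct"] == 0.0
        sheet.loc[0, "mapped_reads"] = 0
        with pytest.raises(UndefinedStatisticError):
            tm.sample_stats(sheet)


class TestRpkm:
    @pytest.mark.parametrize("reads,length,lib,expected", [
        (0, 1000, 10**6, 0.0),
        (100, 1000, 10**6, 100.0),
        (50, 500, 2 * 10**6, 50.0),
    ])
    def test_unit_scale(self, reads, length, lib, expected):
        assert tm.rpkm(reads, length, lib) == pytest.approx(expected)

    @pytest.mark.parametrize("length,lib", [(0, 10**6), (-5, 10**6), (500, 0)])
    def test_domain_errors(self, length, lib):
        with pytest.raises(ValidationError):
            tm.rpkm(10, length, lib)

    @settings(derandomize=True, max_examples=50)
    @given(reads=st.integers(0, 10**7), length=st.integers(1, 20000),
           lib=st.integers(1, 10**9), scale=st.integers(2, 9))
    def test_linearity_and_inverse_proportionality(self, reads, length, lib, scale):
        base = tm.rpkm(reads, length, lib)
        assert tm.rpkm(scale * reads, length, lib) == pytest.approx(scale * base)
        assert tm.rpkm(reads, scale * length, lib) == pytest.approx(base / scale)
        assert tm.rpkm(reads, length, scale * lib) == pytest.approx(base / scale)


class TestBuildExpressionTable:
    def test_merged_is_mean_of_two_replicates(self, make_toy_et):
        et = make_toy_et([10, 10, 10], [30, 30, 30])
        assert (et.rpkm_merged.iloc[0] == 20).all()

    def test_conservation_and_brute_force_merge(self, small_bundle, small_et):
        b, et = small_bundle, small_et
        # per-sample read-count conservation under the RPKM transform
        lengths = b.annotation.set_index("gene_id")["length_bp"].loc[et.genes]
        for col in et.rpkm_rep.columns:
            lib = et.library_sizes[col]
            back = (et.rpkm_rep[col] * lengths * lib / 1e9).sum()
            assert back == pytest.approx(et.counts[col].sum(), rel=1e-9)
        # gene-by-gene independent recomputation of rep and merged values
        rng = np.random.default_rng(0)
        meta = b.sheet.set_index("sample_id")
        for gene in rng.choice(et.genes, 5, replace=False):
            length = lengths[gene]
            for t in et.times_h:
                vals = []
                for r in (1, 2):
                    sid = f"WT_{t}_{r}"
                    lib = meta.loc[sid, "mapped_reads"] - meta.loc[sid, "rrna_reads"]
                    vals.append(b.counts.loc[gene, sid] * 1e9 / (length * lib))
                    assert et.rpkm_rep.loc[gene, (t, r)] == pytest.approx(vals[-1])
                assert et.rpkm_merged.loc[gene, t] == pytest.approx(np.mean(vals))

    def test_incomplete_design_raises(self, small_bundle):
        b = small_bundle
        cm = b.counts.drop(columns=["WT_96_2"])
        sheet = b.sheet[b.sheet["sample_id"] != "WT_96_2"]
        with pytest.raises(DesignError):
            tm.build_expression_table(cm, b.annotation, sheet)


class TestConcordance:
    def test_copy_and_scaling_give_unity(self, small_et):
        et = small_et
        rep = et.rpkm_rep.copy()
        for factor in (1.0, 3.0):
            rep[(0, 2)] = factor * rep[(0, 1)]
            et2 = tm.ExpressionTable(et.counts, rep, et.rpkm_merged, et.library_sizes)
            assert tm.sample_concordance_r2(et2, 0) == pytest.approx(1.0)

    def test_matches_textbook_pearson_squared(self, make_toy_et):
        a = [1.0, 4.0, 2.0, 8.0, 5.0]
        bvec = [2.0, 5.0, 1.0, 9.0, 4.0]
        cols = pd.MultiIndex.from_product([[0], [1, 2]], names=["time_h", "replicate"])
        rpkm = pd.DataFrame(np.column_stack([a, bvec]), columns=cols,
                            index=pd.Index([f"g{i}" for i in range(5)], name="gene_id"))
        et = tm.ExpressionTable(rpkm * 0 + 100, rpkm,
                                rpkm.T.groupby(level="time_h").mean().T,
                                pd.Series(1e6, index=cols))
        expected = sps.pearsonr(a, bvec).statistic ** 2
        assert tm.sample_concordance_r2(et, 0) == pytest.approx(expected)
        # symmetry in the replicates
        swapped = rpkm.copy()
        swapped[(0, 1)], swapped[(0, 2)] = rpkm[(0, 2)], rpkm[(0, 1)]
        et_sw = tm.ExpressionTable(rpkm * 0 + 100, swapped, et.rpkm_merged,
                                   et.library_sizes)
        assert tm.sample_concordance_r2(et_sw, 0) == pytest.approx(expected)

    def test_zero_variance_raises(self, make_toy_et):
        cols = pd.MultiIndex.from_product([[0], [1, 2]], names=["time_h", "replicate"])
        rpkm = pd.DataFrame([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]], columns=cols,
                            index=pd.Index(list("abc"), name="gene_id"))
        et = tm.ExpressionTable(rpkm * 0 + 100, rpkm,
                                rpkm.T.groupby(level="time_h").mean().T,
                                pd.Series(1e6, index=cols))
        with pytest.raises(UndefinedStatisticError):
            tm.sample_concordance_r2(et, 0)
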