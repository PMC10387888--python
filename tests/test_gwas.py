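"""Summary-statistic ingest, filtering, functional weighting and gene scores."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from pathnetgwas import gwas


def _write_sumstats(path, rows, header="chrom\tpos\teffect_allele\tother_allele\tp\trsid\tfs"):
    path.write_text("\n".join([header, *rows]) + "\n")
    return path


class TestReadSummaryStats:
    def test_valid_rows_parse_identically(self, tmp_path):
        f = _write_sumstats(tmp_path / "s.tsv", [
            "1\t100\tA\tG\t0.01\trs1\t",
            "chr2\t200\tC\tT\t0.5\trs2\t0.5",
            "X\t300\tG\tA\t0.9\trs3\t",
        ])
        recs = gwas.read_summary_stats(f)
        assert len(recs) == 3
        assert recs[0].chrom == "1" and recs[1].chrom == "2"  # chr prefix stripped
        assert recs[1].fs == 0.5 and recs[1].p_w == pytest.approx(0.5 / 10**0.5)

    def test_unparsable_p_is_dropped(self, tmp_path):
        f = _write_sumstats(tmp_path / "s.tsv", [
            "1\t100\tA\tG\tNA\trs1\t",
            "1\t200\tC\tT\t0.2\trs2\t",
            "1\t300\tC\tT\t1.5\trs3\t",
        ])
        recs = gwas.read_summary_stats(f)
        assert [r.rsid for r in recs] == ["rs2"]

    def test_header_only_file_gives_empty_list(self, tmp_path):
        f = _write_sumstats(tmp_path / "s.tsv", [])
        assert gwas.read_summary_stats(f) == []

    def test_missing_required_column_is_configuration_error(self, tmp_path):
        f = (tmp_path / "s.tsv")
        f.write_text("chrom\tpos\tp\n1\t100\t0.5\n")
        with pytest.raises(gwas.ColumnSpecError):
            gwas.read_summary_stats(f)

    def test_column_spec_remaps_names(self, tmp_path):
        f = (tmp_path / "s.tsv")
        f.write_text("CHR\tBP\tEA\tOA\tPVAL\n1\t100\tA\tG\t0.01\n")
        recs = gwas.read_summary_stats(
            f, {"chrom": "CHR", "pos": "BP", "effect_allele": "EA",
                "other_allele": "OA", "p": "PVAL"})
        assert len(recs) == 1 and recs[0].p_gwas == 0.01


class TestFilter:
    def test_cutoff_is_strict(self):
        recs = [_rec(p) for p in (0.01, 0.05, 0.9)]
        kept = gwas.filter_by_pvalue(recs, 0.05)
        assert [r.p_gwas for r in kept] == [0.01]

    def test_cutoff_one_keeps_everything_below_one(self):
        recs = [_rec(p) for p in (0.2, 0.8)]
        assert len(gwas.filter_by_pvalue(recs, 1.0)) == 2

    def test_empty_input(self):
        assert gwas.filter_by_pvalue([], 0.05) == []

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_output_size_monotone_in_cutoff(self, ps):
        recs = [_rec(p) for p in ps]
        sizes = [len(gwas.filter_by_pvalue(recs, c)) for c in (0.01, 0.05, 0.5, 1.0)]
        assert sizes == sorted(sizes)


def _rec(p, fs=None, rsid=None):
    return gwas.SnpRecord(chrom="1", pos=100, effect_allele="A",
                          other_allele="G", p_gwas=p, rsid=rsid, fs=fs)


class TestFunctionalWeighting:
    @pytest.mark.parametrize("p, fs, expected", [
        (0.04, 0.0, 0.04),
        (0.04, 1.0, 0.004),
        (0.05, 0.5, 0.05 / 10**0.5),
    ])
    def test_weighting_formula(self, p, fs, expected):
        (out,) = gwas.apply_functional_weighting([_rec(p, fs=fs)])
        assert out.p_w == pytest.approx(expected, rel=1e-12)
        # log-space oracle: log10 p_w = log10 p - fs
        assert math.log10(out.p_w) == pytest.approx(math.log10(p) - fs, abs=1e-12)

    def test_missing_fs_means_no_weighting(self):
        (out,) = gwas.apply_functional_weighting([_rec(0.3)])
        assert out.p_w == 0.3

    def test_fs_source_by_rsid(self):
        (out,) = gwas.apply_functional_weighting(
            [_rec(0.1, rsid="rs7")], fs_source={"rs7": 1.0})
        assert out.p_w == pytest.approx(0.01)

    def test_fs_out_of_range_names_the_record(self):
        with pytest.raises(ValueError, match="rs9"):
            gwas.apply_functional_weighting([_rec(0.1, rsid="rs9")],
                                            fs_source={"rs9": 1.5})

    @given(st.floats(1e-10, 1.0), st.floats(0.0, 1.0))
    def test_weighted_p_never_exceeds_raw(self, p, fs):
        (out,) = gwas.apply_functional_weighting([_rec(p, fs=fs)])
        assert out.p_w <= out.p_gwas
        if fs == 0.0:
            assert out.p_w == out.p_gwas
        elif fs > 1e-10:  # below that, 10**fs rounds to 1.0 in floats
            assert out.p_w < out.p_gwas


class TestSnpToGeneMapping:
    gene = gwas.GeneModel(gene_id="g1", chrom="1", start=100, end=200, window=0)

    def test_half_open_boundaries(self):
        inside = _snp_at(101)   # 0-based 100 -> inside [100, 200)
        outside = _snp_at(100)  # 0-based 99 -> outside
        hits = gwas.map_snps_to_genes([inside, outside], [self.gene])
        assert hits == {"g1": [inside.p_w]}

    def test_snp_in_overlapping_genes_assigned_to_both(self):
        g2 = gwas.GeneModel(gene_id="g2", chrom="1", start=150, end=250, window=0)
        hits = gwas.map_snps_to_genes([_snp_at(180)], [self.gene, g2])
        assert set(hits) == {"g1", "g2"}

    def test_chromosome_prefix_normalized(self):
        g = gwas.GeneModel(gene_id="g3", chrom="chr1", start=100, end=200, window=0)
        assert "g3" in gwas.map_snps_to_genes([_snp_at(150)], [g])

    def test_window_extends_interval(self):
        g = gwas.GeneModel(gene_id="g4", chrom="1", start=1000, end=2000, window=500)
        assert "g4" in gwas.map_snps_to_genes([_snp_at(501)], [g])
        assert gwas.map_snps_to_genes([_snp_at(500)], [g]) == {}


def _snp_at(pos):
    return gwas.SnpRecord(chrom="1", pos=pos, effect_allele="A",
                          other_allele="G", p_gwas=0.01)


class TestGeneScore:
    def test_max_chi2_equals_min_p(self):
        assert gwas.gene_score([0.2, 0.01], "max_chi2") == 0.01

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=20))
    def test_max_chi2_min_p_equivalence_everywhere(self, ps):
        assert gwas.gene_score(ps, "max_chi2") == pytest.approx(min(ps))

    def test_sum_chi2_two_df_closed_form(self):
        # survival of a 2-df chi-squared is exp(-x/2)
        x = 2 * stats.chi2.isf(0.5, df=1)
        assert gwas.gene_score([0.5, 0.5], "sum_chi2") == pytest.approx(
            math.exp(-x / 2), rel=1e-10)
        assert gwas.gene_score([0.5, 0.5], "sum_chi2") == pytest.approx(0.634, abs=5e-4)

    @pytest.mark.parametrize("kind", ["max_chi2", "sum_chi2"])
    def test_single_snp_identity(self, kind):
        assert gwas.gene_score([0.37], kind) == pytest.approx(0.37)

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            gwas.gene_score([], "max_chi2")

    def test_sum_chi2_null_pvalues_are_uniform(self):
        # under the null the aggregated p is itself Uniform(0,1)
        rng = np.random.default_rng(7)
        ps = rng.uniform(size=(10_000, 5))
        chi2_sums = stats.chi2.isf(ps, df=1).sum(axis=1)
        gene_p = stats.chi2.sf(chi2_sums, df=5)
        assert stats.kstest(gene_p, "uniform").pvalue > 0.01


class TestFisherCombine:
    def test_single_dataset_identity(self):
        assert gwas.fisher_combine([0.37]).p_combined == pytest.approx(0.37)

    def test_worked_example_matches_independent_route(self):
        got = gwas.fisher_combine([0.05, 0.05])
        stat, p = stats.combine_pvalues([0.05, 0.05], method="fisher")
        assert got.chi2_stat == pytest.approx(stat)
        assert got.p_combined == pytest.approx(p)
        assert got.chi2_stat == pytest.approx(11.983, abs=1e-3)
        assert got.df == 4

    def test_all_ones_give_one(self):
        got = gwas.fisher_combine([1.0, 1.0])
        assert got.chi2_stat == 0.0 and got.p_combined == 1.0

    def test_nonpositive_p_is_error(self):
        with pytest.raises(ValueError):
            gwas.fisher_combine([0.1, 0.0])

    @given(st.lists(st.floats(1e-10, 1.0), min_size=2, max_size=6))
    def test_permutation_invariant_and_monotone(self, ps):
        base = gwas.fisher_combine(ps).p_combined
        assert gwas.fisher_combine(ps[::-1]).p_combined == pytest.approx(base)
        smaller = [ps[0] / 2] + list(ps[1:])
        assert gwas.fisher_combine(smaller).p_combined <= base + 1e-15


class TestCombineAcrossDatasets:
    def test_only_common_genes_combined(self):
        t1 = gwas.GeneScoreTable("d1", {"a": (0.1, 1, "max_chi2"),
                                        "b": (0.2, 1, "max_chi2")})
        t2 = gwas.GeneScoreTable("d2", {"a": (0.3, 2, "max_chi2")})
        combined = gwas.combine_across_datasets([t1, t2])
        assert set(combined.entries) == {"a"}
        p, n, kind = combined.entries["a"]
        assert kind == "fisher_combined" and n == 3
        assert p == pytest.approx(gwas.fisher_combine([0.1, 0.3]).p_combined)
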