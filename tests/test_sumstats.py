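"""Data model, file dialects, harmonization and the small per-record operations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugtarget_mr.sumstats import (
    AssocRecord,
    GeneModel,
    LDMatrix,
    SumstatsFormatError,
    TargetMap,
    cis_window,
    f_statistic,
    harmonize,
    read_gene_annotation,
    read_ld_matrix,
    read_sumstats,
    read_target_map,
    write_ld_matrix,
    write_results_table,
    write_sumstats,
)
from drugtarget_mr.sumstats import TargetEntry

from conftest import make_record, make_sumstats


class TestReadWrite:
    def test_ma_file_parses_all_valid_rows(self, tmp_path):
        path = tmp_path / "toy.ma"
        path.write_text(
            "SNP A1 A2 freq b se p N\n"
            "rs1 T C 0.3 0.1 0.02 5.7e-7 1000\n"
            "rs2 A G 0.5 -0.2 0.05 6.3e-5 1000\n"
            "rs3 G C 0.12 0.01 0.04 0.8 1000\n"
        )
        ss = read_sumstats(path, dialect="cojo_ma")
        assert len(ss) == 3
        assert ss.get("rs2").beta == -0.2

    def test_zero_se_row_rejected_not_fatal(self, tmp_path):
        path = tmp_path / "bad.ma"
        path.write_text(
            "SNP A1 A2 freq b se p N\n"
            "rs1 T C 0.3 0.1 0.02 5.7e-7 1000\n"
            "rs2 A G 0.5 -0.2 0.0 6.3e-5 1000\n"
            "rs3 G C 0.12 0.01 0.04 0.8 1000\n"
        )
        ss = read_sumstats(path, dialect="cojo_ma")
        assert len(ss) == 2
        assert "rs2" not in ss

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "nose.ma"
        path.write_text("SNP A1 A2 freq b p N\nrs1 T C 0.3 0.1 1e-4 10\n")
        with pytest.raises(SumstatsFormatError, match="se"):
            read_sumstats(path, dialect="cojo_ma")

    def test_round_trip_preserves_content(self, tmp_path):
        ss = make_sumstats([
            make_record("rs1", beta=0.123456, se=0.02, eaf=0.31, n=5000),
            make_record("rs2", ea="A", oa="G", beta=-1.5e-3, se=0.004, eaf=0.07),
        ])
        path = tmp_path / "rt.ma"
        write_sumstats(ss, path)
        back = read_sumstats(path, dialect="cojo_ma")
        assert len(back) == 2
        for rsid in ("rs1", "rs2"):
            a, b = ss.get(rsid), back.get(rsid)
            for fieldname in ("beta", "se", "eaf", "p"):
                assert getattr(a, fieldname) == pytest.approx(
                    getattr(b, fieldname), rel=1e-6)
            assert (a.effect_allele, a.other_allele) == (b.effect_allele, b.other_allele)

    def test_en_dash_minus_accepted(self, tmp_path):
        path = tmp_path / "dash.ma"
        path.write_text("SNP A1 A2 freq b se p N\nrs1 T C 0.21 −0.186 0.009 3.2E–86 31684\n")
        ss = read_sumstats(path, dialect="cojo_ma")
        assert ss.get("rs1").beta == pytest.approx(-0.186)
        assert ss.get("rs1").p == pytest.approx(3.2e-86)

    def test_eqtl_flat_groups_by_gene(self, tmp_path):
        path = tmp_path / "eqtl.tsv"
        path.write_text(
            "gene\tchr\tprobe_bp\tSNP\tsnp_chr\tsnp_bp\tA1\tA2\tfreq\tb\tse\tp\tN\n"
            "G1\t1\t500\trs1\t1\t400\tT\tC\t0.3\t0.2\t0.02\t1e-23\t30000\n"
            "G1\t1\t500\trs2\t1\t600\tA\tG\t0.4\t0.1\t0.02\t5.7e-7\t30000\n"
            "G2\t1\t900\trs1\t1\t400\tT\tC\t0.3\t0.05\t0.02\t0.012\t30000\n"
        )
        by_gene = read_sumstats(path, dialect="eqtl_flat")
        assert set(by_gene) == {"G1", "G2"}
        assert len(by_gene["G1"]) == 2
        assert by_gene["G2"].get("rs1").variant.pos == 400


class TestHarmonize:
    def test_matching_alleles_unchanged(self):
        ref = make_record(beta=0.1)
        other = make_record(beta=0.2)
        v = harmonize(ref, other)
        assert v.action == "kept" and v.record == other

    def test_swapped_alleles_flip_beta_and_eaf(self):
        ref = make_record(ea="T", oa="C", beta=0.1)
        other = make_record(ea="C", oa="T", beta=0.2, eaf=0.3)
        v = harmonize(ref, other)
        assert v.record.beta == pytest.approx(-0.2)
        assert v.record.eaf == pytest.approx(0.7)
        assert (v.record.effect_allele, v.record.other_allele) == ("T", "C")

    def test_strand_flip_resolved(self):
        ref = make_record(ea="T", oa="C", beta=0.1)
        other = make_record(ea="A", oa="G", beta=0.2, eaf=0.3)
        v = harmonize(ref, other)
        assert v.action == "strand_flipped"
        assert v.record.beta == pytest.approx(0.2)

    def test_palindromic_near_half_dropped(self):
        ref = make_record(ea="A", oa="T", eaf=0.50)
        other = make_record(ea="A", oa="T", eaf=0.50)
        v = harmonize(ref, other)
        assert not v.kept and v.reason == "palindromic_ambiguous"

    def test_palindromic_oriented_by_frequency(self):
        ref = make_record(ea="A", oa="T", eaf=0.10)
        other = make_record(ea="A", oa="T", eaf=0.88, beta=0.3)
        v = harmonize(ref, other)  # discordant frequency: reported on opposite strand
        assert v.kept
        assert v.record.beta == pytest.approx(-0.3)

    def test_irreconcilable_alleles_dropped(self):
        ref = make_record(ea="T", oa="C")
        other = make_record(ea="A", oa="C")
        v = harmonize(ref, other)
        assert not v.kept and v.reason == "allele_mismatch"

    def test_different_rsids_rejected(self):
        with pytest.raises(ValueError):
            harmonize(make_record("rs1"), make_record("rs2"))

    @given(
        beta=st.floats(-2, 2, allow_nan=False).filter(lambda b: abs(b) > 1e-6),
        eaf=st.floats(0.01, 0.99),
        swap=st.booleans(),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent_and_double_flip_identity(self, beta, eaf, swap):
        ref = make_record(ea="T", oa="C", beta=0.1)
        ea, oa = ("C", "T") if swap else ("T", "C")
        other = make_record(ea=ea, oa=oa, beta=beta, eaf=eaf)
        once = harmonize(ref, other)
        assert once.kept
        twice = harmonize(ref, once.record)
        assert twice.record == once.record  # idempotence
        # double allele swap returns the original (eaf reflection is float-exact
        # only up to rounding)
        from drugtarget_mr.sumstats import _flip
        back = _flip(_flip(other))
        assert back.beta == other.beta
        assert back.eaf == pytest.approx(other.eaf, abs=1e-15)
        assert (back.effect_allele, back.other_allele) == (
            other.effect_allele, other.other_allele)


class TestSmallOps:
    def test_cis_window_arithmetic(self):
        g = GeneModel("G", "5", 5_005_000, 5_000_000, 5_010_000)
        assert cis_window(g, 1_000_000) == ("5", 4_000_000, 6_010_000)

    def test_cis_window_clamps_at_one(self):
        g = GeneModel("G", "1", 600, 500, 700)
        assert cis_window(g, 1_000_000)[1] == 1

    def test_cis_window_zero_flank(self):
        g = GeneModel("G", "1", 600, 500, 700)
        assert cis_window(g, 0) == ("1", 500, 700)

    def test_f_statistic_table_value(self):
        # strongest loop-diuretic-target eQTL: beta -0.186, se 0.009
        rec = make_record(beta=-0.186, se=0.009)
        assert f_statistic(rec) == pytest.approx((0.186 / 0.009) ** 2, rel=1e-12)
        assert f_statistic(rec) == pytest.approx(427.1, abs=0.1)

    @pytest.mark.parametrize("beta,expected", [(0.0, 0.0), (0.02, 1.0)])
    def test_f_statistic_degenerate(self, beta, expected):
        assert f_statistic(make_record(beta=beta, se=0.02)) == pytest.approx(expected)

    def test_f_statistic_sign_invariant(self):
        a = f_statistic(make_record(beta=0.37, se=0.02))
        b = f_statistic(make_record(beta=-0.37, se=0.02))
        assert a == b


class TestContainers:
    def test_ld_matrix_validates(self):
        with pytest.raises(ValueError, match="diagonal"):
            LDMatrix(["a", "b"], np.array([[0.9, 0.1], [0.1, 1.0]]))
        with pytest.raises(ValueError, match="symmetric"):
            LDMatrix(["a", "b"], np.array([[1.0, 0.3], [0.1, 1.0]]))

    def test_ld_round_trip(self, tmp_path):
        r = np.array([[1.0, 0.5, 0.25], [0.5, 1.0, 0.5], [0.25, 0.5, 1.0]])
        ld = LDMatrix(["rs1", "rs2", "rs3"], r)
        path = tmp_path / "ld.tsv"
        write_ld_matrix(ld, path)
        back = read_ld_matrix(path)
        assert back.variants == ld.variants
        np.testing.assert_allclose(back.r, ld.r, atol=1e-9)

    def test_target_map_rejects_duplicates(self):
        with pytest.raises(ValueError, match="duplicate"):
            TargetMap([
                TargetEntry("torasemide", "diuretic", "SLC12A2"),
                TargetEntry("torasemide", "diuretic", "SLC12A2"),
            ])

    def test_target_map_many_to_many(self, tmp_path):
        path = tmp_path / "targets.tsv"
        path.write_text(
            "drug\tclass\tgene\n"
            "torasemide\tdiuretic\tSLC12A2\n"
            "torasemide\tdiuretic\tSLC12A1\n"
            "bumetanide\tdiuretic\tSLC12A2\n"
        )
        tm = read_target_map(path)
        assert tm.genes == ["SLC12A2", "SLC12A1"]
        assert tm.genes_for_class("diuretic") == ["SLC12A1", "SLC12A2"]

    def test_gene_annotation_reader(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text(
            "chrom\tstart\tend\tgene_id\tprobe_bp\n"
            "5\t127400000\t127500000\tSLC12A2\t127472419\n"
        )
        genes = read_gene_annotation(path)
        assert genes["SLC12A2"].probe_pos == 127472419

    def test_invalid_record_fields_rejected(self):
        with pytest.raises(ValueError):
            make_record(ea="T", oa="T")
        with pytest.raises(ValueError):
            make_record(se=-0.1)
        with pytest.raises(ValueError):
            make_record(eaf=1.2)


class TestResultsTable:
    def test_header_and_row_count(self, tmp_path):
        path = tmp_path / "out.tsv"
        write_results_table([{"Gene": "SLC12A2", "b_SMR": -0.150537}], path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 2
        assert lines[0].startswith("Gene\tProbe\tChr")

    def test_empty_input_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_results_table([], path)
        assert len(path.read_text().strip().split("\n")) == 1

    def test_round_trip_to_printed_precision(self, tmp_path):
        import pandas as pd

        path = tmp_path / "rt.tsv"
        write_results_table(
            [{"Gene": "G", "b_SMR": -0.1505376, "p_SMR": 1.054e-4}], path)
        back = pd.read_csv(path, sep="\t")
        assert back.loc[0, "b_SMR"] == pytest.approx(-0.1505376, rel=1e-5)
        assert back.loc[0, "p_SMR"] == pytest.approx(1.054e-4, rel=1e-5)
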