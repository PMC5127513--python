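"""Summary-statistic parsing, CI/SE conversion, LD matrix IO and harmonisation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrkit.sumstats import (
    Z_975,
    AssocStat,
    LDMatrix,
    SumstatsFormatError,
    ValidationError,
    VariantRecord,
    harmonise,
    read_ld,
    read_sumstats,
    se_from_ci,
    write_ld,
    write_sumstats,
)


def _variant(vid="rs1", ea="A", oa="G", eaf=0.3, chrom="1", pos=100):
    return VariantRecord(vid, chrom, pos, ea, oa, eaf)


def _stat(vid="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.02, p=0.01, n=1000,
          chrom="1", pos=100, **kw):
    return AssocStat(_variant(vid, ea, oa, eaf, chrom, pos), "trait", beta, se, p, n, **kw)


class TestVariantRecord:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ea": "A", "oa": "A"},
            {"eaf": 0.0},
            {"eaf": 1.0},
            {"pos": 0},
            {"ea": "N"},
        ],
    )
    def test_invariants_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            _variant(**{**{"vid": "rs1"}, **kwargs})

    def test_palindromic_detection(self):
        assert _variant(ea="A", oa="T").is_palindromic
        assert _variant(ea="G", oa="C").is_palindromic
        assert not _variant(ea="A", oa="G").is_palindromic

    def test_flip_complements_frequency(self):
        v = _variant(ea="T", oa="C", eaf=0.2).flipped()
        assert (v.effect_allele, v.other_allele, v.eaf) == ("C", "T", 0.8)


class TestAssocStat:
    def test_z_consistency_enforced(self):
        with pytest.raises(ValidationError):
            _stat(beta=0.1, se=0.02, z=3.0)  # beta/se = 5
        s = _stat(beta=0.1, se=0.02, z=5.0)
        assert s.z == 5.0

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValidationError):
            _stat(se=0.0)


class TestSeFromCI:
    def test_hand_computed_log_scale(self):
        # (ln 1.05 - ln 1.01) / (2 * 1.959964)
        assert se_from_ci(1.01, 1.05) == pytest.approx(0.009908, abs=5e-7)
        assert se_from_ci(1.02, 1.07) == pytest.approx(0.0122084, abs=5e-7)

    def test_symmetric_unit_interval(self):
        assert se_from_ci(math.exp(-Z_975), math.exp(Z_975)) == pytest.approx(1.0, rel=1e-12)

    def test_linear_scale(self):
        assert se_from_ci(-Z_975, Z_975, log_scale=False) == pytest.approx(1.0, rel=1e-12)

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValidationError):
            se_from_ci(1.05, 1.01)


class TestReadSumstats:
    HEADER = "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tOR\tSE\tL95\tU95\tP\tN\n"

    def test_or_with_ci_converted_to_log_odds(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text(self.HEADER + "rs7678928\t4\t89222827\tT\tC\t0.46\t.\t1.03\t.\t1.01\t1.05\t0.0055\t234783\n")
        (rec,) = read_sumstats(f)
        assert rec.beta == pytest.approx(math.log(1.03), rel=1e-12)
        assert rec.se == pytest.approx(se_from_ci(1.01, 1.05), rel=1e-12)

    def test_zero_beta(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text(self.HEADER + "rs1\t1\t100\tA\tG\t0.5\t0.0\t.\t1.0\t.\t.\t1.0\t100\n")
        (rec,) = read_sumstats(f)
        assert rec.beta == 0.0 and rec.beta / rec.se == 0.0

    def test_header_driven_column_order(self, tmp_path):
        a = tmp_path / "a.tsv"
        b = tmp_path / "b.tsv"
        a.write_text("SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\nrs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t0.01\t500\n")
        b.write_text("N\tP\tSE\tBETA\tEAF\tOA\tEA\tPOS\tCHR\tSNP\n500\t0.01\t0.02\t0.1\t0.3\tG\tA\t100\t1\trs1\n")
        assert read_sumstats(a) == read_sumstats(b)

    def test_missing_mandatory_column(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("SNP\tCHR\tPOS\tEA\tOA\tBETA\tSE\tP\tN\nrs1\t1\t100\tA\tG\t0.1\t0.02\t0.01\t500\n")
        with pytest.raises(SumstatsFormatError, match="EAF"):
            read_sumstats(f)

    def test_invalid_eaf_names_variant(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text("SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\nrs99\t1\t100\tA\tG\t1.5\t0.1\t0.02\t0.01\t500\n")
        with pytest.raises(ValidationError, match="rs99"):
            read_sumstats(f)

    def test_malformed_row_reported_with_line_number(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text(
            "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"
            "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t0.01\t500\n"
            "rs2\t1\t200\tA\tG\t0.3\tnot_a_number\t0.02\t0.01\t500\n"
        )
        with pytest.warns(UserWarning, match="line.*3"):
            recs = read_sumstats(f)
        assert [r.variant.id for r in recs] == ["rs1"]

    def test_round_trip_preserves_fields(self, tmp_path):
        recs = [
            _stat("rs1", beta=0.123456789012, se=0.0123456789012, p=1.23e-9, n=12345),
            _stat("rs2", ea="C", oa="T", eaf=0.87654321, beta=-0.05, se=0.011, p=0.5,
                  n=5000, n_cases=1000, n_controls=4000),
        ]
        f = tmp_path / "rt.tsv"
        write_sumstats(recs, f)
        back = read_sumstats(f)
        for a, b in zip(recs, back):
            assert b.variant == a.variant
            assert b.beta == pytest.approx(a.beta, rel=1e-12)
            assert b.se == pytest.approx(a.se, rel=1e-12)
            assert b.p == pytest.approx(a.p, rel=1e-12)
            assert (b.n, b.n_cases, b.n_controls) == (a.n, a.n_cases, a.n_controls)


class TestLDMatrix:
    def test_identity_round_trip(self, tmp_path):
        ld = LDMatrix(["a", "b", "c"], np.eye(3))
        f = tmp_path / "ld.tsv"
        write_ld(ld, f)
        back = read_ld(f)
        assert back.ids == ld.ids
        np.testing.assert_allclose(back.r, ld.r, rtol=1e-12)

    def test_half_stored_matrix_symmetrised(self):
        r = np.eye(3)
        r[0, 1] = 0.7  # stored once
        with pytest.warns(UserWarning, match="symmetrised"):
            ld = LDMatrix(["a", "b", "c"], r)
        assert ld.r[1, 0] == ld.r[0, 1]

    def test_negative_eigenvalue_repaired(self):
        # strongly inconsistent correlations: min eigenvalue < 0
        r = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(r).min() < 0
        with pytest.warns(UserWarning, match="repaired"):
            ld = LDMatrix(list("abc"), r)
        # oracle: eigenvalue clipping keeps the matrix a unit-diagonal PSD matrix
        assert ld.min_eigenvalue() >= -1e-10
        np.testing.assert_allclose(np.diag(ld.r), 1.0, rtol=1e-12)

    def test_non_square_rejected(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("\ta\tb\na\t1\t0\n")
        with pytest.raises(SumstatsFormatError):
            read_ld(f)

    def test_round_trip_12_digits(self, tmp_path):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((4, 4))
        c = np.corrcoef(a @ a.T)
        ld = LDMatrix(list("wxyz"), c)
        f = tmp_path / "ld.tsv"
        write_ld(ld, f)
        np.testing.assert_allclose(read_ld(f).r, ld.r, rtol=1e-11, atol=1e-12)


class TestHarmonise:
    def test_opposite_allele_sign_flipped(self):
        exp = _stat("rs1", ea="A", oa="G", eaf=0.3, beta=0.1)
        out = _stat("rs1", ea="G", oa="A", eaf=0.7, beta=-0.04)
        (pair,) = harmonise([exp], [out]).pairs
        assert pair.flipped
        assert pair.Gamma.beta == pytest.approx(0.04)
        assert pair.Gamma.variant.effect_allele == "A"
        assert pair.Gamma.variant.eaf == pytest.approx(0.3)

    def test_strand_complement_resolved(self):
        exp = _stat("rs1", ea="T", oa="C", eaf=0.3, beta=0.1)
        out = _stat("rs1", ea="A", oa="G", eaf=0.3, beta=0.05)
        (pair,) = harmonise([exp], [out]).pairs
        assert not pair.flipped
        assert pair.Gamma.beta == pytest.approx(0.05)

    def test_palindromic_ambiguous_excluded_by_default(self):
        exp = _stat("rs1", ea="A", oa="T", eaf=0.5)
        out = _stat("rs1", ea="A", oa="T", eaf=0.5)
        res = harmonise([exp], [out])
        assert res.pairs == []
        assert res.excluded["rs1"] == "palindromic_ambiguous_eaf"

    def test_palindromic_kept_when_requested_and_flagged(self):
        exp = _stat("rs1", ea="A", oa="T", eaf=0.5)
        out = _stat("rs1", ea="A", oa="T", eaf=0.5)
        (pair,) = harmonise([exp], [out], policy="keep").pairs
        assert pair.palindromic_flag

    def test_palindromic_outside_window_kept(self):
        exp = _stat("rs1", ea="A", oa="T", eaf=0.2)
        out = _stat("rs1", ea="A", oa="T", eaf=0.2)
        (pair,) = harmonise([exp], [out]).pairs
        assert pair.palindromic_flag

    def test_irreconcilable_alleles_excluded_with_reason(self):
        exp = _stat("rs1", ea="A", oa="G")
        out = _stat("rs1", ea="A", oa="C")
        res = harmonise([exp], [out])
        assert res.excluded["rs1"] == "allele_mismatch"

    def test_unpaired_variants_dropped(self):
        exp = [_stat("rs1"), _stat("rs2", pos=200)]
        out = [_stat("rs1")]
        res = harmonise(exp, out)
        assert len(res) == 1

    def test_idempotent_on_aligned_pairs(self):
        exp = _stat("rs1", beta=0.1)
        out = _stat("rs1", beta=0.05)
        first = harmonise([exp], [out]).pairs[0]
        again = harmonise([first.gamma], [first.Gamma]).pairs[0]
        assert again.gamma == first.gamma
        assert again.Gamma == first.Gamma
        assert not again.flipped

    def test_allele_coding_invariance(self):
        """Recoding the outcome on the other allele leaves the harmonised numbers unchanged."""
        exp = _stat("rs1", ea="A", oa="G", eaf=0.3, beta=0.1)
        out = _stat("rs1", ea="A", oa="G", eaf=0.3, beta=0.05)
        p1 = harmonise([exp], [out]).pairs[0]
        p2 = harmonise([exp], [out.flipped()]).pairs[0]
        assert p2.gamma == p1.gamma
        assert p2.Gamma.beta == p1.Gamma.beta
        v1, v2 = p1.Gamma.variant, p2.Gamma.variant
        assert (v2.effect_allele, v2.other_allele) == (v1.effect_allele, v1.other_allele)
        assert v2.eaf == pytest.approx(v1.eaf, rel=1e-12)


@settings(derandomize=True, max_examples=50)
@given(
    lower=st.floats(0.5, 1.5),
    width=st.floats(1e-4, 1.0),
    level=st.floats(0.5, 0.999),
)
def test_se_from_ci_positive_and_monotone_in_width(lower, width, level):
    se1 = se_from_ci(lower, lower + width, level=level)
    se2 = se_from_ci(lower, lower + 2 * width, level=level)
    assert 0 < se1 < se2
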