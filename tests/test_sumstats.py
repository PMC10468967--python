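"""Summary-statistics I/O round-trips and allele harmonization rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrtriad.sumstats import (
    CANONICAL_COLUMNS, HarmonizationResult, SumstatsFormatError, VariantAssoc,
    harmonize_pair, harmonize_tables, read_sumstats, write_sumstats,
)
from .conftest import make_table


def va(ea="A", oa="G", beta=0.2, eaf=0.3, vid="rs1", **kw):
    kw.setdefault("chrom", "1")
    kw.setdefault("pos", 1000)
    kw.setdefault("se", 0.05)
    kw.setdefault("pval", 1e-6)
    return VariantAssoc(variant_id=vid, effect_allele=ea, other_allele=oa,
                        beta=beta, eaf=eaf, **kw)


class TestReadWrite:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        rows = [{"beta": rng.normal(), "se": float(rng.uniform(0.01, 1)),
                 "pval": float(rng.uniform(1e-10, 1)),
                 "eaf": float(rng.uniform(0.01, 0.99))} for _ in range(100)]
        table = make_table(rows)
        path = tmp_path / "t.tsv"
        write_sumstats(table, path)
        back = read_sumstats(path, trait_id="trait")
        pd.testing.assert_frame_equal(back.data, table.data)
        assert back.n_rejected == 0

    def test_well_formed_three_rows(self, tmp_path):
        table = make_table([{"beta": 0.1, "se": 0.1, "pval": 0.5}] * 3)
        path = tmp_path / "t.tsv"
        write_sumstats(table, path)
        assert len(read_sumstats(path)) == 3

    def test_zero_se_row_rejected_and_counted(self, tmp_path):
        table = pd.DataFrame({
            "variant_id": ["rs1", "rs2"], "chrom": ["1", "1"],
            "pos": [100, 200], "effect_allele": ["A", "A"],
            "other_allele": ["G", "G"], "eaf": [0.3, 0.3],
            "beta": [0.1, 0.1], "se": [0.1, 0.0], "pval": [0.5, 0.5],
            "n": [100.0, 100.0]})
        path = tmp_path / "t.tsv"
        table.to_csv(path, sep="\t", index=False)
        back = read_sumstats(path)
        assert len(back) == 1 and back.n_rejected == 1
        assert list(back.data["variant_id"]) == ["rs1"]

    def test_header_alias_mapping_matches_canonical(self, tmp_path):
        table = make_table([{"beta": 0.12, "se": 0.03, "pval": 1e-4}])
        canonical = tmp_path / "canonical.tsv"
        write_sumstats(table, canonical)
        aliased = tmp_path / "aliased.tsv"
        df = table.data.rename(columns={"beta": "BETA", "se": "SE",
                                        "pval": "P", "variant_id": "SNP"})
        df.to_csv(aliased, sep="\t", index=False)
        a = read_sumstats(canonical, trait_id="t")
        b = read_sumstats(aliased, trait_id="t", column_map={
            "BETA": "beta", "SE": "se", "P": "pval", "SNP": "variant_id"})
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_empty_table_round_trip(self, tmp_path):
        table = make_table([])
        path = tmp_path / "t.tsv"
        write_sumstats(table, path)
        assert path.read_text().startswith("variant_id\t")
        assert len(read_sumstats(path)) == 0

    def test_missing_eaf_written_as_na_and_read_back(self, tmp_path):
        table = make_table([{"beta": 0.1, "se": 0.1, "pval": 0.5, "eaf": np.nan}])
        path = tmp_path / "t.tsv"
        write_sumstats(table, path)
        assert "NA" in path.read_text()
        back = read_sumstats(path)
        assert np.isnan(back.data["eaf"].iloc[0])

    def test_missing_mandatory_column_is_format_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        make_table([{"beta": 0.1, "se": 0.1, "pval": 0.5}]).data.drop(
            columns=["se"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(SumstatsFormatError, match="se"):
            read_sumstats(path)

    def test_duplicate_variant_ids_rejected(self):
        with pytest.raises(SumstatsFormatError, match="duplicate"):
            make_table([{"variant_id": "rs1", "beta": 0, "se": 1, "pval": 0.5},
                        {"variant_id": "rs1", "beta": 0, "se": 1, "pval": 0.5}])


# hand-built truth table: exposure (A, G); every ordered outcome allele pair
ALLELE_TRUTH_TABLE = [
    # (outcome ea, oa) -> (status, outcome beta after alignment)
    (("A", "G"), ("ok", 0.3)),       # direct match
    (("G", "A"), ("ok", -0.3)),      # swap
    (("T", "C"), ("ok", 0.3)),       # strand flip
    (("C", "T"), ("ok", -0.3)),      # strand flip + swap
    (("A", "C"), ("incompatible", None)),
    (("C", "A"), ("incompatible", None)),
    (("A", "T"), ("incompatible", None)),
    (("T", "A"), ("incompatible", None)),
    (("G", "C"), ("incompatible", None)),
    (("C", "G"), ("incompatible", None)),
    (("G", "T"), ("incompatible", None)),
    (("T", "G"), ("incompatible", None)),
]


class TestHarmonization:
    @pytest.mark.parametrize("out_alleles,expected", ALLELE_TRUTH_TABLE)
    def test_allele_configuration_truth_table(self, out_alleles, expected):
        res = harmonize_pair(va("A", "G", 0.2),
                             va(out_alleles[0], out_alleles[1], 0.3, eaf=0.7))
        status, beta = expected
        assert res.status == status
        if status == "ok":
            assert res.outcome.beta == pytest.approx(beta)
            assert res.outcome.effect_allele == "A"
            assert res.outcome.other_allele == "G"
            assert res.exposure.effect_allele == res.outcome.effect_allele

    def test_swap_flips_sign_and_eaf(self):
        res = harmonize_pair(va("A", "G", 0.2), va("G", "A", 0.3, eaf=0.7))
        assert res.outcome.beta == pytest.approx(-0.3)
        assert res.outcome.eaf == pytest.approx(0.3)

    def test_palindromic_near_half_eaf_dropped(self):
        res = harmonize_pair(va("A", "T", 0.2, eaf=0.50), va("A", "T", 0.3, eaf=0.5))
        assert res.status == "drop_palindromic"

    def test_palindromic_missing_eaf_dropped(self):
        res = harmonize_pair(va("A", "T", 0.2, eaf=None), va("A", "T", 0.3, eaf=0.2))
        assert res.status == "drop_palindromic"

    def test_palindromic_window_boundary(self):
        inside = harmonize_pair(va("A", "T", 0.2, eaf=0.43), va("A", "T", 0.3, eaf=0.4))
        outside = harmonize_pair(va("A", "T", 0.2, eaf=0.41), va("A", "T", 0.3, eaf=0.4))
        assert inside.status == "drop_palindromic"
        assert outside.status == "ok"

    def test_palindromic_opposite_eaf_side_flips(self):
        res = harmonize_pair(va("A", "T", 0.2, eaf=0.2), va("A", "T", 0.3, eaf=0.8))
        assert res.ok and res.outcome.beta == pytest.approx(-0.3)
        assert res.outcome.eaf == pytest.approx(0.2)
        assert (res.outcome.effect_allele, res.outcome.other_allele) == ("A", "T")

    def test_palindromic_same_eaf_side_kept(self):
        res = harmonize_pair(va("C", "G", 0.2, eaf=0.2), va("C", "G", 0.3, eaf=0.25))
        assert res.ok and res.outcome.beta == pytest.approx(0.3)

    def test_different_variant_ids_rejected(self):
        with pytest.raises(ValueError):
            harmonize_pair(va(vid="rs1"), va(vid="rs2"))

    @given(st.sampled_from([p for p, (s, _) in ALLELE_TRUTH_TABLE if s == "ok"]),
           st.floats(-1, 1, allow_nan=False),
           st.floats(0.1, 0.9))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_harmonization_is_involution_safe(self, out_alleles, beta, eaf):
        first = harmonize_pair(va("A", "G", 0.2),
                               va(out_alleles[0], out_alleles[1], beta, eaf=eaf))
        assert first.ok
        again = harmonize_pair(first.exposure, first.outcome)
        assert again.ok
        assert again.outcome == first.outcome

    def test_harmonize_tables_pairs_shared_variants(self):
        exp = make_table([{"beta": 0.2, "se": 0.02, "pval": 1e-8},
                          {"beta": 0.1, "se": 0.02, "pval": 1e-6}])
        out_rows = exp.data.copy()
        out_rows.loc[0, ["effect_allele", "other_allele"]] = ["G", "A"]
        out_rows.loc[0, "beta"] = -0.3
        out_rows.loc[0, "eaf"] = 0.7
        out = make_table([], trait_id="out")
        out.data = out_rows
        h = harmonize_tables(exp, out)
        assert list(h["variant_id"]) == ["rs1", "rs2"]
        assert h.loc[0, "b_gy"] == pytest.approx(0.3)  # un-swapped
        assert (h["effect_allele"] == "A").all()
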