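import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrkit.summary_data import (SummaryDataError, harmonize,
                                orient_positive_exposure, read_summary_table)

from conftest import make_dataset, make_harmonized


def _write(tmp_path, text, name="stats.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadSummaryTable:
    def test_parses_valid_tsv(self, tmp_path):
        path = _write(tmp_path, (
            "SNP\tEA\tOA\tBETA\tSE\tP\n"
            "rs1\ta\tG\t0.1\t0.01\t1e-9\n"
            "rs2\tC\tT\t-0.2\t0.02\t1e-12\n"
            "rs3\tG\tA\t0.05\t0.01\t0.5\n"))
        ds = read_summary_table(path)
        assert len(ds) == 3
        assert list(ds.table["effect_allele"]) == ["A", "C", "G"]  # upper-cased
        assert ds.table["beta"].tolist() == [0.1, -0.2, 0.05]

    def test_invalid_rows_skipped(self, tmp_path):
        path = _write(tmp_path, (
            "SNP\tEA\tOA\tBETA\tSE\tP\n"
            "rs1\tA\tG\t0.1\t0.01\t1e-9\n"
            "rs2\tC\tT\t-0.2\t0\t1e-12\n"   # SE = 0
            "rs3\tG\tA\t0.05\t0.01\t0.5\n"))
        ds = read_summary_table(path)
        assert len(ds) == 2
        assert "rs2" not in set(ds.table["rsid"])

    def test_missing_mapped_column_is_fatal(self, tmp_path):
        path = _write(tmp_path, "SNP\tEA\tOA\tSE\tP\nrs1\tA\tG\t0.01\t1e-9\n")
        with pytest.raises(SummaryDataError, match="missing from header"):
            read_summary_table(path)

    def test_mostly_invalid_file_is_fatal(self, tmp_path):
        path = _write(tmp_path, (
            "SNP\tEA\tOA\tBETA\tSE\tP\n"
            "rs1\tA\tG\t0.1\t0\t1e-9\n"
            "rs2\tC\tT\t0.2\t0\t1e-9\n"
            "rs3\tG\tA\t0.05\t0.01\t0.5\n"))
        with pytest.raises(SummaryDataError, match="failed validation"):
            read_summary_table(path)

    def test_comma_delimiter_autodetected(self, tmp_path):
        path = _write(tmp_path, "SNP,EA,OA,BETA,SE,P\nrs1,A,G,0.1,0.01,1e-9\n",
                      name="stats.csv")
        assert len(read_summary_table(path)) == 1

    def test_custom_column_map(self, tmp_path):
        path = _write(tmp_path, "variant\tref\talt\tb\ts\tpval\nrs1\tG\tA\t0.1\t0.01\t1e-9\n")
        ds = read_summary_table(path, column_map={
            "rsid": "variant", "effect_allele": "ref", "other_allele": "alt",
            "beta": "b", "se": "s", "pvalue": "pval"})
        assert ds.table.loc[0, "effect_allele"] == "G"


# exposure rows paired with outcome rows covering every allele configuration
HARMONY_CASES = [
    # (exp EA, OA, eaf) (out EA, OA, eaf, beta) -> expected kept sign or drop reason
    ("match", ("A", "G", 0.3), ("A", "G", 0.3, 0.05), +1),
    ("swap", ("A", "G", 0.3), ("G", "A", 0.7, 0.05), -1),
    ("palindromic-concordant", ("A", "T", 0.2), ("A", "T", 0.25, 0.05), +1),
    ("palindromic-swap", ("A", "T", 0.2), ("T", "A", 0.75, 0.05), -1),
    ("palindromic-strand-discordant", ("C", "G", 0.2), ("C", "G", 0.8, 0.05), -1),
    ("palindromic-ambiguous", ("A", "T", 0.50, ), ("A", "T", 0.50, 0.05),
     "palindromic-ambiguous"),
    ("palindromic-band-edge", ("A", "T", 0.42), ("A", "T", 0.2, 0.05),
     "palindromic-ambiguous"),
    ("mismatch", ("A", "G", 0.3), ("A", "C", 0.3, 0.05), "allele-mismatch"),
]


class TestHarmonize:
    @pytest.mark.parametrize("label,exp_al,out_al,expected",
                             HARMONY_CASES, ids=[c[0] for c in HARMONY_CASES])
    def test_allele_configurations(self, label, exp_al, out_al, expected):
        exposure = make_dataset([
            {"rsid": "rs1", "effect_allele": exp_al[0], "other_allele": exp_al[1],
             "eaf": exp_al[2], "beta": 0.10, "se": 0.01, "pvalue": 1e-9},
            # anchor SNP so a drop never empties the harmonised set
            {"rsid": "rs_anchor", "effect_allele": "A", "other_allele": "G",
             "eaf": 0.3, "beta": 0.10, "se": 0.01, "pvalue": 1e-9}])
        outcome = make_dataset([
            {"rsid": "rs1", "effect_allele": out_al[0], "other_allele": out_al[1],
             "eaf": out_al[2], "beta": out_al[3], "se": 0.02, "pvalue": 0.01},
            {"rsid": "rs_anchor", "effect_allele": "A", "other_allele": "G",
             "eaf": 0.3, "beta": 0.02, "se": 0.02, "pvalue": 0.01}])
        h = harmonize(exposure, outcome)
        if isinstance(expected, str):
            assert "rs1" not in set(h.snps["rsid"])
            assert h.dropped.set_index("rsid").loc["rs1", "reason"] == expected
        else:
            got = h.snps.set_index("rsid").loc["rs1", "beta_out"]
            assert got == pytest.approx(expected * 0.05)

    def test_missing_in_outcome_logged(self):
        exposure = make_dataset([
            {"rsid": f"rs{i}", "effect_allele": "A", "other_allele": "G",
             "beta": 0.1, "se": 0.01, "pvalue": 1e-9} for i in range(10)])
        outcome = make_dataset([
            {"rsid": f"rs{i}", "effect_allele": "A", "other_allele": "G",
             "beta": 0.05, "se": 0.02, "pvalue": 0.01} for i in range(7)])
        h = harmonize(exposure, outcome)
        assert len(h) == 7
        assert (h.dropped["reason"] == "missing-in-outcome").sum() == 3
        # retained + dropped account for every exposure SNP
        assert len(h) + len(h.dropped) == 10

    def test_drop_all_policy_removes_palindromes(self):
        exposure = make_dataset([
            {"rsid": "rs1", "effect_allele": "A", "other_allele": "T",
             "eaf": 0.2, "beta": 0.1, "se": 0.01, "pvalue": 1e-9},
            {"rsid": "rs2", "effect_allele": "A", "other_allele": "G",
             "eaf": 0.2, "beta": 0.1, "se": 0.01, "pvalue": 1e-9}])
        outcome = make_dataset([
            {"rsid": "rs1", "effect_allele": "A", "other_allele": "T",
             "eaf": 0.2, "beta": 0.05, "se": 0.02, "pvalue": 0.01},
            {"rsid": "rs2", "effect_allele": "A", "other_allele": "G",
             "eaf": 0.2, "beta": 0.05, "se": 0.02, "pvalue": 0.01}])
        h = harmonize(exposure, outcome, palindrome_policy="drop_all")
        assert set(h.snps["rsid"]) == {"rs2"}

    def test_empty_intersection_fatal(self):
        exposure = make_dataset([{"rsid": "rs1", "effect_allele": "A",
                                  "other_allele": "G", "beta": 0.1, "se": 0.01,
                                  "pvalue": 1e-9}])
        outcome = make_dataset([{"rsid": "rs9", "effect_allele": "A",
                                 "other_allele": "G", "beta": 0.05, "se": 0.02,
                                 "pvalue": 0.01}])
        with pytest.raises(SummaryDataError, match="missing-in-outcome"):
            harmonize(exposure, outcome)

    def test_rerun_on_aligned_output_is_identity(self):
        exposure = make_dataset([
            {"rsid": "rs1", "effect_allele": "A", "other_allele": "G",
             "eaf": 0.3, "beta": 0.1, "se": 0.01, "pvalue": 1e-9}])
        outcome = make_dataset([
            {"rsid": "rs1", "effect_allele": "G", "other_allele": "A",
             "eaf": 0.7, "beta": 0.05, "se": 0.02, "pvalue": 0.01}])
        h1 = harmonize(exposure, outcome)
        aligned = make_dataset([
            {"rsid": "rs1", "effect_allele": "A", "other_allele": "G",
             "eaf": 0.3, "beta": h1.snps.loc[0, "beta_out"], "se": 0.02,
             "pvalue": 0.01}])
        h2 = harmonize(exposure, aligned)
        pd.testing.assert_frame_equal(h1.snps, h2.snps)


class TestOrientPositiveExposure:
    def test_flips_negative_exposure_rows(self):
        h = make_harmonized([-0.1, 0.1], [0.01, 0.01], [0.05, 0.05], [0.02, 0.02])
        o = orient_positive_exposure(h)
        assert o.snps["beta_exp"].tolist() == [0.1, 0.1]
        assert o.snps["beta_out"].tolist() == [-0.05, 0.05]
        assert o.snps["se_exp"].tolist() == h.snps["se_exp"].tolist()

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(
        st.floats(-1, 1).filter(lambda x: abs(x) > 1e-6),
        st.floats(-1, 1)), min_size=1, max_size=8))
    def test_idempotent_and_ratio_preserving(self, pairs):
        bx = [p[0] for p in pairs]
        by = [p[1] for p in pairs]
        h = make_harmonized(bx, [0.01] * len(bx), by, [0.02] * len(bx))
        once = orient_positive_exposure(h)
        twice = orient_positive_exposure(once)
        pd.testing.assert_frame_equal(once.snps, twice.snps)
        assert (once.snps["beta_exp"] >= 0).all()
        ratios_before = np.array(by) / np.array(bx)
        ratios_after = (once.snps["beta_out"] / once.snps["beta_exp"]).to_numpy()
        np.testing.assert_allclose(ratios_after, ratios_before, rtol=1e-12)
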