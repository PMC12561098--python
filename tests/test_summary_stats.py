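"""Summary-statistics I/O, instrument selection and harmonization."""

import numpy as np
import pandas as pd
import pytest

from mrmediate import (FormatError, InputError, InsufficientInstrumentsError,
                       InstrumentSet, build_summary_stats, f_statistic,
                       harmonize, read_summary_stats, select_instruments,
                       simulate_triangle, SimulationTruth, variance_explained)
from mrmediate.summary_stats import ACTION_DROP_MIS, ACTION_DROP_PAL, ACTION_FLIPPED

from conftest import make_table


def write_ssf(df: pd.DataFrame, path):
    """Write a canonical frame under the default GWAS-SSF column names."""
    from mrmediate.summary_stats import DEFAULT_DIALECT
    df.rename(columns=DEFAULT_DIALECT).to_csv(path, sep="\t", index=False)


class TestReadSummaryStats:
    def test_well_formed_table_passes_through(self, tmp_path):
        p = tmp_path / "ss.tsv"
        write_ssf(make_table([{}, {}, {}]), p)
        ss = read_summary_stats(p, trait_id="t")
        assert ss.n_variants == 3
        assert ss.n_dropped == 0

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        p = tmp_path / "ss.tsv"
        write_ssf(make_table([{}, {"se": 0.0}, {"pval": 0.0},
                              {"effect_allele": "A", "other_allele": "A"}]), p)
        ss = read_summary_stats(p, trait_id="t")
        assert ss.n_variants == 1
        assert ss.n_dropped == 3

    def test_or_dialect_log_transforms(self, tmp_path):
        p = tmp_path / "or.tsv"
        df = make_table([{"beta": 1.267}])
        write_ssf(df, p)
        ss = read_summary_stats(p, trait_id="t", effect_is_or=True)
        assert ss.table["beta"].iloc[0] == pytest.approx(np.log(1.267), abs=1e-9)
        assert ss.table["beta"].iloc[0] == pytest.approx(0.23663, abs=5e-5)

    def test_missing_mandatory_column_names_it(self, tmp_path):
        p = tmp_path / "bad.tsv"
        df = make_table([{}]).drop(columns=["se"])
        write_ssf(df, p)
        with pytest.raises(FormatError, match="standard_error"):
            read_summary_stats(p, trait_id="t")

    def test_empty_table_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        write_ssf(make_table([{}]).iloc[:0], p)
        with pytest.raises(InputError):
            read_summary_stats(p, trait_id="t")

    def test_custom_dialect_and_extra_columns(self, tmp_path):
        p = tmp_path / "custom.csv"
        df = make_table([{}]).rename(columns={"rsid": "SNP", "pval": "P"})
        df["study"] = "abc"
        df.to_csv(p, index=False)
        ss = read_summary_stats(
            p, trait_id="t",
            dialect={"rsid": "SNP", "pval": "P", "chrom": "chrom",
                     "pos": "pos", "effect_allele": "effect_allele",
                     "other_allele": "other_allele", "eaf": "eaf",
                     "beta": "beta", "se": "se", "n": "n"})
        assert ss.n_variants == 1
        assert "study" in ss.extra.columns


class TestSelectInstruments:
    def test_p_threshold_count(self):
        pvals = [1e-9, 1e-8, 1e-7, 1e-6, 0.5]
        ss = build_summary_stats(
            make_table([{"pval": p} for p in pvals]), "t")
        iv = select_instruments(ss, p_threshold=5e-8)
        assert iv.n_instruments == 2

    def test_clump_keeps_smaller_p(self):
        ss = build_summary_stats(
            make_table([{"pval": 1e-10}, {"pval": 1e-9}]), "t")
        ld = pd.DataFrame(np.array([[1.0, np.sqrt(0.9)], [np.sqrt(0.9), 1.0]]),
                          index=["rs1", "rs2"], columns=["rs1", "rs2"])
        iv = select_instruments(ss, p_threshold=5e-8, clump_r2=0.001, ld=ld)
        assert iv.rsids == ["rs1"]

    def test_greedy_clumping_matches_bruteforce_oracle(self, rng):
        n = 10
        pvals = 10.0 ** rng.uniform(-20, -9, n)
        ss = build_summary_stats(make_table([{"pval": p} for p in pvals]), "t")
        corr = rng.uniform(-1, 1, (n, n)) * 0.6
        r = (corr + corr.T) / 2
        np.fill_diagonal(r, 1.0)
        rsids = [f"rs{i + 1}" for i in range(n)]
        ld = pd.DataFrame(r, index=rsids, columns=rsids)
        clump_r2 = 0.1
        # independent exhaustive greedy re-implementation
        order = sorted(range(n), key=lambda i: (pvals[i], rsids[i]))
        kept = []
        for i in order:
            if all(r[i, j] ** 2 < clump_r2 for j in kept):
                kept.append(i)
        expected = [rsids[i] for i in kept]
        iv = select_instruments(ss, p_threshold=5e-8, clump_r2=clump_r2, ld=ld)
        assert sorted(iv.rsids) == sorted(expected)

    def test_row_order_invariance(self, rng):
        pvals = 10.0 ** rng.uniform(-20, -9, 8)
        tab = make_table([{"pval": p} for p in pvals])
        ss1 = build_summary_stats(tab, "t")
        ss2 = build_summary_stats(tab.sample(frac=1, random_state=1), "t")
        iv1 = select_instruments(ss1)
        iv2 = select_instruments(ss2)
        assert iv1.rsids == iv2.rsids

    def test_nothing_passes_is_an_error(self):
        ss = build_summary_stats(make_table([{"pval": 0.5}]), "t")
        with pytest.raises(InsufficientInstrumentsError):
            select_instruments(ss, p_threshold=5e-8)


class TestInstrumentStrength:
    @pytest.mark.parametrize("beta,se,expected", [
        (0.1, 0.02, 25.0),
        (-0.1, 0.02, 25.0),
        (0.0447, 0.01, 19.9809),
    ])
    def test_f_statistic(self, beta, se, expected):
        assert f_statistic(beta, se) == pytest.approx(expected, abs=1e-4)

    def test_f_statistic_rejects_bad_se(self):
        with pytest.raises(InputError):
            f_statistic(0.1, 0.0)

    @pytest.mark.parametrize("beta,eaf,expected", [
        (0.1, 0.5, 0.005),
        (0.0, 0.3, 0.0),
    ])
    def test_variance_explained(self, beta, eaf, expected):
        assert variance_explained(beta, eaf) == pytest.approx(expected)

    def test_r2_total_recovers_generative_r2(self):
        # 100 instruments simulated to explain r2 = 0.06 of the exposure
        exp, _, _, truth = simulate_triangle(
            SimulationTruth(0.3, 0.25, 0.175, seed=11))
        x = exp.table.iloc[:truth.n_snp_x]
        total = float(np.sum(variance_explained(x["beta"], x["eaf"])))
        assert total == pytest.approx(truth.r2_x, abs=0.01)


class TestHarmonize:
    def _iv(self, rows):
        tab = make_table(rows)
        tab["f_stat"] = (tab["beta"] / tab["se"]) ** 2
        return InstrumentSet("exp", tab, 5e-8, 0.001, 0.0)

    def test_reversed_alleles_flip_beta_and_eaf(self):
        iv = self._iv([{"effect_allele": "A", "other_allele": "G",
                        "beta": 0.10}])
        out = build_summary_stats(make_table(
            [{"effect_allele": "G", "other_allele": "A", "beta": -0.05,
              "eaf": 0.7}]), "out")
        hs = harmonize(iv, out)
        row = hs.table.iloc[0]
        assert row["action"] == ACTION_FLIPPED
        assert row["beta_out"] == pytest.approx(0.05)
        assert row["eaf_out"] == pytest.approx(0.3)

    def test_ambiguous_palindromic_dropped(self):
        iv = self._iv([{"effect_allele": "A", "other_allele": "T",
                        "eaf": 0.50}])
        out = build_summary_stats(make_table(
            [{"effect_allele": "A", "other_allele": "T", "eaf": 0.50}]), "out")
        hs = harmonize(iv, out)
        assert hs.table["action"].iloc[0] == ACTION_DROP_PAL
        assert hs.n_snp == 0

    def test_unambiguous_palindromic_kept(self):
        iv = self._iv([{"effect_allele": "A", "other_allele": "T",
                        "eaf": 0.15}])
        out = build_summary_stats(make_table(
            [{"effect_allele": "A", "other_allele": "T", "eaf": 0.18}]), "out")
        hs = harmonize(iv, out)
        assert hs.n_snp == 1

    def test_allele_mismatch_dropped(self):
        iv = self._iv([{"effect_allele": "A", "other_allele": "G"}])
        out = build_summary_stats(make_table(
            [{"effect_allele": "A", "other_allele": "C"}]), "out")
        hs = harmonize(iv, out)
        assert hs.table["action"].iloc[0] == ACTION_DROP_MIS

    def test_involution(self, simple_exposure, simple_outcome):
        iv = select_instruments(simple_exposure, p_threshold=1e-5)
        hs1 = harmonize(iv, simple_outcome)
        # already aligned: harmonizing again changes nothing
        hs2 = harmonize(iv, simple_outcome)
        pd.testing.assert_frame_equal(hs1.table, hs2.table)
        assert (hs1.table["action"] == "kept").all()

    def test_flipping_all_outcome_rows_gives_same_set(self, simple_exposure,
                                                      simple_outcome):
        iv = select_instruments(simple_exposure, p_threshold=1e-5)
        hs1 = harmonize(iv, simple_outcome)
        flipped = simple_outcome.table.copy()
        flipped[["effect_allele", "other_allele"]] = \
            flipped[["other_allele", "effect_allele"]].to_numpy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        out2 = build_summary_stats(flipped, "out", trait_type="binary")
        hs2 = harmonize(iv, out2)
        for col in ("beta_out", "se_out", "eaf_out"):
            np.testing.assert_allclose(hs1.retained[col], hs2.retained[col])
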