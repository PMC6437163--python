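import io
import itertools

import numpy as np
import pandas as pd
import pytest

from mrpath import (LDInfo, MREstimate, harmonize, ld_prune,
                    read_results, read_summary_stats, write_results)
from mrpath.summary_io import SummaryStatsError

from conftest import make_table


def _csv(text):
    return io.StringIO(text)


class TestReadSummaryStats:
    def test_well_formed_file_reads_identically(self):
        t = read_summary_stats(_csv(
            "SNP\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"
            "rs1\ta\tg\t0.3\t0.05\t0.005\t1e-20\t1000\n"
            "rs2\tT\tC\t0.2\t-0.04\t0.004\t1e-18\t1000\n"
            "rs3\tG\tC\t0.6\t0.03\t0.006\t1e-8\t1000\n"))
        assert len(t) == 3 and t.n_dropped == 0
        assert list(t.data["effect_allele"]) == ["A", "T", "G"]

    @pytest.mark.parametrize("row,reason", [
        ("rs2\tT\tC\t0.2\t-0.04\t0\t1e-18\t1000", "non-positive se"),
        ("rs2\tT\tT\t0.2\t-0.04\t0.01\t1e-18\t1000", "identical alleles"),
        ("rs2\tT\tC\t1.2\t-0.04\t0.01\t1e-18\t1000", "eaf out of (0,1)"),
        ("rs2\tT\tC\t0.2\t-0.04\t0.01\t0\t1000", "p out of (0,1]"),
        ("rs2\tX\tC\t0.2\t-0.04\t0.01\t1e-4\t1000", "invalid allele"),
    ])
    def test_invalid_rows_dropped_and_counted(self, row, reason):
        t = read_summary_stats(_csv(
            "SNP\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"
            f"rs1\tA\tG\t0.3\t0.05\t0.005\t1e-20\t1000\n{row}\n"))
        assert len(t) == 1 and t.n_dropped == 1
        assert t.drop_log[0] == ("rs2", reason)

    def test_column_map_parses_gwas_dialect_identically(self):
        canonical = read_summary_stats(_csv(
            "SNP,EA,OA,EAF,BETA,SE,P,N\nrs1,A,G,0.3,0.05,0.005,1e-20,1000\n"))
        dialect = read_summary_stats(_csv(
            "MarkerName,A1,A2,Freq,Effect,StdErr,Pval,SampleSize\n"
            "rs1,A,G,0.3,0.05,0.005,1e-20,1000\n"),
            column_map={"MarkerName": "SNP", "A1": "EA", "A2": "OA",
                        "Freq": "EAF", "Effect": "BETA", "StdErr": "SE",
                        "Pval": "P", "SampleSize": "N"})
        pd.testing.assert_frame_equal(canonical.data, dialect.data)

    def test_missing_mandatory_column_named_in_error(self):
        with pytest.raises(SummaryStatsError, match="se"):
            read_summary_stats(_csv("SNP,EA,OA,BETA,P\nrs1,A,G,0.05,1e-20\n"))

    def test_all_rows_invalid_is_an_error(self):
        with pytest.raises(SummaryStatsError, match="no valid rows"):
            read_summary_stats(_csv("SNP,EA,OA,BETA,SE,P\nrs1,A,G,0.05,0,1e-20\n"))


class TestHarmonize:
    def test_swapped_alleles_flip_beta_and_eaf(self, tiny_tables):
        exposure, outcome = tiny_tables
        h = harmonize(exposure, outcome)
        # rs2: outcome alleles swapped AND exposure beta negative
        i = list(h.variant_ids).index("rs2")
        assert h.beta_gx[i] == pytest.approx(0.04)
        assert h.beta_gy[i] == pytest.approx(0.015)  # flipped twice

    def test_flip_invariance(self, tiny_tables):
        exposure, outcome = tiny_tables
        ref = harmonize(exposure, outcome)
        flipped = outcome.data.copy()
        flipped.loc[0, ["effect_allele", "other_allele"]] = ["G", "A"]
        flipped.loc[0, "beta"] *= -1
        flipped.loc[0, "eaf"] = 1 - flipped.loc[0, "eaf"]
        alt = harmonize(exposure, type(outcome)("outcome", flipped, "binary"))
        np.testing.assert_allclose(ref.beta_gy, alt.beta_gy)
        np.testing.assert_allclose(ref.beta_gx, alt.beta_gx)

    def test_negative_exposure_beta_reoriented(self, tiny_tables):
        h = harmonize(*tiny_tables)
        assert np.all(h.beta_gx > 0)
        log = h.orientation_log.set_index("variant_id")
        assert "reoriented" in log.loc["rs2", "action"]

    def test_palindromic_drop_policy(self):
        exposure = make_table([("rs1", "A", "T", 0.5, 0.05, 0.005, 1e-20, 1000),
                               ("rs2", "A", "G", 0.3, 0.04, 0.005, 1e-10, 1000)])
        outcome = make_table([("rs1", "A", "T", 0.5, 0.01, 0.01, 0.1, 1000),
                              ("rs2", "A", "G", 0.3, 0.01, 0.01, 0.1, 1000)],
                             trait_type="binary")
        h = harmonize(exposure, outcome, palindromic_policy="drop")
        assert list(h.variant_ids) == ["rs2"]
        log = h.orientation_log.set_index("variant_id")
        assert log.loc["rs1", "reason"] == "palindromic"

    def test_palindromic_infer_by_eaf(self):
        # eaf 0.9 vs 0.1: other-strand representation, beta must flip back
        exposure = make_table([("rs1", "A", "T", 0.9, 0.05, 0.005, 1e-20, 1000)])
        outcome = make_table([("rs1", "A", "T", 0.1, 0.02, 0.01, 0.1, 1000)],
                             trait_type="binary")
        h = harmonize(exposure, outcome, palindromic_policy="infer_by_eaf")
        assert h.beta_gy[0] == pytest.approx(-0.02)
        # ambiguous frequency inside the window is dropped
        outcome2 = make_table([("rs1", "A", "T", 0.5, 0.02, 0.01, 0.1, 1000)],
                              trait_type="binary")
        with pytest.raises(SummaryStatsError):
            harmonize(exposure, outcome2, palindromic_policy="infer_by_eaf")

    def test_idempotent(self, tiny_tables):
        exposure, outcome = tiny_tables
        h1 = harmonize(exposure, outcome)
        exp2 = make_table(
            [(v, "A", "G", 0.3, bx, sx, 1e-10, 1000)
             for v, bx, sx in zip(h1.variant_ids, h1.beta_gx, h1.se_gx)])
        out2 = make_table(
            [(v, "A", "G", 0.3, by, sy, 0.5, 1000)
             for v, by, sy in zip(h1.variant_ids, h1.beta_gy, h1.se_gy)],
            trait_type="binary")
        h2 = harmonize(exp2, out2)
        np.testing.assert_allclose(h1.beta_gx, h2.beta_gx)
        np.testing.assert_allclose(h1.beta_gy, h2.beta_gy)

    def test_irreconcilable_alleles_dropped_with_reason(self, tiny_tables):
        exposure, outcome = tiny_tables
        broken = outcome.data.copy()
        broken.loc[2, ["effect_allele", "other_allele"]] = ["A", "T"]
        h = harmonize(exposure, make_table(list(broken.itertuples(index=False)),
                                           trait_type="binary"))
        assert "rs3" not in h.variant_ids
        log = h.orientation_log.set_index("variant_id")
        assert "mismatch" in log.loc["rs3", "reason"]

    def test_empty_intersection_raises(self, tiny_tables):
        exposure, _ = tiny_tables
        other = make_table([("rs99", "A", "G", 0.3, 0.01, 0.01, 0.5, 1000)],
                           trait_type="binary")
        with pytest.raises(SummaryStatsError):
            harmonize(exposure, other)


class TestLDPrune:
    def _pair(self, p1, p2, r2):
        t = make_table([("rs1", "A", "G", 0.3, 0.05, 0.005, p1, 1000),
                        ("rs2", "T", "C", 0.2, 0.04, 0.005, p2, 1000)])
        return t, LDInfo(pairs=[("rs1", "rs2", r2)])

    def test_above_threshold_keeps_smaller_p(self):
        t, ld = self._pair(1e-10, 1e-8, 0.06)
        out = ld_prune(t, ld)
        assert list(out.data["variant_id"]) == ["rs1"]

    def test_below_threshold_keeps_both(self):
        t, ld = self._pair(1e-10, 1e-8, 0.04)
        assert len(ld_prune(t, ld)) == 2

    def test_missing_pairs_treated_independent(self):
        t, _ = self._pair(1e-10, 1e-8, 0.9)
        assert len(ld_prune(t, LDInfo.identity())) == 2

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        rows = [(f"rs{i}", "A", "G", 0.3, rng.uniform(0.01, 0.1), 0.005,
                 rng.uniform(1e-12, 1e-6), 1000) for i in range(12)]
        pairs = [(f"rs{i}", f"rs{j}", float(rng.random() * 0.2))
                 for i, j in itertools.combinations(range(12), 2)]
        ld = LDInfo(pairs=pairs)
        base = ld_prune(make_table(rows), ld)
        shuffled = make_table([rows[i] for i in rng.permutation(12)])
        assert set(base.data["variant_id"]) == \
            set(ld_prune(shuffled, ld).data["variant_id"])

    def test_chain_matches_exhaustive_search(self):
        """Chained LD: greedy equals brute force over all subsets."""
        n = 10
        pvals = [10 ** -(12 - i) for i in range(n)]
        rows = [(f"rs{i}", "A", "G", 0.3, 0.05, 0.005, pvals[i], 1000)
                for i in range(n)]
        pairs = [(f"rs{i}", f"rs{i+1}", 0.5) for i in range(n - 1)]
        ld = LDInfo(pairs=pairs)

        def feasible(subset):
            return all(ld.r2(f"rs{i}", f"rs{j}") <= 0.05
                       for i, j in itertools.combinations(subset, 2))

        best = None
        for size in range(n, 0, -1):
            cands = [s for s in itertools.combinations(range(n), size)
                     if feasible(s)]
            if cands:
                best = min(cands, key=lambda s: sorted(pvals[i] for i in s))
                break
        got = set(ld_prune(make_table(rows), ld).data["variant_id"])
        assert got == {f"rs{i}" for i in best}


class TestLDInfoIO:
    def test_pair_list_round_trip(self, tmp_path):
        path = tmp_path / "ld.tsv"
        path.write_text("ID_A\tID_B\tR2\nrs1\trs2\t0.3\nrs2\trs3\t0.9\n")
        ld = LDInfo.read(path)
        assert ld.r2("rs1", "rs2") == pytest.approx(0.3)
        assert ld.r2("rs3", "rs2") == pytest.approx(0.9)
        assert ld.r2("rs1", "rs3") == 0.0  # absent pair = independent
        assert ld.r2("rs1", "rs1") == 1.0

    def test_matrix_form_round_trip(self, tmp_path):
        path = tmp_path / "ld.csv"
        path.write_text(",rs1,rs2\nrs1,1.0,-0.6\nrs2,-0.6,1.0\n")
        ld = LDInfo.read(path)
        m = ld.correlation_matrix(["rs1", "rs2"])
        assert m[0, 1] == pytest.approx(-0.6)
        assert ld.r2("rs1", "rs2") == pytest.approx(0.36)

    def test_asymmetric_matrix_rejected(self):
        mat = pd.DataFrame([[1.0, 0.2], [0.5, 1.0]],
                           index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            LDInfo(matrix=mat)


class TestWriteResults:
    def _estimates(self):
        from mrpath.heterogeneity import HeterogeneityStats
        het = HeterogeneityStats(3.0, 4, 0.55, 0.0, np.array([1.0, 2.0]))
        es = [MREstimate("ivw_fixed", -0.18, 0.02, -0.219, -0.141, 1e-19, 5,
                         heterogeneity=het),
              MREstimate("wald", 0.5, 0.2, 0.108, 0.892, 0.012, 1)]
        return es

    def test_round_trip(self, tmp_path):
        path = tmp_path / "res.tsv"
        write_results(self._estimates(), path)
        df = read_results(path)
        assert df.loc[0, "beta"] == pytest.approx(-0.18, abs=1e-12)
        assert df.loc[0, "OR"] == pytest.approx(np.exp(-0.18), rel=1e-11)
        assert df.loc[0, "Q"] == pytest.approx(3.0)

    def test_single_snp_q_columns_empty(self, tmp_path):
        path = tmp_path / "res.tsv"
        write_results(self._estimates(), path)
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        assert raw.loc[1, "Q"] == ""

    def test_empty_collection_header_only(self, tmp_path):
        path = tmp_path / "res.tsv"
        write_results([], path)
        df = read_results(path)
        assert len(df) == 0 and list(df.columns)[0] == "method"
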