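"""I/O, validation and allele harmonisation of summary statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_table
from osteomr.errors import ConfigurationError, InputError
from osteomr.sumstats import (
    SummaryStatsTable,
    harmonize,
    read_sumstats,
    write_sumstats,
)

HEADER = "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"


def _write(tmp_path, body, name="s.tsv"):
    path = tmp_path / name
    path.write_text(HEADER + body)
    return path


class TestReadSumstats:
    def test_well_formed_file_round_trips_identity(self, tmp_path):
        body = (
            "rs1\t1\t100\tA\tG\t0.3\t0.05\t0.01\t1e-6\t10000\n"
            "rs2\t2\t200\tC\tT\t0.5\t-0.02\t0.02\t0.3\t10000\n"
            "rs3\t3\t300\tG\tA\t0.7\t0.00\t0.01\t1.0\t10000\n"
        )
        table = read_sumstats(_write(tmp_path, body))
        assert len(table) == 3
        assert table.df.loc[1, "beta"] == -0.02

    def test_invariant_violating_rows_are_dropped(self, tmp_path):
        body = (
            "rs1\t1\t100\tA\tG\t0.3\t0.05\t0.01\t1e-6\t10000\n"
            "rs2\t2\t200\tC\tT\t0.5\t-0.02\t0.0\t0.3\t10000\n"  # se = 0
        )
        table = read_sumstats(_write(tmp_path, body))
        assert len(table) == 1
        assert table.snp_ids == ["rs1"]

    def test_lowercase_alleles_are_normalised(self, tmp_path):
        body = (
            "rs1\t1\t100\ta\tg\t0.3\t0.05\t0.01\t1e-6\t10000\n"
            "rs2\t2\t200\tc\tT\t0.5\t-0.02\t0.02\t0.3\t10000\n"
            "rs3\t3\t300\tG\ta\t0.7\t0.01\t0.01\t0.9\t10000\n"
        )
        table = read_sumstats(_write(tmp_path, body))
        assert len(table) == 3
        assert set(table.df["effect_allele"]) <= set("ACGT")

    def test_indels_and_multiallelic_rejected(self, tmp_path):
        body = (
            "rs1\t1\t100\tAT\tG\t0.3\t0.05\t0.01\t1e-6\t10000\n"
            "rs2\t2\t200\tC\tC\t0.5\t-0.02\t0.02\t0.3\t10000\n"
            "rs3\t3\t300\tG\tA\t0.7\t0.01\t0.01\t0.9\t10000\n"
        )
        table = read_sumstats(_write(tmp_path, body))
        assert table.snp_ids == ["rs3"]

    def test_missing_column_is_configuration_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("SNP\tBETA\nrs1\t0.1\n")
        with pytest.raises(ConfigurationError):
            read_sumstats(path)

    def test_empty_file_is_input_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(HEADER)
        with pytest.raises((InputError, Exception)):
            read_sumstats(path)

    def test_column_map_renames(self, tmp_path):
        path = tmp_path / "renamed.tsv"
        path.write_text(
            "rsid\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"
            "rs1\t1\t100\tA\tG\t0.3\t0.05\t0.01\t1e-6\t10000\n"
        )
        table = read_sumstats(path, column_map={"rsid": "snp_id"})
        assert table.snp_ids == ["rs1"]

    def test_duplicate_snp_id_rejected(self):
        with pytest.raises(InputError, match="duplicate"):
            make_table([{"snp_id": "rs1"}, {"snp_id": "rs1"}])


def test_write_read_round_trip_is_bit_exact(tmp_path, random_table):
    path = tmp_path / "rt.tsv"
    write_sumstats(random_table, path)
    back = read_sumstats(path)
    pd.testing.assert_frame_equal(back.df, random_table.df, check_exact=True)


def test_gzip_round_trip(tmp_path, random_table):
    path = tmp_path / "rt.tsv.gz"
    write_sumstats(random_table, path)
    back = read_sumstats(path)
    pd.testing.assert_frame_equal(back.df, random_table.df, check_exact=True)


class TestHarmonize:
    def test_already_aligned_pair(self):
        x = make_table([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        y = make_table([{"effect_allele": "A", "other_allele": "G", "beta": 0.05}])
        h = harmonize(x, y)
        assert h.df.loc[0, "bx"] == 0.1
        assert h.df.loc[0, "by"] == 0.05

    def test_swapped_alleles_flip_sign(self):
        x = make_table([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        y = make_table(
            [{"effect_allele": "G", "other_allele": "A", "beta": 0.05, "eaf": 0.7}]
        )
        h = harmonize(x, y)
        assert h.df.loc[0, "by"] == -0.05

    def test_strand_complement_resolved(self):
        x = make_table([{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        # T/C is A/G read from the other strand
        y = make_table([{"effect_allele": "T", "other_allele": "C", "beta": 0.05}])
        h = harmonize(x, y)
        assert h.df.loc[0, "by"] == 0.05

    def test_palindromic_near_half_excluded(self):
        # 5-SNP set: one ambiguous A/T SNP with eaf 0.52 inside the 0.08
        # window is dropped; the other four pairs survive unchanged
        rows_x = [
            {"effect_allele": "A", "other_allele": "T", "eaf": 0.52, "beta": 0.1},
            {"effect_allele": "A", "other_allele": "G", "eaf": 0.30, "beta": 0.2},
            {"effect_allele": "C", "other_allele": "T", "eaf": 0.10, "beta": 0.3},
            {"effect_allele": "G", "other_allele": "A", "eaf": 0.80, "beta": 0.4},
            {"effect_allele": "T", "other_allele": "C", "eaf": 0.25, "beta": 0.5},
        ]
        x = make_table(rows_x)
        y = make_table([dict(r, beta=r["beta"] / 2) for r in rows_x])
        h = harmonize(x, y, palindrome_eaf_window=0.08)
        assert len(h) == 4
        assert h.exclusions["palindromic"] == ["rs1"]
        assert np.allclose(h.df["by"], h.df["bx"] / 2)

    def test_palindromic_outside_window_oriented_by_eaf(self):
        x = make_table(
            [{"effect_allele": "A", "other_allele": "T", "eaf": 0.2, "beta": 0.1}]
        )
        y_same = make_table(
            [{"effect_allele": "A", "other_allele": "T", "eaf": 0.22, "beta": 0.05}]
        )
        y_flipped = make_table(
            [{"effect_allele": "A", "other_allele": "T", "eaf": 0.78, "beta": 0.05}]
        )
        assert harmonize(x, y_same).df.loc[0, "by"] == 0.05
        assert harmonize(x, y_flipped).df.loc[0, "by"] == -0.05

    def test_irreconcilable_alleles_excluded(self):
        x = make_table(
            [
                {"effect_allele": "A", "other_allele": "G"},
                {"effect_allele": "C", "other_allele": "T"},
            ]
        )
        y = make_table(
            [
                {"effect_allele": "A", "other_allele": "C"},
                {"effect_allele": "C", "other_allele": "T"},
            ]
        )
        h = harmonize(x, y)
        assert h.exclusions["allele_mismatch"] == ["rs1"]
        assert len(h) == 1

    def test_empty_intersection_is_input_error(self):
        x = make_table([{"snp_id": "rs1"}])
        y = make_table([{"snp_id": "rs2"}])
        with pytest.raises(InputError):
            harmonize(x, y)

    def test_self_harmonisation_is_identity(self, random_table):
        h = harmonize(random_table, random_table)
        non_palindromic = h.df
        assert np.array_equal(non_palindromic["bx"], non_palindromic["by"])
        assert np.array_equal(non_palindromic["se_bx"], non_palindromic["se_by"])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(flips=st.lists(st.booleans(), min_size=50, max_size=50))
    def test_invariance_to_outcome_allele_convention(self, flips):
        # flipping EA/OA, negating beta and complementing eaf per SNP of
        # the outcome table must leave the harmonised pairs unchanged
        rng = np.random.default_rng(99)
        rows = []
        pairs = [("A", "G"), ("C", "T"), ("G", "T"), ("A", "C")]
        for i in range(50):
            ea, oa = pairs[i % len(pairs)]
            rows.append(
                {
                    "snp_id": f"rs{i + 1}",
                    "effect_allele": ea,
                    "other_allele": oa,
                    "eaf": float(rng.uniform(0.05, 0.95)),
                    "beta": float(rng.normal(0, 0.1)),
                    "se": float(rng.uniform(0.005, 0.02)),
                }
            )
        x = make_table(rows)
        y_rows = []
        for row, flip in zip(rows, flips):
            r = dict(row)
            if flip:
                r["effect_allele"], r["other_allele"] = (
                    r["other_allele"],
                    r["effect_allele"],
                )
                r["beta"] = -r["beta"]
                r["eaf"] = 1 - r["eaf"]
            y_rows.append(r)
        y = make_table(y_rows)
        h_ref = harmonize(x, x)
        h_flip = harmonize(x, y)
        np.testing.assert_allclose(
            h_flip.df["by"].to_numpy(), h_ref.df["by"].to_numpy(), atol=1e-15
        )
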