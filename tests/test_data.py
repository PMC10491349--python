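"""I/O, validation, harmonization and instrument selection."""

import numpy as np
import pandas as pd
import pytest

from mrmediate import (
    GwasInputError,
    harmonize,
    read_summary_stats,
    select_instruments,
    write_results,
)
from mrmediate.univariable import ivw

from conftest import make_summary_stats

HEADER = "snp_id\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"


def _write(tmp_path, body, name="stats.tsv", header=HEADER):
    p = tmp_path / name
    p.write_text(header + body)
    return p


class TestReadSummaryStats:
    def test_well_formed_file_passes_through(self, tmp_path):
        p = _write(
            tmp_path,
            "rs1\tA\tG\t0.3\t0.1\t0.01\t1e-20\t50000\n"
            "rs2\tC\tT\t0.2\t-0.08\t0.012\t1e-12\t50000\n"
            "rs3\tG\tA\t0.4\t0.05\t0.011\t1e-9\t50000\n",
        )
        ss = read_summary_stats(p)
        assert len(ss) == 3
        assert ss.drop_counts == {}

    def test_zero_se_row_dropped_and_counted(self, tmp_path):
        p = _write(
            tmp_path,
            "rs1\tA\tG\t0.3\t0.1\t0.0\t1e-20\t50000\n"
            "rs2\tC\tT\t0.2\t-0.08\t0.012\t1e-12\t50000\n",
        )
        ss = read_summary_stats(p)
        assert len(ss) == 1
        assert ss.drop_counts["nonpositive_se"] == 1

    def test_missing_mapped_column_is_hard_error_naming_it(self, tmp_path):
        p = _write(
            tmp_path,
            "rs1\tA\tG\t0.1\t0.01\t1e-20\t50000\n",
            header="snp_id\teffect_allele\tother_allele\tbeta\tse\tpval\tn\n",
        )
        with pytest.raises(GwasInputError, match="eaf"):
            read_summary_stats(p, column_map={"eaf": "frequency"})

    def test_empty_file_is_hard_error(self, tmp_path):
        p = _write(tmp_path, "")
        with pytest.raises(GwasInputError):
            read_summary_stats(p)

    def test_gzip_and_column_map(self, tmp_path):
        import gzip

        p = tmp_path / "stats.tsv.gz"
        body = (
            "rsid\tea\toa\tfrq\tb\tstderr\tp\tN\n"
            "rs1\tA\tG\t0.3\t0.1\t0.01\t1e-20\t50000\n"
        )
        with gzip.open(p, "wt") as fh:
            fh.write(body)
        ss = read_summary_stats(
            p,
            column_map={
                "snp_id": "rsid", "effect_allele": "ea", "other_allele": "oa",
                "eaf": "frq", "beta": "b", "se": "stderr", "pval": "p", "n": "N",
            },
        )
        assert len(ss) == 1
        assert ss.table.at[0, "beta"] == 0.1

    def test_indel_alleles_dropped(self, tmp_path):
        p = _write(
            tmp_path,
            "rs1\tAT\tG\t0.3\t0.1\t0.01\t1e-20\t50000\n"
            "rs2\tC\tT\t0.2\t-0.08\t0.012\t1e-12\t50000\n",
        )
        ss = read_summary_stats(p)
        assert len(ss) == 1
        assert ss.drop_counts["non_snv_allele"] == 1


class TestHarmonize:
    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = make_summary_stats("exp", rows=[
            ("rs1", "1", 1000, "A", "G", 0.30, 0.10, 0.010, 1e-20, 50_000),
        ])
        out = make_summary_stats("out", rows=[
            ("rs1", "1", 1000, "G", "A", 0.30, 0.05, 0.010, 1e-6, 60_000),
        ])
        data = harmonize(exp, out)
        assert data.beta_Y[0] == pytest.approx(-0.05)
        prov = data.provenance.set_index("snp_id")
        assert bool(prov.at["rs1", "flipped"])

    def test_palindromic_mid_frequency_dropped(self):
        exp = make_summary_stats("exp", rows=[
            ("rs1", "1", 1000, "A", "T", 0.50, 0.10, 0.010, 1e-20, 50_000),
            ("rs2", "2", 2000, "C", "G", 0.20, 0.09, 0.010, 1e-18, 50_000),
        ])
        out = make_summary_stats("out", rows=[
            ("rs1", "1", 1000, "A", "T", 0.30, 0.05, 0.010, 1e-6, 60_000),
            ("rs2", "2", 2000, "C", "G", 0.22, 0.04, 0.010, 1e-5, 60_000),
        ])
        data = harmonize(exp, out, palindrome_eaf_window=0.08)
        assert data.snp_ids == ["rs2"]
        prov = data.provenance.set_index("snp_id")
        assert prov.at["rs1", "dropped_reason"] == "palindromic_ambiguous"
        assert bool(prov.at["rs2", "palindromic_inferred"])

    def test_identity_when_allele_coding_matches(self):
        exp = make_summary_stats("exp")
        out = make_summary_stats("out")
        data = harmonize(exp, out)
        np.testing.assert_array_equal(data.beta_Y, exp.table["beta"].to_numpy())
        assert not data.provenance["flipped"].any()

    def test_missing_snps_dropped_with_reason(self):
        exp = make_summary_stats("exp")
        out = make_summary_stats("out", rows=[
            ("rs1", "1", 1000, "A", "G", 0.30, 0.05, 0.010, 1e-6, 60_000),
        ])
        data = harmonize(exp, out)
        assert data.snp_ids == ["rs1"]
        prov = data.provenance.set_index("snp_id")
        assert (prov.loc[["rs2", "rs3"], "dropped_reason"] == "missing").all()

    def test_no_shared_snps_is_hard_error(self):
        exp = make_summary_stats("exp")
        out = make_summary_stats("out", rows=[
            ("rs9", "9", 900, "A", "G", 0.30, 0.05, 0.010, 1e-6, 60_000),
        ])
        with pytest.raises(GwasInputError, match="no harmonizable"):
            harmonize(exp, out)

    def test_flip_involution(self):
        """Re-flipping every outcome allele must reproduce beta_Y exactly."""
        exp = make_summary_stats("exp")
        out = make_summary_stats("out")
        flipped_tab = out.table.copy()
        flipped_tab[["effect_allele", "other_allele"]] = flipped_tab[
            ["other_allele", "effect_allele"]
        ].to_numpy()
        flipped_tab["beta"] = -flipped_tab["beta"]
        flipped_tab["eaf"] = 1 - flipped_tab["eaf"]
        out_flipped = type(out)("out", "continuous", flipped_tab)
        d1 = harmonize(exp, out)
        d2 = harmonize(exp, out_flipped)
        np.testing.assert_array_equal(d1.beta_Y, d2.beta_Y)
        np.testing.assert_array_equal(d1.se_Y, d2.se_Y)

    def test_row_counts_conserve(self):
        exp = make_summary_stats("exp", rows=[
            ("rs1", "1", 1000, "A", "G", 0.30, 0.10, 0.010, 1e-20, 50_000),
            ("rs2", "2", 2000, "A", "T", 0.50, 0.09, 0.010, 1e-18, 50_000),
            ("rs3", "3", 3000, "G", "A", 0.40, 0.05, 0.011, 1e-9, 50_000),
        ])
        out = make_summary_stats("out", rows=[
            ("rs1", "1", 1000, "A", "G", 0.30, 0.05, 0.010, 1e-6, 60_000),
            ("rs2", "2", 2000, "A", "T", 0.50, 0.04, 0.010, 1e-5, 60_000),
        ])
        data = harmonize(exp, out)
        prov = data.provenance
        assert len(prov) == 3  # every input SNP accounted for
        assert data.n_snps + (prov["dropped_reason"] != "").sum() == 3


class TestEstimateInvariance:
    def test_estimates_invariant_to_allele_recoding(self):
        rng = np.random.default_rng(7)
        rows_e, rows_o = [], []
        for j in range(15):
            ea, oa = ("A", "G") if j % 2 else ("C", "T")
            eaf = rng.uniform(0.1, 0.45)
            bx = rng.normal(0, 0.08)
            by = 0.3 * bx + rng.normal(0, 0.01)
            rows_e.append((f"rs{j}", "1", 1000 + j, ea, oa, eaf, bx, 0.008, 1e-12, 50_000))
            if rng.random() < 0.5:  # randomly recode the outcome file
                rows_o.append((f"rs{j}", "1", 1000 + j, oa, ea, 1 - eaf, -by, 0.01, 0.01, 60_000))
            else:
                rows_o.append((f"rs{j}", "1", 1000 + j, ea, oa, eaf, by, 0.01, 0.01, 60_000))
        exp = make_summary_stats("exp", rows=rows_e)
        out_recoded = make_summary_stats("out", rows=rows_o)
        out_plain = make_summary_stats(
            "out",
            rows=[(r[0], r[1], r[2], e[3], e[4], e[5],
                   r[6] if (r[3], r[4]) == (e[3], e[4]) else -r[6], r[7], r[8], r[9])
                  for r, e in zip(rows_o, rows_e)],
        )
        b1 = ivw(harmonize(exp, out_recoded)).beta
        b2 = ivw(harmonize(exp, out_plain)).beta
        assert b1 == pytest.approx(b2, abs=1e-15)


class TestSelectInstruments:
    def test_threshold_without_positions(self):
        rows = [
            (f"rs{i}", None, None, "A", "G", 0.3, 0.1, 0.01, p, 50_000)
            for i, p in enumerate([1e-9, 1e-7, 1e-10, 0.5, 4e-8])
        ]
        ss = make_summary_stats("exp", rows=rows)
        ss.table.drop(columns=["chrom", "pos"], inplace=True)
        kept = select_instruments(ss, 5e-8)
        assert sorted(kept.snp_ids) == ["rs0", "rs2", "rs4"]

    def test_greedy_positional_pruning(self):
        rows = [
            ("rs1", "1", 100_000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 50_000),
            ("rs2", "1", 105_000, "A", "G", 0.3, 0.1, 0.01, 1e-12, 50_000),
        ]
        kept = select_instruments(make_summary_stats("exp", rows=rows), 5e-8, 10_000_000)
        assert list(kept.snp_ids) == ["rs2"]

    def test_nothing_passes_is_hard_error(self):
        rows = [("rs1", "1", 100, "A", "G", 0.3, 0.01, 0.01, 0.2, 50_000)]
        with pytest.raises(GwasInputError, match="no instruments"):
            select_instruments(make_summary_stats("exp", rows=rows))

    def test_different_chromosomes_not_pruned(self):
        rows = [
            ("rs1", "1", 100_000, "A", "G", 0.3, 0.1, 0.01, 1e-9, 50_000),
            ("rs2", "2", 100_000, "A", "G", 0.3, 0.1, 0.01, 1e-12, 50_000),
        ]
        kept = select_instruments(make_summary_stats("exp", rows=rows), 5e-8, 10_000_000)
        assert sorted(kept.snp_ids) == ["rs1", "rs2"]


class TestWriteResults:
    def test_mr_estimate_round_trip(self, tmp_path, fixture20):
        res = ivw(fixture20)
        out = tmp_path / "ivw.tsv"
        write_results(res, out, metadata={"seed": 3})
        df = pd.read_csv(out, sep="\t")
        assert list(df.columns[:7]) == [
            "method", "beta", "se", "ci_low", "ci_high", "pval", "n_snps"
        ]
        assert df.at[0, "beta"] == pytest.approx(res.beta)
        sidecar = out.with_suffix(".tsv.json")
        assert sidecar.exists()
        import json

        payload = json.loads(sidecar.read_text())
        assert payload["metadata"]["seed"] == 3
        assert payload["results"]["beta"] == res.beta

    def test_empty_report_header_only(self, tmp_path):
        out = tmp_path / "empty.tsv"
        write_results(pd.DataFrame(columns=["a", "b"]), out)
        df = pd.read_csv(out, sep="\t")
        assert list(df.columns) == ["a", "b"] and df.empty
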