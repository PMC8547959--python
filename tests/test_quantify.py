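"""Nucleotide-contribution accounting, codon usage, gene-length effects."""

import numpy as np
import pandas as pd
import pytest

from emalekit import templates as T
from emalekit.io import GenomeAssembly, write_sam
from emalekit.quantify import (assembly_fractions, build_label_arrays,
                               codon_usage_profile, count_codons,
                               fraction_deviation, gene_length_comparison,
                               read_fractions)
from emalekit.synthetic import default_config, simulate

from .conftest import random_dna


class TestAssemblyFractions:
    def test_exact_bookkeeping(self, rng):
        asm = GenomeAssembly({"c": random_dna(rng, 100_000, 0.7)})
        rep = assembly_fractions(asm, [("c", 10_000, 12_000)], [])
        assert rep.fractions["element"] == pytest.approx(0.02)
        assert rep.bases["element"] == 2_000

    def test_no_annotations_gives_host_one(self, rng):
        asm = GenomeAssembly({"c": random_dna(rng, 10_000, 0.7)})
        rep = assembly_fractions(asm, [], [])
        assert rep.fractions["host"] == 1.0

    def test_nested_ngaro_bases_count_as_ngaro(self, rng):
        asm = GenomeAssembly({"c": random_dna(rng, 50_000, 0.7)})
        rep = assembly_fractions(asm, [("c", 10_000, 30_000)],
                                 [("c", 15_000, 21_000)])
        assert rep.bases["element"] == 14_000
        assert rep.bases["ngaro"] == 6_000

    def test_fractions_sum_to_one_on_random_configs(self, rng):
        for _ in range(20):
            L = int(rng.integers(10_000, 50_000))
            asm = GenomeAssembly({"c": "A" * L})
            s = int(rng.integers(0, L - 5000))
            rep = assembly_fractions(asm, [("c", s, s + 4000)],
                                     [("c", s + 1000, s + 2000)])
            assert sum(rep.fractions.values()) == pytest.approx(1.0)
            assert sum(rep.bases.values()) == L

    def test_out_of_bounds_annotation_rejected(self, rng):
        asm = GenomeAssembly({"c": "A" * 1000})
        with pytest.raises(ValueError):
            assembly_fractions(asm, [("c", 500, 2000)], [])


def _sam(tmp_path, records, lengths):
    path = tmp_path / "r.sam"
    write_sam(records, lengths, path)
    return path


class TestReadFractions:
    def test_host_only_reads_give_zero_element(self, rng, tmp_path):
        asm = GenomeAssembly({"c": random_dna(rng, 20_000, 0.7)})
        labels = build_label_arrays(asm, [("c", 15_000, 18_000)], [])
        recs = [(f"r{i}", asm.contigs["c"][i * 100:i * 100 + 500], "c",
                 i * 100, "+") for i in range(50)]
        rep = read_fractions(_sam(tmp_path, recs, asm.lengths()), labels)
        assert rep.fractions["element"] == 0.0

    def test_cigar_insertion_and_deletion_attribution(self, tmp_path):
        # read: 10M 5I 10M over a boundary at ref position 15
        asm = GenomeAssembly({"c": "A" * 40})
        labels = build_label_arrays(asm, [("c", 15, 40)], [])
        path = tmp_path / "r.sam"
        path.write_text("@HD\tVN:1.6\n@SQ\tSN:c\tLN:40\n"
                        "r1\t0\tc\t6\t60\t10M5I10M\t*\t0\t0\t"
                        + "A" * 25 + "\t*\n"
                        "r2\t0\tc\t6\t60\t10M8D10M\t*\t0\t0\t"
                        + "A" * 20 + "\t*\n")
        rep = read_fractions(path, labels)
        # r1: ref 5..15 host (10), insertion at ref 15 -> host class of
        # position 14 (5), ref 15..25 element (10)
        # r2: ref 5..15 host (10), deletion skips to 23, ref 23..33 element
        assert rep.bases["host"] == 25
        assert rep.bases["element"] == 20

    def test_unmapped_and_secondary_skipped(self, tmp_path):
        asm = GenomeAssembly({"c": "A" * 100})
        labels = build_label_arrays(asm, [], [])
        path = tmp_path / "r.sam"
        path.write_text("@HD\tVN:1.6\n@SQ\tSN:c\tLN:100\n"
                        "r1\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\t*\n"
                        "r2\t256\tc\t1\t60\t4M\t*\t0\t0\tAAAA\t*\n"
                        "r3\t0\tc\t1\t60\t4M\t*\t0\t0\tAAAA\t*\n")
        rep = read_fractions(path, labels)
        assert rep.skipped_records == 2
        assert rep.total_bases == 4

    def test_unknown_reference_rejected(self, tmp_path):
        labels = {"c": np.zeros(100, dtype=np.uint8)}
        path = tmp_path / "r.sam"
        path.write_text("@HD\tVN:1.6\n@SQ\tSN:other\tLN:100\n"
                        "r1\t0\tother\t1\t60\t4M\t*\t0\t0\tAAAA\t*\n")
        with pytest.raises(ValueError):
            read_fractions(path, labels)

    def test_uniform_sampling_matches_binomial_oracle(self, tmp_path):
        cfg = default_config(3)
        cfg.read_params.sampling = "uniform"
        cfg.read_params.count = 4000
        asm, truth, reads = simulate(cfg)
        labels = truth.class_label_arrays(asm)
        path = _sam(tmp_path, list(reads.sam_records(asm)), asm.lengths())
        rep = read_fractions(path, labels)
        truth_counts = truth.class_base_counts(asm)
        total = sum(truth_counts.values())
        p = truth_counts["element"] / total
        # per-read element fraction is noisy; 3 binomial s.e. over reads
        se = np.sqrt(p * (1 - p) / cfg.read_params.count)
        assert abs(rep.fractions["element"] - p) <= 3 * se

    def test_systematic_sampling_deviation_shrinks_with_depth(self, tmp_path):
        cfg = default_config(4)
        devs = []
        for count in (500, 2000, 8000):
            cfg.read_params.count = count
            asm, truth, reads = simulate(cfg)
            labels = truth.class_label_arrays(asm)
            path = _sam(tmp_path, list(reads.sam_records(asm)),
                        asm.lengths())
            rep = read_fractions(path, labels)
            fa = assembly_fractions(
                asm, [(r.contig, r.start, r.end)
                      for r in truth.by_class("element")],
                [(r.contig, r.start, r.end)
                 for r in truth.by_class("ngaro")])
            devs.append(max(fraction_deviation(fa, rep).values()))
        assert devs[-1] <= devs[0] + 0.05
        assert devs[-1] < 0.3


class TestCodonUsage:
    def test_single_gene_counts(self):
        assert count_codons(["ATGAAA"]) == {"ATG": 1, "AAA": 1}

    def test_total_codons_conserved(self, rng):
        orfs = [random_dna(rng, 3 * int(rng.integers(10, 50)), 0.5)
                for _ in range(5)]
        tables, _ = codon_usage_profile({"e": (0.4, orfs),
                                         "f": (0.5, orfs),
                                         "g": (0.6, orfs)})
        for t in tables:
            assert t.total_codons == sum(len(o) // 3 for o in orfs)

    def test_counting_invariant_under_orf_permutation(self, rng):
        orfs = [random_dna(rng, 300, 0.5) for _ in range(4)]
        a = count_codons(orfs)
        b = count_codons(orfs[::-1])
        assert a == b

    def test_gc3_tracks_element_gc_across_templates(self, rng):
        elements = {}
        for tid, tmpl in T.element_templates().items():
            orfs = [tmpl.core[g.start:g.end] for g in tmpl.genes]
            elements[f"t{tid}"] = (tmpl.gc, orfs)
        tables, rho = codon_usage_profile(elements)
        assert len(tables) == 8
        assert rho > 0.9

    def test_elements_without_orfs_excluded(self):
        tables, rho = codon_usage_profile({"a": (0.4, []), "b": (0.5, []),
                                           "c": (0.6, [])})
        assert tables == [] and np.isnan(rho)


class TestGeneLengths:
    def _table(self, shift=0):
        rows = []
        for i in range(8):
            has = i < 4
            rows.append({"element_id": f"e{i}", "label": "MCP",
                         "aa_length": 450 - (shift if has else 0),
                         "has_ngaro": has})
            rows.append({"element_id": f"e{i}", "label": "PEN",
                         "aa_length": 300, "has_ngaro": has})
        return pd.DataFrame(rows)

    def test_undisrupted_panel_has_equal_medians(self):
        df = gene_length_comparison(self._table(0))
        mcp = df[df["label"] == "MCP"].iloc[0]
        assert mcp["median_with_ngaro"] == mcp["median_without_ngaro"]

    def test_deliberate_truncation_shifts_only_affected_label(self):
        df = gene_length_comparison(self._table(200)).set_index("label")
        assert df.loc["MCP", "median_with_ngaro"] \
            < df.loc["MCP", "median_without_ngaro"]
        assert df.loc["PEN", "median_with_ngaro"] \
            == df.loc["PEN", "median_without_ngaro"]
        assert df.loc["MCP", "p_ranksum"] < df.loc["PEN", "p_ranksum"]

    def test_stratum_sizes_sum_to_panel_size(self):
        df = gene_length_comparison(self._table(0)).set_index("label")
        for label in ("MCP", "PEN"):
            assert df.loc[label, "n_with_ngaro"] \
                + df.loc[label, "n_without_ngaro"] == 8

    def test_label_missing_in_one_stratum_reports_no_test(self):
        df = pd.DataFrame([
            {"element_id": "a", "label": "MCP", "aa_length": 450,
             "has_ngaro": False},
        ])
        out = gene_length_comparison(df).set_index("label")
        assert out.loc["MCP", "n_with_ngaro"] == 0
        assert np.isnan(out.loc["MCP", "p_ranksum"])
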