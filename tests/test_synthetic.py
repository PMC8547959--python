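"""The synthetic-genome generator and its ground truth."""

import numpy as np
import pytest

from emalekit import templates as T
from emalekit._util import gc_fraction, revcomp
from emalekit.io import write_fasta
from emalekit.synthetic import (ElementSpec, PlantError,
                                SimulationConfig, SizingError,
                                default_config, generate_host_assembly,
                                plant_elements, simulate, simulate_reads)


@pytest.fixture(scope="module")
def default_run():
    cfg = default_config(1)
    asm, truth, reads = simulate(cfg)
    return cfg, asm, truth, reads


class TestHostAssembly:
    def test_contig_gc_is_exact(self):
        cfg = SimulationConfig(seed=1, contig_lengths=[100_000])
        asm, truth = generate_host_assembly(cfg)
        gc = gc_fraction(asm.contigs["ctg01"])
        assert 0.685 <= gc <= 0.715
        # exact-count sampling: realized GC equals the rounded target
        assert gc == pytest.approx(round(0.70 * 100_000) / 100_000)

    def test_one_host_record_per_contig(self):
        cfg = SimulationConfig(seed=2, contig_lengths=[50_000, 60_000])
        asm, truth = generate_host_assembly(cfg)
        hosts = truth.by_class("host")
        assert len(hosts) == 2
        assert {h.end - h.start for h in hosts} == {50_000, 60_000}

    def test_identical_seed_gives_byte_identical_fasta(self, tmp_path):
        cfg = default_config(9)
        for name in ("a", "b"):
            asm, _, _ = simulate(cfg)
            write_fasta(asm, tmp_path / f"{name}.fasta")
        assert (tmp_path / "a.fasta").read_bytes() \
            == (tmp_path / "b.fasta").read_bytes()

    def test_contig_too_small_for_features_rejected(self):
        cfg = SimulationConfig(seed=1, contig_lengths=[20_000],
                               element_specs=[ElementSpec(1, 0, 10_000)])
        with pytest.raises(SizingError):
            generate_host_assembly(cfg)


class TestPlanting:
    def test_tsd_pair_identical_and_of_requested_length(self):
        cfg = SimulationConfig(seed=5, contig_lengths=[120_000],
                               element_specs=[ElementSpec(
                                   4, 0, 50_000, tir_length=900,
                                   tsd_length=5)])
        host, _ = generate_host_assembly(cfg)
        asm, truth = plant_elements(host, cfg)
        tsds = truth.by_class("tsd")
        assert len(tsds) == 2
        seq = asm.contigs["ctg01"]
        left, right = sorted(tsds, key=lambda r: r.start)
        assert left.end - left.start == right.end - right.start == 5
        assert seq[left.start:left.end] == seq[right.start:right.end]
        el = truth.by_class("element")[0]
        assert (left.end, right.start) == (el.start, el.end)

    def test_tsd_zero_plants_no_duplication(self):
        cfg = SimulationConfig(seed=5, contig_lengths=[120_000],
                               element_specs=[ElementSpec(
                                   4, 0, 50_000, tsd_length=0)])
        host, _ = generate_host_assembly(cfg)
        asm, truth = plant_elements(host, cfg)
        assert truth.by_class("tsd") == []
        el = truth.by_class("element")[0]
        seq = asm.contigs["ctg01"]
        # flanks share no constructed junction duplication
        assert seq[el.start - 1] != seq[el.end]

    def test_overlapping_targets_rejected_naming_both(self):
        cfg = SimulationConfig(seed=5, contig_lengths=[120_000],
                               element_specs=[
                                   ElementSpec(1, 0, 50_000),
                                   ElementSpec(2, 0, 51_000)])
        host, _ = generate_host_assembly(cfg)
        with pytest.raises(PlantError, match="element@50.*element@51000"):
            plant_elements(host, cfg)

    def test_tir_arms_are_reverse_complements(self, default_run):
        _, asm, truth, _ = default_run
        for el in truth.by_class("element"):
            tirs = sorted((r for r in truth.children(el.feature_id)
                           if r.feature_class == "tir"),
                          key=lambda r: r.start)
            assert len(tirs) == 2
            seq = asm.contigs[el.contig]
            left = seq[tirs[0].start:tirs[0].end]
            right = seq[tirs[1].start:tirs[1].end]
            assert right == revcomp(left)

    def test_children_contained_and_top_level_disjoint(self, default_run):
        _, asm, truth, _ = default_run
        by_id = {r.feature_id: r for r in truth.records}
        for r in truth.records:
            if r.parent_id and r.feature_class not in ("tsd",):
                p = by_id[r.parent_id]
                assert p.start <= r.start and r.end <= p.end
        top = sorted((r for r in truth.records
                      if r.parent_id is None
                      and r.feature_class in ("element", "ngaro", "solo")),
                     key=lambda r: (r.contig, r.start))
        for a, b in zip(top, top[1:]):
            assert a.contig != b.contig or a.end <= b.start

    def test_composition_conserved(self, default_run):
        _, asm, truth, _ = default_run
        counts = truth.class_base_counts(asm)
        assert sum(counts.values()) == asm.total_length

    def test_planted_feature_gc_within_two_points(self, default_run):
        _, asm, truth, _ = default_run
        for r in truth.by_class("element"):
            if r.end - r.start < 2000:
                continue
            # element GC is defined net of nested retrotransposons
            seq = asm.contigs[r.contig]
            parts = [seq[r.start:r.end]]
            for n in truth.children(r.feature_id):
                if n.feature_class == "ngaro":
                    parts = [seq[r.start:n.start], seq[n.end:r.end]]
            gc = gc_fraction("".join(parts))
            want = T.element_templates()[r.type_id].realized_gc
            assert abs(gc - want) <= 0.02, (r.feature_id, gc, want)
        for r in truth.by_class("ngaro"):
            gc = gc_fraction(asm.contigs[r.contig][r.start:r.end])
            assert abs(gc - T.ngaro_templates()[r.type_id].realized_gc) <= 0.02

    def test_partial_elements_flush_with_contig_end(self, default_run):
        _, asm, truth, _ = default_run
        partials = [r for r in truth.by_class("element")
                    if r.attrs["completeness"] == "partial"]
        assert len(partials) == 3
        for r in partials:
            L = len(asm.contigs[r.contig])
            assert r.start == 0 or r.end == L

    def test_word_identity_groups_elements_by_template(self, default_run):
        from emalekit.dotplot import wordmatch_dotplot
        _, asm, truth, _ = default_run
        els = [r for r in truth.by_class("element")
               if r.attrs["completeness"] == "complete"]
        seqs = {}
        for r in els:
            seq = asm.contigs[r.contig][r.start:r.end]
            for n in truth.children(r.feature_id):
                if n.feature_class == "ngaro":
                    seq = (asm.contigs[r.contig][r.start:n.start]
                           + asm.contigs[r.contig][n.end:r.end])
            seqs[r.feature_id] = seq
        m = wordmatch_dotplot(seqs)
        types = {r.feature_id: r.type_id for r in els}
        for a in seqs:
            for b in seqs:
                if a >= b:
                    continue
                cov = m.coverage(a, b)
                if types[a] == types[b]:
                    assert cov > 0.5, (a, b, cov)
                else:
                    assert cov < 0.3, (a, b, cov)


class TestReads:
    def test_zero_substitution_reads_are_exact_substrings(self, default_run):
        _, asm, truth, reads = default_run
        seqs = dict(reads.reads)
        for rid, contig, start, strand in reads.truth_placements[:300]:
            frag = asm.contigs[contig][start:start + len(seqs[rid])]
            want = revcomp(seqs[rid]) if strand == "-" else seqs[rid]
            assert want == frag

    def test_substituted_reads_match_within_rate(self):
        cfg = default_config(6)
        cfg.read_params.substitution_rate = 0.02
        cfg.read_params.count = 200
        asm, truth, reads = simulate(cfg)
        seqs = dict(reads.reads)
        for rid, contig, start, strand in reads.truth_placements[:50]:
            frag = asm.contigs[contig][start:start + len(seqs[rid])]
            read = revcomp(seqs[rid]) if strand == "-" else seqs[rid]
            mism = sum(1 for x, y in zip(read, frag) if x != y)
            assert mism / len(read) < 0.05

    def test_oversized_read_length_skips_contig_with_warning(self):
        cfg = SimulationConfig(seed=1, contig_lengths=[5_000])
        cfg.read_params.length = 10_000
        cfg.read_params.count = 10
        asm, _ = generate_host_assembly(cfg)
        with pytest.warns(UserWarning, match="exceeds contig"):
            rs = simulate_reads(asm, cfg)
        assert rs.reads == []

    def test_read_class_fractions_converge_to_assembly_fractions(self,
                                                                 default_run):
        _, asm, truth, reads = default_run
        labels = truth.class_label_arrays(asm)
        counts = {0: 0, 1: 0, 2: 0}
        seqs = dict(reads.reads)
        for rid, contig, start, strand in reads.truth_placements:
            arr = labels[contig][start:start + len(seqs[rid])]
            for k in counts:
                counts[k] += int((arr == k).sum())
        total = sum(counts.values())
        truth_counts = truth.class_base_counts(asm)
        tt = sum(truth_counts.values())
        assert abs(counts[1] / total - truth_counts["element"] / tt) < 0.003
        assert abs(counts[2] / total - truth_counts["ngaro"] / tt) < 0.003


class TestConfigRoundTrip:
    def test_json_round_trip(self):
        cfg = default_config(3)
        back = SimulationConfig.from_json(cfg.to_json())
        assert back == cfg
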