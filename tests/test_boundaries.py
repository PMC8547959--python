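"""Element delimitation: TIRs, completeness, TSDs, cross-strain loci."""

import pytest

from emalekit._util import revcomp
from emalekit.boundaries import (ElementRecord, TirPair,
                                 classify_completeness,
                                 cross_strain_locus_search, delimit_element,
                                 find_tsd)
from emalekit.gc_profile import CandidateSegment
from emalekit.io import GenomeAssembly
from emalekit.synthetic import (ElementSpec, SimulationConfig,
                                _valid_tsd_site, generate_host_assembly,
                                plant_elements)

from .conftest import random_dna


def _constructed(rng, tir_len=900, tsd="ACGTA"):
    """Host with one planted element with exact TIRs and a known TSD."""
    host = random_dna(rng, 60_000, 0.70)
    p = 30_000
    while not _valid_tsd_site(host, p, len(tsd)):
        p += 7
    tsd_seq = host[p - len(tsd):p] if tsd else ""
    tir = random_dna(rng, tir_len, 0.35)
    core = random_dna(rng, 18_000, 0.35)
    element = tir + core + revcomp(tir)
    seq = host[:p] + element + tsd_seq + host[p:]
    asm = GenomeAssembly({"c": seq})
    return asm, p, p + len(element), tir_len, tsd_seq


class TestDelimitation:
    def test_exact_tir_recovered_with_exact_boundaries(self, rng):
        asm, start, end, tir_len, _ = _constructed(rng)
        cand = CandidateSegment("c", start + 120, end - 80, 0.35, 0.70)
        rec = delimit_element(cand, asm)
        assert rec.tir is not None
        assert rec.tir.length == tir_len
        assert rec.tir.identity == 1.0
        assert (rec.start, rec.end) == (start, end)
        assert rec.completeness == "complete"

    def test_no_terminal_self_similarity_gives_no_tir(self, rng):
        seq = random_dna(rng, 30_000, 0.70)
        cand = CandidateSegment("c", 10_000, 20_000, 0.5, 0.7)
        rec = delimit_element(cand, GenomeAssembly({"c": seq}))
        assert rec.tir is None

    def test_too_short_candidate_warns(self, rng):
        seq = random_dna(rng, 2_000, 0.5)
        cand = CandidateSegment("c", 900, 1_050, 0.5, 0.7)
        with pytest.warns(UserWarning):
            rec = delimit_element(cand, GenomeAssembly({"c": seq}))
        assert rec.tir is None


class TestCompleteness:
    def _rec(self, start, end, tir=True):
        rec = ElementRecord("e", "c", start, end)
        if tir:
            rec.tir = TirPair(start, start + 500, end - 500, end, 1.0)
        return rec

    def test_tirs_plus_host_flanks_is_complete(self):
        assert classify_completeness(self._rec(5000, 25_000), 60_000) \
            == "complete"

    def test_element_at_contig_start_is_partial(self):
        assert classify_completeness(self._rec(0, 20_000), 60_000) == "partial"

    def test_tirs_but_spanning_whole_contig_is_partial(self):
        assert classify_completeness(self._rec(0, 20_000), 20_000) == "partial"

    def test_missing_tir_is_partial(self):
        assert classify_completeness(self._rec(5000, 25_000, tir=False),
                                     60_000) == "partial"


class TestTsd:
    def test_known_junction_duplication_recovered(self, rng):
        asm, start, end, _, tsd_seq = _constructed(rng, tsd="ACGTA")
        rec = ElementRecord("e", "c", start, end)
        tsd = find_tsd(asm, rec)
        assert tsd is not None
        assert tsd.sequence == tsd_seq and tsd.length == len(tsd_seq)

    def test_no_shared_junction_sequence_gives_none(self, rng):
        asm, start, end, _, _ = _constructed(rng, tsd="")
        tsd = find_tsd(asm, ElementRecord("e", "c", start, end))
        assert tsd is None

    def test_reported_tsd_reverifiable_by_string_equality(self, rng):
        asm, start, end, _, _ = _constructed(rng, tsd="ACGTAGCTA")
        rec = ElementRecord("e", "c", start, end)
        tsd = find_tsd(asm, rec)
        seq = asm.contigs["c"]
        assert seq[start - tsd.length:start] == seq[end:end + tsd.length] \
            == tsd.sequence

    def test_short_flank_caps_search_with_warning(self, rng):
        seq = random_dna(rng, 1_000, 0.5)
        rec = ElementRecord("e", "c", 5, 990)
        with pytest.warns(UserWarning):
            find_tsd(GenomeAssembly({"c": seq}), rec)


def _two_strain_fixture():
    """Strain A with 12 elements; strain B shares 6 of the insertions."""
    shared, private = [], []
    for i in range(12):
        spec = ElementSpec(type_id=8, contig=i // 6, position=45_000
                           + (i % 6) * 42_000, tir_length=400,
                           tsd_length=4 + (i % 3))
        (shared if i % 2 == 0 else private).append(spec)
    cfg_a = SimulationConfig(seed=77, contig_lengths=[310_000, 310_000],
                             element_specs=shared + private,
                             min_insert_gap=20_000)
    cfg_b = SimulationConfig(seed=77, contig_lengths=[310_000, 310_000],
                             element_specs=shared, min_insert_gap=20_000)
    host, _ = generate_host_assembly(cfg_a)
    asm_a, truth_a = plant_elements(host, cfg_a)
    asm_b, truth_b = plant_elements(host, cfg_b)
    asm_a.name, asm_b.name = "A", "B"
    return asm_a, truth_a, asm_b, truth_b, len(shared)


@pytest.fixture(scope="module")
def strains():
    return _two_strain_fixture()


class TestCrossStrainLoci:
    def test_shared_and_private_insertions_classified_perfectly(self, strains):
        asm_a, truth_a, asm_b, truth_b, n_shared = strains
        shared_ids = {r.feature_id for r in truth_b.by_class("element")}
        correct = 0
        elements = truth_a.by_class("element")
        for tr in elements:
            rec = ElementRecord(tr.feature_id, tr.contig, tr.start, tr.end,
                                completeness="complete")
            lm = cross_strain_locus_search(rec, asm_a, {"B": asm_b},
                                           flank=6_000)[0]
            if tr.feature_id in shared_ids:
                correct += lm.shared and lm.occupancy == "occupied"
            else:
                correct += (not lm.shared) and lm.occupancy == "empty"
        assert correct == len(elements)

    def test_empty_allele_reveals_tsd_exactly_once(self, strains):
        asm_a, truth_a, asm_b, truth_b, _ = strains
        shared_ids = {r.feature_id for r in truth_b.by_class("element")}
        tr = next(r for r in truth_a.by_class("element")
                  if r.feature_id not in shared_ids
                  and int(r.attrs["tsd_length"]) >= 5)
        rec = ElementRecord(tr.feature_id, tr.contig, tr.start, tr.end)
        lm = cross_strain_locus_search(rec, asm_a, {"B": asm_b},
                                       flank=6_000)[0]
        assert lm.occupancy == "empty"
        k = int(tr.attrs["tsd_length"])
        tsd = asm_a.contigs[tr.contig][tr.end:tr.end + k]
        junction = asm_b.contigs[lm.subject_contig][
            lm.subject_start - 2 * k:lm.subject_end + 2 * k]
        assert junction.count(tsd) == 1

    def test_query_against_itself_recovers_own_locus(self, strains):
        asm_a, truth_a, *_ = strains
        tr = truth_a.by_class("element")[0]
        rec = ElementRecord(tr.feature_id, tr.contig, tr.start, tr.end)
        lm = cross_strain_locus_search(rec, asm_a, {"self": asm_a},
                                       flank=6_000)[0]
        assert lm.occupancy == "occupied" and lm.shared
        assert lm.subject_contig == tr.contig
        assert abs(lm.subject_start - tr.start) <= 20
        assert abs(lm.subject_end - tr.end) <= 20

    def test_no_other_assembly_rejected(self, strains):
        asm_a, truth_a, *_ = strains
        tr = truth_a.by_class("element")[0]
        rec = ElementRecord(tr.feature_id, tr.contig, tr.start, tr.end)
        with pytest.raises(ValueError):
            cross_strain_locus_search(rec, asm_a, {})
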