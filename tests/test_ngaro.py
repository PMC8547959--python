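"""Retrotransposon detection, repeat architecture, typing and statistics."""

import pytest
from scipy import stats

from emalekit import templates as T
from emalekit._util import gc_fraction, mutate_substitutions
from emalekit.ngaro import (classify_insertion_site, classify_ngaro,
                            detect_high_gc_insertions,
                            detect_split_direct_repeats, excise,
                            integration_bias_test)

from .conftest import random_dna
from .oracles import fisher_two_sided


def _ngaro_db():
    return {tid: {"sequence": t.sequence, "proteins": t.proteins,
                  "repeat_a": t.repeat_a, "repeat_b": t.repeat_b}
            for tid, t in T.ngaro_templates().items()}


class TestInsertionDetection:
    def test_planted_gc_rich_insertion_recovered(self, rng):
        element = random_dna(rng, 16_000, 0.35)
        insert = random_dna(rng, 6_000, 0.60)
        seq = element[:7000] + insert + element[7000:]
        hits = detect_high_gc_insertions(seq)
        assert len(hits) == 1
        s, e = hits[0]
        ov = min(e, 13_000) - max(s, 7_000)
        assert ov / 6_000 >= 0.95 and ov / (e - s) >= 0.95

    def test_element_without_insertion_is_empty(self, rng):
        assert detect_high_gc_insertions(random_dna(rng, 12_000, 0.35)) == []

    def test_two_adjacent_insertions_resolved(self, rng):
        element = random_dna(rng, 15_000, 0.33)
        ins = [random_dna(rng, 5_000, 0.62) for _ in range(2)]
        # two insertions separated by a short stretch of element DNA
        seq = (element[:6000] + ins[0] + element[6000:6400] + ins[1]
               + element[6400:])
        hits = detect_high_gc_insertions(seq)
        assert len(hits) == 2

    def test_short_element_is_noop(self, rng):
        assert detect_high_gc_insertions(random_dna(rng, 1000, 0.35)) == []

    def test_excision_is_idempotent_and_lowers_gc(self, rng):
        element = random_dna(rng, 14_000, 0.35)
        seq = element[:5000] + random_dna(rng, 6_000, 0.62) + element[5000:]
        hits = detect_high_gc_insertions(seq)
        once = excise(seq, hits)
        assert gc_fraction(once) < gc_fraction(seq)
        again_hits = detect_high_gc_insertions(once)
        assert excise(once, again_hits) == once


class TestSplitDirectRepeats:
    def test_constructed_architecture_recovered_exactly(self, rng):
        a = random_dna(rng, 300, 0.6)
        b = random_dna(rng, 250, 0.6)
        mid = random_dna(rng, 5_000, 0.6)
        # junction-clean fixture: no chance single-base arm extensions
        if mid[0] == b[0]:
            mid = ("A" if b[0] != "A" else "C") + mid[1:]
        if mid[-1] == a[-1]:
            mid = mid[:-1] + ("A" if a[-1] != "A" else "C")
        seq = a + mid + b + a + b
        rs = detect_split_direct_repeats(seq)
        assert rs is not None and rs.complete and not rs.solo
        assert rs.a1 == (0, 300)
        assert rs.b1 == (5_300, 5_550)
        assert rs.a2 == (5_550, 5_850)
        assert rs.b2 == (5_850, 6_100)
        assert rs.identity_a == 1.0 and rs.identity_b == 1.0

    def test_repeat_free_sequence_gives_none(self, rng):
        assert detect_split_direct_repeats(random_dna(rng, 4_000, 0.5)) is None

    def test_too_short_candidate_rejected(self):
        with pytest.raises(ValueError):
            detect_split_direct_repeats("ACGT" * 50)

    def test_solo_ab_pair_flagged(self, rng):
        # short host margins, as delivered by the template word scan
        tmpl = T.ngaro_templates()[1]
        host = random_dna(rng, 100, 0.7)
        seq = host + tmpl.repeat_a + tmpl.repeat_b + host
        rs = detect_split_direct_repeats(
            seq, known_repeats=[(tmpl.repeat_a, tmpl.repeat_b)])
        assert rs is not None and rs.solo
        assert rs.a1 == (100, 400) and rs.b1 == (400, 650)

    def test_element_tail_with_upstream_orfs_is_not_solo(self):
        # B1A2B2 tail of a truncated copy: upstream ORFs forbid a solo call
        tmpl = T.ngaro_templates()[2]
        seq = tmpl.sequence[len(tmpl.repeat_a) + 2000:]
        rs = detect_split_direct_repeats(
            seq, known_repeats=[(tmpl.repeat_a, tmpl.repeat_b)])
        assert rs is None or not rs.solo


class TestClassification:
    def test_full_length_type2_derivative_is_2a(self, rng):
        seq = mutate_substitutions(rng, T.ngaro_templates()[2].sequence, 0.02)
        assert classify_ngaro(seq, _ngaro_db()) == (2, "full")

    def test_orf1_deleted_type2_derivative_is_2b(self, rng):
        trunc = T.ngaro_orf1_deleted(T.ngaro_templates()[2])
        seq = mutate_substitutions(rng, trunc, 0.02)
        assert classify_ngaro(seq, _ngaro_db()) == (2, "orf1_truncated")

    def test_reverse_complemented_copy_still_types(self, rng):
        from emalekit._util import revcomp
        seq = revcomp(mutate_substitutions(
            rng, T.ngaro_templates()[3].sequence, 0.02))
        tid, variant = classify_ngaro(seq, _ngaro_db())
        assert (tid, variant) == (3, "full")

    def test_random_sequence_is_unassigned(self, rng):
        tid, _ = classify_ngaro(random_dna(rng, 6_000, 0.6), _ngaro_db())
        assert tid == "unassigned"

    def test_all_templates_type_to_themselves(self):
        db = _ngaro_db()
        for tid, t in T.ngaro_templates().items():
            assert classify_ngaro(t.sequence, db) == (tid, "full")


class TestInsertionSites:
    def test_site_classification(self):
        orfs = [(100, 400), (600, 900)]
        tirs = [(0, 50), (950, 1000)]
        assert classify_insertion_site((500, 500), orfs, tirs) == "intergenic"
        assert classify_insertion_site((200, 200), orfs, tirs) == "genic"
        assert classify_insertion_site((20, 20), orfs, tirs) == "tir"


class TestFisher:
    def test_five_zero_table(self):
        # [[5,0],[0,5]] has two-sided p = 2/C(10,5) = 1/126
        s = integration_bias_test(["intergenic"] * 5,
                                  {"intergenic": 0, "genic": 5})
        assert s.table == [[5, 0], [0, 5]]
        assert s.p_two_sided == pytest.approx(1 / 126, rel=1e-9)

    def test_proportional_rows_give_p_one(self):
        s = integration_bias_test(["intergenic", "genic"],
                                  {"intergenic": 10, "genic": 10})
        assert s.p_two_sided == pytest.approx(1.0)

    def test_zero_insertions_rejected(self):
        with pytest.raises(ValueError):
            integration_bias_test([], {"intergenic": 10, "genic": 10})

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            _, p = stats.fisher_exact([[a, b], [c, d]])
            assert abs(p - fisher_two_sided([[a, b], [c, d]])) <= 1e-12

    def test_p_invariant_under_row_and_column_swap(self, rng):
        for _ in range(20):
            a, b, c, d = (int(x) + 1 for x in rng.integers(0, 10, size=4))
            _, p1 = stats.fisher_exact([[a, b], [c, d]])
            _, p2 = stats.fisher_exact([[d, c], [b, a]])
            assert p1 == pytest.approx(p2, rel=1e-12)
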