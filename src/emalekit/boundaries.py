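"""Precise element delimitation: TIRs, completeness, TSDs, locus orthology.

A GC-screen candidate is delimited by locally aligning its 5' arm against
the reverse complement of its 3' arm (terminal inverted repeats snap the
outer element boundaries); completeness requires a TIR pair plus host DNA
on both flanks; the target site duplication is the longest exact match
between the upstream-flank suffix and downstream-flank prefix; and element
insertion loci are compared across strains by mapping up to 10 kb of each
host flank onto the other assemblies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib
from Bio import Align

from ._util import revcomp
from .gc_profile import CandidateSegment, segment_mean_gc
from .io import GenomeAssembly
from .orfs import OrfRecord, assign_type_by_cumulative_bitscore

__all__ = ["TirPair", "TsdRecord", "ElementRecord", "LocusMatch",
           "delimit_element", "classify_completeness", "find_tsd",
           "cross_strain_locus_search"]

MIN_TIR_LEN = 100
MIN_TIR_IDENTITY = 0.9
TIR_ARM = 3000          # searched at each end of the candidate
# Outward slack beyond the refined boundary: GC changepoint refinement on a
# 17-point contrast (mid-GC element vs host) can err by ~2x100 bp, and the
# TIR must lie fully inside the searched arm for the boundary snap.
ARM_MARGIN = 400
MAX_TSD = 15
FLANK_BP = 10_000
MIN_FLANK_ALN = 200
MIN_FLANK_IDENTITY = 0.9
EMPTY_GAP = 50          # <= this between mapped flanks -> empty allele
OCCUPIED_GAP = 1000     # >= this -> candidate occupied locus


def _nt_aligner() -> Align.PairwiseAligner:
    # match +1 / mismatch -2, affine gap 5/2 (first gap base costs 7)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner

_NT_ALIGNER = _nt_aligner()


@dataclass
class TirPair:
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    identity: float

    @property
    def length(self) -> int:
        return self.left_end - self.left_start


@dataclass
class TsdRecord:
    sequence: str
    length: int
    left_start: int
    right_start: int
    capped: bool = False   # search limited by a short host flank


@dataclass
class ElementRecord:
    element_id: str
    contig: str
    start: int
    end: int
    orientation: str = "+"
    completeness: str = "partial"
    gc: float = float("nan")           # retrotransposon-excised
    tir: TirPair | None = None
    tsd: TsdRecord | None = None
    type_assignment: int | str | None = None
    gc_group: str | None = None
    nested_ngaro_ids: list[str] = field(default_factory=list)
    orfs: list[OrfRecord] = field(default_factory=list)
    at_contig_end: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LocusMatch:
    query_element_id: str
    subject_strain: str
    subject_contig: str | None
    subject_start: int | None
    subject_end: int | None
    flank_sides: list[str]
    occupancy: str            # occupied|empty|ambiguous
    shared: bool
    flank_truncated: bool = False


def _align_tir(left_arm: str, right_arm_rc: str):
    if not left_arm or not right_arm_rc:
        return None
    score = _NT_ALIGNER.score(left_arm, right_arm_rc)
    if score < MIN_TIR_LEN * 0.5:
        return None
    aln = _NT_ALIGNER.align(left_arm, right_arm_rc)[0]
    qb, rb = aln.aligned
    if len(qb) == 0:
        return None
    matches = 0
    cols = 0
    for (qs, qe), (rs, re) in zip(qb, rb):
        matches += sum(1 for a, b in zip(left_arm[qs:qe], right_arm_rc[rs:re])
                       if a == b)
        cols += qe - qs
    span_q = int(qb[-1][1] - qb[0][0])
    span_r = int(rb[-1][1] - rb[0][0])
    identity = matches / max(span_q, span_r)
    if min(span_q, span_r) < MIN_TIR_LEN or identity < MIN_TIR_IDENTITY:
        return None
    return (int(qb[0][0]), int(qb[-1][1]), int(rb[0][0]), int(rb[-1][1]),
            identity)


def delimit_element(candidate: CandidateSegment, assembly: GenomeAssembly,
                    element_id: str = "element",
                    orfs: list[OrfRecord] | None = None) -> ElementRecord:
    """Delimit a candidate segment into an element record.

    The first and last ``TIR_ARM`` bp of the candidate (with a small
    outward margin) are locally aligned — 5' arm against the reverse
    complement of the 3' arm — and, when a repeat of >= 100 bp at >= 0.9
    identity is found, the outer element boundaries snap to the TIR outer
    ends.  The element is oriented so the primase/helicase ORF lies 5'
    (falling back to ORF-strand majority).
    """
    seq = assembly.contigs[candidate.contig]
    start, end = candidate.start, candidate.end
    rec = ElementRecord(element_id, candidate.contig, start, end,
                        at_contig_end=(start == 0 or end == len(seq)))
    if end - start < 2 * MIN_TIR_LEN:
        warnings.warn(f"candidate {element_id} shorter than twice the "
                      f"minimum TIR length; returned without TIR")
    else:
        left_lo = max(0, start - ARM_MARGIN)
        left_hi = min(len(seq), start + TIR_ARM)
        right_hi = min(len(seq), end + ARM_MARGIN)
        right_lo = max(0, end - TIR_ARM)
        left_arm = seq[left_lo:left_hi]
        right_rc = revcomp(seq[right_lo:right_hi])
        hit = _align_tir(left_arm, right_rc)
        if hit is not None:
            qs, qe, rs, re, identity = hit
            tir = TirPair(left_lo + qs, left_lo + qe,
                          right_hi - re, right_hi - rs, identity)
            rec.tir = tir
            rec.start, rec.end = tir.left_start, tir.right_end
            rec.at_contig_end = (rec.start == 0 or rec.end == len(seq))
    rec.gc = segment_mean_gc(seq, rec.start, rec.end)
    if orfs:
        inside = [o for o in orfs if o.start >= rec.start and o.end <= rec.end]
        prim = [o for o in inside
                if o.label and o.label.startswith("primase_helicase")]
        if prim:
            rec.orientation = prim[0].strand
        elif inside:
            plus = sum(1 for o in inside if o.strand == "+")
            rec.orientation = "+" if plus * 2 >= len(inside) else "-"
        rec.orfs = inside
    rec.completeness = classify_completeness(rec, len(seq))
    return rec


def classify_completeness(element: ElementRecord, contig_length: int) -> str:
    """Complete iff a TIR pair is present and host DNA flanks both sides."""
    if (element.tir is not None and element.start > 0
            and element.end < contig_length):
        return "complete"
    return "partial"


def find_tsd(assembly: GenomeAssembly, element: ElementRecord,
             max_len: int = MAX_TSD) -> TsdRecord | None:
    """Longest exact duplication (<= max_len bp) flanking the element."""
    seq = assembly.contigs[element.contig]
    up = seq[max(0, element.start - max_len):element.start]
    down = seq[element.end:element.end + max_len]
    capped = len(up) < max_len or len(down) < max_len
    if capped:
        warnings.warn(f"TSD search for {element.element_id} capped at "
                      f"{min(len(up), len(down))} bp by a short flank")
    for L in range(min(len(up), len(down)), 0, -1):
        if up[-L:] == down[:L]:
            return TsdRecord(down[:L], L, element.start - L, element.end,
                             capped)
    return None


def _map_flank(flank: str, subject: GenomeAssembly,
               min_identity: float = MIN_FLANK_IDENTITY,
               min_len: int = MIN_FLANK_ALN):
    """Best infix placement of a flank in a subject assembly, or None."""
    if len(flank) < min_len:
        return None
    best = None
    max_dist = int(len(flank) * (1 - min_identity))
    for cid, seq in subject.contigs.items():
        res = edlib.align(flank, seq, mode="HW", task="locations", k=max_dist)
        if res["editDistance"] < 0:
            continue
        ident = 1 - res["editDistance"] / len(flank)
        loc = res["locations"][0]
        cand = (ident, cid, int(loc[0] or 0), int(loc[1]) + 1)
        if best is None or cand[0] > best[0]:
            best = cand
    if best is None:
        return None
    ident, cid, s, e = best
    if e - s < min_len:
        return None
    return {"contig": cid, "start": s, "end": e, "identity": ident}


def _element_like(seq: str, query_element_seq: str,
                  type_db=None, query_type=None) -> bool:
    """Is ``seq`` a homolog of the query element (type-matched)?"""
    if len(seq) < 1000:
        return False
    if type_db:
        assignment = assign_type_by_cumulative_bitscore(seq, type_db)
        if assignment.assigned != "inconclusive":
            return query_type is None or assignment.assigned == query_type
    from .dotplot import wordmatch_dotplot
    m = wordmatch_dotplot({"q": query_element_seq, "s": seq})
    return m.coverage("q", "s") >= 0.3


def cross_strain_locus_search(element: ElementRecord,
                              query_assembly: GenomeAssembly,
                              other_assemblies: dict[str, GenomeAssembly],
                              flank: int = FLANK_BP,
                              type_db: dict | None = None
                              ) -> list[LocusMatch]:
    """Locate the element's insertion locus in other strains.

    Up to ``flank`` bp of host sequence on each side of the element is
    mapped onto every subject assembly; a locus is *occupied* when a
    homologous, type-matched element lies between (or adjacent to) the
    mapped flanks and *empty* when the flanks abut directly; it is shared
    when occupied with at least one matching flank.
    """
    if not other_assemblies:
        raise ValueError("at least one other assembly is required")
    seq = query_assembly.contigs[element.contig]
    left = seq[max(0, element.start - flank):element.start]
    right = seq[element.end:element.end + flank]
    truncated = len(left) < flank or len(right) < flank
    if truncated:
        warnings.warn(f"flank for {element.element_id} truncated by a "
                      f"contig end; reduced flank used")
    eseq = seq[element.start:element.end]
    out = []
    for strain, subject in sorted(other_assemblies.items()):
        lm = _map_flank(left, subject)
        rm = _map_flank(right, subject)
        sides = [s for s, m in (("left", lm), ("right", rm)) if m]
        if not sides:
            out.append(LocusMatch(element.element_id, strain, None, None,
                                  None, [], "ambiguous", False, truncated))
            continue
        occupancy = "ambiguous"
        s_contig = s_start = s_end = None
        if lm and rm and lm["contig"] == rm["contig"] \
                and lm["end"] <= rm["start"] + EMPTY_GAP:
            gap = rm["start"] - lm["end"]
            s_contig = lm["contig"]
            s_start, s_end = lm["end"], rm["start"]
            if gap <= EMPTY_GAP:
                occupancy = "empty"
            elif gap >= OCCUPIED_GAP:
                gseq = subject.contigs[s_contig][lm["end"]:rm["start"]]
                occupancy = "occupied" if _element_like(
                    gseq, eseq, type_db, element.type_assignment) else "ambiguous"
        elif lm or rm:
            # one usable flank: look for the element just beyond it
            m, side = (lm, "left") if lm else (rm, "right")
            s_contig = m["contig"]
            sub = subject.contigs[s_contig]
            span = int(1.5 * element.length)
            if side == "left":
                s_start, s_end = m["end"], min(len(sub), m["end"] + span)
            else:
                s_start, s_end = max(0, m["start"] - span), m["start"]
            if _element_like(sub[s_start:s_end], eseq, type_db,
                             element.type_assignment):
                occupancy = "occupied"
        shared = occupancy == "occupied" and bool(sides)
        out.append(LocusMatch(element.element_id, strain, s_contig, s_start,
                              s_end, sides, occupancy, shared, truncated))
    return out
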