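"""Six-frame ORF calling, local protein alignment and homology typing.

ORFs are called stop-to-stop (not ATG-anchored) in all six frames, matching
permissive curation of compact viral genomes.  Candidate ORFs are scored
against a reference virophage proteome by Smith-Waterman local alignment
under BLOSUM62 with affine gaps (open 11 / extend 1), and bitscores use the
fixed gapped-BLOSUM62 statistics (lambda = 0.267, K = 0.041).  Partial
elements are assigned to a type by the highest cumulative bitscore against
per-type protein sets; cumulative maxima below 100 are "inconclusive".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._util import revcomp

__all__ = [
    "OrfRecord", "AlignmentHit", "TypeAssignment",
    "find_orfs_six_frame", "local_align_protein", "annotate_orfs",
    "assign_type_by_cumulative_bitscore",
    "bitscore", "protein_aligner",
]

LAMBDA = 0.267
LN_K = math.log(0.041)
GAP_OPEN = 11   # BLAST convention: a gap of length k costs open + k*extend
GAP_EXTEND = 1
DEFAULT_MIN_AA = 50
DEFAULT_MIN_BITSCORE = 50.0
INCONCLUSIVE_CUTOFF = 100.0
FRAGMENT_COVERAGE = 0.5

_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


def _blosum62_x0():
    m = substitution_matrices.load("BLOSUM62").copy()
    for ch in m.alphabet:
        m["X", ch] = 0.0
        m[ch, "X"] = 0.0
    return m

BLOSUM62_X0 = _blosum62_x0()


def protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = BLOSUM62_X0
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner

_ALIGNER = protein_aligner()


def bitscore(raw: float) -> float:
    """Normalized bitscore from a raw Smith-Waterman score."""
    return (LAMBDA * raw - LN_K) / math.log(2)


@dataclass
class OrfRecord:
    """A stop-to-stop open reading frame.

    Coordinates are on the forward strand, 0-based half-open, and include
    the trailing stop codon (in reading direction) when one bounds the ORF;
    calling on the reverse complement yields the mirrored coordinate set
    with strands flipped and peptides preserved.
    """

    contig: str
    start: int
    end: int
    strand: str
    frame: int
    peptide: str
    stop_included: bool = True
    fragmented: bool = False
    hit: "AlignmentHit | None" = None

    @property
    def orf_id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}({self.strand})"

    @property
    def aa_length(self) -> int:
        return len(self.peptide)

    @property
    def label(self) -> str | None:
        return self.hit.reference_id if self.hit else None


@dataclass
class AlignmentHit:
    query_id: str
    reference_id: str
    raw_score: float
    bitscore: float
    identity: float = float("nan")
    query_coverage: float = float("nan")
    ref_coverage: float = float("nan")
    ref_span: tuple[int, int] | None = None
    query_span: tuple[int, int] | None = None   # aligned peptide positions


def gene_span(orf: "OrfRecord") -> tuple[int, int]:
    """Forward-strand nt interval of the aligned (gene-like) portion of a
    labeled ORF; falls back to the raw stop-to-stop interval.

    Stop-to-stop ORFs extend upstream to the previous stop codon, so the
    aligned span is the better estimate of where the encoded gene lies.
    """
    if orf.hit is None or orf.hit.query_span is None:
        return (orf.start, orf.end)
    qs, qe = orf.hit.query_span
    if orf.strand == "+":
        return (orf.start + 3 * qs, orf.start + 3 * qe)
    return (orf.end - 3 * qe, orf.end - 3 * qs)


@dataclass
class TypeAssignment:
    element_id: str
    scores: dict[int, float]
    assigned: int | str = "inconclusive"
    margin: float = 0.0
    tie: bool = False


def _orfs_one_strand(seq: str, contig: str, strand: str, min_aa: int,
                     total_len: int) -> list[OrfRecord]:
    out = []
    for frame in range(3):
        usable = len(seq) - frame
        n_codons = usable // 3
        if n_codons == 0:
            continue
        sub = seq[frame:frame + 3 * n_codons]
        pep = str(Seq(sub).translate())
        pos = 0
        for i, chunk in enumerate(pep.split("*")):
            start_codon = pos
            pos += len(chunk) + 1
            if len(chunk) < min_aa:
                continue
            end_codon = start_codon + len(chunk)
            has_stop = end_codon < n_codons
            s = frame + 3 * start_codon
            e = frame + 3 * (end_codon + (1 if has_stop else 0))
            if strand == "+":
                fs, fe = s, e
            else:
                fs, fe = total_len - e, total_len - s
            out.append(OrfRecord(contig, fs, fe, strand, frame, chunk,
                                 stop_included=has_stop))
    return out


def find_orfs_six_frame(sequence: str, min_aa: int = DEFAULT_MIN_AA,
                        contig: str = "seq") -> list[OrfRecord]:
    """All stop-to-stop ORFs of >= min_aa residues in all six frames."""
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if not sequence:
        return []
    fwd = _orfs_one_strand(sequence, contig, "+", min_aa, len(sequence))
    rev = _orfs_one_strand(revcomp(sequence), contig, "-", min_aa,
                           len(sequence))
    return sorted(fwd + rev, key=lambda o: (o.start, o.end, o.strand))


def _validate_peptide(pep: str, name: str) -> None:
    for i, ch in enumerate(pep):
        if ch not in _PROTEIN_ALPHABET:
            raise ValueError(f"illegal residue {ch!r} at position {i} "
                             f"of {name}")


def local_align_protein(query: str, reference: str,
                        coordinates: bool = True) -> AlignmentHit:
    """Smith-Waterman local alignment of two peptides.

    BLOSUM62 with X scored 0, affine gaps (open 11 / extend 1); identity and
    coverage are computed from the first optimal alignment.
    """
    _validate_peptide(query, "query")
    _validate_peptide(reference, "reference")
    if not query or not reference:
        return AlignmentHit("query", "reference", 0.0, bitscore(0.0),
                            0.0, 0.0, 0.0)
    raw = float(_ALIGNER.score(query, reference))
    hit = AlignmentHit("query", "reference", raw, bitscore(raw))
    if coordinates and raw > 0:
        aln = _ALIGNER.align(query, reference)[0]
        qb, rb = aln.aligned
        matches = 0
        aligned_q = sum(int(e - s) for s, e in qb)
        for (qs, qe), (rs, re) in zip(qb, rb):
            matches += sum(1 for a, b in zip(query[qs:qe], reference[rs:re])
                           if a == b)
        hit.identity = matches / aligned_q if aligned_q else 0.0
        hit.query_coverage = (qb[-1][1] - qb[0][0]) / len(query)
        hit.ref_coverage = (rb[-1][1] - rb[0][0]) / len(reference)
        hit.ref_span = (int(rb[0][0]), int(rb[-1][1]))
        hit.query_span = (int(qb[0][0]), int(qb[-1][1]))
    return hit


def _pep_words(pep: str, k: int = 4) -> set[str]:
    return {pep[i:i + k] for i in range(len(pep) - k + 1)}


def annotate_orfs(orfs: list[OrfRecord], reference_proteins: dict[str, str],
                  min_bitscore: float = DEFAULT_MIN_BITSCORE
                  ) -> list[OrfRecord]:
    """Label each ORF with its best-scoring reference protein.

    References sharing fewer than two exact peptide 4-mers with the ORF are
    skipped before alignment (homologs at the bitscore cutoff share many).
    An ORF is flagged ``fragmented`` when its best hit covers less than half
    of the reference and an adjacent same-strand ORF hits the same reference
    on a mostly non-overlapping (complementary) region.
    """
    if not reference_proteins:
        raise ValueError("reference protein set is empty")
    refs = sorted(reference_proteins.items())
    ref_words = {rid: _pep_words(pep) for rid, pep in refs}
    for orf in orfs:
        best_ref, best_raw = None, 0.0
        words = _pep_words(orf.peptide)
        for rid, rpep in refs:
            if not rpep or len(words & ref_words[rid]) < 2:
                continue
            raw = float(_ALIGNER.score(orf.peptide, rpep))
            if raw > best_raw:
                best_ref, best_raw = rid, raw
        orf.hit = None
        if best_ref is not None and bitscore(best_raw) >= min_bitscore:
            hit = local_align_protein(orf.peptide, reference_proteins[best_ref])
            hit.query_id = orf.orf_id
            hit.reference_id = best_ref
            orf.hit = hit
    # fragmentation: adjacent same-strand ORFs hitting complementary halves
    labeled = [o for o in orfs if o.hit is not None]
    labeled.sort(key=lambda o: (o.contig, o.strand, o.start))
    for a, b in zip(labeled, labeled[1:]):
        if (a.contig != b.contig or a.strand != b.strand
                or a.hit.reference_id != b.hit.reference_id):
            continue
        if (a.hit.ref_coverage > FRAGMENT_COVERAGE
                or b.hit.ref_coverage > FRAGMENT_COVERAGE):
            continue
        if a.hit.ref_span and b.hit.ref_span:
            ov = (min(a.hit.ref_span[1], b.hit.ref_span[1])
                  - max(a.hit.ref_span[0], b.hit.ref_span[0]))
            shorter = min(a.hit.ref_span[1] - a.hit.ref_span[0],
                          b.hit.ref_span[1] - b.hit.ref_span[0])
            if ov < 0.5 * max(shorter, 1):
                a.fragmented = b.fragmented = True
    return orfs


def assign_type_by_cumulative_bitscore(
        element_sequence: str,
        type_species_db: dict[int, dict[str, str]],
        element_id: str = "element",
        min_aa: int = DEFAULT_MIN_AA,
        orfs: list[OrfRecord] | None = None) -> TypeAssignment:
    """Type an element by cumulative best-per-ORF bitscores.

    Each ORF contributes its single best bitscore against each type's
    protein set (best hit only, avoiding double counting of paralogous
    hits); the type with the maximal cumulative score wins, ties break to
    the lower type id (flagged), and maxima below 100 are "inconclusive".
    """
    if orfs is None:
        orfs = find_orfs_six_frame(element_sequence, min_aa=min_aa)
    assignment = TypeAssignment(element_id, {})
    if not orfs:
        assignment.scores = {tid: 0.0 for tid in type_species_db}
        return assignment
    orf_words = [_pep_words(o.peptide) for o in orfs]
    for tid in sorted(type_species_db):
        peps = [(pep, _pep_words(pep))
                for pep in type_species_db[tid].values() if pep]
        total = 0.0
        for orf, words in zip(orfs, orf_words):
            best = 0.0
            for pep, pwords in peps:
                if len(words & pwords) < 2:
                    continue
                raw = float(_ALIGNER.score(orf.peptide, pep))
                best = max(best, raw)
            if best > 0:
                total += bitscore(best)
        assignment.scores[tid] = total
    ranked = sorted(assignment.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    top_id, top = ranked[0]
    runner = ranked[1][1] if len(ranked) > 1 else 0.0
    assignment.margin = top - runner
    assignment.tie = len(ranked) > 1 and top == runner
    if top >= INCONCLUSIVE_CUTOFF:
        assignment.assigned = top_id
    return assignment
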