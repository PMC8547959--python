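"""Ngaro retrotransposon detection, structure, typing and site statistics.

Ngaros appear as GC-rich ~6 kb insertions interrupting AT-rich virophage
elements (or sitting in host DNA), carry split direct repeats with
A1-[ORFs]-B1A2B2 architecture, separate into four types with no cross-type
nucleotide similarity, and occur with or without their 5' ORF1 (Gag-like)
— the ORF1-truncated "b" variants.  Integration-site preference between
intergenic and genic/TIR element DNA is tested with Fisher's exact test on
a base-composition-weighted 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._util import encode_seq, kmer_codes, revcomp, runs_of_true, seq_kmer_codes
from .gc_profile import compute_gc_profile
from .io import GenomeAssembly
from .orfs import bitscore, find_orfs_six_frame, protein_aligner

__all__ = [
    "RepeatStructure", "NgaroRecord", "InsertionSiteStats",
    "detect_high_gc_insertions", "detect_split_direct_repeats",
    "classify_ngaro", "integration_bias_test", "find_ngaro_candidates",
    "classify_insertion_site",
]

INSERTION_DELTA = 0.10      # GC points above the element's own baseline
INSERTION_MIN_LEN = 2000
INSERTION_MAX_LEN = 12000
INSERTION_WINDOW = 200
INSERTION_STEP = 50
REPEAT_MIN_ARM = 50
REPEAT_MIN_IDENTITY = 0.9
REPEAT_TOL = 100            # B1A2B2 contiguity tolerance, bp
ORF1_REGION = 2500          # 5' span expected to contain ORF1, bp
# Minimum fragment size considered when testing for ORF1: nonsense
# substitutions can split a Gag ORF into sub-200 aa pieces that still align
# strongly, so presence is decided by homology of >=100 aa fragments.
ORF1_MIN_AA = 100
TYPE_MIN_COVERAGE = 0.30
SCAN_K = 16
SCAN_JOIN_GAP = 400
SCAN_MIN_LEN = 500

_ALIGNER = protein_aligner()


@dataclass
class RepeatStructure:
    a1: tuple[int, int] | None
    b1: tuple[int, int] | None
    a2: tuple[int, int] | None
    b2: tuple[int, int] | None
    identity_a: float = float("nan")
    identity_b: float = float("nan")
    solo: bool = False

    @property
    def complete(self) -> bool:
        return None not in (self.a1, self.b1, self.a2, self.b2)


@dataclass
class NgaroRecord:
    ngaro_id: str
    contig: str
    start: int
    end: int
    container: str = "host"            # element|host
    container_element_id: str | None = None
    type_id: int | str = "unassigned"
    variant: str = "full"              # full|orf1_truncated
    structure: RepeatStructure | None = None
    gc: float = float("nan")
    solo: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class InsertionSiteStats:
    table: list[list[int]]    # [[ins_intergenic, ins_other],
    #                            [bases_intergenic, bases_other]]
    odds_ratio: float
    p_two_sided: float
    p_binomial: float
    construction: str = ("rows: Ngaro insertions in intergenic vs genic+TIR "
                         "element DNA; columns weighted by per-class base "
                         "totals from the same annotations")


# ---------------------------------------------------------------------------
# GC-rich insertion calling within an element

def _refine_rise(cgc, cok, edge, radius, flank, rising, seq_len):
    """Changepoint: maximal (right-minus-left) GC step if ``rising``."""
    lo, hi = max(0, edge - radius), min(seq_len, edge + radius)
    best_t, best = edge, -np.inf
    for t in range(lo, hi + 1):
        na = cok[t] - cok[max(0, t - flank)]
        nb = cok[min(seq_len, t + flank)] - cok[t]
        if na < 40 or nb < 40:
            continue
        ga = (cgc[t] - cgc[max(0, t - flank)]) / na
        gb = (cgc[min(seq_len, t + flank)] - cgc[t]) / nb
        score = (gb - ga) if rising else (ga - gb)
        if score > best:
            best, best_t = score, t
    return best_t


def detect_high_gc_insertions(element_sequence: str,
                              delta: float = INSERTION_DELTA,
                              min_len: int = INSERTION_MIN_LEN,
                              max_len: int = INSERTION_MAX_LEN,
                              exclude: list[tuple[int, int]] | None = None
                              ) -> list[tuple[int, int]]:
    """Intervals of the element whose GC rises >= delta above the element's
    own (trimmed-mean) baseline — candidate retrotransposon insertions.

    ``exclude`` intervals (e.g. TIRs) are ignored when estimating the
    baseline.  Adjacent insertions separated by any run of element-like
    windows are reported as separate intervals.
    """
    if len(element_sequence) < min_len:
        return []
    prof = compute_gc_profile(element_sequence, INSERTION_WINDOW,
                              INSERTION_STEP)
    vals = prof.values.copy()
    if vals.size == 0:
        return []
    base_vals = vals.copy()
    if exclude:
        pos = prof.positions()
        for s, e in exclude:
            base_vals[(pos + INSERTION_WINDOW > s) & (pos < e)] = np.nan
    finite = base_vals[~np.isnan(base_vals)]
    if finite.size == 0:
        return []
    baseline = float(stats.trim_mean(np.sort(finite), 0.2))
    mask = np.zeros(vals.size, dtype=bool)
    good = ~np.isnan(vals)
    mask[good] = vals[good] >= baseline + delta
    arr = encode_seq(element_sequence)
    gc = ((arr == 1) | (arr == 2)).astype(np.int64)
    ok = (arr >= 0).astype(np.int64)
    cgc = np.concatenate([[0], np.cumsum(gc)])
    cok = np.concatenate([[0], np.cumsum(ok)])
    out = []
    for i, j in runs_of_true(mask):
        s = i * INSERTION_STEP
        e = (j - 1) * INSERTION_STEP + INSERTION_WINDOW
        s = _refine_rise(cgc, cok, s, INSERTION_WINDOW, INSERTION_WINDOW,
                         True, len(element_sequence))
        e = _refine_rise(cgc, cok, e, INSERTION_WINDOW, INSERTION_WINDOW,
                         False, len(element_sequence))
        if min_len <= e - s <= max_len:
            out.append((s, e))
    return out


def excise(sequence: str, intervals: list[tuple[int, int]]) -> str:
    """Remove intervals from a sequence (idempotent for fixed intervals)."""
    if not intervals:
        return sequence
    out, cursor = [], 0
    for s, e in sorted(intervals):
        out.append(sequence[cursor:s])
        cursor = max(cursor, e)
    out.append(sequence[cursor:])
    return "".join(out)


# ---------------------------------------------------------------------------
# split direct repeats

def _self_repeat_pairs(seq: str, min_arm: int, min_identity: float):
    """Same-strand repeat pairs from clustered k-mer self-matches."""
    codes, valid = seq_kmer_codes(seq, SCAN_K)
    pos = np.flatnonzero(valid)
    cod = codes[valid]
    order = np.argsort(cod, kind="stable")
    cod_s, pos_s = cod[order], pos[order]
    matches = []  # (diagonal, i)
    bounds = np.flatnonzero(np.concatenate([[True], np.diff(cod_s) != 0,
                                            [True]]))
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        if b1 - b0 < 2 or b1 - b0 > 50:
            continue
        group = np.sort(pos_s[b0:b1])
        for x in range(len(group)):
            for y in range(x + 1, len(group)):
                i, j = int(group[x]), int(group[y])
                if j - i >= min_arm:
                    matches.append((j - i, i))
    if not matches:
        return []
    matches.sort()
    clusters = []
    # bridge dirty stretches: clustered substitutions can leave >100 bp
    # without a clean shared k-mer inside one repeat arm; the identity
    # check over the full clustered span validates the bridge
    for d, i in matches:
        if clusters and abs(d - clusters[-1]["d"]) <= 30 \
                and i - clusters[-1]["imax"] <= 150:
            c = clusters[-1]
            c["imax"] = max(c["imax"], i)
            c["d"] = d
        else:
            clusters.append({"d": d, "imin": i, "imax": i})
    pairs = []
    for c in clusters:
        a0, a1 = c["imin"], c["imax"] + SCAN_K
        if a1 - a0 < min_arm:
            continue
        b0 = a0 + c["d"]
        arm1, arm2 = seq[a0:a1], seq[b0:b0 + (a1 - a0)]
        n = min(len(arm1), len(arm2))
        if n < min_arm:
            continue
        ident = sum(1 for x, y in zip(arm1[:n], arm2[:n]) if x == y) / n
        if ident >= min_identity:
            pairs.append(((a0, a1), (b0, b0 + n), ident))
    return pairs


def detect_split_direct_repeats(candidate: str,
                                known_repeats: list[tuple[str, str]] | None = None,
                                min_arm: int = REPEAT_MIN_ARM,
                                min_identity: float = REPEAT_MIN_IDENTITY,
                                tol: int = REPEAT_TOL
                                ) -> RepeatStructure | None:
    """Resolve the A1-[ORFs]-B1A2B2 split-direct-repeat architecture.

    Same-strand repeat pairs (arms >= 50 bp at >= 0.9 identity) are found
    by clustered exact k-mer self-matches; the architecture requires
    A1 < B1 <= A2 < B2 with B1A2B2 contiguous within ``tol``.  A single
    detached A+B pair (matched against ``known_repeats`` — (A, B) sequence
    tuples from resolved full-length elements or bundled templates) with no
    long ORFs in between is flagged ``solo``.
    """
    if len(candidate) < 500:
        raise ValueError("candidate shorter than 500 bp")
    pairs = _self_repeat_pairs(candidate, min_arm, min_identity)
    best = None
    for ai, (a1, a2, ia) in enumerate(pairs):
        for bi, (b1, b2, ib) in enumerate(pairs):
            if ai == bi:
                continue
            if not (a1[0] < b1[0] <= a2[0] < b2[0]):
                continue
            if abs(a2[0] - b1[1]) > tol or abs(b2[0] - a2[1]) > tol:
                continue
            total = (a1[1] - a1[0]) + (b1[1] - b1[0])
            if best is None or total > best[0]:
                best = (total, RepeatStructure(a1, b1, a2, b2, ia, ib))
    if best is not None:
        return best[1]
    if known_repeats:
        import edlib
        for rep_a, rep_b in known_repeats:
            ra = edlib.align(rep_a, candidate, mode="HW", task="locations",
                             k=int(len(rep_a) * 0.15))
            rb = edlib.align(rep_b, candidate, mode="HW", task="locations",
                             k=int(len(rep_b) * 0.15))
            if ra["editDistance"] < 0 or rb["editDistance"] < 0:
                continue
            (as_, ae), (bs, be) = ra["locations"][0], rb["locations"][0]
            ae, be = ae + 1, be + 1
            if not (as_ < bs and abs(bs - ae) <= tol):
                continue
            # a solo pair is a detached A+B with no coding sequence around
            # it — not the B1A2B2 tail of a full-length element
            flanks = [candidate[:as_], candidate[ae:bs], candidate[be:]]
            if any(find_orfs_six_frame(f, min_aa=100)
                   for f in flanks if len(f) >= 300):
                continue
            return RepeatStructure((as_, ae), (bs, be), None, None,
                                   1 - ra["editDistance"] / len(rep_a),
                                   1 - rb["editDistance"] / len(rep_b),
                                   solo=True)
    return None


# ---------------------------------------------------------------------------
# typing and ORF1 status

def _orient_to_template(candidate: str, template: str) -> tuple[str, float]:
    """Orient the candidate to the template; return (sequence, coverage)."""
    from .dotplot import wordmatch_dotplot
    m = wordmatch_dotplot({"c": candidate, "t": template})
    fwd = m.match_count("c", "t", "+")
    rev = m.match_count("c", "t", "-")
    cov = m.coverage("c", "t")
    return (revcomp(candidate) if rev > fwd else candidate), cov


def classify_ngaro(candidate: str, ngaro_type_db: dict[int, dict]
                   ) -> tuple[int | str, str]:
    """Assign (type_id, variant) by word-10 similarity to the type templates.

    ``ngaro_type_db`` maps type_id -> {"sequence": str, "proteins":
    {label: peptide}}.  The variant is ``orf1_truncated`` when no ORF of
    >= 200 aa within the 5' 2.5 kb has its best protein hit on the type's
    ORF1 (Gag-like) reference.
    """
    best_tid, best_cov, oriented = "unassigned", 0.0, candidate
    for tid in sorted(ngaro_type_db):
        seq_t = ngaro_type_db[tid]["sequence"]
        cand_o, cov = _orient_to_template(candidate, seq_t)
        if cov > best_cov:
            best_tid, best_cov, oriented = tid, cov, cand_o
    if best_cov < TYPE_MIN_COVERAGE:
        return "unassigned", "full"
    proteins = ngaro_type_db[best_tid].get("proteins", {})
    orf1_ref = proteins.get("ORF1_gag")
    if orf1_ref is None:
        return best_tid, "full"
    head = oriented[:ORF1_REGION + 1500]
    orfs = [o for o in find_orfs_six_frame(head, min_aa=ORF1_MIN_AA)
            if o.start < ORF1_REGION]
    # "ORF1-like" means a strong alignment to the type's Gag-like reference;
    # a nonsense/readthrough fusion with ORF2 still counts as ORF1 present.
    has_orf1 = any(
        bitscore(float(_ALIGNER.score(o.peptide, orf1_ref))) >= 50
        for o in orfs)
    return best_tid, ("full" if has_orf1 else "orf1_truncated")


# ---------------------------------------------------------------------------
# genome-wide candidate scan

def find_ngaro_candidates(assembly: GenomeAssembly,
                          template_sequences: dict[int, str],
                          min_len: int = SCAN_MIN_LEN
                          ) -> list[tuple[str, int, int]]:
    """Intervals with dense exact 16-mer matches to any Ngaro template."""
    pool = []
    for seq in template_sequences.values():
        for s in (seq, revcomp(seq)):
            codes, valid = seq_kmer_codes(s, SCAN_K)
            pool.append(codes[valid])
    pool = np.unique(np.concatenate(pool))
    out = []
    for cid, seq in assembly.contigs.items():
        codes, valid = seq_kmer_codes(seq, SCAN_K)
        hit = np.zeros(len(codes), dtype=bool)
        hit[valid] = np.isin(codes[valid], pool)
        hp = np.flatnonzero(hit)
        if hp.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(hp) > SCAN_JOIN_GAP)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [hp.size - 1]])
        for s_i, e_i in zip(starts, ends):
            s, e = int(hp[s_i]), int(hp[e_i]) + SCAN_K
            if e - s >= min_len:
                out.append((cid, s, e))
    return out


def classify_insertion_site(insertion: tuple[int, int],
                            orf_intervals: list[tuple[int, int]],
                            tir_intervals: list[tuple[int, int]]) -> str:
    """intergenic / genic / tir classification of an insertion point."""
    point = insertion[0]
    for s, e in tir_intervals:
        if s <= point <= e:
            return "tir"
    for s, e in orf_intervals:
        if s < point < e:
            return "genic"
    return "intergenic"


def integration_bias_test(site_classes: list[str],
                          class_bases: dict[str, int]) -> InsertionSiteStats:
    """Fisher's exact test for intergenic integration preference.

    Rows: insertions in intergenic vs elsewhere (genic + TIR); columns
    weight the comparison by the per-class base totals of the same element
    annotations.  A binomial tail P(X >= k | p = intergenic fraction) is
    reported as a cross-check.
    """
    if not site_classes:
        raise ValueError("no insertions supplied")
    k = sum(1 for c in site_classes if c == "intergenic")
    n = len(site_classes)
    bi = int(class_bases.get("intergenic", 0))
    bo = int(sum(v for c, v in class_bases.items() if c != "intergenic"))
    table = [[k, n - k], [bi, bo]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    p_binom = float(stats.binom.sf(k - 1, n, bi / max(bi + bo, 1)))
    return InsertionSiteStats(table, float(odds), float(p), p_binom)
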