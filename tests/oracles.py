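"""Independent oracles used by the test suite.

Each oracle is a deliberately simple, quadratic-or-worse implementation
kept separate from the package code paths it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def blosum62_x0(a: str, b: str) -> float:
    if a == "X" or b == "X":
        return 0.0
    return float(_B62[a, b])


def sw_gotoh(query: str, ref: str, open_cost: int = 11,
             extend_cost: int = 1) -> float:
    """Quadratic-time Gotoh local alignment score (gap of length k costs
    open_cost + k*extend_cost)."""
    n, m = len(query), len(ref)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)   # gap in ref (vertical)
    F = np.full((n + 1, m + 1), NEG)   # gap in query (horizontal)
    best = 0.0
    first = open_cost + extend_cost
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - first, E[i - 1][j] - extend_cost)
            F[i][j] = max(H[i][j - 1] - first, F[i][j - 1] - extend_cost)
            diag = H[i - 1][j - 1] + blosum62_x0(query[i - 1], ref[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def fisher_two_sided(table) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration with
    exact rational arithmetic."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
        if px <= p_obs:
            total += px
    return float(total)


def word_match_count(a: str, b: str, word: int) -> int:
    """Brute-force count of exact forward word matches between a and b."""
    index: dict[str, int] = {}
    for j in range(len(b) - word + 1):
        w = b[j:j + word]
        if "N" not in w:
            index[w] = index.get(w, 0) + 1
    count = 0
    for i in range(len(a) - word + 1):
        w = a[i:i + word]
        if "N" not in w:
            count += index.get(w, 0)
    return count


def gc_profile_direct(seq: str, window: int, step: int) -> list[float]:
    """Direct per-window GC counting (N excluded from both sides)."""
    out = []
    for start in range(0, len(seq) - window + 1, step):
        w = seq[start:start + window]
        gc = sum(1 for ch in w if ch in "GC")
        n = sum(1 for ch in w if ch == "N")
        out.append(float("nan") if n == window else gc / (window - n))
    return out


STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def orf_intervals_direct(seq: str, min_aa: int) -> set[tuple[int, int, str]]:
    """Stop-codon-scan oracle for six-frame stop-to-stop ORF coordinates
    (trailing stop included; forward-strand coordinates)."""
    found = set()
    for strand in "+-":
        s = seq if strand == "+" else seq.translate(_COMP)[::-1]
        L = len(s)
        for frame in range(3):
            codon_starts = list(range(frame, L - 2, 3))
            stops = [i for i in codon_starts if s[i:i + 3] in STOP_CODONS]
            borders = [frame - 3] + stops + [None]
            for prev, nxt in zip(borders[:-1], borders[1:]):
                begin = prev + 3
                if nxt is None:
                    last = codon_starts[-1] + 3 if codon_starts else begin
                    end = last
                    n_codons = (end - begin) // 3
                else:
                    end = nxt + 3
                    n_codons = (nxt - begin) // 3
                if n_codons < min_aa:
                    continue
                if strand == "+":
                    found.add((begin, end, "+"))
                else:
                    found.add((L - end, L - begin, "-"))
    return found
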