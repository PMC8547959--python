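"""Small shared helpers: sequence encoding, k-mer codes, intervals, RNG."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")

# 2-bit base codes; -1 marks anything outside ACGT
_BASE2BIT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE2BIT[ord(_b)] = _i
    _BASE2BIT[ord(_b.lower())] = _i

BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Sequence -> int8 array of 2-bit codes, -1 for ambiguous bases."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE2BIT[raw]


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Polynomial k-mer codes over a 2-bit array.

    Returns (codes, valid) of length len(arr)-k+1; ``valid`` is False where
    the window contains an ambiguous base.  Requires k <= 31 (int64 safe).
    """
    if k > 31:
        raise ValueError("k must be <= 31")
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    codes = np.zeros(n, dtype=np.int64)
    clean = np.where(arr < 0, 0, arr).astype(np.int64)
    for i in range(k):
        codes += clean[i:n + i] << (2 * (k - 1 - i))
    bad = (arr < 0).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return codes, valid


def seq_kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    return kmer_codes(encode_seq(seq), k)


def gc_fraction(seq: str) -> float:
    """GC over unambiguous bases; NaN if no unambiguous base."""
    arr = encode_seq(seq)
    ok = arr >= 0
    n = int(ok.sum())
    if n == 0:
        return float("nan")
    gc = int(((arr == 1) | (arr == 2)).sum())
    return gc / n


def runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index intervals."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min over both intervals of overlap/len; 0 if disjoint or empty."""
    ov = min(a[1], b[1]) - max(a[0], b[0])
    la, lb = a[1] - a[0], b[1] - b[0]
    if ov <= 0 or la <= 0 or lb <= 0:
        return 0.0
    return min(ov / la, ov / lb)


def interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def child_rng(seed: int, *stream: int) -> np.random.Generator:
    """Deterministic child generator for a named stream."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


def random_seq_exact_gc(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random sequence whose realized GC equals round(gc*length)/length.

    G/C and A/T are split evenly at random within their pools.
    """
    if length <= 0:
        return ""
    n_gc = int(round(gc * length))
    strong = rng.integers(0, 2, size=n_gc)          # 0 -> G, 1 -> C
    weak = rng.integers(0, 2, size=length - n_gc)   # 0 -> A, 1 -> T
    arr = np.empty(length, dtype=np.int8)
    arr[:n_gc] = np.where(strong == 0, 2, 1)        # codes: G=2, C=1
    arr[n_gc:] = np.where(weak == 0, 0, 3)          # A=0, T=3
    rng.shuffle(arr)
    return decode_seq(arr)


def decode_seq(arr: np.ndarray) -> str:
    out = np.empty(len(arr), dtype="S1")
    lut = np.frombuffer(b"ACGT", dtype="S1")
    ok = arr >= 0
    out[ok] = lut[arr[ok]]
    out[~ok] = b"N"
    return out.tobytes().decode("ascii")


def mutate_substitutions(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply i.i.d. substitutions at the given per-base rate (no indels)."""
    if rate <= 0 or not seq:
        return seq
    arr = encode_seq(seq)
    hit = np.flatnonzero((rng.random(len(arr)) < rate) & (arr >= 0))
    if hit.size == 0:
        return seq
    shift = rng.integers(1, 4, size=hit.size)
    arr[hit] = (arr[hit] + shift) % 4
    return decode_seq(arr)
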