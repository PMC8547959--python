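"""Sliding-window GC profiling and low-GC candidate segment calling.

The primary screen for integrated virophage elements: windows of the host
assembly are scanned for GC values far below the genome baseline, runs of
low-GC windows are merged and size-filtered, and the resulting segment
boundaries are refined to the maximal-contrast changepoint at single-base
resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._util import encode_seq, runs_of_true

__all__ = ["GcProfile", "CandidateSegment", "compute_gc_profile",
           "call_low_gc_segments"]

DEFAULT_WINDOW = 500
DEFAULT_STEP = 100
DEFAULT_DELTA = 0.15      # points below baseline, as a fraction
DEFAULT_MIN_LEN = 2000
DEFAULT_MERGE_GAP = 1000


@dataclass
class GcProfile:
    """Windowed GC values for one contig.

    ``values[i]`` is (#G + #C)/(window - #N) over [i*step, i*step+window);
    all-N windows are NaN.  Ambiguous bases are excluded from numerator and
    denominator (``n_policy`` = "exclude").
    """

    contig: str
    window: int
    step: int
    values: np.ndarray
    n_policy: str = "exclude"

    def positions(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.step

    def to_tsv(self) -> str:
        lines = ["contig\tstart\tend\tgc"]
        for i, v in enumerate(self.values):
            s = i * self.step
            lines.append(f"{self.contig}\t{s}\t{s + self.window}\t"
                         f"{'' if np.isnan(v) else f'{v:.4f}'}")
        return "\n".join(lines) + "\n"


@dataclass
class CandidateSegment:
    contig: str
    start: int
    end: int
    mean_gc: float
    host_baseline_gc: float
    at_contig_end: bool = False
    attrs: dict = field(default_factory=dict)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start


def _cumsums(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative counts of GC and of unambiguous bases (leading 0)."""
    arr = encode_seq(seq)
    gc = ((arr == 1) | (arr == 2)).astype(np.int64)
    ok = (arr >= 0).astype(np.int64)
    return (np.concatenate([[0], np.cumsum(gc)]),
            np.concatenate([[0], np.cumsum(ok)]))


def compute_gc_profile(sequence: str, window: int = DEFAULT_WINDOW,
                       step: int = DEFAULT_STEP,
                       contig: str = "seq") -> GcProfile:
    """Windowed GC fractions; empty profile (with a warning) if the sequence
    is shorter than one window."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    n = (len(sequence) - window) // step + 1
    if n <= 0:
        warnings.warn(f"sequence ({len(sequence)} bp) shorter than window "
                      f"({window} bp); empty profile")
        return GcProfile(contig, window, step, np.empty(0))
    cgc, cok = _cumsums(sequence)
    starts = np.arange(n) * step
    gc = cgc[starts + window] - cgc[starts]
    ok = cok[starts + window] - cok[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(ok > 0, gc / np.maximum(ok, 1), np.nan)
    return GcProfile(contig, window, step, values)


def segment_mean_gc(sequence: str, start: int, end: int) -> float:
    cgc, cok = _cumsums(sequence[start:end])
    ok = cok[-1]
    return float(cgc[-1] / ok) if ok else float("nan")


def _refine_edge(cgc: np.ndarray, cok: np.ndarray, edge: int, radius: int,
                 flank: int, left_edge: bool, seq_len: int) -> int:
    """Move ``edge`` to the position maximizing the outside-minus-inside GC
    contrast over ``flank``-bp windows, within +-radius."""
    lo = max(0, edge - radius)
    hi = min(seq_len, edge + radius)
    best_t, best_score = edge, -np.inf
    for t in range(lo, hi + 1):
        a0, a1 = max(0, t - flank), t
        b0, b1 = t, min(seq_len, t + flank)
        na = cok[a1] - cok[a0]
        nb = cok[b1] - cok[b0]
        if na < 50 or nb < 50:
            # allow segments to snap onto contig ends
            if (left_edge and t == 0) or (not left_edge and t == seq_len):
                return t
            continue
        ga = (cgc[a1] - cgc[a0]) / na
        gb = (cgc[b1] - cgc[b0]) / nb
        score = (ga - gb) if left_edge else (gb - ga)
        if score > best_score:
            best_score, best_t = score, t
    return best_t


def call_low_gc_segments(profile: GcProfile, sequence: str,
                         baseline: float | None = None,
                         delta: float = DEFAULT_DELTA,
                         min_len: int = DEFAULT_MIN_LEN,
                         merge_gap: int = DEFAULT_MERGE_GAP,
                         refine: bool = True) -> list[CandidateSegment]:
    """Call maximal low-GC runs against the host baseline.

    Windows with value <= baseline - delta are joined into runs, merged
    across gaps <= merge_gap, filtered to >= min_len, then each boundary is
    refined to the maximal-contrast changepoint within one window of the
    run edge.  ``baseline`` defaults to the median window value of the
    profile (the pipeline passes the genome-wide median).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    vals = profile.values
    if vals.size == 0:
        return []
    if baseline is None:
        baseline = float(np.nanmedian(vals))
    mask = np.zeros(vals.size, dtype=bool)
    good = ~np.isnan(vals)
    mask[good] = vals[good] <= baseline - delta
    step, window = profile.step, profile.window
    spans = [(i * step, (j - 1) * step + window) for i, j in runs_of_true(mask)]
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    cgc, cok = _cumsums(sequence)
    out = []
    for s, e in merged:
        if e - s < min_len:
            continue
        if refine:
            s = _refine_edge(cgc, cok, s, window, window, True, len(sequence))
            e = _refine_edge(cgc, cok, e, window, window, False, len(sequence))
        ok = cok[e] - cok[s]
        mean_gc = float((cgc[e] - cgc[s]) / ok) if ok else float("nan")
        out.append(CandidateSegment(
            profile.contig, s, e, mean_gc, baseline,
            at_contig_end=(s == 0 or e == len(sequence))))
    return out
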