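"""Nucleotide-contribution accounting, codon usage and gene-length effects.

Host / element / Ngaro fractions of a genome are estimated two ways:
exact base bookkeeping over the assembly annotations, and CIGAR-aware
attribution of aligned read bases to the class of their reference
position.  Nested retrotransposon bases count as Ngaro, not element, in
both estimators, so the two are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomeAssembly, read_sam

__all__ = ["FractionReport", "CodonTable", "assembly_fractions",
           "read_fractions", "fraction_deviation", "codon_usage_profile",
           "gene_length_comparison", "build_label_arrays"]

CLASSES = ("host", "element", "ngaro")


@dataclass
class FractionReport:
    strain: str
    total_bases: int
    bases: dict[str, int]
    fractions: dict[str, float]
    estimator: str              # assembly|reads
    skipped_records: int = 0

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions, name=f"{self.strain}:{self.estimator}")


@dataclass
class CodonTable:
    element_id: str
    counts: dict[str, int]
    gc3: float
    element_gc: float
    synonymous_usage: dict[str, dict[str, float]]

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())


def build_label_arrays(assembly: GenomeAssembly,
                       element_intervals: list[tuple[str, int, int]],
                       ngaro_intervals: list[tuple[str, int, int]]
                       ) -> dict[str, np.ndarray]:
    """Per-contig class labels (0 host, 1 element, 2 ngaro); ngaro wins
    inside elements."""
    labels = {cid: np.zeros(len(seq), dtype=np.uint8)
              for cid, seq in assembly.contigs.items()}
    for cid, s, e in element_intervals:
        if cid not in labels or s < 0 or e > len(labels[cid]):
            raise ValueError(f"annotation [{s},{e}) outside contig {cid}")
        labels[cid][s:e] = 1
    for cid, s, e in ngaro_intervals:
        if cid not in labels or s < 0 or e > len(labels[cid]):
            raise ValueError(f"annotation [{s},{e}) outside contig {cid}")
        labels[cid][s:e] = 2
    return labels


def _report(strain: str, counts: np.ndarray, estimator: str,
            skipped: int = 0) -> FractionReport:
    total = int(counts.sum())
    bases = {cls: int(counts[i]) for i, cls in enumerate(CLASSES)}
    fractions = {cls: (bases[cls] / total if total else float("nan"))
                 for cls in CLASSES}
    return FractionReport(strain, total, bases, fractions, estimator, skipped)


def assembly_fractions(assembly: GenomeAssembly,
                       element_intervals: list[tuple[str, int, int]],
                       ngaro_intervals: list[tuple[str, int, int]],
                       strain: str | None = None) -> FractionReport:
    """Exact per-class base bookkeeping over the assembly annotations."""
    labels = build_label_arrays(assembly, element_intervals, ngaro_intervals)
    counts = np.zeros(3, dtype=np.int64)
    for arr in labels.values():
        counts += np.bincount(arr, minlength=3)[:3]
    return _report(strain or assembly.name, counts, "assembly")


def read_fractions(sam_path: str | Path,
                   labels: dict[str, np.ndarray],
                   strain: str = "assembly") -> FractionReport:
    """Attribute aligned read bases to host/element/ngaro classes.

    Unmapped, secondary and supplementary records are skipped (counted).
    CIGAR handling: M/=/X bases take the class of their reference
    position; insertions are attributed to the class at the insertion
    point; deletions are not counted.
    """
    counts = np.zeros(3, dtype=np.int64)
    skipped = 0
    for rec in read_sam(sam_path):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            skipped += 1
            continue
        if rec.reference_name not in labels:
            raise ValueError(f"alignment {rec.query_name!r} maps to unknown "
                             f"reference {rec.reference_name!r}")
        arr = labels[rec.reference_name]
        rpos = rec.reference_start
        for op, ln in rec.cigartuples:
            if op in (0, 7, 8):        # M, =, X
                counts += np.bincount(arr[rpos:rpos + ln], minlength=3)[:3]
                rpos += ln
            elif op == 1:              # I: class at the insertion point
                counts[arr[min(max(rpos - 1, 0), len(arr) - 1)]] += ln
            elif op in (2, 3):         # D, N
                rpos += ln
            # S/H/P consume no reference and are not attributed
    return _report(strain, counts, "reads", skipped)


def fraction_deviation(a: FractionReport, b: FractionReport
                       ) -> dict[str, float]:
    """Absolute per-class deviation between two estimators, in percentage
    points."""
    return {cls: abs(a.fractions[cls] - b.fractions[cls]) * 100
            for cls in CLASSES}


# ---------------------------------------------------------------------------
# codon usage

_STANDARD = {
    "F": ["TTT", "TTC"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"], "M": ["ATG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "A": ["GCT", "GCC", "GCA", "GCG"], "Y": ["TAT", "TAC"],
    "H": ["CAT", "CAC"], "Q": ["CAA", "CAG"], "N": ["AAT", "AAC"],
    "K": ["AAA", "AAG"], "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
    "C": ["TGT", "TGC"], "W": ["TGG"], "R": ["CGT", "CGC", "CGA", "CGG",
                                             "AGA", "AGG"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "*": ["TAA", "TAG", "TGA"],
}
_CODON_TO_AA = {c: aa for aa, cs in _STANDARD.items() for c in cs}


def count_codons(orf_sequences: list[str]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in orf_sequences:
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            counts[codon] = counts.get(codon, 0) + 1
    return counts


def codon_usage_profile(elements: dict[str, tuple[float, list[str]]]
                        ) -> tuple[list[CodonTable], float]:
    """Per-element codon statistics and the GC3-vs-element-GC correlation.

    ``elements`` maps element id to (element GC, list of ORF nucleotide
    sequences).  Elements without ORFs are excluded.  Returns the codon
    tables and the Spearman correlation of GC3 against element GC (NaN
    with < 3 usable elements).
    """
    tables = []
    for eid, (egc, orf_seqs) in sorted(elements.items()):
        if not orf_seqs:
            continue
        counts = count_codons(orf_seqs)
        third = [c[2] for c, n in counts.items() for _ in range(n)]
        gc3 = sum(1 for b in third if b in "GC") / len(third) if third else float("nan")
        usage: dict[str, dict[str, float]] = {}
        for aa, codons in _STANDARD.items():
            if aa == "*":
                continue
            tot = sum(counts.get(c, 0) for c in codons)
            if tot:
                usage[aa] = {c: counts.get(c, 0) / tot for c in codons}
        tables.append(CodonTable(eid, counts, gc3, egc, usage))
    if len(tables) < 3:
        return tables, float("nan")
    rho = stats.spearmanr([t.element_gc for t in tables],
                          [t.gc3 for t in tables]).statistic
    return tables, float(rho)


# ---------------------------------------------------------------------------
# gene length vs retrotransposon presence

def gene_length_comparison(orf_table: pd.DataFrame,
                           labels: list[str] | None = None) -> pd.DataFrame:
    """Compare conserved-gene lengths between Ngaro-containing and
    Ngaro-free elements.

    ``orf_table`` needs columns element_id, label, aa_length, has_ngaro.
    Returns one row per gene label with per-stratum n/median/IQR and a
    two-sided rank-sum p (NaN when a stratum is empty).
    """
    req = {"element_id", "label", "aa_length", "has_ngaro"}
    if not req.issubset(orf_table.columns):
        raise ValueError(f"orf_table must have columns {sorted(req)}")
    rows = []
    use = labels or sorted(orf_table["label"].dropna().unique())
    for label in use:
        sub = orf_table[orf_table["label"] == label]
        strata = {}
        for has, name in ((True, "with_ngaro"), (False, "without_ngaro")):
            vals = sub.loc[sub["has_ngaro"] == has, "aa_length"].to_numpy()
            strata[name] = vals
            rows_entry = {
                f"n_{name}": len(vals),
                f"median_{name}": float(np.median(vals)) if len(vals) else float("nan"),
                f"iqr_{name}": (float(np.percentile(vals, 75)
                                      - np.percentile(vals, 25))
                                if len(vals) else float("nan")),
            }
            strata[f"_{name}"] = rows_entry
        row = {"label": label}
        row.update(strata["_with_ngaro"])
        row.update(strata["_without_ngaro"])
        a, b = strata["with_ngaro"], strata["without_ngaro"]
        if len(a) and len(b):
            row["p_ranksum"] = float(stats.mannwhitneyu(
                a, b, alternative="two-sided").pvalue)
        else:
            row["p_ranksum"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
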