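"""Readers and writers for FASTA, GFF3 and SAM, plus the core containers.

Internal coordinates are 0-based half-open throughout the package; GFF3
output converts to 1-based inclusive on the way out and back on the way in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pysam
from Bio import SeqIO

__all__ = [
    "GenomeAssembly", "Feature", "AnnotationBundle",
    "read_fasta", "write_fasta", "read_gff3", "write_gff3",
    "write_sam", "read_sam",
]

IUPAC_NT = set("ACGTNRYSWKMBDHVU")


class FastaError(ValueError):
    pass


class Gff3Error(ValueError):
    pass


@dataclass
class GenomeAssembly:
    """Named contigs with upper-case sequence; the substrate of all scans."""

    contigs: dict[str, str] = field(default_factory=dict)
    name: str = "assembly"

    def __len__(self) -> int:
        return len(self.contigs)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def lengths(self) -> dict[str, int]:
        return {cid: len(s) for cid, s in self.contigs.items()}


def read_fasta(path: str | Path, name: str | None = None) -> GenomeAssembly:
    """Read a FASTA file into a :class:`GenomeAssembly`.

    Sequences are upper-cased; duplicate record ids and non-IUPAC characters
    are rejected with the offending id/position named.
    """
    path = Path(path)
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise FastaError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        for i, ch in enumerate(seq):
            if ch not in IUPAC_NT:
                raise FastaError(
                    f"non-IUPAC character {ch!r} at position {i} of record "
                    f"{rec.id!r} in {path}")
        contigs[rec.id] = seq
    if not contigs:
        raise FastaError(f"no FASTA records in {path}")
    return GenomeAssembly(contigs, name=name or path.stem)


def write_fasta(assembly: GenomeAssembly, path: str | Path, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for cid, seq in assembly.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")


# ---------------------------------------------------------------------------
# GFF3 feature forest

@dataclass
class Feature:
    """One annotated interval; ``children`` encodes GFF3 Parent nesting."""

    id: str
    type: str
    contig: str
    start: int      # 0-based
    end: int        # half-open
    strand: str = "."
    attrs: dict[str, str] = field(default_factory=dict)
    children: list["Feature"] = field(default_factory=list)

    def walk(self):
        yield self
        for ch in self.children:
            yield from ch.walk()

    def __eq__(self, other) -> bool:  # order-sensitive deep equality
        if not isinstance(other, Feature):
            return NotImplemented
        return (self.id, self.type, self.contig, self.start, self.end,
                self.strand, self.attrs, self.children) == \
               (other.id, other.type, other.contig, other.start, other.end,
                other.strand, other.attrs, other.children)


@dataclass
class AnnotationBundle:
    """Feature forests keyed by strain/assembly name."""

    strains: dict[str, list[Feature]] = field(default_factory=dict)

    def all_features(self, strain: str):
        for root in self.strains.get(strain, []):
            yield from root.walk()


def _validate_tree(root: Feature) -> None:
    for ch in root.children:
        if ch.contig != root.contig or ch.start < root.start or ch.end > root.end:
            raise Gff3Error(
                f"child feature {ch.id!r} [{ch.start},{ch.end}) extends past "
                f"parent {root.id!r} [{root.start},{root.end})")
        _validate_tree(ch)


def _esc(v: str) -> str:
    return str(v).replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_gff3(features: list[Feature], path: str | Path,
               validate: bool = True) -> None:
    """Write a feature forest as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]

    def emit(feat: Feature, parent: str | None) -> None:
        attrs = [f"ID={_esc(feat.id)}"]
        if parent is not None:
            attrs.append(f"Parent={_esc(parent)}")
        for k in sorted(feat.attrs):
            attrs.append(f"{_esc(k)}={_esc(feat.attrs[k])}")
        lines.append("\t".join([
            feat.contig, "emalekit", feat.type,
            str(feat.start + 1), str(feat.end), ".", feat.strand or ".", ".",
            ";".join(attrs)]))
        for ch in feat.children:
            emit(ch, feat.id)

    for root in features:
        if validate:
            _validate_tree(root)
        emit(root, None)
    Path(path).write_text("\n".join(lines) + "\n")


def _unesc(v: str) -> str:
    return v.replace("%3B", ";").replace("%3D", "=").replace("%2C", ",")


def read_gff3(path: str | Path) -> list[Feature]:
    """Read GFF3 back into a feature forest (inverse of :func:`write_gff3`)."""
    by_id: dict[str, Feature] = {}
    order: list[tuple[Feature, str | None]] = []
    for raw in Path(path).read_text().splitlines():
        if not raw or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) != 9:
            raise Gff3Error(f"malformed GFF3 line: {raw!r}")
        attrs: dict[str, str] = {}
        for pair in cols[8].split(";"):
            if pair:
                k, _, v = pair.partition("=")
                attrs[_unesc(k)] = _unesc(v)
        fid = attrs.pop("ID", None)
        parent = attrs.pop("Parent", None)
        if fid is None:
            raise Gff3Error(f"feature without ID: {raw!r}")
        feat = Feature(fid, cols[2], cols[0], int(cols[3]) - 1, int(cols[4]),
                       cols[6], attrs)
        by_id[fid] = feat
        order.append((feat, parent))
    roots: list[Feature] = []
    for feat, parent in order:
        if parent is None:
            roots.append(feat)
        else:
            if parent not in by_id:
                raise Gff3Error(f"dangling Parent {parent!r} for {feat.id!r}")
            by_id[parent].children.append(feat)
    for root in roots:
        _validate_tree(root)
    return roots


# ---------------------------------------------------------------------------
# SAM

def write_sam(records: list[tuple[str, str, str, int, str]],
              contig_lengths: dict[str, int], path: str | Path) -> None:
    """Write single-end alignments as SAM.

    ``records`` holds (read_id, sequence, contig, 0-based start, strand);
    the CIGAR is a full-length match (the read simulator introduces
    substitutions only).  A minimal @SQ header is emitted.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for cid, ln in contig_lengths.items():
            fh.write(f"@SQ\tSN:{cid}\tLN:{ln}\n")
        for rid, seq, contig, start, strand in records:
            flag = 16 if strand == "-" else 0
            out_seq = seq
            fh.write("\t".join([
                rid, str(flag), contig, str(start + 1), "60",
                f"{len(seq)}M", "*", "0", "0", out_seq, "*"]) + "\n")


def read_sam(path: str | Path):
    """Iterate mapped records of a SAM file (pysam AlignedSegments)."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            yield rec
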