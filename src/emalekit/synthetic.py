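"""Synthetic host genomes with planted virophage elements and retrotransposons.

The generator emulates the study system: high-GC (~70%) host contigs carrying
AT-richer integrated virophage elements (5.5-21.5 kb, 29-53% GC) flanked by
terminal inverted repeats (TIRs, 0.2-2.3 kb) and exact target site
duplications (TSDs, 1-9 bp), GC-rich ~6 kb Ngaro retrotransposon insertions
with split direct repeats (A1-[ORFs]-B1A2B2) nested inside elements or in
host DNA, partial elements truncated at contig ends, and long reads with
ground-truth placements.  Every planted feature is recorded in a
:class:`TruthSet` that downstream detection stages are benchmarked against.

The host background is i.i.d. base sampling with P(G)+P(C) = ``host_gc``
split evenly; there are no repeats beyond the planted ones, so detection
acceptance against the truth is unambiguous.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import templates as T
from ._util import (child_rng, mutate_substitutions, random_seq_exact_gc,
                    revcomp)
from .io import Feature, GenomeAssembly

__all__ = [
    "ElementSpec", "NgaroSpec", "ReadParams", "SimulationConfig",
    "TruthRecord", "TruthSet", "ReadSet",
    "generate_host_assembly", "plant_elements", "simulate_reads",
    "simulate", "default_config",
]


class PlantError(ValueError):
    pass


class SizingError(ValueError):
    pass


@dataclass
class ElementSpec:
    """One planted virophage element.

    ``length`` of None uses the template's natural size (2*tir + core).
    ``partial`` is None for a complete insertion, or "left"/"right" to plant
    a truncated element flush with the corresponding contig end (partial
    elements keep regenerated TIRs but have no TSD and no host flank on the
    truncated side).
    """

    type_id: int
    contig: int                 # index into contig list
    position: int               # host coordinate of the insertion point
    tir_length: int = 900
    tsd_length: int = 5
    length: int | None = None
    gc: float | None = None     # must stay within 0.03 of the template GC
    strand: str = "+"
    partial: str | None = None
    keep_frac: float = 0.6      # core fraction kept for partial elements
    mutation_rate: float = 0.02


@dataclass
class NgaroSpec:
    """One planted Ngaro retrotransposon.

    ``target`` is ("element", element_index, site) with site either
    ("intergenic", k) / ("genic", k) resolved against the element template,
    or ("host", contig_index, position).  ``solo`` plants only a detached
    A+B repeat pair (no ORFs).
    """

    type_id: int
    target: tuple
    orf1_truncated: bool = False
    solo: bool = False
    mutation_rate: float = 0.02


@dataclass
class ReadParams:
    length: int = 8000
    count: int = 10000
    substitution_rate: float = 0.0
    # "systematic": evenly spaced starts with a random phase (balanced
    # coverage, the default used for fraction accounting); "uniform": i.i.d.
    # start positions.
    sampling: str = "systematic"


@dataclass
class SimulationConfig:
    seed: int
    contig_lengths: list[int] = field(default_factory=lambda: [1_000_000] * 5)
    host_gc: float = 0.70
    element_specs: list[ElementSpec] = field(default_factory=list)
    ngaro_specs: list[NgaroSpec] = field(default_factory=list)
    read_params: ReadParams = field(default_factory=ReadParams)
    min_insert_gap: int = 5000   # minimum host gap between insertion points

    @property
    def n_contigs(self) -> int:
        return len(self.contig_lengths)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        def tuplify(v):
            return tuple(tuplify(x) for x in v) if isinstance(v, list) else v

        d = json.loads(text)
        d["element_specs"] = [ElementSpec(**e)
                              for e in d.get("element_specs", [])]
        d["ngaro_specs"] = [NgaroSpec(**{**n, "target": tuplify(n["target"])})
                            for n in d.get("ngaro_specs", [])]
        d["read_params"] = ReadParams(**d.get("read_params", {}))
        return cls(**d)


@dataclass
class TruthRecord:
    feature_id: str
    feature_class: str    # host|element|ngaro|tir|tsd|repeat_unit|orf|solo
    contig: str
    start: int            # 0-based half-open, final assembly coordinates
    end: int
    strand: str = "+"
    type_id: int | None = None
    parent_id: str | None = None
    attrs: dict = field(default_factory=dict)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class TruthSet:
    records: list[TruthRecord] = field(default_factory=list)

    def by_class(self, cls: str) -> list[TruthRecord]:
        return [r for r in self.records if r.feature_class == cls]

    def get(self, feature_id: str) -> TruthRecord:
        for r in self.records:
            if r.feature_id == feature_id:
                return r
        raise KeyError(feature_id)

    def children(self, parent_id: str) -> list[TruthRecord]:
        return [r for r in self.records if r.parent_id == parent_id]

    def class_base_counts(self, assembly: GenomeAssembly) -> dict[str, int]:
        """host/element/ngaro base totals; nested ngaro bases count as ngaro."""
        labels = self.class_label_arrays(assembly)
        counts = {"host": 0, "element": 0, "ngaro": 0}
        for arr in labels.values():
            counts["host"] += int((arr == 0).sum())
            counts["element"] += int((arr == 1).sum())
            counts["ngaro"] += int((arr == 2).sum())
        return counts

    def class_label_arrays(self, assembly: GenomeAssembly) -> dict[str, np.ndarray]:
        """Per-contig label arrays: 0=host, 1=element, 2=ngaro."""
        labels = {cid: np.zeros(len(seq), dtype=np.uint8)
                  for cid, seq in assembly.contigs.items()}
        for r in self.by_class("element"):
            labels[r.contig][r.start:r.end] = 1
        for r in self.by_class("ngaro"):
            labels[r.contig][r.start:r.end] = 2
        return labels

    def to_features(self) -> list[Feature]:
        """Truth records as a GFF3-ready feature forest."""
        feats: dict[str, Feature] = {}
        roots: list[Feature] = []
        gff_type = {"host": "region", "element": "mobile_genetic_element",
                    "ngaro": "mobile_genetic_element", "tir": "inverted_repeat",
                    "tsd": "direct_repeat", "repeat_unit": "repeat_unit",
                    "orf": "ORF", "solo": "direct_repeat"}
        for r in self.records:
            attrs = {k: str(v) for k, v in r.attrs.items()}
            attrs["feature_class"] = r.feature_class
            if r.type_id is not None:
                attrs["type_id"] = str(r.type_id)
            f = Feature(r.feature_id, gff_type[r.feature_class], r.contig,
                        r.start, r.end, r.strand, attrs)
            feats[r.feature_id] = f
            # TSDs flank (rather than nest inside) their element, so they are
            # emitted as siblings carrying an element=<id> attribute.
            parent = r.parent_id
            if parent is not None and r.feature_class != "tsd":
                feats[parent].children.append(f)
            else:
                if parent is not None:
                    f.attrs["element"] = parent
                roots.append(f)
        return roots

    def to_tsv(self) -> str:
        lines = ["feature_id\tfeature_class\tcontig\tstart\tend\tstrand"
                 "\ttype_id\tparent_id"]
        for r in self.records:
            lines.append("\t".join([
                r.feature_id, r.feature_class, r.contig, str(r.start),
                str(r.end), r.strand,
                "" if r.type_id is None else str(r.type_id),
                r.parent_id or ""]))
        return "\n".join(lines) + "\n"


@dataclass
class ReadSet:
    reads: list[tuple[str, str]]                       # (read_id, sequence)
    truth_placements: list[tuple[str, str, int, str]]  # (id, contig, start, strand)
    skipped: int = 0

    def sam_records(self, assembly: GenomeAssembly):
        """(read_id, reference-oriented sequence, contig, start, strand)."""
        seqs = dict(self.reads)
        for rid, contig, start, strand in self.truth_placements:
            seq = seqs[rid]
            if strand == "-":
                seq = revcomp(seq)
            yield (rid, seq, contig, start, strand)


# ---------------------------------------------------------------------------
# host background

def generate_host_assembly(config: SimulationConfig
                           ) -> tuple[GenomeAssembly, TruthSet]:
    """Generate i.i.d. host contigs at the configured GC.

    Realized per-contig GC equals ``round(host_gc * L)/L`` by construction
    (exact-count base sampling).  Output is identical for identical config
    and seed.
    """
    largest = 0
    for spec in config.element_specs:
        tmpl = T.element_templates()[spec.type_id]
        natural = 2 * spec.tir_length + len(tmpl.core)
        largest = max(largest, spec.length or natural)
    for cl in config.contig_lengths:
        if largest and cl < 2 * largest:
            raise SizingError(
                f"contig length {cl} is smaller than twice the largest "
                f"planted feature ({largest} bp)")
    contigs: dict[str, str] = {}
    truth = TruthSet()
    for i, cl in enumerate(config.contig_lengths):
        rng = child_rng(config.seed, 10, i)
        cid = f"ctg{i + 1:02d}"
        contigs[cid] = random_seq_exact_gc(rng, cl, config.host_gc)
        truth.records.append(TruthRecord(f"host_{cid}", "host", cid, 0, cl))
    return GenomeAssembly(contigs, name="synthetic"), truth


# ---------------------------------------------------------------------------
# element / ngaro assembly

def _resolve_ngaro_offset(template: T.ElementTemplate, core_len: int,
                          site: tuple) -> int:
    """Map an ("intergenic"|"genic", k) site onto a core offset."""
    kind, k = site
    genes = [g for g in template.genes if g.end <= core_len]
    if kind == "genic":
        g = genes[k % len(genes)]
        return (g.start + g.end) // 2
    # intergenic: midpoint of the spacer following gene k
    g = genes[k % len(genes)]
    nxt = [h for h in genes if h.start >= g.end]
    hi = nxt[0].start if nxt else core_len
    return (g.end + hi) // 2


def _ngaro_sequence(spec: NgaroSpec, rng: np.random.Generator) -> tuple[str, dict]:
    tmpl = T.ngaro_templates()[spec.type_id]
    if spec.solo:
        seq = tmpl.repeat_a + tmpl.repeat_b
        seq = mutate_substitutions(rng, seq, spec.mutation_rate)
        return seq, {"solo": True, "repeats": [(0, len(tmpl.repeat_a)),
                                               (len(tmpl.repeat_a), len(seq))]}
    seq = T.ngaro_orf1_deleted(tmpl) if spec.orf1_truncated else tmpl.sequence
    la, lb = len(tmpl.repeat_a), len(tmpl.repeat_b)
    n = len(seq)
    meta = {
        "solo": False,
        "repeats": [(0, la),                        # A1
                    (n - la - 2 * lb, n - la - lb),  # B1
                    (n - la - lb, n - lb),           # A2
                    (n - lb, n)],                    # B2
    }
    return mutate_substitutions(rng, seq, spec.mutation_rate), meta


@dataclass
class _Insertion:
    position: int            # host coordinate (pre-insertion)
    sequence: str
    tsd: int
    kind: str                # element|ngaro|solo
    meta: dict


def _build_element(spec: ElementSpec, idx: int,
                   ngaros: list[tuple[int, NgaroSpec]],
                   rng: np.random.Generator) -> tuple[str, dict]:
    """Assemble one element; returns (sequence, metadata with rel coords)."""
    tmpl = T.element_templates()[spec.type_id]
    if spec.gc is not None and abs(spec.gc - tmpl.gc) > 0.03:
        raise PlantError(
            f"element {idx}: requested GC {spec.gc:.2f} departs from the "
            f"type {spec.type_id} template GC {tmpl.gc:.2f}")
    core = tmpl.core
    if spec.length is not None:
        core_len = spec.length - 2 * spec.tir_length
        if core_len < 500:
            raise SizingError(f"element {idx}: length {spec.length} leaves "
                              f"<500 bp of core at tir={spec.tir_length}")
        if core_len < len(core):
            core = core[:core_len]
        elif core_len > len(core):
            core = core + random_seq_exact_gc(rng, core_len - len(core), tmpl.gc)
    if spec.partial:
        keep = max(500, int(len(core) * spec.keep_frac))
        core = core[:keep] if spec.partial == "right" else core[-keep:]
    core = mutate_substitutions(rng, core, spec.mutation_rate)
    genes = [g for g in tmpl.genes if g.end <= len(core)] if spec.partial != "left" \
        else [g for g in tmpl.genes]  # re-map below for left truncation
    if spec.partial == "left":
        shift = len(tmpl.core) - len(core)
        genes = [T.TemplateGene(g.label, g.start - shift, g.end - shift, g.peptide)
                 for g in tmpl.genes if g.start >= shift]

    # nested retrotransposons, inserted at descending core offsets
    ngaro_meta: list[dict] = []
    resolved = []
    for n_idx, nspec in ngaros:
        kind = nspec.target[2] if len(nspec.target) > 2 else ("intergenic", 0)
        off = kind if isinstance(kind, int) else \
            _resolve_ngaro_offset(tmpl, len(core), kind)
        resolved.append((off, n_idx, nspec))
    for off, n_idx, nspec in sorted(resolved, reverse=True):
        nseq, nmeta = _ngaro_sequence(nspec, child_rng(rng.integers(2**31), 0))
        disrupted = [g.label for g in genes if g.start < off < g.end]
        core = core[:off] + nseq + core[off:]
        genes = [g if g.end <= off else
                 T.TemplateGene(g.label, g.start + len(nseq), g.end + len(nseq),
                                g.peptide) if g.start >= off else None
                 for g in genes]
        genes = [g for g in genes if g is not None]
        for m in ngaro_meta:   # shift previously placed (higher-offset) ngaros
            m["span"] = (m["span"][0] + len(nseq), m["span"][1] + len(nseq))
            m["repeats"] = [(a + len(nseq), b + len(nseq))
                            for a, b in m["repeats"]]
        ngaro_meta.append({"index": n_idx, "spec": nspec,
                           "span": (off, off + len(nseq)),
                           "repeats": [(a + off, b + off)
                                       for a, b in nmeta["repeats"]],
                           "disrupted": disrupted})

    tir = mutate_substitutions(rng, tmpl.tir_source[:spec.tir_length],
                               spec.mutation_rate)
    seq = tir + core + revcomp(tir)
    off0 = len(tir)
    gene_rel = [(g.label, g.start + off0, g.end + off0, "+") for g in genes]
    tir_rel = [(0, len(tir)), (len(seq) - len(tir), len(seq))]
    for m in ngaro_meta:
        m["span"] = (m["span"][0] + off0, m["span"][1] + off0)
        m["repeats"] = [(a + off0, b + off0) for a, b in m["repeats"]]

    if spec.strand == "-":
        n = len(seq)
        seq = revcomp(seq)
        gene_rel = [(lb, n - e, n - s, "-") for lb, s, e, _ in gene_rel]
        tir_rel = [(n - e, n - s) for s, e in reversed(tir_rel)]
        for m in ngaro_meta:
            s, e = m["span"]
            m["span"] = (n - e, n - s)
            m["repeats"] = [(n - b, n - a) for a, b in reversed(m["repeats"])]
            m["strand"] = "-"
    meta = {"index": idx, "spec": spec, "genes": gene_rel, "tirs": tir_rel,
            "ngaros": ngaro_meta}
    return seq, meta


def _longest_junction_match(left: str, right: str, max_len: int) -> int:
    lim = min(max_len, len(left), len(right))
    for L in range(lim, 0, -1):
        if left[-L:] == right[:L]:
            return L
    return 0


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _valid_tsd_site(host: str, p: int, k: int, max_ext: int = 40) -> bool:
    """True when duplicating host[p-k:p] yields a clean junction.

    Two conditions keep the planted truth unambiguous: the longest exact
    junction match must equal k (so the TSD is well defined), and outward
    extension of a terminal-repeat alignment across the junction must never
    reach a positive score under match +1 / mismatch -2 (so chance flank
    matches cannot shift the delimited element boundary).
    """
    if p - k - max_ext - 1 < 0 or p + max_ext + 1 > len(host):
        return False
    left = host[:p]
    right = host[p - k:p] + host[p:]
    if _longest_junction_match(left, right, 15) != k:
        return False
    score = 0
    for i in range(1, max_ext):
        score += 1 if left[-i] == _COMP[right[i - 1]] else -2
        if score > 0:
            return False
    return True


def plant_elements(assembly: GenomeAssembly, config: SimulationConfig
                   ) -> tuple[GenomeAssembly, TruthSet]:
    """Plant all configured elements and retrotransposons; return the new
    assembly and the full truth annotation.

    Each complete element is inserted as TSD-left + TIR + core + inverted
    TIR + TSD-right, the TSD being an exact duplication of the insertion
    site suffix.  Insertion points are nudged deterministically (in 7 bp
    steps) until the junction's longest exact match equals the requested
    TSD length, so the truth TSD is well defined.  Partial elements are
    placed flush with a contig end.  Ngaro specs targeting an element are
    nested inside it; host-targeted ngaros and solo A+B repeat pairs are
    inserted directly into host DNA (no TSD).
    """
    cids = list(assembly.contigs)
    by_element: dict[int, list[tuple[int, NgaroSpec]]] = {}
    host_ngaros: list[tuple[int, NgaroSpec]] = []
    for n_idx, nspec in enumerate(config.ngaro_specs):
        if nspec.target[0] == "element":
            by_element.setdefault(nspec.target[1], []).append((n_idx, nspec))
        else:
            host_ngaros.append((n_idx, nspec))

    inserts: dict[int, list[_Insertion]] = {i: [] for i in range(len(cids))}
    for e_idx, espec in enumerate(config.element_specs):
        rng = child_rng(config.seed, 20, e_idx)
        seq, meta = _build_element(espec, e_idx, by_element.get(e_idx, []), rng)
        host = assembly.contigs[cids[espec.contig]]
        if espec.partial:
            pos = 0 if espec.partial == "left" else len(host)
            inserts[espec.contig].append(
                _Insertion(pos, seq, 0, "element", meta))
            continue
        p, k = espec.position, espec.tsd_length
        for attempt in range(400):
            if _valid_tsd_site(host, p, k):
                break
            p += 7
        else:
            raise PlantError(f"element {e_idx}: no valid TSD site near "
                             f"{espec.position}")
        inserts[espec.contig].append(_Insertion(p, seq, k, "element", meta))

    for n_idx, nspec in host_ngaros:
        rng = child_rng(config.seed, 30, n_idx)
        seq, nmeta = _ngaro_sequence(nspec, rng)
        _, contig_i, pos = nspec.target
        kind = "solo" if nspec.solo else "ngaro"
        inserts[contig_i].append(_Insertion(
            pos, seq, 0, kind,
            {"index": n_idx, "spec": nspec, **nmeta}))

    # overlap validation in host coordinates
    for ci, ins in inserts.items():
        ins.sort(key=lambda x: x.position)
        for a, b in zip(ins, ins[1:]):
            if b.position - a.position < config.min_insert_gap:
                raise PlantError(
                    f"plant targets overlap on {cids[ci]}: "
                    f"{a.kind}@{a.position} and {b.kind}@{b.position} "
                    f"(closer than {config.min_insert_gap} bp)")

    truth = TruthSet()
    new_contigs: dict[str, str] = {}
    for ci, cid in enumerate(cids):
        host = assembly.contigs[cid]
        truth_host_len = 0
        parts: list[str] = []
        cursor = 0
        shift = 0
        for ins in inserts[ci]:
            parts.append(host[cursor:ins.position])
            start = ins.position + shift
            dup = host[ins.position - ins.tsd:ins.position] if ins.tsd else ""
            parts.append(ins.sequence)
            parts.append(dup)
            _emit_truth(truth, cid, start, ins)
            shift += len(ins.sequence) + len(dup)
            cursor = ins.position
        parts.append(host[cursor:])
        new_contigs[cid] = "".join(parts)
        truth.records.append(TruthRecord(f"host_{cid}", "host", cid, 0,
                                         len(new_contigs[cid])))
    out = GenomeAssembly(new_contigs, name=assembly.name)
    # stable record order: host records last -> put them first instead
    truth.records.sort(key=lambda r: (r.feature_class != "host", r.contig,
                                      r.start))
    return out, truth


def _emit_truth(truth: TruthSet, cid: str, start: int, ins: _Insertion) -> None:
    m = ins.meta
    if ins.kind == "element":
        spec: ElementSpec = m["spec"]
        eid = f"E{m['index'] + 1:02d}"
        end = start + len(ins.sequence)
        truth.records.append(TruthRecord(
            eid, "element", cid, start, end, spec.strand, spec.type_id,
            attrs={"completeness": "partial" if spec.partial else "complete",
                   "tir_length": spec.tir_length,
                   "tsd_length": 0 if spec.partial else spec.tsd_length}))
        for j, (s, e) in enumerate(m["tirs"]):
            truth.records.append(TruthRecord(
                f"{eid}_tir{j + 1}", "tir", cid, start + s, start + e,
                spec.strand, parent_id=eid))
        if ins.tsd:
            truth.records.append(TruthRecord(
                f"{eid}_tsd1", "tsd", cid, start - ins.tsd, start, "+",
                parent_id=eid))
            truth.records.append(TruthRecord(
                f"{eid}_tsd2", "tsd", cid, end, end + ins.tsd, "+",
                parent_id=eid))
        for label, s, e, strand in m["genes"]:
            truth.records.append(TruthRecord(
                f"{eid}_{label}", "orf", cid, start + s, start + e, strand,
                parent_id=eid, attrs={"label": label}))
        for nm in m["ngaros"]:
            _emit_ngaro_truth(truth, cid, start, nm, parent=eid)
    elif ins.kind == "ngaro":
        _emit_ngaro_truth(truth, cid, start,
                          {**m, "span": (0, len(ins.sequence)),
                           "repeats": m["repeats"]}, parent=None)
    else:  # solo repeat pair
        nid = f"S{m['index'] + 1:02d}"
        truth.records.append(TruthRecord(
            nid, "solo", cid, start, start + len(ins.sequence), "+",
            m["spec"].type_id))
        for j, (a, b) in enumerate(m["repeats"]):
            truth.records.append(TruthRecord(
                f"{nid}_rep{j + 1}", "repeat_unit", cid, start + a, start + b,
                "+", parent_id=nid))


def _emit_ngaro_truth(truth: TruthSet, cid: str, base: int, nm: dict,
                      parent: str | None) -> None:
    nspec: NgaroSpec = nm["spec"]
    nid = f"N{nm['index'] + 1:02d}"
    s, e = nm["span"]
    truth.records.append(TruthRecord(
        nid, "ngaro", cid, base + s, base + e, nm.get("strand", "+"),
        nspec.type_id, parent_id=parent,
        attrs={"variant": "orf1_truncated" if nspec.orf1_truncated else "full",
               "container": "element" if parent else "host",
               **({"disrupted": ",".join(nm["disrupted"])}
                  if nm.get("disrupted") else {})}))
    for j, (a, b) in enumerate(nm["repeats"]):
        truth.records.append(TruthRecord(
            f"{nid}_rep{j + 1}", "repeat_unit", cid, base + a, base + b,
            nm.get("strand", "+"), parent_id=nid))


# ---------------------------------------------------------------------------
# long reads

def simulate_reads(assembly: GenomeAssembly, config: SimulationConfig
                   ) -> ReadSet:
    """Simulate single-end long reads with truth placements.

    Systematic sampling (default) spaces read starts evenly over the genome
    with a random phase, which gives balanced per-base coverage; "uniform"
    draws i.i.d. start positions.  Starts are drawn over the extended range
    [-(L_read-1), L_contig) and clipped, so per-base coverage is uniform in
    expectation including contig ends.  Substitution errors only.
    """
    rp = config.read_params
    rng = child_rng(config.seed, 40)
    cids, lens, usable = [], [], []
    skipped = 0
    for cid, seq in assembly.contigs.items():
        if rp.length > len(seq):
            warnings.warn(f"read length {rp.length} exceeds contig {cid} "
                          f"({len(seq)} bp); contig skipped")
            skipped += 1
            continue
        cids.append(cid)
        lens.append(len(seq))
        usable.append(len(seq) + rp.length - 1)
    if not cids:
        return ReadSet([], [], skipped=rp.count)
    total = sum(usable)
    offsets = np.concatenate([[0], np.cumsum(usable)])
    if rp.sampling == "systematic":
        stride = total / rp.count
        phase = rng.random() * stride
        gpos = (phase + stride * np.arange(rp.count)).astype(np.int64)
    else:
        gpos = rng.integers(0, total, size=rp.count)
        gpos.sort()
    strands = rng.random(rp.count) < 0.5
    reads, placements = [], []
    for i, g in enumerate(gpos):
        ci = int(np.searchsorted(offsets, g, side="right")) - 1
        start = int(g - offsets[ci]) - (rp.length - 1)
        s, e = max(0, start), min(lens[ci], start + rp.length)
        if e - s < 1:
            continue
        frag = assembly.contigs[cids[ci]][s:e]
        strand = "-" if strands[i] else "+"
        seq = revcomp(frag) if strand == "-" else frag
        seq = mutate_substitutions(rng, seq, rp.substitution_rate)
        rid = f"read{i + 1:06d}"
        reads.append((rid, seq))
        placements.append((rid, cids[ci], s, strand))
    return ReadSet(reads, placements, skipped=skipped)


# ---------------------------------------------------------------------------
# end-to-end convenience + default study conditions

def simulate(config: SimulationConfig
             ) -> tuple[GenomeAssembly, TruthSet, ReadSet]:
    host, _ = generate_host_assembly(config)
    assembly, truth = plant_elements(host, config)
    reads = simulate_reads(assembly, config)
    return assembly, truth, reads


def default_config(seed: int) -> SimulationConfig:
    """The default study conditions: 5 x 1 Mb contigs at 70% GC with 15
    planted elements (all 8 types, TIRs 0.2-2.3 kb, TSDs 1-9 bp, 3 partial
    at contig ends), 6 Ngaros (4 types, 2 ORF1-truncated, 4 nested inside
    elements), one solo A+B repeat pair, and 10,000 x 8 kb error-free reads.
    """
    elements = [
        # contig, position, type, tir, tsd, strand
        ElementSpec(1, 0, 150_000, tir_length=900, tsd_length=5),
        ElementSpec(2, 0, 450_000, tir_length=200, tsd_length=3),
        ElementSpec(3, 1, 150_000, tir_length=1500, tsd_length=1),
        ElementSpec(4, 1, 450_000, tir_length=700, tsd_length=9),
        ElementSpec(5, 1, 750_000, tir_length=2300, tsd_length=4, strand="-"),
        ElementSpec(6, 2, 150_000, tir_length=400, tsd_length=5),
        ElementSpec(7, 2, 450_000, tir_length=1100, tsd_length=3),
        ElementSpec(8, 3, 150_000, tir_length=450, tsd_length=2, strand="-"),
        ElementSpec(1, 3, 450_000, tir_length=600, tsd_length=6),
        ElementSpec(3, 3, 750_000, tir_length=800, tsd_length=5, strand="-"),
        ElementSpec(4, 4, 150_000, tir_length=1000, tsd_length=4),
        ElementSpec(6, 4, 450_000, tir_length=900, tsd_length=3),
        ElementSpec(1, 0, 0, tir_length=500, partial="right"),
        ElementSpec(5, 2, 0, tir_length=700, partial="right"),
        ElementSpec(4, 4, 0, tir_length=900, partial="left"),
    ]
    ngaros = [
        NgaroSpec(1, ("element", 0, ("intergenic", 4))),
        NgaroSpec(2, ("element", 2, ("intergenic", 5))),
        NgaroSpec(3, ("element", 4, ("intergenic", 3))),
        NgaroSpec(4, ("element", 10, ("genic", 8))),
        NgaroSpec(1, ("host", 1, 900_000), orf1_truncated=True),
        NgaroSpec(2, ("host", 3, 900_000), orf1_truncated=True),
    ]
    solo = [NgaroSpec(1, ("host", 2, 900_000), solo=True)]
    return SimulationConfig(seed=seed, element_specs=elements,
                            ngaro_specs=ngaros + solo)
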