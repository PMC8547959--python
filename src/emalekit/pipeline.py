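"""End-to-end driver: GC screen -> homology confirmation -> delimitation ->
typing -> retrotransposon analysis -> cross-strain loci -> quantification.

The detection rule mirrors the combined screen used for real assemblies: a
candidate must pass the GC screen AND contain at least one ORF whose best
hit against the reference virophage proteome reaches the bitscore cutoff
(the two screens are redundant on clear elements; their intersection keeps
precision high).  All stage parameters live in :class:`PipelineConfig` and
are recorded in the run manifest, so a run is reproducible byte-for-byte
from config + seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import templates as T
from ._util import gc_fraction, interval_overlap
from .boundaries import (ElementRecord, cross_strain_locus_search,
                         delimit_element, find_tsd)
from .dotplot import (GC_GROUP_CUTOFF, LINKAGE_THRESHOLD, TypeClusters,
                      assign_gc_group, cluster_elements, wordmatch_dotplot)
from .gc_profile import (CandidateSegment, call_low_gc_segments,
                         compute_gc_profile)
from .io import Feature, GenomeAssembly, write_gff3
from .ngaro import (InsertionSiteStats, NgaroRecord,
                    classify_insertion_site, classify_ngaro,
                    detect_high_gc_insertions, detect_split_direct_repeats,
                    excise, find_ngaro_candidates, integration_bias_test)
from .orfs import (annotate_orfs, assign_type_by_cumulative_bitscore,
                   find_orfs_six_frame, gene_span)
from .quantify import (assembly_fractions, build_label_arrays,
                       codon_usage_profile, fraction_deviation,
                       gene_length_comparison, read_fractions)

log = logging.getLogger("emalekit")

__all__ = ["PipelineConfig", "PipelineResult", "StrainResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the package defaults."""

    seed: int = 0
    gc_window: int = 500
    gc_step: int = 100
    gc_delta: float = 0.15
    gc_min_len: int = 2000
    gc_merge_gap: int = 1000
    min_orf_aa: int = 50
    min_hit_bitscore: float = 50.0
    tsd_max_len: int = 15
    word_length: int = 10
    linkage_threshold: float = LINKAGE_THRESHOLD
    gc_group_cutoff: float = GC_GROUP_CUTOFF
    ngaro_delta: float = 0.10
    ngaro_min_len: int = 2000
    ngaro_max_len: int = 12000
    locus_flank: int = 10_000
    join_gap_cover: float = 0.6   # fraction of an inter-segment gap that must
    #                               look retrotransposon-like to join segments

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


@dataclass
class StrainResult:
    strain: str
    elements: list[ElementRecord] = field(default_factory=list)
    ngaros: list[NgaroRecord] = field(default_factory=list)
    solos: list[NgaroRecord] = field(default_factory=list)
    clusters: TypeClusters | None = None
    fractions_assembly: object = None
    fractions_reads: object = None
    deviation_pp: dict[str, float] | None = None
    site_stats: InsertionSiteStats | None = None
    codon_rho: float = float("nan")
    gene_lengths: pd.DataFrame | None = None
    loci: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for el in self.elements:
            rows.append({"strain": self.strain, "element": el.element_id,
                         "contig": el.contig, "start": el.start,
                         "end": el.end, "length": el.length,
                         "type": el.type_assignment,
                         "gc": round(el.gc, 4), "gc_group": el.gc_group,
                         "completeness": el.completeness,
                         "tir_length": el.tir.length if el.tir else 0,
                         "tsd": el.tsd.sequence if el.tsd else "",
                         "n_ngaro": len(el.nested_ngaro_ids)})
        return pd.DataFrame(rows)

    def counts_by_type(self) -> pd.DataFrame:
        df = self.summary()
        if df.empty:
            return df
        return (df.groupby(["type", "completeness"]).size()
                  .rename("count").reset_index())


@dataclass
class PipelineResult:
    config: PipelineConfig
    strains: dict[str, StrainResult] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        frames = [s.summary() for s in self.strains.values()]
        frames = [f for f in frames if not f.empty]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def _candidate_segments(assembly: GenomeAssembly, cfg: PipelineConfig
                        ) -> list[CandidateSegment]:
    profiles = {cid: compute_gc_profile(seq, cfg.gc_window, cfg.gc_step, cid)
                for cid, seq in assembly.contigs.items()}
    allvals = np.concatenate([p.values for p in profiles.values()
                              if p.values.size])
    baseline = float(np.nanmedian(allvals)) if allvals.size else float("nan")
    segments = []
    for cid, prof in profiles.items():
        segments.extend(call_low_gc_segments(
            prof, assembly.contigs[cid], baseline=baseline,
            delta=cfg.gc_delta, min_len=cfg.gc_min_len,
            merge_gap=cfg.gc_merge_gap))
    return segments


def _join_interrupted(segments: list[CandidateSegment],
                      scan_hits: list[tuple[str, int, int]],
                      cfg: PipelineConfig) -> list[CandidateSegment]:
    """Join candidate segments whose separating gap is retrotransposon-like
    (a GC-rich Ngaro splits the low-GC run of an interrupted element)."""
    out: list[CandidateSegment] = []
    by_contig: dict[str, list[CandidateSegment]] = {}
    for seg in segments:
        by_contig.setdefault(seg.contig, []).append(seg)
    for cid in sorted(by_contig):
        segs = sorted(by_contig[cid], key=lambda s: s.start)
        cur = segs[0]
        for nxt in segs[1:]:
            gap = (cur.end, nxt.start)
            gap_len = gap[1] - gap[0]
            cover = sum(interval_overlap(gap, (s, e))
                        for c, s, e in scan_hits if c == cid)
            if 0 < gap_len <= cfg.ngaro_max_len \
                    and cover >= cfg.join_gap_cover * gap_len:
                cur = CandidateSegment(
                    cid, cur.start, nxt.end,
                    (cur.mean_gc * cur.length + nxt.mean_gc * nxt.length)
                    / (cur.length + nxt.length),
                    cur.host_baseline_gc,
                    cur.at_contig_end or nxt.at_contig_end)
            else:
                out.append(cur)
                cur = nxt
        out.append(cur)
    return out


def _analyze_strain(strain: str, assembly: GenomeAssembly,
                    cfg: PipelineConfig, reference_proteome: dict[str, str],
                    ngaro_db: dict[int, dict], sam_path=None) -> StrainResult:
    res = StrainResult(strain)
    t0 = time.perf_counter()
    segments = _candidate_segments(assembly, cfg)
    scan_hits = find_ngaro_candidates(
        assembly, {tid: db["sequence"] for tid, db in ngaro_db.items()})
    segments = _join_interrupted(segments, scan_hits, cfg)
    log.info("stage=gc_screen strain=%s segments=%d ngaro_scan_hits=%d "
             "elapsed=%.1fs", strain, len(segments), len(scan_hits),
             time.perf_counter() - t0)

    # homology confirmation + delimitation
    elements: list[ElementRecord] = []
    for i, seg in enumerate(sorted(segments, key=lambda s: (s.contig,
                                                            s.start))):
        seq = assembly.contigs[seg.contig]
        lo, hi = max(0, seg.start - 500), min(len(seq), seg.end + 500)
        orfs = find_orfs_six_frame(seq[lo:hi], min_aa=cfg.min_orf_aa,
                                   contig=seg.contig)
        for o in orfs:
            o.start += lo
            o.end += lo
        annotate_orfs(orfs, reference_proteome,
                      min_bitscore=cfg.min_hit_bitscore)
        if not any(o.hit for o in orfs):
            continue
        el = delimit_element(seg, assembly,
                             element_id=f"{strain}_E{len(elements) + 1:03d}",
                             orfs=orfs)
        if el.completeness == "complete":
            el.tsd = find_tsd(assembly, el, max_len=cfg.tsd_max_len)
        elements.append(el)
    log.info("stage=delimit strain=%s elements=%d", strain, len(elements))

    # retrotransposon insertions: union of the genome-wide template scan and
    # the within-element GC caller
    ngaro_intervals: list[tuple[str, int, int, str | None]] = []
    claimed: set[tuple[str, int, int]] = set()
    for el in elements:
        eseq = assembly.contigs[el.contig][el.start:el.end]
        tirs = []
        if el.tir:
            tirs = [(el.tir.left_start - el.start, el.tir.left_end - el.start),
                    (el.tir.right_start - el.start, el.tir.right_end - el.start)]
        rel_hits = detect_high_gc_insertions(
            eseq, delta=cfg.ngaro_delta, min_len=cfg.ngaro_min_len,
            max_len=cfg.ngaro_max_len, exclude=tirs)
        abs_hits = [(el.start + s, el.start + e) for s, e in rel_hits]
        for c, s, e in scan_hits:
            if c == el.contig and interval_overlap((s, e), el.interval) > 0:
                # the template scan delimits the insertion more precisely
                # than the GC caller; drop any GC fragment it overlaps
                abs_hits = [h for h in abs_hits
                            if interval_overlap(h, (s, e)) == 0]
                abs_hits.append((s, e))
                claimed.add((c, s, e))
        for s, e in sorted(set(abs_hits)):
            ngaro_intervals.append((el.contig, s, e, el.element_id))
    for c, s, e in scan_hits:
        if (c, s, e) not in claimed:
            ngaro_intervals.append((c, s, e, None))

    known_repeats = [(db["repeat_a"], db["repeat_b"])
                     for db in ngaro_db.values()]
    el_by_id = {el.element_id: el for el in elements}
    for c, s, e, container in sorted(ngaro_intervals):
        seq = assembly.contigs[c][s:e]
        if len(seq) < 500:
            continue
        structure = detect_split_direct_repeats(seq,
                                                known_repeats=known_repeats)
        if structure is not None and structure.solo:
            rec = NgaroRecord(f"{strain}_S{len(res.solos) + 1:03d}", c, s, e,
                              container="element" if container else "host",
                              container_element_id=container,
                              structure=structure, solo=True,
                              gc=gc_fraction(seq))
            res.solos.append(rec)
            continue
        if structure is None and len(seq) < 1500:
            continue
        tid, variant = classify_ngaro(seq, ngaro_db)
        if tid == "unassigned" and structure is None:
            continue
        rec = NgaroRecord(f"{strain}_N{len(res.ngaros) + 1:03d}", c, s, e,
                          container="element" if container else "host",
                          container_element_id=container, type_id=tid,
                          variant=variant, structure=structure,
                          gc=gc_fraction(seq))
        res.ngaros.append(rec)
        if container:
            el_by_id[container].nested_ngaro_ids.append(rec.ngaro_id)
    log.info("stage=ngaro strain=%s ngaros=%d solos=%d", strain,
             len(res.ngaros), len(res.solos))

    # element GC and typing on retrotransposon-excised sequence
    excised_seqs: dict[str, str] = {}
    for el in elements:
        eseq = assembly.contigs[el.contig][el.start:el.end]
        nested = [(n.start - el.start, n.end - el.start)
                  for n in res.ngaros if n.container_element_id == el.element_id]
        eseq_x = excise(eseq, nested)
        excised_seqs[el.element_id] = eseq_x
        el.gc = gc_fraction(eseq_x)
        el.gc_group = assign_gc_group(el.gc)

    complete = {el.element_id: excised_seqs[el.element_id]
                for el in elements if el.completeness == "complete"}
    type_db: dict[int, dict[str, str]] = {}
    if complete:
        matrix = wordmatch_dotplot(complete, word=cfg.word_length)
        res.clusters = cluster_elements(
            matrix, complete, threshold=cfg.linkage_threshold,
            gc={eid: el_by_id[eid].gc for eid in complete})
        for el in elements:
            if el.element_id in res.clusters.labels:
                el.type_assignment = res.clusters.labels[el.element_id]
        for tid, species_id in res.clusters.type_species.items():
            type_db[tid] = {o.label or o.orf_id: o.peptide
                            for o in el_by_id[species_id].orfs}
    for el in elements:
        if el.completeness == "partial" and type_db:
            assignment = assign_type_by_cumulative_bitscore(
                excised_seqs[el.element_id], type_db,
                element_id=el.element_id, min_aa=cfg.min_orf_aa)
            el.type_assignment = assignment.assigned
    res.elements = elements

    # integration-site statistics over element-contained insertions.  Sites
    # are classified on the excised element, with gene intervals taken from
    # alignment-trimmed labeled ORFs, so neither the retrotransposon's own
    # ORFs nor stop-to-stop overhang across the junction misclassify a site.
    in_element = [n for n in res.ngaros if n.container == "element"]
    if in_element:
        exc_annot: dict[str, tuple[list, list]] = {}
        class_bases = {"intergenic": 0, "genic": 0, "tir": 0}
        for el in elements:
            exc = excised_seqs[el.element_id]
            orfs_x = find_orfs_six_frame(exc, min_aa=cfg.min_orf_aa)
            annotate_orfs(orfs_x, reference_proteome,
                          min_bitscore=cfg.min_hit_bitscore)
            gene_iv = [gene_span(o) for o in orfs_x if o.hit]
            tir_iv = []
            if el.tir:
                tl = el.tir.length
                tir_iv = [(0, tl), (len(exc) - tl, len(exc))]
            exc_annot[el.element_id] = (gene_iv, tir_iv)
            labels = np.zeros(len(exc), dtype=np.uint8)
            for s, e in gene_iv:
                labels[max(0, s):e] = 1
            for s, e in tir_iv:
                labels[max(0, s):e] = 2
            class_bases["intergenic"] += int((labels == 0).sum())
            class_bases["genic"] += int((labels == 1).sum())
            class_bases["tir"] += int((labels == 2).sum())
        site_classes = []
        for n in in_element:
            el = el_by_id[n.container_element_id]
            off = n.start - el.start
            off -= sum(n2.end - n2.start for n2 in res.ngaros
                       if n2.container_element_id == el.element_id
                       and n2.start < n.start)
            gene_iv, tir_iv = exc_annot[el.element_id]
            site_classes.append(classify_insertion_site((off, off),
                                                        gene_iv, tir_iv))
        res.site_stats = integration_bias_test(site_classes, class_bases)

    # codon usage + gene-length effect
    codon_in = {}
    orf_rows = []
    for el in elements:
        eseq = assembly.contigs[el.contig]
        orf_seqs = []
        for o in el.orfs:
            if any(n.container_element_id == el.element_id
                   and interval_overlap((o.start, o.end), n.interval) > 0
                   for n in res.ngaros):
                continue
            orf_seqs.append(eseq[o.start:o.end])
            if o.label:
                orf_rows.append({"element_id": el.element_id,
                                 "label": o.label,
                                 "aa_length": o.aa_length,
                                 "has_ngaro": bool(el.nested_ngaro_ids)})
        if el.completeness == "complete":
            codon_in[el.element_id] = (el.gc, orf_seqs)
    _, res.codon_rho = codon_usage_profile(codon_in)
    if orf_rows:
        res.gene_lengths = gene_length_comparison(pd.DataFrame(orf_rows))

    # nucleotide contributions
    el_iv = [(el.contig, el.start, el.end) for el in elements]
    ng_iv = [(n.contig, n.start, n.end) for n in res.ngaros]
    res.fractions_assembly = assembly_fractions(assembly, el_iv, ng_iv,
                                                strain=strain)
    if sam_path is not None:
        labels = build_label_arrays(assembly, el_iv, ng_iv)
        res.fractions_reads = read_fractions(sam_path, labels, strain=strain)
        res.deviation_pp = fraction_deviation(res.fractions_assembly,
                                              res.fractions_reads)
    return res


def run_pipeline(assemblies: dict[str, GenomeAssembly] | GenomeAssembly,
                 config: PipelineConfig | None = None,
                 reference_proteome: dict[str, str] | None = None,
                 ngaro_db: dict[int, dict] | None = None,
                 sam_paths: dict[str, str] | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis on one or more assemblies.

    With more than one strain, cross-strain locus orthology is evaluated
    for every complete element.  Results are deterministic given config
    and inputs; when ``outdir`` is set, per-strain GFF3/TSV reports and a
    JSON manifest (with the resolved config) are written.
    """
    cfg = config or PipelineConfig()
    if isinstance(assemblies, GenomeAssembly):
        assemblies = {assemblies.name: assemblies}
    if reference_proteome is None:
        reference_proteome = T.reference_proteome()
    if ngaro_db is None:
        ngaro_db = {tid: {"sequence": t.sequence, "proteins": t.proteins,
                          "repeat_a": t.repeat_a, "repeat_b": t.repeat_b}
                    for tid, t in T.ngaro_templates().items()}
    result = PipelineResult(cfg)
    for strain in sorted(assemblies):
        sam = (sam_paths or {}).get(strain)
        result.strains[strain] = _analyze_strain(
            strain, assemblies[strain], cfg, reference_proteome, ngaro_db,
            sam_path=sam)
    if len(assemblies) > 1:
        for strain, sres in result.strains.items():
            others = {s: a for s, a in assemblies.items() if s != strain}
            for el in sres.elements:
                if el.completeness != "complete":
                    continue
                sres.loci.extend(cross_strain_locus_search(
                    el, assemblies[strain], others, flank=cfg.locus_flank))
    if outdir is not None:
        _write_reports(result, assemblies, Path(outdir))
    return result


def _element_features(sres: StrainResult) -> list[Feature]:
    feats = []
    for el in sres.elements:
        f = Feature(el.element_id, "mobile_genetic_element", el.contig,
                    el.start, el.end, el.orientation,
                    {"completeness": el.completeness,
                     "type": str(el.type_assignment),
                     "gc": f"{el.gc:.4f}"})
        if el.tir:
            f.children.append(Feature(f"{el.element_id}_tir1",
                                      "inverted_repeat", el.contig,
                                      el.tir.left_start, el.tir.left_end,
                                      el.orientation))
            f.children.append(Feature(f"{el.element_id}_tir2",
                                      "inverted_repeat", el.contig,
                                      el.tir.right_start, el.tir.right_end,
                                      el.orientation))
        for k, orf in enumerate(o for o in el.orfs if o.hit):
            f.children.append(Feature(
                f"{el.element_id}_orf{k + 1:02d}", "ORF", el.contig,
                orf.start, orf.end, orf.strand,
                {"label": orf.hit.reference_id,
                 "bitscore": f"{orf.hit.bitscore:.1f}"}))
        feats.append(f)
        if el.tsd:
            feats.append(Feature(f"{el.element_id}_tsd", "direct_repeat",
                                 el.contig, el.tsd.left_start,
                                 el.tsd.left_start + el.tsd.length, "+",
                                 {"element": el.element_id,
                                  "tsd_seq": el.tsd.sequence}))
    for n in sres.ngaros + sres.solos:
        feats.append(Feature(n.ngaro_id, "mobile_genetic_element", n.contig,
                             n.start, n.end, "+",
                             {"class": "solo" if n.solo else "ngaro",
                              "type": str(n.type_id),
                              "variant": n.variant,
                              "container": n.container}))
    return feats


def _write_reports(result: PipelineResult,
                   assemblies: dict[str, GenomeAssembly], outdir: Path
                   ) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for strain, sres in result.strains.items():
        write_gff3(_element_features(sres), outdir / f"{strain}.gff3",
                   validate=False)
        df = sres.summary()
        df.to_csv(outdir / f"{strain}.elements.tsv", sep="\t", index=False)
    manifest = {
        "config": json.loads(result.config.to_json()),
        "strains": {s: {"n_elements": len(r.elements),
                        "n_ngaros": len(r.ngaros),
                        "n_solos": len(r.solos)}
                    for s, r in result.strains.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")
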