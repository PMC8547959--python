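"""Bundled synthetic element and retrotransposon templates.

The eight virophage-element templates are synthetic gene mosaics: each type
carries a type-specific variant of a shared core gene set (major capsid
protein MCP, penton PEN, packaging ATPase, maturation protease PRO, the
virion protein MV14, a primase/helicase marking the 5' end, and an
integrase whose kind and position differ between the low-GC and mid-GC
groups), encoded into DNA with synonymous-codon choices biased toward the
type's target GC.  Templates are generated deterministically from a fixed
internal seed, so no external sequence download is required; real template
FASTA files can be supplied instead wherever a template set is accepted.

The four Ngaro retrotransposon templates carry the split-direct-repeat
architecture A1-[ORF1 ORF2 ORF3]-B1A2B2 (Gag-like, RT+RNaseH, tyrosine
recombinase) with no cross-type nucleotide similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from ._util import child_rng, random_seq_exact_gc, revcomp

# Fixed generator seed for the bundled templates (not user-tunable: templates
# are reference data shared between the simulator and the classifiers).
TEMPLATE_SEED = 7604

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# label -> peptide length (aa)
GENE_LENGTHS = {
    "primase_helicase_S": 450,
    "primase_helicase_L": 700,
    "rve_INT": 400,
    "pPolB": 600,
    "YR": 350,
    "MCP": 450,
    "PEN": 300,
    "ATPase": 250,
    "PRO": 200,
    "MV14": 150,
    "MV19": 180,
    "MV12": 160,
    "MV08": 140,
    "Tlr6F": 200,
    "methylase": 220,
    "RNR": 180,
    "MCP_div": 420,
    "ATPase_div": 240,
    "ORFan1": 150,
    "ORFan2": 120,
}

# Genes whose base peptides form the reference "mavirus-like" proteome used
# by the homology screen (divergent/ORFan genes are deliberately excluded).
REFERENCE_LABELS = [
    "primase_helicase_S", "primase_helicase_L", "rve_INT", "pPolB", "YR",
    "MCP", "PEN", "ATPase", "PRO", "MV14", "MV19", "MV12", "MV08", "Tlr6F",
]

# Per-type gene order.  Low-GC types 1-4: short primase/helicase, 5'-located
# rve-INT, pPolB.  Mid-GC types 5-8: long primase/helicase, YR, 3'-located
# rve-INT.  The canonical MV14-ATPase-PRO-PEN-MCP morphogenesis order is used
# in types 4-7 only; PEN always precedes MCP and MV14 always precedes ATPase.
TYPE_LAYOUTS = {
    1: ["primase_helicase_S", "rve_INT", "pPolB", "Tlr6F", "MV14", "ATPase",
        "MV19", "PRO", "MV12", "PEN", "MCP"],
    2: ["primase_helicase_S", "rve_INT", "pPolB", "Tlr6F", "MV12",
        "ORFan1", "MCP_div", "ATPase_div", "ORFan2"],
    3: ["primase_helicase_S", "rve_INT", "pPolB", "MV19", "MV14", "ATPase",
        "PRO", "MV08", "PEN", "MCP"],
    4: ["primase_helicase_S", "rve_INT", "pPolB", "MV12", "MV19", "MV14",
        "ATPase", "PRO", "PEN", "MCP"],
    5: ["primase_helicase_L", "MV19", "MV14", "ATPase", "PRO", "PEN", "MCP",
        "MV12", "YR", "rve_INT"],
    6: ["primase_helicase_L", "MV08", "MV14", "ATPase", "PRO", "PEN", "MCP",
        "MV19", "YR", "rve_INT"],
    7: ["primase_helicase_L", "methylase", "RNR", "MV14", "ATPase", "PRO",
        "PEN", "MCP", "MV19", "YR", "rve_INT"],
    8: ["primase_helicase_L", "YR", "MV12", "MV19"],
}

# Canonical template GC by type: low-GC group 1-4, mid-GC group 5-8, matching
# the observed 29.7-52.7% range and ascending with the numbering convention.
TYPE_GC = {1: 0.30, 2: 0.33, 3: 0.355, 4: 0.38,
           5: 0.47, 6: 0.49, 7: 0.51, 8: 0.53}

# Fraction of residues mutated from the shared base peptide in each type's
# variant: keeps protein-level homology detectable while making nucleotide
# 10-mer similarity between types negligible.
TYPE_AA_DIVERGENCE = 0.45

_SPACER = 100       # intergenic spacer between genes, bp
_TIR_SRC_LEN = 2500  # per-type terminal-inverted-repeat source length, bp

_SYN_CODONS: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _SYN_CODONS.setdefault(_aa, []).append(_codon)
for _aa in _SYN_CODONS:
    _SYN_CODONS[_aa].sort()
_CODON_GC_COUNT = {c: c.count("G") + c.count("C")
                   for cs in _SYN_CODONS.values() for c in cs}


@dataclass(frozen=True)
class TemplateGene:
    label: str
    start: int   # 0-based, within template core
    end: int     # half-open; includes the trailing stop codon
    peptide: str


@dataclass(frozen=True)
class ElementTemplate:
    type_id: int
    gc: float
    core: str                       # gene mosaic, no TIRs
    genes: tuple[TemplateGene, ...]
    tir_source: str                 # left-arm source; right arm is its revcomp

    @property
    def proteins(self) -> dict[str, str]:
        return {g.label: g.peptide for g in self.genes}

    @property
    def realized_gc(self) -> float:
        """Realized GC of the core (the coding constraint keeps it within a
        few points of the design target ``gc``)."""
        from ._util import gc_fraction
        return gc_fraction(self.core)


@dataclass(frozen=True)
class NgaroTemplate:
    type_id: int
    gc: float
    sequence: str
    repeat_a: str
    repeat_b: str
    genes: tuple[TemplateGene, ...]  # coordinates on ``sequence``
    orf1_span: tuple[int, int]

    @property
    def proteins(self) -> dict[str, str]:
        return {g.label: g.peptide for g in self.genes}

    @property
    def realized_gc(self) -> float:
        from ._util import gc_fraction
        return gc_fraction(self.sequence)


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, len(AA20), size=length))


def _mutate_peptide(rng: np.random.Generator, pep: str, frac: float) -> str:
    arr = list(pep)
    n = int(round(frac * len(arr)))
    for i in rng.choice(len(arr), size=n, replace=False):
        arr[i] = AA20[int(rng.integers(0, len(AA20)))]
    return "".join(arr)


def encode_peptide(rng: np.random.Generator, peptide: str, gc: float) -> str:
    """Encode a peptide into DNA with composition-weighted synonymous codons.

    Each codon is drawn with probability proportional to its likelihood
    under an i.i.d. base model at an adaptive GC level; a feedback term
    (integral of the running GC error) tilts that level so the realized GC
    tracks the target.  Sampling codons from a composition-typical
    distribution — rather than greedily taking the GC-optimal codon — keeps
    the codon vocabulary broad, so independently encoded genes share no
    more exact words than random sequence of the same composition would.
    A trailing TAA stop is appended.
    """
    out: list[str] = []
    gc_count = 0
    total = 0
    for aa in peptide:
        codons = _SYN_CODONS[aa]
        err = gc * total - gc_count          # >0 means GC is running low
        p_gc = min(0.92, max(0.08, gc + 0.2 * np.tanh(err / 4.0)))
        weights = np.array([
            (p_gc / 2) ** _CODON_GC_COUNT[c]
            * ((1 - p_gc) / 2) ** (3 - _CODON_GC_COUNT[c])
            for c in codons])
        weights /= weights.sum()
        codon = codons[int(rng.choice(len(codons), p=weights))]
        out.append(codon)
        gc_count += _CODON_GC_COUNT[codon]
        total += 3
    out.append("TAA")
    return "".join(out)


@lru_cache(maxsize=1)
def base_peptides() -> dict[str, str]:
    """Shared base peptide per gene label (the reference proteome)."""
    peps = {}
    for idx, (label, length) in enumerate(sorted(GENE_LENGTHS.items())):
        rng = child_rng(TEMPLATE_SEED, 1, idx)
        peps[label] = _random_peptide(rng, length)
    return peps


@lru_cache(maxsize=1)
def reference_proteome() -> dict[str, str]:
    peps = base_peptides()
    return {label: peps[label] for label in REFERENCE_LABELS}


@lru_cache(maxsize=1)
def element_templates() -> dict[int, ElementTemplate]:
    peps = base_peptides()
    out: dict[int, ElementTemplate] = {}
    for type_id, layout in TYPE_LAYOUTS.items():
        gc = TYPE_GC[type_id]
        rng = child_rng(TEMPLATE_SEED, 2, type_id)
        parts: list[str] = []
        genes: list[TemplateGene] = []
        pos = 0
        for label in layout:
            spacer = random_seq_exact_gc(rng, _SPACER, gc)
            parts.append(spacer)
            pos += len(spacer)
            if label in ("ORFan1", "ORFan2", "MCP_div", "ATPase_div"):
                pep = _random_peptide(rng, GENE_LENGTHS[label])
            else:
                pep = _mutate_peptide(rng, peps[label], TYPE_AA_DIVERGENCE)
            dna = encode_peptide(rng, pep, gc)
            genes.append(TemplateGene(label, pos, pos + len(dna), pep))
            parts.append(dna)
            pos += len(dna)
        parts.append(random_seq_exact_gc(rng, _SPACER, gc))
        tir_src = random_seq_exact_gc(rng, _TIR_SRC_LEN, gc)
        out[type_id] = ElementTemplate(type_id, gc, "".join(parts),
                                       tuple(genes), tir_src)
    return out


NGARO_GC = 0.66            # GC-rich relative to both element groups
NGARO_REPEAT_A = 300       # bp
NGARO_REPEAT_B = 250       # bp
NGARO_ORF_LENGTHS = {"ORF1_gag": 450, "ORF2_rt_rh": 900, "ORF3_yr": 350}
_NGARO_SPACER = 60


@lru_cache(maxsize=1)
def ngaro_templates() -> dict[int, NgaroTemplate]:
    """Four retrotransposon templates with A1-[ORFs]-B1A2B2 structure."""
    out: dict[int, NgaroTemplate] = {}
    for type_id in range(1, 5):
        rng = child_rng(TEMPLATE_SEED, 3, type_id)
        rep_a = random_seq_exact_gc(rng, NGARO_REPEAT_A, NGARO_GC)
        rep_b = random_seq_exact_gc(rng, NGARO_REPEAT_B, NGARO_GC)
        parts = [rep_a]
        pos = len(rep_a)
        genes: list[TemplateGene] = []
        orf1_span = (0, 0)
        for label, aa_len in NGARO_ORF_LENGTHS.items():
            spacer = random_seq_exact_gc(rng, _NGARO_SPACER, NGARO_GC)
            parts.append(spacer)
            pos += len(spacer)
            pep = _random_peptide(rng, aa_len)
            dna = encode_peptide(rng, pep, NGARO_GC)
            genes.append(TemplateGene(label, pos, pos + len(dna), pep))
            if label == "ORF1_gag":
                orf1_span = (pos, pos + len(dna))
            parts.append(dna)
            pos += len(dna)
        parts.append(random_seq_exact_gc(rng, _NGARO_SPACER, NGARO_GC))
        parts.extend([rep_b, rep_a, rep_b])   # ... B1 A2 B2
        out[type_id] = NgaroTemplate(type_id, NGARO_GC, "".join(parts),
                                     rep_a, rep_b, tuple(genes), orf1_span)
    return out


def ngaro_orf1_deleted(template: NgaroTemplate) -> str:
    """The ORF1-truncated ("b") variant: a ~2 kb deletion covering ORF1."""
    s, e = template.orf1_span
    start = max(len(template.repeat_a), s - _NGARO_SPACER)
    end = min(start + 2000, e + 10)
    return template.sequence[:start] + template.sequence[end:]


def build_element_sequence(template: ElementTemplate, tir_length: int,
                           core: str | None = None) -> str:
    """Assemble TIR + core + revcomp(TIR) from a template."""
    if tir_length > len(template.tir_source):
        raise ValueError(f"tir_length {tir_length} exceeds template TIR source "
                         f"({len(template.tir_source)} bp)")
    core = template.core if core is None else core
    tir = template.tir_source[:tir_length]
    return tir + core + revcomp(tir)


def type_species_proteins() -> dict[int, dict[str, str]]:
    """Per-type protein sets used for cumulative-bitscore type assignment."""
    return {tid: t.proteins for tid, t in element_templates().items()}
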