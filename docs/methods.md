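# Methods

## The problem

High-GC genome assemblies of the marine flagellate *Cafeteria burkhardae*
(~70% GC) carry two families of nested mobile elements: endogenous
mavirus-like virophage genomes (EMALEs; 5.5–21.5 kb, 29–53% GC, flanked by
terminal inverted repeats and short target site duplications) and Ngaro
tyrosine-recombinase retrotransposons (DIRS order; ~6 kb, GC-rich relative
to the virophage elements they often interrupt, with split direct repeats
A1–[ORFs]–B1A2B2). `emalekit` re-implements the discovery, delimitation,
classification and quantification workflow for such elements as a tested
pipeline, and pairs it with a synthetic-genome generator whose ground truth
makes every stage verifiable without multi-megabase real assemblies.

## Detection model

1. **GC screen.** Sliding-window GC (window 500 bp, step 100 bp) against a
   genome-wide baseline (median of all window values; robust while mobile
   elements are a few percent of the genome). Windows at least 15 points
   below baseline form candidate runs, merged across gaps ≤ 1 kb and kept
   at ≥ 2 kb. Defaults were chosen so that a mavirus-scale element (19 kb,
   ~30% GC) is unmissable in a 70% GC host while mid-GC (~50%) elements
   still clear the contrast. Run edges are refined to the single-base
   changepoint maximising the GC contrast of 500 bp flanks within one
   window of the edge.
2. **Retrotransposon-aware joining.** A GC-rich Ngaro splits its host
   element's low-GC run in two. Adjacent candidates are re-joined when the
   gap between them (≤ 12 kb) is mostly covered by a genome-wide
   retrotransposon template scan (dense exact 16-mer matches to any Ngaro
   reference sequence).
3. **Homology confirmation.** Six-frame stop-to-stop ORFs (≥ 50 aa) inside
   each candidate are aligned (Smith–Waterman, BLOSUM62, gap open 11 /
   extend 1, bitscores from λ = 0.267, K = 0.041) against a reference
   virophage proteome. A candidate survives only with at least one hit at
   ≥ 50 bits — the intersection of the GC and similarity screens, which
   keeps precision high on realistic backgrounds. References sharing < 2
   exact peptide 4-mers with an ORF are skipped before alignment; homologs
   at the bitscore cutoff share dozens.
4. **Delimitation.** The candidate's terminal 3 kb arms (with 400 bp of
   outward slack, covering the changepoint error on 17-point contrasts)
   are locally aligned — 5′ arm against the reverse complement of the 3′
   arm (match +1, mismatch −2, affine gaps 7/2) — and the element
   boundaries snap to the outer ends of any terminal inverted repeat of
   ≥ 100 bp at ≥ 0.9 identity. Elements are oriented so the
   primase/helicase ORF lies 5′ (ORF-strand majority as fallback).
   *Complete* = TIR pair plus host DNA on both flanks; everything else
   (contig ends, short contigs) is *partial*. The target site duplication
   is the longest exact match (≤ 15 bp) between upstream-flank suffix and
   downstream-flank prefix; 1 bp TSDs are reported but indistinguishable
   from chance, which is left to the caller.
5. **Ngaro analysis.** Within elements, insertions are called as windowed
   GC runs ≥ 10 points above the element's own trimmed-mean baseline
   (2–12 kb); genome-wide, candidates come from the 16-mer template scan
   (the two are unioned, preferring the scan's bounds). Split direct
   repeats are resolved from clustered exact k-mer self-matches (arms
   ≥ 50 bp, ≥ 0.9 identity, B1A2B2 contiguous within 100 bp); an isolated
   A+B pair matching known repeats with no intervening ORFs is a *solo*
   record. Types are assigned by word-10 similarity to the four templates;
   the ORF1 ("a"/"b") status is decided by whether any ≥ 100 aa ORF
   fragment in the oriented 5′ 2.5 kb aligns to the type's Gag-like
   reference at ≥ 50 bits. Fragment-level homology, rather than a single
   ≥ 200 aa ORF, is used because a nonsense substitution can split an
   intact Gag gene into sub-200 aa pieces that still align strongly — a
   decision made after observing exactly that failure mode on mutated
   synthetic copies; assembly errors produce the same apparent pseudogenes
   in real data.
6. **Typing.** Complete elements (retrotransposon-excised) are clustered
   by single linkage on a word-10 dot-plot similarity at threshold 0.30;
   clusters are numbered by ascending median GC (low-GC types before
   mid-GC types) and the longest member is the type species. Partial
   elements get the type with the highest cumulative best-per-ORF bitscore
   against the type-species protein sets; maxima below 100 bits are
   *inconclusive*. Elements are labelled low-GC (< 0.43) or mid-GC
   (≥ 0.43), the midpoint of the observed gap between the groups.
7. **Statistics and accounting.** Integration-site preference uses a
   two-sided Fisher's exact test on [insertions in intergenic vs
   genic+TIR element DNA] against the per-class base totals of the same
   annotations (a binomial tail is reported as cross-check). Sites are
   classified on the *excised* element with gene intervals taken from
   alignment-trimmed labelled ORFs, so neither the retrotransposon's own
   ORFs nor stop-to-stop read-through across the junction contaminates the
   classification. Host/element/ngaro genome fractions are computed from
   exact assembly bookkeeping (nested Ngaro bases count as Ngaro) and,
   independently, by CIGAR-aware attribution of aligned read bases
   (insertions take the class at the insertion point; deletions are not
   counted; secondary/supplementary/unmapped records are skipped). Codon
   usage is summarised per element (64 codon counts, GC3, synonymous usage)
   with a Spearman correlation of GC3 against element GC; conserved-gene
   lengths are compared between Ngaro-containing and Ngaro-free elements
   with a two-sided rank-sum test.
8. **Cross-strain loci.** Up to 10 kb of host flank on each side of a
   complete element is mapped onto other assemblies by infix (edit
   distance) alignment, accepting placements ≥ 200 bp at ≥ 0.9 identity.
   Flanks abutting within 50 bp mark an empty allele; a ≥ 1 kb gap whose
   sequence is a type-matched homolog of the query marks an occupied one;
   a locus is *shared* when occupied with at least one matching flank.
   Infix edit-distance alignment is used here because a quadratic
   affine-gap DP over 10 kb × Mb-scale subjects is not tractable; the
   acceptance thresholds are unchanged.

## Dot-plot similarity

The similarity between two sequences is the fraction of the shorter
covered by *diagonal word-match runs*: at least two exact shared 10-mers
on one diagonal (either strand) within 25 bp of each other. Plain
bag-of-words coverage is unusable here: at 10–20 kb scale and AT-skewed
composition, two unrelated i.i.d. sequences already share 25–30% of their
words, swamping a 0.30 threshold. Diagonal runs are the computable analog
of the block patterns a human reads in a dot plot; measured on the bundled
templates they give ≤ 0.17 between types, ≥ 0.42 within a type even at 19%
pairwise divergence, and exactly 1.0 for identical or reverse-complement
pairs.

## The synthetic generator

The generator emulates the study system, not generic genomes:

- **Host**: i.i.d. base sampling with exact-count composition (realised
  per-contig GC equals the rounded target), G/C and A/T split evenly; no
  repeats beyond the planted features, so detection acceptance is
  unambiguous. Default: 5 contigs × 1 Mb at 70% GC.
- **Elements**: eight bundled templates — synthetic gene mosaics carrying
  type-specific variants (45% residue divergence) of a shared core gene set
  (MCP, PEN, ATPase, PRO, MV14, MV19, MV12, primase/helicase, rve-INT in
  low-GC types near the 5′ end, tyrosine recombinase plus 3′ rve-INT in
  mid-GC types; type 2 carries divergent capsid ORFans, type 8 is short
  and lacks the morphogenesis module). Type design GCs ascend 0.30–0.53;
  coding constraints land realised GC within ~3 points of target (floor
  ≈ 0.33 for coding sequence), and truth/tests compare against the
  realised template GC. Peptides are encoded with composition-weighted
  synonymous-codon sampling under an integral GC-error feedback: greedy
  GC-optimal choice would concentrate the codon vocabulary at extreme GC
  and make unrelated genes share exact words. Planted copies are
  substitution-mutated templates (default 2%); TIR arms (taken from a
  per-type 2.5 kb source, 0.2–2.3 kb per element) stay exact reverse
  complements; partial elements are truncated cores placed flush with a
  contig end, with regenerated TIRs and no TSD.
- **Insertion sites** are nudged in 7 bp steps until (i) the junction's
  longest exact match equals the requested TSD length and (ii) no chance
  reverse-complement run across the junction reaches a positive +1/−2
  alignment score. Without these checks the planted truth itself is
  ambiguous — a chance extension moves the true boundary — and
  exact-recovery acceptance would be ill-posed.
- **Ngaros**: four templates (~6.4 kb, design GC 0.66, realised ≈ 0.60)
  with A(300 bp)–ORF1(Gag, 450 aa)–ORF2(RT+RNaseH, 900 aa)–ORF3(YR,
  350 aa)–B(250 bp)A B structure and independent per-type peptides (no
  cross-type similarity). The "b" variant deletes ~2 kb covering ORF1.
  Default: 6 insertions (4 nested in elements — 3 intergenic, 1 genic —
  2 ORF1-truncated in host DNA) plus one solo A+B pair.
- **Reads**: single-end, fixed length (default 10,000 × 8 kb), drawn
  either systematically (evenly spaced starts with random phase — balanced
  coverage, the default used for fraction accounting) or i.i.d. uniform;
  starts are drawn over the extended range and clipped so per-base
  coverage is uniform in expectation including contig ends. Substitution
  errors only; error-free by default.

What the generator does **not** emulate: host repeat families, indel or
chimera read errors, heterozygous insertions (ploidy is deliberately
deferred), assembly collapse of near-identical copies. Passing the
acceptance properties therefore demonstrates correctness of the method's
logic under clean conditions, not performance on real assemblies, where
repeats and assembly artifacts add failure modes that in practice are
handled by manual curation.

## Problem sizes

The acceptance suite and `scripts/acceptance.py` run the full pipeline on
the default study conditions (5 Mb per genome, 15 elements, 6 Ngaros,
10,000 reads) over 20 seeds — about 10 s per seed. The two-strain locus
fixture uses 2 × 620 kb strains with 12 insertions (6 shared). Unit tests
use 100–300 kb genomes.

## Numerical choices and tie-breaks

- Bitscore constants fixed at gapped BLOSUM62 defaults (λ = 0.267,
  K = 0.041); `X` scores 0 against everything.
- Cumulative type scores count each ORF once per type (best hit only),
  avoiding double-counting of paralogous hits; exact ties break to the
  lower type id and are flagged.
- Repeat-architecture ties break to the largest total repeat length.
- Clustering is deterministic given input order; element-id order breaks
  ties. GC-group boundary 0.43 assigns the boundary value to "mid".
- All internal coordinates are 0-based half-open; GFF3 output is 1-based
  inclusive. TSDs flank the element rather than nest inside it, so they
  are emitted as sibling features referencing the element by attribute.
- Degenerate inputs: sequences shorter than one window give an empty
  profile (with a warning); empty ORF sets type as "inconclusive" with
  score 0; zero insertions make the Fisher test an error rather than a
  p-value.

## Known limitations

- The GC insertion caller needs ~10 points of contrast; a Ngaro inside the
  most GC-rich element types is found by the template scan only, which in
  turn assumes the retrotransposon family is known from at least one
  resolved copy (true in the study system; the generator ships templates).
- The 0.30 linkage threshold and the diagonal-run similarity are explicit
  stand-ins for a by-eye block-pattern reading; no published threshold
  exists to copy.
- Fisher's test treats insertion sites as independent; nested or adjacent
  insertions in one element violate this mildly.
- On real assemblies the intersection detection rule inherits the
  reference proteome's coverage: a virophage with no recognisable homolog
  in the supplied protein set and host-like GC would be missed.
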