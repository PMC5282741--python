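# Methods

This note records the models, rules and numerical choices behind
`annoforge`, and what the synthetic validation does and does not show.

## Coordinate and sequence conventions

All in-memory intervals are 0-based half-open on the forward strand of
their contig; GFF3 on disk is 1-based inclusive, converted only in
`annoforge.io`. A transcript's CDS is stored as a single genome interval;
its per-exon CDS segments are the intersections with the exons. Intron
donor/acceptor dinucleotides are read on the coding strand
(reverse-complemented for minus-strand genes). Introns shorter than 4 bp
cannot hold both splice dinucleotides: they report the first
`min(2, len)` bases as donor and the remainder (possibly empty) as
acceptor, and are never labelled canonical — at least four bases are
needed for a real donor/acceptor pair.

## The synthetic genome forge

The forge emulates the data situation of a compact, AT-rich, gene-dense
amoebozoan genome annotated mostly by prediction. Defaults (all
`ForgeConfig` fields):

| parameter | default | rationale |
|---|---|---|
| GC target | 0.32 | mid-range of compact AT-rich nuclear genomes |
| genes / contigs | 120 / 3 | ~200 kb total; multi-contig I/O exercised (1–5 allowed) |
| exons per gene | 2–6 | multi-exon but short genes |
| intron length | 60–120 bp, GT..AG | short AT-rich introns |
| UTRs | 100 bp 5', 150 bp 3' | modest, single-exon-terminal UTRs |
| CDS | 60–320 codons | desk-scale genes, always ≥ 50-codon ORFs |
| read counts | lognormal(µ=4, σ=1.2), min 1 | long-tailed expression profile |
| read length | 100 bp | used only in the coverage proxy |
| contaminant GC | 0.55 | ≥ 0.15 offset from target, as a bacterial food source would show |
| pileup depths | 23 (deletion, 22 supporting); 56 and 33 (substitutions, unanimous) | near-unanimous read evidence at audited sites |

Genes are built mRNA-first: 5'UTR + (ATG, stop-free codon run, stop) +
3'UTR, split into exons **at codon boundaries only**, with GT..AG introns
inserted between. Exon boundaries on codon boundaries make every frame
manipulation exactly analysable: skipping an internal exon removes whole
codons (never creating a stop), splitting a gene at any intron leaves two
half-CDSs of whole codons, and the micro-intron defects below have
byte-exact expected repairs.

Planted defect kinds and their expected pipeline verdicts:

* `UTR_MISSING` — observed model trimmed to its CDS ⇒ `UTR_ONLY`.
* `SPLIT_MODEL` — one true gene annotated as two half-models ⇒ `MERGE`.
* `FUSED_MODEL` — two adjacent true genes annotated as one model (the
  intergenic region becomes an "intron", the fused CDS reads through a
  stop) ⇒ `SPLIT`.
* `HIDDEN_ISOFORM` — the truth carries an exon-skipping second isoform
  the observed annotation lacks ⇒ `NEW_ISOFORM`. Isoform genes are held
  at ≥ 112 codons so the skipped product still exceeds 50 codons.
* `NOVEL_GENE_UNANNOTATED` — gene present in the genome and transcript
  set but absent from the observed GFF ⇒ `NOVEL_GENE`. With
  `novel_gap_count > 0` some of these loci are withheld from the genome
  entirely (an assembly gap): the transcript then fails alignment and
  must come out of the orphan ladder as `NOVEL`.
* `GENOME_BASE_DELETION` — a true ATT (Ile) codon whose final base the
  genome lacks; the annotation compensates with a 2 bp "AT" intron, and
  the pileup shows a single-base `T` insertion immediately after the
  intron in 22 of 23 reads ⇒ `GENOME_DELETION`, repair `+1 Ile`.
* `GENOME_BASE_SUBSTITUTION` — a true TTA (Leu) codon the genome carries
  as TAA (a stop); the annotation hides it in a 3 bp intron, and all
  reads (56, then 33, at the two planted sites) carry the `T` ⇒
  `GENOME_SUBSTITUTION`, repair `+1 Leu, stop removed`.
* `CONTAMINANT_CONTIG` / `SPIKEIN_CONTIG` / `ARTEFACT_TRANSCRIPT` —
  extra-genomic transcript records: bacterial-GC sequences with a foreign
  taxon label; copies of the synthetic spike-in database; and shuffled
  sequences rejection-sampled until no reading frame holds a 50-codon
  stop-free stretch.

Two deliberate simplifications, both visible in the ledger semantics:
genome-error defects are planted on plus-strand genes only (the audit
itself is strand-generic; this keeps the pileup bookkeeping on one
strand), and at those loci the *truth* GFF carries the same compensating
micro-intron as the observed GFF — a "clean" model would be
unrepresentable on the released genome, and the evidence for the error
lives in the genome+pileup, not in the annotation diff. Transcripts at
those loci are spliced from the genome (so they align perfectly); the
read-level evidence of the error is synthesised directly into the pileup
columns. The forge plants read *counts* and pileup columns, never
read-level sequences: the audited computations consume counts and
pileups, so simulating reads would add noise without adding coverage of
any code path.

Determinism: everything derives from one root seed through fixed
numpy `default_rng([seed, stream])` substreams; identical configs give
byte-identical files.

## Spliced alignment

The mapper is built for compact genomes and substitution-type errors:
exact 15-mer seeds are grouped per (contig, strand, diagonal); runs on a
diagonal merge across gaps ≤ 50 bp (an isolated substitution breaks
seeds but not the diagonal); merged runs chain co-linearly by dynamic
programming with genome gaps of 1–5000 bp as introns; unaligned query
bases at a junction are distributed to maximise matches, with canonical
junctions (GT-AG on the coding strand) breaking ties and the leftmost
placement used when no canonical choice exists. Identity counts
mismatches inside blocks; coverage is aligned bases over transcript
length. Indels inside exons are not modelled — the forge's error model is
substitution-only, and a gapped extender would be a different project.

Junction placement under noise is the one place the mapper can
legitimately disagree with an annotation: an error adjacent to a junction
can make the true placement score-losing. Two mitigations keep this from
cascading: structure/model chain comparisons canonicalise every intron to
its leftmost sequence-preserving placement first, and when several noisy
structures demand different modifications of one gene, only the
best-supported record is applied (the rest are demoted to UNCHANGED with
a note).

## Update classification

The rule order is this package's explicit operationalisation of
rule-based annotation updating — reference updaters do not publish their
rule set, so the order here is normative for this artifact and is tested
as such: (1) no overlapping model ⇒ novel gene (structures overlapping a
model only on the opposite strand are reported as novel with a
strand-conflict note; assemblers do emit antisense contigs); (2) a
structure whose longest start-initiated ORF spans the CDS of ≥ 2
same-strand models ⇒ merge; (3) ≥ 2 span-disjoint structures over one
model whose own CDS translation contains an internal stop ⇒ split; (4)
identical intron chain over the CDS with termini extended > 10 bp beyond
the model ⇒ UTR-only (UTR-side introns are allowed to differ); (5) a
differing chain while a sibling structure retains an existing isoform ⇒
new isoform; (6)–(7) exon-count and junction comparisons over the CDS
span; (8) unchanged. Structures lacking an ORF of ≥ 50 codons are never
promoted to novel genes (reported unchanged-with-note). Models flagged as
pseudogenes would be excluded from matching; the forge does not plant
them.

Protein changes are classified on translated old/new CDS pairs
(prefix/suffix relations for N/C truncation/extension, single contiguous
block insertion/deletion for exon gain/loss, otherwise internal change).
A CDS with an internal stop is not classified — it is exactly the
situation the genome audit exists for, and the record carries a flag
instead. The 10 bp terminus slack absorbs end-extension jitter from
seed-boundary effects without letting genuine UTR additions (≥ tens of
bp) pass as unchanged.

## Micro-intron audit

Thresholds: flag introns `< 5 bp`; calls need support ≥ 0.8 of covering
reads and depth ≥ 5 — documented near-unanimous evidence motivates a
high bar, and both knobs are CLI flags. Insertion evidence is accepted
within ±2 bp of either intron boundary ("immediately after the intron"
in either strand's reading). Substitution calls are restricted to edits
that abolish an in-intron stop codon, the one mechanism with a
documented precedent; other supported substitutions return NO_CALL with
a note. The pileup dialect carries `ins_base` because a repair needs the
inserted base's identity, not merely its count. Repairs re-enter the
intron (plus the inserted base for deletions) into the spliced CDS,
require the re-entered bases to restore the frame (length ≡ 0 mod 3),
and re-translate the full CDS; any remaining premature stop is reported
as `REPAIR_FAILED` with its residue position.

## Orphan ladder

Rung order: genome/cDNA ⇒ annotated; related-species nucleotide hit ⇒
known; non-related hit ⇒ artefact; translated search of the longest
predicted ORF against the related database ⇒ known; multiple stop codons
in all reading frames ⇒ artefact; else novel. The multi-stop rung sits
above novel because a sequence with no plausible ORF anywhere is an
assembly error regardless of database coverage. ORFs running off the
transcript end are kept and marked partial — assemblies truncate
transcripts, and discarding stop-less ORFs would bias the ladder against
exactly the fragmented transcripts it triages. Internal search
thresholds (defaults: cDNA 0.90/0.50, nucleotide 0.75/0.50, protein
0.30/0.50 identity/coverage, 50-codon ORF floor) are explicit
configuration, surfaced in the output.

The internal search engine is a k-mer-seeded, diagonal-merged, ungapped
local aligner (nucleotide k = 11, amino-acid k = 4 over six-frame
translations). It recognises near-identical and block-identical matches
— all this pipeline needs — and is deterministic; it is not a
general-purpose gapped search.

## What the validation shows — and does not

The end-to-end check recovers all 41 planted defects with precision =
recall = 1.0 on error-free transcripts and ≥ 0.9 at 0.5% per-base error
(measured ≥ 0.93 across seeds), on a ~200 kb genome in well under a
minute on one CPU. Problem sizes throughout (120-gene genome, 40-gene
unit fixtures, 1,000-multiset metric oracles, 10⁴-point filter grid)
were chosen so the whole suite illustrates every code path at desk
scale.

Passing these tests shows the *rules* are implemented exactly as stated,
with exact expected outputs. It does not show the rules are sufficient
for real data: the forge has no repeats, no paralogy, no indel
sequencing errors, no coverage-dependent transcript fragmentation, no
chimeric mis-assemblies spanning loci, and expression levels independent
of assembly quality. Real genomes also present trans-splicing,
non-coding RNA and pseudogene complications that are explicit non-goals
here.
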