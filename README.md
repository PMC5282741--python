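# annoforge

Audit and refine eukaryotic genome annotations with *de novo*
transcriptome assemblies — and prove the audit works on a synthetic
genome where every planted defect is known in advance.

## The problem

Automated gene prediction leaves annotations incomplete in systematic
ways: UTRs are missing, neighbouring genes get fused or one gene gets
split in two, alternative splice isoforms go unreported, and single-base
errors in the genome sequence itself force curators to invent
biologically impossible "micro-introns" (shorter than 5 bp — splicing
needs a 2 bp donor, a 2 bp acceptor and a branch point) just to keep a
reading frame open. Assembled RNA-seq transcripts are empirical evidence
against all of these, but turning them into annotation updates requires a
chain of filters and comparisons, each with edge cases that are hard to
validate on real data because no ground truth exists.

`annoforge` implements that chain as a tested library plus CLI:

1. **Spike-in removal** — local alignment against a spike-in database
   (identity ≥ 0.90 over ≥ 0.50 of the transcript, configurable).
2. **TAGC contamination filtering** — taxon-annotated GC×coverage
   verdicts: foreign taxon ⇒ removed; unassigned ⇒ kept only inside the
   GC band *mean ± k·sd* (default k = 3) of the taxon-confirmed target
   transcripts.
3. **Spliced alignment** — a deterministic k-mer seed-and-chain mapper
   (k = 15, introns ≤ 5 kb, GT-AG-preferring junction placement, both
   strands), followed by the acceptance filter: identity ≥ 95% **and**
   transcript coverage ≥ 90%, boundaries inclusive.
4. **Locus assembly** — accepted alignments cluster transitively by exon
   overlap per contig and strand; distinct exon chains become candidate
   isoforms.
5. **Annotation update** — an explicit rule order (first match wins):
   novel gene → merge (one ORF spanning ≥ 2 models) → split (disjoint
   structures over a stop-broken model) → UTR-only → new isoform → exon
   gain/loss → intron change → unchanged; protein-level consequences
   (N/C truncation or extension, exon gain/loss, internal change) are
   classified by translating old vs new CDS.
6. **Orphan triage** — transcripts failing genome alignment descend an
   elimination ladder: cDNA hit ⇒ annotated; related-species hit ⇒ known;
   non-related hit ⇒ artefact; translated ORF hit ⇒ known; stops in all
   six frames ⇒ artefact; else novel.
7. **Micro-intron genome audit** — every annotated intron < 5 bp is
   tested against read pileups: a supported single-base insertion at the
   intron boundary calls a **genome deletion** (the intron bases plus the
   inserted base re-enter the CDS as in-frame codons); a unanimous
   in-intron substitution that abolishes a stop codon calls a **genome
   substitution**. Each call proposes a repair and re-translates to check
   the premature stop is gone.

The **synthetic genome forge** makes the whole chain falsifiable: it
generates an AT-rich, gene-dense genome (defaults: 120 genes, 32% GC,
GT-AG introns of 60–120 bp, 2–6 exons per gene) together with a damaged
"existing annotation", spliced transcripts with read counts, pileup
columns at audit sites, contaminant/spike-in/artefact sequences — and a
machine-readable ledger naming every planted defect and the verdict the
pipeline must reach.

## Worked example

```bash
annoforge forge --seed 9 --n-genes 40 \
  --defects '{"UTR_MISSING": 3, "GENOME_BASE_DELETION": 1,
              "CONTAMINANT_CONTIG": 2, "SPIKEIN_CONTIG": 1}' --out demo
annoforge decontam demo/transcripts.fasta demo/read_counts.tsv \
  demo/taxon.tsv --spikeins demo/spikeins.fasta --outdir demo/decon
annoforge refine demo/decon/kept.fasta demo/genome.fasta --outdir demo/refine
annoforge update demo/observed.gff3 demo/genome.fasta \
  demo/refine/good_transcripts.fasta --outdir demo/update
annoforge intron-audit demo/observed.gff3 demo/genome.fasta demo/pileup.tsv
```

prints, in order: `removed 1 spike-in transcripts` and `kept 40, removed
2` (the planted spike-in copy and both bacterial contaminants are gone),
`40 good / 0 failed; 40 loci` (every genuine transcript aligns perfectly
and clusters into one locus per gene), an update summary whose first rows
read

```
          category  count
Gene model updated      3
          UTR_ONLY      3
         UNCHANGED     37
```

(the three models planted without UTRs are the three UTR-only updates;
nothing else moves), and finally

```
1 micro-intron sites in 1 genes (0 with several); 1 genome-error calls
```

— the planted single-base genome deletion is found as a 2 bp intron whose
pileup shows an insertion, and `audit.tsv` records the repair
(`+1 Ile`, i.e. the intron bases plus the supported inserted base form
one in-frame isoleucine codon).

`annoforge stats` reports the usual assembly summary (total transcripts,
contig N50, E90N50 — the N50 over the most-expressed transcripts holding
90% of reads — GC%, length statistics, exons per transcript).

## File formats

Standard formats are FASTA (wrap 60) and a GFF3 subset
(gene/mRNA/exon/CDS with ID/Parent/Name; 1-based inclusive on disk,
0-based half-open in memory). Tab-separated dialects:

* `read_counts.tsv` — `transcript_id, count`
* `taxon.tsv` — `contig_id, taxon`
* `pileup.tsv` — `contig, pos (1-based), ref, A, C, G, T, N, ins, del,
  ins_base`; `ins_base` is the most frequent inserted base (`.` when
  none) — the repair proposer needs its identity, not just a count
* `alignments.tsv` — a 12-column PSL-like table: ids, strand, identity,
  coverage, query/target spans, and a `qstart:tstart:length` block list
* `ledger.tsv` — planted defect kind, locus, expected verdict, and a
  JSON details column
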