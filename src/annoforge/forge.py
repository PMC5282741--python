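"""Synthetic genome forge with a planted-defect truth ledger.

Emulates the situation the audit pipeline is built for: a gene-dense
eukaryotic genome with short AT-rich introns and multi-exon genes, an
existing annotation that is incomplete or wrong in known ways (missing
UTRs, fused/split models, hidden isoforms, unannotated genes), single-base
genome-sequence errors compensated by impossible micro-introns, bacterial
contaminant contigs with offset GC, spike-in controls and shuffled
assembly artefacts. Every planted defect is recorded in a machine-readable
ledger together with the verdict the pipeline is expected to emit, so the
whole downstream analysis has exact expected outputs.

Genes are built mRNA-first: a 5'UTR, an ATG-initiated stop-free codon run,
a stop codon and a 3'UTR are split into exons at codon boundaries and
GT..AG introns are inserted between them. All exon/intron boundaries
therefore fall on codon boundaries, which keeps every frame manipulation
(exon skips, gene splits, micro-intron repairs) exactly analysable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import (GeneModel, Interval, SequenceRecord, STOP_CODONS,
                     TranscriptModel, revcomp)

BASES = np.array(list("ACGT"))


class ForgeError(ValueError):
    """Raised for infeasible or inconsistent forge configurations."""


class DefectKind(str, Enum):
    UTR_MISSING = "UTR_MISSING"
    FUSED_MODEL = "FUSED_MODEL"
    SPLIT_MODEL = "SPLIT_MODEL"
    HIDDEN_ISOFORM = "HIDDEN_ISOFORM"
    NOVEL_GENE_UNANNOTATED = "NOVEL_GENE_UNANNOTATED"
    GENOME_BASE_DELETION = "GENOME_BASE_DELETION"
    GENOME_BASE_SUBSTITUTION = "GENOME_BASE_SUBSTITUTION"
    CONTAMINANT_CONTIG = "CONTAMINANT_CONTIG"
    SPIKEIN_CONTIG = "SPIKEIN_CONTIG"
    ARTEFACT_TRANSCRIPT = "ARTEFACT_TRANSCRIPT"


#: verdict the downstream pipeline must emit for each planted defect kind
EXPECTED_VERDICT: dict[DefectKind, str] = {
    DefectKind.UTR_MISSING: "UTR_ONLY",
    DefectKind.FUSED_MODEL: "SPLIT",
    DefectKind.SPLIT_MODEL: "MERGE",
    DefectKind.HIDDEN_ISOFORM: "NEW_ISOFORM",
    DefectKind.NOVEL_GENE_UNANNOTATED: "NOVEL_GENE",
    DefectKind.GENOME_BASE_DELETION: "GENOME_DELETION",
    DefectKind.GENOME_BASE_SUBSTITUTION: "GENOME_SUBSTITUTION",
    DefectKind.CONTAMINANT_CONTIG: "CONTAMINANT",
    DefectKind.SPIKEIN_CONTIG: "SPIKEIN_REMOVED",
    DefectKind.ARTEFACT_TRANSCRIPT: "ARTEFACT",
}

#: defect kinds that consume genomic genes (FUSED_MODEL consumes two)
_GENE_KINDS = (
    DefectKind.UTR_MISSING, DefectKind.SPLIT_MODEL, DefectKind.HIDDEN_ISOFORM,
    DefectKind.NOVEL_GENE_UNANNOTATED, DefectKind.GENOME_BASE_DELETION,
    DefectKind.GENOME_BASE_SUBSTITUTION,
)


@dataclass
class LedgerEntry:
    kind: DefectKind
    contig_id: str
    start: int
    end: int
    gene_ids: list[str]
    transcript_ids: list[str]
    expected_verdict: str
    details: dict = field(default_factory=dict)


@dataclass
class ForgeConfig:
    """Parameter envelope of the synthetic genome.

    Defaults mimic a compact AT-rich amoebozoan genome: ~32% GC, short
    (60-120 bp) GT-AG introns, 2-6 exons per gene and 100-bp reads.
    """

    seed: int = 0
    n_genes: int = 120
    gc_target: float = 0.32
    exons_per_gene_range: tuple[int, int] = (2, 6)
    intron_length_range: tuple[int, int] = (60, 120)
    utr_lengths: tuple[int, int] = (100, 150)       # 5', 3' in bp
    defect_spec: dict[DefectKind, int] = field(default_factory=dict)
    n_contigs: int = 3
    cds_codons_range: tuple[int, int] = (60, 320)
    spacer_length_range: tuple[int, int] = (250, 450)
    novel_gap_count: int = 0   # NOVEL genes withheld from the genome entirely
    expression_log_mean: float = 4.0
    expression_log_sd: float = 1.2
    read_length: int = 100
    contaminant_gc: float = 0.55
    contaminant_length_range: tuple[int, int] = (600, 1800)
    spikein_db_size: int = 8
    spikein_length_range: tuple[int, int] = (250, 1500)
    artefact_length: int = 600
    deletion_site_depth: int = 23
    substitution_site_depths: tuple[int, ...] = (56, 33)
    pileup_flank: int = 5
    target_taxon: str = "Dictyostelium discoideum"
    contaminant_taxon: str = "Escherichia coli"

    def validate(self) -> None:
        if not 0.0 < self.gc_target < 1.0:
            raise ForgeError("gc_target must lie in (0,1)")
        for name in ("exons_per_gene_range", "intron_length_range",
                     "cds_codons_range", "spacer_length_range",
                     "contaminant_length_range", "spikein_length_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ForgeError(f"{name} must be a non-empty range with min >= 1")
        if self.intron_length_range[0] < 4:
            raise ForgeError("non-defect introns need at least 4 bp (GT..AG)")
        if self.n_genes < 1 or not 1 <= self.n_contigs <= 5:
            raise ForgeError("need n_genes >= 1 and 1 <= n_contigs <= 5")
        spec = {DefectKind(k): v for k, v in self.defect_spec.items()}
        for kind, count in spec.items():
            if count < 0:
                raise ForgeError(f"negative defect count for {kind}")
        needed = sum(
            spec.get(k, 0) for k in _GENE_KINDS
        ) + 2 * spec.get(DefectKind.FUSED_MODEL, 0)
        if needed > self.n_genes:
            raise ForgeError(
                f"defect_spec consumes {needed} genes but only "
                f"{self.n_genes} are generated"
            )
        if self.novel_gap_count > spec.get(
                DefectKind.NOVEL_GENE_UNANNOTATED, 0):
            raise ForgeError("novel_gap_count exceeds planted novel genes")


# ----------------------------------------------------------------------
# sequence helpers

def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=n, p=p))


def _rand_codons(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        c = _rand_seq(rng, 3, gc)
        if c not in STOP_CODONS:
            out.append(c)
    return out


def _flip(iv: Interval, length: int) -> Interval:
    return (length - iv[1], length - iv[0])


# ----------------------------------------------------------------------
# per-gene blueprints

@dataclass
class _GeneBlock:
    gene_id: str
    kind: Optional[DefectKind]
    seq: str
    transcripts: list[TranscriptModel]      # local coords, contig filled later
    micro_intron: Optional[Interval] = None  # local, for DEL/SUB defects
    split_intron_index: Optional[int] = None
    skipped_exon: Optional[Interval] = None

    def flipped(self) -> "_GeneBlock":
        """Reverse-complement the block (gene becomes minus strand)."""
        L = len(self.seq)
        new_ts = []
        for t in self.transcripts:
            new_ts.append(TranscriptModel(
                transcript_id=t.transcript_id, gene_id=t.gene_id,
                contig_id=t.contig_id, strand="-",
                exons=[_flip(e, L) for e in t.exons],
                cds=_flip(t.cds, L) if t.cds else None,
            ))
        return replace(
            self, seq=revcomp(self.seq), transcripts=new_ts,
            micro_intron=_flip(self.micro_intron, L) if self.micro_intron else None,
            skipped_exon=_flip(self.skipped_exon, L) if self.skipped_exon else None,
            split_intron_index=(
                len(self.transcripts[0].exons) - self.split_intron_index
                if self.split_intron_index is not None else None),
        )


def _build_gene(rng: np.random.Generator, cfg: ForgeConfig, gene_id: str,
                kind: Optional[DefectKind]) -> _GeneBlock:
    e_lo, e_hi = cfg.exons_per_gene_range
    n_exons = int(rng.integers(e_lo, e_hi + 1))
    if kind is DefectKind.HIDDEN_ISOFORM:
        n_exons = max(n_exons, 3)
    if kind is DefectKind.SPLIT_MODEL:
        n_exons = max(n_exons, 2)
    min_chunk = 16 if kind in (DefectKind.GENOME_BASE_DELETION,
                               DefectKind.GENOME_BASE_SUBSTITUTION) else 12
    c_lo, c_hi = cfg.cds_codons_range
    floor = n_exons * min_chunk + 2
    if kind is DefectKind.HIDDEN_ISOFORM:
        # isoform genes stay large enough that the exon-skipped product is
        # still a plausible (>= ~50 codon) protein
        floor = max(floor, 112)
    n_codons = int(rng.integers(max(c_lo, floor), max(c_hi, floor) + 1))

    # chunk sizes in codons, each >= min_chunk, summing to n_codons
    extra = n_codons - n_exons * min_chunk
    cuts = sorted(int(x) for x in rng.integers(0, extra + 1, size=n_exons - 1))
    bounds = [0] + cuts + [extra]
    chunks = [min_chunk + bounds[i + 1] - bounds[i] for i in range(n_exons)]

    codons = (["ATG"] + _rand_codons(rng, n_codons - 2, cfg.gc_target)
              + [["TAA", "TAG", "TGA"][int(rng.integers(0, 3))]])

    defect_exon = defect_codon = None
    if kind in (DefectKind.GENOME_BASE_DELETION,
                DefectKind.GENOME_BASE_SUBSTITUTION):
        defect_exon = int(rng.integers(0, n_exons))
        lo = sum(chunks[:defect_exon]) + 7
        hi = sum(chunks[:defect_exon + 1]) - 7
        lo = max(lo, 1)                      # never the ATG
        hi = min(hi, n_codons - 1)           # never the stop
        defect_codon = int(rng.integers(lo, hi))
        codons[defect_codon] = (
            "ATT" if kind is DefectKind.GENOME_BASE_DELETION else "TTA")

    utr5 = _rand_seq(rng, cfg.utr_lengths[0], cfg.gc_target)
    utr3 = _rand_seq(rng, cfg.utr_lengths[1], cfg.gc_target)
    i_lo, i_hi = cfg.intron_length_range
    introns = []
    for _ in range(n_exons - 1):
        ilen = int(rng.integers(i_lo, i_hi + 1))
        introns.append("GT" + _rand_seq(rng, ilen - 4, cfg.gc_target) + "AG")

    parts: list[str] = []
    pos = 0

    def emit(s: str) -> None:
        nonlocal pos
        parts.append(s)
        pos += len(s)

    exons: list[Interval] = []
    micro: Optional[Interval] = None
    cds_start = cds_end = 0
    codon_at = 0
    for i in range(n_exons):
        exon_start = pos
        if i == 0:
            emit(utr5)
            cds_start = pos
        chunk = codons[codon_at:codon_at + chunks[i]]
        if defect_exon == i:
            d = defect_codon - codon_at
            emit("".join(chunk[:d]))
            exons.append((exon_start, pos))
            micro_start = pos
            # genome carries the damaged remnant of the true codon:
            # deletion: true ATT lost its final T -> 2-bp "AT" intron
            # substitution: true TTA reads TAA -> 3-bp stop-masking intron
            emit("AT" if kind is DefectKind.GENOME_BASE_DELETION else "TAA")
            micro = (micro_start, pos)
            exon_start = pos
            emit("".join(chunk[d + 1:]))
        else:
            emit("".join(chunk))
        codon_at += chunks[i]
        if i == n_exons - 1:
            cds_end = pos
            emit(utr3)
        exons.append((exon_start, pos))
        if i < n_exons - 1:
            emit(introns[i])

    transcript = TranscriptModel(
        transcript_id=f"{gene_id}.1", gene_id=gene_id, contig_id="?",
        strand="+", exons=exons, cds=(cds_start, cds_end),
    )
    block = _GeneBlock(gene_id, kind, "".join(parts), [transcript],
                       micro_intron=micro)

    if kind is DefectKind.SPLIT_MODEL:
        block.split_intron_index = int(rng.integers(1, n_exons))
    elif kind is DefectKind.HIDDEN_ISOFORM:
        # a second, exon-skipping isoform; skipped exons are pure-CDS whole
        # codons, so the shorter protein simply lacks one internal block
        internal = [j for j in range(1, n_exons - 1)
                    if n_codons - chunks[j] >= 55]
        j = (internal[int(rng.integers(0, len(internal)))] if internal
             else min(range(1, n_exons - 1), key=lambda j: chunks[j]))
        iso_exons = [e for idx, e in enumerate(exons) if idx != j]
        block.skipped_exon = exons[j]
        block.transcripts.append(TranscriptModel(
            transcript_id=f"{gene_id}.2", gene_id=gene_id, contig_id="?",
            strand="+", exons=iso_exons, cds=(cds_start, cds_end),
        ))
    return block


# ----------------------------------------------------------------------
# genome assembly

@dataclass
class ForgeOutput:
    config: ForgeConfig
    genome: dict[str, str]
    genome_records: list[SequenceRecord]
    truth: list[GeneModel]
    ledger: list[LedgerEntry]
    spikein_db: list[SequenceRecord]
    contaminants: list[SequenceRecord]
    artefacts: list[SequenceRecord]
    spike_transcripts: list[SequenceRecord]
    gap_transcripts: list[SequenceRecord]
    gene_kind: dict[str, Optional[DefectKind]]


def generate_genome(config: ForgeConfig) -> ForgeOutput:
    """Build genome contigs, truth gene models and the defect ledger.

    A pure function of the configuration (which includes the seed): the
    same config always yields byte-identical output.
    """
    config.validate()
    rng_layout = np.random.default_rng([config.seed, 0])
    rng_struct = np.random.default_rng([config.seed, 1])
    rng_extra = np.random.default_rng([config.seed, 3])
    spec = {DefectKind(k): v for k, v in config.defect_spec.items()}

    n = config.n_genes
    # contiguous index chunks => contig layout; adjacency needed for FUSED
    sizes = [n // config.n_contigs] * config.n_contigs
    for i in range(n % config.n_contigs):
        sizes[i] += 1
    sizes = [s for s in sizes if s > 0]
    chunk_of = {}
    idx = 0
    for ci, s in enumerate(sizes):
        for _ in range(s):
            chunk_of[idx] = ci
            idx += 1

    assigned: dict[int, DefectKind] = {}
    fused_pairs: list[tuple[int, int]] = []
    n_fused = spec.get(DefectKind.FUSED_MODEL, 0)
    if n_fused:
        candidates = [i for i in range(n - 1) if chunk_of[i] == chunk_of[i + 1]]
        rng_layout.shuffle(candidates)
        for i in candidates:
            if len(fused_pairs) == n_fused:
                break
            if i not in assigned and i + 1 not in assigned:
                assigned[i] = assigned[i + 1] = DefectKind.FUSED_MODEL
                fused_pairs.append((i, i + 1))
        if len(fused_pairs) < n_fused:
            raise ForgeError("could not place all FUSED_MODEL defects")
    free = [i for i in range(n) if i not in assigned]
    rng_layout.shuffle(free)
    queue: list[DefectKind] = []
    for kind in _GENE_KINDS:
        queue.extend([kind] * spec.get(kind, 0))
    for kind, i in zip(queue, free):
        assigned[i] = kind

    novel_indices = sorted(i for i, k in assigned.items()
                           if k is DefectKind.NOVEL_GENE_UNANNOTATED)
    gap_indices = set(novel_indices[:config.novel_gap_count])

    strands: dict[int, str] = {}
    for i in range(n):
        kind = assigned.get(i)
        if kind in (DefectKind.GENOME_BASE_DELETION,
                    DefectKind.GENOME_BASE_SUBSTITUTION):
            strands[i] = "+"   # keeps pileup bookkeeping on the forward strand
        elif i in strands:
            continue
        else:
            strand = "+" if rng_layout.random() < 0.5 else "-"
            strands[i] = strand
            if kind is DefectKind.FUSED_MODEL and i + 1 in assigned \
                    and assigned[i + 1] is DefectKind.FUSED_MODEL \
                    and (i, i + 1) in fused_pairs:
                strands[i + 1] = strand

    blocks: list[_GeneBlock] = []
    for i in range(n):
        gid = f"gene_{i + 1:03d}"
        block = _build_gene(rng_struct, config, gid, assigned.get(i))
        if strands[i] == "-":
            block = block.flipped()
        blocks.append(block)

    # lay blocks onto contigs with AT-rich spacers
    genome: dict[str, str] = {}
    truth: list[GeneModel] = []
    gap_transcripts: list[SequenceRecord] = []
    placed: dict[int, tuple[str, int]] = {}   # index -> (contig, offset)
    s_lo, s_hi = config.spacer_length_range
    idx = 0
    for ci, size in enumerate(sizes):
        cid = f"contig_{ci + 1}"
        parts = []
        pos = 0
        spacer = _rand_seq(rng_struct, int(rng_layout.integers(s_lo, s_hi + 1)),
                           config.gc_target)
        parts.append(spacer)
        pos += len(spacer)
        for _ in range(size):
            block = blocks[idx]
            if idx in gap_indices:
                # locus withheld from the assembly: transcript exists,
                # genome does not contain it
                t = block.transcripts[0]
                mrna = "".join(block.seq[s:e] for s, e in t.exons)
                if t.strand == "-":
                    mrna = revcomp(mrna)
                gap_transcripts.append(
                    SequenceRecord(t.transcript_id, mrna, "gap novel"))
            else:
                placed[idx] = (cid, pos)
                parts.append(block.seq)
                pos += len(block.seq)
                transcripts = []
                for t in block.transcripts:
                    off = placed[idx][1]
                    transcripts.append(TranscriptModel(
                        transcript_id=t.transcript_id, gene_id=t.gene_id,
                        contig_id=cid, strand=t.strand,
                        exons=[(s + off, e + off) for s, e in t.exons],
                        cds=(t.cds[0] + off, t.cds[1] + off),
                    ))
                truth.append(GeneModel(block.gene_id, cid,
                                       transcripts[0].strand, transcripts))
            spacer = _rand_seq(
                rng_struct, int(rng_layout.integers(s_lo, s_hi + 1)),
                config.gc_target)
            parts.append(spacer)
            pos += len(spacer)
            idx += 1
        genome[cid] = "".join(parts)

    truth_by_id = {g.gene_id: g for g in truth}

    # extra-genomic material, generated now so the ledger is complete
    spikein_db = [
        SequenceRecord(
            f"ERCC_syn_{k + 1:02d}",
            _rand_seq(rng_extra,
                      int(rng_extra.integers(*_inc(config.spikein_length_range))),
                      0.50),
            "synthetic spike-in control")
        for k in range(config.spikein_db_size)
    ]
    contaminants = [
        SequenceRecord(
            f"contam_{k + 1:02d}",
            _rand_seq(rng_extra,
                      int(rng_extra.integers(*_inc(config.contaminant_length_range))),
                      config.contaminant_gc),
            "bacterial contaminant")
        for k in range(spec.get(DefectKind.CONTAMINANT_CONTIG, 0))
    ]
    spikes = []
    for k in range(spec.get(DefectKind.SPIKEIN_CONTIG, 0)):
        src = spikein_db[int(rng_extra.integers(0, len(spikein_db)))]
        spikes.append(SequenceRecord(f"spike_{k + 1:02d}", src.sequence,
                                     f"copy of {src.id}"))
    artefacts = []
    from .orphans import flag_artefact
    for k in range(spec.get(DefectKind.ARTEFACT_TRANSCRIPT, 0)):
        for _ in range(1000):
            seq = _rand_seq(rng_extra, config.artefact_length, config.gc_target)
            if flag_artefact(seq):
                break
        else:  # pragma: no cover - would need absurd parameters
            raise ForgeError("could not forge a multi-stop artefact")
        artefacts.append(SequenceRecord(f"artefact_{k + 1:02d}", seq,
                                        "shuffled assembly artefact"))

    # ledger
    ledger: list[LedgerEntry] = []
    sub_depths = config.substitution_site_depths
    sub_i = 0
    for i in sorted(assigned):
        kind = assigned[i]
        gid = f"gene_{i + 1:03d}"
        if kind is DefectKind.FUSED_MODEL:
            if not any(i == a for a, _ in fused_pairs):
                continue      # second member; covered by the pair entry
            gid2 = f"gene_{i + 2:03d}"
            g1, g2 = truth_by_id[gid], truth_by_id[gid2]
            ledger.append(LedgerEntry(
                kind, g1.contig_id, g1.span[0], g2.span[1], [gid, gid2],
                [t.transcript_id for g in (g1, g2) for t in g.transcripts],
                EXPECTED_VERDICT[kind]))
            continue
        if kind is DefectKind.NOVEL_GENE_UNANNOTATED and i in gap_indices:
            t = blocks[i].transcripts[0]
            ledger.append(LedgerEntry(
                kind, t.transcript_id, 0, t.length, [gid],
                [t.transcript_id], "NOVEL", {"in_gap": True}))
            continue
        g = truth_by_id[gid]
        entry = LedgerEntry(kind, g.contig_id, g.span[0], g.span[1], [gid],
                            [t.transcript_id for t in g.transcripts],
                            EXPECTED_VERDICT[kind])
        block = blocks[i]
        off = placed[i][1]
        if kind is DefectKind.GENOME_BASE_DELETION:
            s, e = block.micro_intron
            entry.start, entry.end = s + off, e + off
            depth = config.deletion_site_depth
            entry.details = {"inserted_base": "T",
                             "support": [depth - 1, depth]}
        elif kind is DefectKind.GENOME_BASE_SUBSTITUTION:
            s, e = block.micro_intron
            entry.start, entry.end = s + off, e + off
            depth = int(sub_depths[sub_i % len(sub_depths)])
            sub_i += 1
            entry.details = {"alt_base": "T", "offset": 1,
                             "support": [depth, depth]}
        elif kind is DefectKind.SPLIT_MODEL:
            entry.details = {"split_intron_index": block.split_intron_index}
        elif kind is DefectKind.HIDDEN_ISOFORM:
            s, e = block.skipped_exon
            entry.details = {"skipped_exon": [s + off, e + off]}
        ledger.append(entry)
    for rec in contaminants:
        ledger.append(LedgerEntry(
            DefectKind.CONTAMINANT_CONTIG, rec.id, 0, len(rec), [], [rec.id],
            EXPECTED_VERDICT[DefectKind.CONTAMINANT_CONTIG],
            {"taxon": config.contaminant_taxon}))
    for rec in spikes:
        ledger.append(LedgerEntry(
            DefectKind.SPIKEIN_CONTIG, rec.id, 0, len(rec), [], [rec.id],
            EXPECTED_VERDICT[DefectKind.SPIKEIN_CONTIG],
            {"source": rec.description}))
    for rec in artefacts:
        ledger.append(LedgerEntry(
            DefectKind.ARTEFACT_TRANSCRIPT, rec.id, 0, len(rec), [], [rec.id],
            EXPECTED_VERDICT[DefectKind.ARTEFACT_TRANSCRIPT]))

    gene_kind = {f"gene_{i + 1:03d}": assigned.get(i) for i in range(n)}
    records = [SequenceRecord(cid, seq, "synthetic contig")
               for cid, seq in genome.items()]
    return ForgeOutput(config, genome, records, truth, ledger, spikein_db,
                       contaminants, artefacts, spikes, gap_transcripts,
                       gene_kind)


def _inc(rng_pair: tuple[int, int]) -> tuple[int, int]:
    return (rng_pair[0], rng_pair[1] + 1)


# ----------------------------------------------------------------------
# observed annotation

def plant_annotation_defects(truth: Sequence[GeneModel],
                             ledger: Sequence[LedgerEntry]) -> list[GeneModel]:
    """Derive the 'existing annotation' by damaging truth models per ledger."""
    by_id = {g.gene_id: g for g in truth}
    drop: set[str] = set()
    add: list[GeneModel] = []
    repl: dict[str, GeneModel] = {}
    for e in ledger:
        if e.kind in (DefectKind.CONTAMINANT_CONTIG, DefectKind.SPIKEIN_CONTIG,
                      DefectKind.ARTEFACT_TRANSCRIPT,
                      DefectKind.GENOME_BASE_DELETION,
                      DefectKind.GENOME_BASE_SUBSTITUTION):
            continue
        if e.kind is DefectKind.NOVEL_GENE_UNANNOTATED:
            if e.details.get("in_gap"):
                continue
            if e.gene_ids[0] not in by_id:
                raise ForgeError(f"ledger names unknown gene {e.gene_ids[0]}")
            drop.add(e.gene_ids[0])
            continue
        for gid in e.gene_ids:
            if gid not in by_id:
                raise ForgeError(f"ledger names unknown gene {gid}")
        if e.kind is DefectKind.UTR_MISSING:
            g = by_id[e.gene_ids[0]]
            t = g.transcripts[0]
            cs, ce = t.cds
            exons = [(max(s, cs), min(e2, ce)) for s, e2 in t.exons
                     if min(e2, ce) > max(s, cs)]
            repl[g.gene_id] = GeneModel(g.gene_id, g.contig_id, g.strand, [
                TranscriptModel(t.transcript_id, g.gene_id, g.contig_id,
                                g.strand, exons, (cs, ce))])
        elif e.kind is DefectKind.HIDDEN_ISOFORM:
            g = by_id[e.gene_ids[0]]
            repl[g.gene_id] = GeneModel(g.gene_id, g.contig_id, g.strand,
                                        [copy.deepcopy(g.transcripts[0])])
        elif e.kind is DefectKind.SPLIT_MODEL:
            g = by_id[e.gene_ids[0]]
            t = g.transcripts[0]
            k = e.details["split_intron_index"]
            if not 1 <= k <= len(t.exons) - 1:
                raise ForgeError(f"bad split index for {g.gene_id}")
            cs, ce = t.cds
            left, right = t.exons[:k], t.exons[k:]
            drop.add(g.gene_id)
            for tag, exons, cds in (
                    ("a", left, (max(cs, left[0][0]), left[-1][1])),
                    ("b", right, (right[0][0], min(ce, right[-1][1])))):
                gid = f"{g.gene_id}_{tag}"
                add.append(GeneModel(gid, g.contig_id, g.strand, [
                    TranscriptModel(f"{gid}.1", gid, g.contig_id, g.strand,
                                    list(exons), cds)]))
        elif e.kind is DefectKind.FUSED_MODEL:
            g1, g2 = (by_id[g] for g in e.gene_ids)
            drop.update(e.gene_ids)
            t1, t2 = g1.transcripts[0], g2.transcripts[0]
            exons = sorted(t1.exons + t2.exons)
            cds = (min(t1.cds[0], t2.cds[0]), max(t1.cds[1], t2.cds[1]))
            gid = f"{g1.gene_id}_{g2.gene_id}_fused"
            add.append(GeneModel(gid, g1.contig_id, g1.strand, [
                TranscriptModel(f"{gid}.1", gid, g1.contig_id, g1.strand,
                                exons, cds)]))
    observed: list[GeneModel] = []
    for g in truth:
        if g.gene_id in drop:
            continue
        observed.append(repl.get(g.gene_id, copy.deepcopy(g)))
    observed.extend(add)
    return observed


# ----------------------------------------------------------------------
# transcripts, read counts, pileup evidence

@dataclass
class TranscriptEvidence:
    transcripts: list[SequenceRecord]
    read_counts: dict[str, int]
    pileup: pd.DataFrame
    taxon_map: dict[str, str]


def simulate_transcripts_and_evidence(
        out: ForgeOutput, error_rate: float = 0.0,
        seed: Optional[int] = None) -> TranscriptEvidence:
    """Spliced transcripts with read counts, plus pileup columns at audit sites.

    Read counts follow a long-tailed log-normal profile; no read-level
    simulation is performed — the audited computations consume counts and
    pileup columns, not raw reads. Per-base errors are iid substitutions.
    """
    if not 0.0 <= error_rate <= 0.05:
        raise ForgeError("error rate must lie in [0, 0.05]")
    cfg = out.config
    rng = np.random.default_rng([cfg.seed if seed is None else seed, 2])

    def draw_count(scale: float = 1.0) -> int:
        x = rng.lognormal(cfg.expression_log_mean, cfg.expression_log_sd)
        return max(1, int(round(x * scale)))

    def mutate(seq: str) -> str:
        if error_rate == 0.0:
            return seq
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
        for i in hits:
            cur = arr[i].decode()
            alts = [b for b in "ACGT" if b != cur]
            arr[i] = alts[int(rng.integers(0, 3))].encode()
        return arr.tobytes().decode()

    transcripts: list[SequenceRecord] = []
    counts: dict[str, int] = {}
    taxa: dict[str, str] = {}
    for gene in out.truth:
        for t in gene.transcripts:
            seq = mutate(t.spliced_sequence(out.genome))
            transcripts.append(SequenceRecord(t.transcript_id, seq,
                                              f"from {gene.gene_id}"))
            counts[t.transcript_id] = draw_count()
            taxa[t.transcript_id] = cfg.target_taxon
    for rec in out.gap_transcripts:
        seq = mutate(rec.sequence)
        transcripts.append(SequenceRecord(rec.id, seq, rec.description))
        counts[rec.id] = draw_count()
        taxa[rec.id] = cfg.target_taxon
    for rec in out.spike_transcripts:
        transcripts.append(rec)
        counts[rec.id] = draw_count()
    for rec in out.contaminants:
        transcripts.append(rec)
        counts[rec.id] = draw_count(scale=0.25)
        taxa[rec.id] = cfg.contaminant_taxon
    for rec in out.artefacts:
        transcripts.append(rec)
        counts[rec.id] = draw_count(scale=0.1)

    rows = []
    flank = cfg.pileup_flank
    for e in out.ledger:
        if e.kind not in (DefectKind.GENOME_BASE_DELETION,
                          DefectKind.GENOME_BASE_SUBSTITUTION):
            continue
        contig = out.genome[e.contig_id]
        depth = int(e.details["support"][1])
        support = int(e.details["support"][0])
        s, iv_end = e.start, e.end
        alt_pos = s + e.details.get("offset", 0) \
            if e.kind is DefectKind.GENOME_BASE_SUBSTITUTION else None
        ins_pos = iv_end if e.kind is DefectKind.GENOME_BASE_DELETION else None
        for p in range(max(0, s - flank), min(len(contig), iv_end + flank)):
            ref = contig[p]
            base_counts = {b: 0 for b in "ACGTN"}
            if p == alt_pos:
                base_counts[e.details["alt_base"]] = support
                base_counts[ref] += depth - support
            else:
                base_counts[ref] = depth
            rows.append({
                "contig": e.contig_id, "pos": p + 1, "ref": ref,
                **base_counts,
                "ins": support if p == ins_pos else 0,
                "del": 0,
                "ins_base": e.details["inserted_base"]
                if p == ins_pos else ".",
            })
    pileup = pd.DataFrame(
        rows, columns=["contig", "pos", "ref", "A", "C", "G", "T", "N",
                       "ins", "del", "ins_base"])
    return TranscriptEvidence(transcripts, counts, pileup, taxa)


# ----------------------------------------------------------------------
# one-call convenience

@dataclass
class ForgeRun:
    output: ForgeOutput
    observed: list[GeneModel]
    evidence: TranscriptEvidence

    @property
    def config(self) -> ForgeConfig:
        return self.output.config

    @property
    def genome(self) -> dict[str, str]:
        return self.output.genome

    @property
    def truth(self) -> list[GeneModel]:
        return self.output.truth

    @property
    def ledger(self) -> list[LedgerEntry]:
        return self.output.ledger


def run_forge(config: ForgeConfig, error_rate: float = 0.0) -> ForgeRun:
    out = generate_genome(config)
    observed = plant_annotation_defects(out.truth, out.ledger)
    evidence = simulate_transcripts_and_evidence(out, error_rate)
    return ForgeRun(out, observed, evidence)
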