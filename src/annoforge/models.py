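"""Core domain types shared across the pipeline.

Coordinate convention, binding for every module: in memory all intervals are
0-based half-open ``[start, end)`` on the forward strand of their contig.
GFF3 on disk is 1-based inclusive; the conversion happens only in
:mod:`annoforge.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a coding sequence with the standard genetic code.

    Trailing incomplete codons are ignored; stop codons appear as ``*``.
    """
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


class ModelError(ValueError):
    """Raised when a gene/transcript model violates its structural invariants."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (uppercase A/C/G/T/N)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("sequence record with empty id")
        if not self.sequence:
            raise ModelError(f"sequence record {self.id!r} has empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ModelError(
                f"sequence record {self.id!r} contains non-IUPAC characters: "
                f"{sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TranscriptModel:
    """One transcript: ordered exons plus an optional CDS interval.

    ``exons`` are genome-forward intervals sorted by start regardless of
    strand; ``cds`` is a single genome interval whose per-exon segments are
    the intersections with the exons (the usual GFF CDS rows).
    """

    transcript_id: str
    gene_id: str
    contig_id: str
    strand: str
    exons: list[Interval]
    cds: Optional[Interval] = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ModelError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ModelError(f"{self.transcript_id}: no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ModelError(f"{self.transcript_id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise ModelError(f"{self.transcript_id}: overlapping exons")
            prev_end = e
        if self.cds is not None:
            cs, ce = self.cds
            if not (self.exons[0][0] <= cs < ce <= self.exons[-1][1]):
                raise ModelError(
                    f"{self.transcript_id}: CDS {self.cds} outside exon span"
                )

    # ------------------------------------------------------------------
    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> list[Interval]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    def cds_segments(self) -> list[Interval]:
        """CDS rows: intersection of the CDS interval with each exon."""
        if self.cds is None:
            return []
        cs, ce = self.cds
        segs = []
        for s, e in self.exons:
            lo, hi = max(s, cs), min(e, ce)
            if lo < hi:
                segs.append((lo, hi))
        return segs

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        """mRNA sequence: exon slices concatenated, 5'→3' on the coding strand."""
        contig = genome[self.contig_id]
        seq = "".join(contig[s:e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_sequence(self, genome: dict[str, str]) -> str:
        """Spliced coding sequence, 5'→3' on the coding strand."""
        contig = genome[self.contig_id]
        seq = "".join(contig[s:e] for s, e in self.cds_segments())
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class GeneModel:
    """A gene: one or more transcripts sharing contig and strand."""

    gene_id: str
    contig_id: str
    strand: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ModelError(f"{self.gene_id}: gene without transcripts")
        for t in self.transcripts:
            if t.contig_id != self.contig_id or t.strand != self.strand:
                raise ModelError(
                    f"{self.gene_id}: transcript {t.transcript_id} disagrees on "
                    "contig/strand"
                )

    @property
    def span(self) -> Interval:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )


@dataclass
class TranscriptAlignment:
    """A spliced transcript-to-genome alignment.

    ``blocks`` are gapless (qstart, qend, tstart, tend) pieces, co-linear and
    non-overlapping on both axes; for strand '-' the query coordinates refer
    to the reverse-complemented transcript (PSL convention).
    """

    transcript_id: str
    contig_id: str
    strand: str
    blocks: list[tuple[int, int, int, int]]
    identity: float
    coverage: float

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ModelError(f"{self.transcript_id}: alignment without blocks")
        prev = None
        for qs, qe, ts, te in self.blocks:
            if qe - qs != te - ts or qe <= qs:
                raise ModelError(f"{self.transcript_id}: malformed block")
            if prev is not None and (qs < prev[1] or ts < prev[3]):
                raise ModelError(f"{self.transcript_id}: blocks not co-linear")
            prev = (qs, qe, ts, te)
        if not (0.0 <= self.identity <= 1.0 and 0.0 <= self.coverage <= 1.0):
            raise ModelError(f"{self.transcript_id}: identity/coverage out of range")

    @property
    def aligned_bases(self) -> int:
        return sum(qe - qs for qs, qe, _, _ in self.blocks)

    @property
    def target_span(self) -> Interval:
        return (self.blocks[0][2], self.blocks[-1][3])

    def exon_intervals(self) -> list[Interval]:
        """Genome exon intervals: blocks merged across zero target gaps."""
        exons: list[list[int]] = []
        for qs, qe, ts, te in self.blocks:
            if exons and ts == exons[-1][1]:
                exons[-1][1] = te
            else:
                exons.append([ts, te])
        return [(s, e) for s, e in exons]
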