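"""Summary statistics for transcript sets: N50, E90N50, GC content.

E90N50 is the N50 recomputed over the most highly expressed transcripts
that together account for 90% of the mapped reads — fragmentation among
barely-expressed contigs then no longer drags the statistic down.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .models import GeneModel, SequenceRecord


@dataclass
class AssemblyStats:
    total_transcripts: int
    n_ge_1000: int
    gc_percent: float
    max_length: int
    n50: int
    e90n50: int
    mean_length: float
    total_bases: int
    n_exons: Optional[int] = None
    mean_exons_per_transcript: Optional[float] = None

    def rows(self) -> list[tuple[str, object]]:
        out: list[tuple[str, object]] = [
            ("Total transcripts", self.total_transcripts),
            ("Transcripts >= 1000 bp", self.n_ge_1000),
            ("GC content (%)", self.gc_percent),
            ("Maximum transcript length (bp)", self.max_length),
            ("Contig N50", self.n50),
            ("Contig E90N50", self.e90n50),
            ("Mean length (bp)", self.mean_length),
            ("Total assembled bases", self.total_bases),
        ]
        if self.n_exons is not None:
            out.append(("No. exons", self.n_exons))
            out.append(("Mean exons/transcript", self.mean_exons_per_transcript))
        return out


def contig_n50(lengths: Sequence[int]) -> int:
    """Largest length L such that contigs >= L hold at least half of all bases.

    Evaluated over lengths sorted descending; the first length at which the
    running sum reaches half the total is returned, so the result is always
    a member of the input.
    """
    if not lengths:
        raise ValueError("contig_n50 of an empty length set")
    if any(x < 1 for x in lengths):
        raise ValueError("contig lengths must be >= 1")
    half = sum(lengths) / 2
    running = 0
    for x in sorted(lengths, reverse=True):
        running += x
        if running >= half:
            return x
    raise AssertionError("unreachable")


def e90n50(lengths: Sequence[int], read_counts: Sequence[int],
           ids: Optional[Sequence[str]] = None) -> int:
    """N50 of the minimal most-expressed prefix holding >= 90% of reads.

    Transcripts are ranked by read count descending; ties break by longer
    length first, then lexicographic id (when ids are given) so the prefix
    is deterministic. The transcript straddling the 90% boundary is
    included.
    """
    if len(lengths) != len(read_counts):
        raise ValueError("lengths and read_counts must be parallel")
    if any(c < 0 for c in read_counts):
        raise ValueError("read counts must be >= 0")
    total = sum(read_counts)
    if total == 0:
        raise ValueError("e90n50 undefined for all-zero read counts")
    if ids is None:
        ids = [""] * len(lengths)
    order = sorted(
        range(len(lengths)),
        key=lambda i: (-read_counts[i], -lengths[i], ids[i]),
    )
    threshold = 0.9 * total
    running = 0
    prefix: list[int] = []
    for i in order:
        prefix.append(lengths[i])
        running += read_counts[i]
        if running >= threshold:
            break
    return contig_n50(prefix)


def gc_fraction(sequences: Iterable[str]) -> float:
    """(G+C) / (A+C+G+T) over all sequences; N is excluded from the denominator."""
    gc = acgt = 0
    empty = True
    for seq in sequences:
        empty = False
        for base in seq:
            if base in "GC":
                gc += 1
                acgt += 1
            elif base in "AT":
                acgt += 1
    if empty:
        raise ValueError("gc_fraction of an empty sequence set")
    if acgt == 0:
        raise ValueError("gc_fraction undefined: no A/C/G/T bases")
    return gc / acgt


def summarize(transcripts: Sequence[SequenceRecord],
              read_counts: dict[str, int],
              models: Optional[Sequence[GeneModel]] = None) -> AssemblyStats:
    """Assembly summary table for a transcript set with read counts."""
    if not transcripts:
        raise ValueError("summarize of an empty transcript set")
    missing = [t.id for t in transcripts if t.id not in read_counts]
    if missing:
        raise ValueError(f"transcripts without read counts: {missing}")
    lengths = [len(t) for t in transcripts]
    counts = [read_counts[t.id] for t in transcripts]
    ids = [t.id for t in transcripts]
    total_bases = sum(lengths)
    n_exons = mean_ex = None
    if models is not None:
        mts = [t for g in models for t in g.transcripts]
        n_exons = sum(len(t.exons) for t in mts)
        mean_ex = round(n_exons / len(mts), 2) if mts else 0.0
    return AssemblyStats(
        total_transcripts=len(transcripts),
        n_ge_1000=sum(1 for x in lengths if x >= 1000),
        gc_percent=round(100 * gc_fraction(t.sequence for t in transcripts), 1),
        max_length=max(lengths),
        n50=contig_n50(lengths),
        e90n50=e90n50(lengths, counts, ids),
        mean_length=round(total_bases / len(lengths), 1),
        total_bases=total_bases,
        n_exons=n_exons,
        mean_exons_per_transcript=mean_ex,
    )
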