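"""Transcript-to-genome spliced mapping, acceptance filtering and locus assembly.

The mapper is a deterministic seed-and-chain aligner built for compact
genomes: exact k-mer seeds are grouped per diagonal (isolated substitutions
break seeds but stay on the diagonal), merged runs become gapless blocks,
and blocks are chained co-linearly with genome gaps up to ``max_intron``
acting as introns. Junction placement prefers canonical GT-AG dinucleotides
on the coding strand; where that is impossible the leftmost
score-preserving placement is used. Both strands are always searched.

Accepted alignments (identity and transcript coverage at or above the
thresholds) are clustered transitively by exon overlap on the same contig
and strand into loci, each exposing its distinct exon-chain variants —
candidate isoforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .models import SequenceRecord, TranscriptAlignment, revcomp

DEFAULT_KMER = 15
DEFAULT_MAX_INTRON = 5000
MERGE_GAP = 50          # same-diagonal seed runs merged across gaps this size
MAX_QGAP = 50           # unaligned query bases tolerated at a junction


class GenomeIndex:
    """Exact k-mer index of a genome (forward strand)."""

    def __init__(self, genome: dict[str, str], k: int = DEFAULT_KMER):
        self.k = k
        self.genome = genome
        self.index: dict[str, list[tuple[str, int]]] = {}
        for contig, seq in genome.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i:i + k], []).append((contig, i))

    def seeds(self, query: str) -> dict[str, dict[int, list[int]]]:
        """contig -> diagonal -> sorted query positions of seed hits."""
        out: dict[str, dict[int, list[int]]] = {}
        k = self.k
        for q in range(len(query) - k + 1):
            for contig, t in self.index.get(query[q:q + k], ()):
                out.setdefault(contig, {}).setdefault(t - q, []).append(q)
        return out


@dataclass
class AlignmentVerdict:
    transcript_id: str
    status: str                      # GOOD | FAILED
    alignment: Optional[TranscriptAlignment] = None
    reason: str = ""


@dataclass
class LocusStructure:
    """One distinct exon chain at a locus, with its supporting transcripts."""

    structure_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]]
    transcript_ids: list[str] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(self.exons[i][1], self.exons[i + 1][0])
                for i in range(len(self.exons) - 1)]

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        seq = "".join(genome[self.contig_id][s:e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class Locus:
    locus_id: str
    contig_id: str
    strand: str
    structures: list[LocusStructure]

    @property
    def span(self) -> tuple[int, int]:
        return (min(s.span[0] for s in self.structures),
                max(s.span[1] for s in self.structures))


# ----------------------------------------------------------------------
# mapping

def _chain_blocks(blocks: list[list[int]], max_intron: int) -> list[list[int]]:
    """Best co-linear chain by dynamic programming over [qs, qe, ts, te] blocks."""
    blocks = sorted(blocks, key=lambda b: (b[0], b[2]))
    n = len(blocks)
    score = [0.0] * n
    back = [-1] * n
    for i, b in enumerate(blocks):
        score[i] = float(b[1] - b[0])
        for j in range(i):
            a = blocks[j]
            if a[1] >= b[1] or a[3] >= b[3]:
                continue
            overlap = max(0, a[1] - b[0])
            qgap = max(0, b[0] - a[1])
            tgap = (b[2] + overlap) - a[3]
            if tgap < 0 or tgap > max_intron or qgap > MAX_QGAP:
                continue
            gain = b[1] - max(b[0], a[1])
            if score[j] + gain > score[i]:
                score[i] = score[j] + gain
                back[i] = j
    best = max(range(n), key=lambda i: score[i])
    chain = []
    while best != -1:
        chain.append(blocks[best])
        best = back[best]
    return [list(b) for b in reversed(chain)]


def _junction_bases(strand: str) -> tuple[str, str]:
    # canonical GT..AG on the coding strand, expressed on the plus strand
    return ("GT", "AG") if strand == "+" else ("CT", "AC")


def _refine_chain(q: str, contig: str, chain: list[list[int]],
                  strand: str) -> list[list[int]]:
    """Trim overlaps, absorb unaligned junction bases, place junctions.

    After refinement consecutive blocks abut on the query; every internal
    query base is inside a block (possibly as a mismatch).
    """
    donor, acceptor = _junction_bases(strand)
    out = [chain[0][:]]
    for b in chain[1:]:
        a = out[-1]
        b = b[:]
        if b[0] < a[1]:                       # trim query overlap off b
            o = a[1] - b[0]
            b[0] += o
            b[2] += o
        qgap = b[0] - a[1]
        tgap = b[2] - a[3]
        if qgap > 0:
            # distribute unaligned query bases; intron length is fixed at
            # tgap - qgap regardless of the split point
            best_s, best_score, best_canon = 0, -1, False
            for s in range(qgap + 1):
                left = sum(1 for j in range(s)
                           if q[a[1] + j] == contig[a[3] + j])
                right = sum(1 for j in range(qgap - s)
                            if q[b[0] - 1 - j] == contig[b[2] - 1 - j])
                i_start, i_end = a[3] + s, b[2] - (qgap - s)
                canon = (contig[i_start:i_start + 2] == donor
                         and contig[i_end - 2:i_end] == acceptor
                         and i_end - i_start >= 4)
                key = (left + right, canon)
                if key > (best_score, best_canon):
                    best_score, best_canon, best_s = left + right, canon, s
            a[1] += best_s
            a[3] += best_s
            b[0] -= qgap - best_s
            b[2] -= qgap - best_s
            qgap, tgap = 0, b[2] - a[3]
        if tgap == 0:                          # same diagonal: merge
            a[1], a[3] = b[1], b[3]
            continue
        # score-preserving junction shift, preferring canonical dinucleotides
        max_r = 0
        while (b[0] + max_r < b[1]
               and q[a[1] + max_r] == contig[a[3] + max_r]):
            max_r += 1
        max_l = 0
        while (a[1] - max_l > a[0]
               and q[a[1] - 1 - max_l] == contig[b[2] - 1 - max_l]):
            max_l += 1
        chosen = 0
        found = False
        for d in range(-max_l, max_r + 1):     # leftmost canonical wins
            i_start, i_end = a[3] + d, b[2] + d
            if (i_end - i_start >= 4 and contig[i_start:i_start + 2] == donor
                    and contig[i_end - 2:i_end] == acceptor):
                chosen, found = d, True
                break
        if not found:
            chosen = -max_l                    # leftmost placement
        a[1] += chosen
        a[3] += chosen
        b[0] += chosen
        b[2] += chosen
        out.append(b)
    return out


def map_transcript(record: SequenceRecord, index: GenomeIndex,
                   max_intron: int = DEFAULT_MAX_INTRON,
                   min_seed_run: int = 0) -> list[TranscriptAlignment]:
    """Spliced alignments of one transcript, best (most matches) first."""
    results: list[TranscriptAlignment] = []
    k = index.k
    for strand in "+-":
        q = record.sequence if strand == "+" else revcomp(record.sequence)
        for contig_id, diags in index.seeds(q).items():
            contig = index.genome[contig_id]
            blocks: list[list[int]] = []
            for diag, qpos in diags.items():
                qpos.sort()
                start = prev = qpos[0]
                for p in qpos[1:] + [None]:
                    if p is None or p - prev > MERGE_GAP:
                        if prev + k - start >= max(k, min_seed_run):
                            blocks.append([start, prev + k,
                                           start + diag, prev + k + diag])
                        if p is not None:
                            start = p
                    if p is not None:
                        prev = p
            if not blocks:
                continue
            chain = _chain_blocks(blocks, max_intron)
            chain = _refine_chain(q, contig, chain, strand)
            # terminal extension while bases match
            a = chain[0]
            while a[0] > 0 and a[2] > 0 and q[a[0] - 1] == contig[a[2] - 1]:
                a[0] -= 1
                a[2] -= 1
            b = chain[-1]
            while (b[1] < len(q) and b[3] < len(contig)
                   and q[b[1]] == contig[b[3]]):
                b[1] += 1
                b[3] += 1
            aligned = sum(e[1] - e[0] for e in chain)
            matches = sum(
                1 for qs, qe, ts, te in chain
                for j in range(qe - qs) if q[qs + j] == contig[ts + j]
            )
            results.append(TranscriptAlignment(
                transcript_id=record.id, contig_id=contig_id, strand=strand,
                blocks=[tuple(e) for e in chain],
                identity=matches / aligned if aligned else 0.0,
                coverage=aligned / len(q),
            ))
    results.sort(key=lambda a: (-a.identity * a.aligned_bases, a.contig_id,
                                a.strand))
    return results


# ----------------------------------------------------------------------
# acceptance filter

def accept_alignment(a: Optional[TranscriptAlignment],
                     min_identity: float = 0.95,
                     min_coverage: float = 0.90,
                     transcript_id: str = "") -> AlignmentVerdict:
    """GOOD iff identity >= min_identity and coverage >= min_coverage.

    Both boundaries are inclusive; a missing alignment fails outright.
    """
    if a is None:
        return AlignmentVerdict(transcript_id, "FAILED", None, "no alignment")
    reasons = []
    if a.identity < min_identity:
        reasons.append(f"identity {a.identity:.4f} < {min_identity}")
    if a.coverage < min_coverage:
        reasons.append(f"coverage {a.coverage:.4f} < {min_coverage}")
    if reasons:
        return AlignmentVerdict(a.transcript_id, "FAILED", a,
                                "; ".join(reasons))
    return AlignmentVerdict(a.transcript_id, "GOOD", a)


def filter_transcripts(records: Sequence[SequenceRecord], index: GenomeIndex,
                       min_identity: float = 0.95, min_coverage: float = 0.90,
                       max_intron: int = DEFAULT_MAX_INTRON
                       ) -> list[AlignmentVerdict]:
    """Map every transcript and apply the acceptance filter to its best hit."""
    verdicts = []
    for rec in records:
        hits = map_transcript(rec, index, max_intron=max_intron)
        verdicts.append(accept_alignment(hits[0] if hits else None,
                                         min_identity, min_coverage,
                                         transcript_id=rec.id))
    return verdicts


# ----------------------------------------------------------------------
# locus assembly

def _exon_overlap(a: Sequence[tuple[int, int]],
                  b: Sequence[tuple[int, int]]) -> bool:
    for s1, e1 in a:
        for s2, e2 in b:
            if min(e1, e2) > max(s1, s2):
                return True
    return False


def assemble_loci(verdicts: Sequence[AlignmentVerdict]) -> list[Locus]:
    """Cluster GOOD alignments into loci by transitive exon overlap.

    Alignments on the same contig and strand sharing at least 1 bp of exon
    overlap merge into one locus; each locus lists its distinct exon-chain
    variants with the transcripts supporting each.
    """
    good = [v.alignment for v in verdicts if v.status == "GOOD"]
    items = [(a, a.exon_intervals()) for a in good]
    parent = list(range(len(items)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            ai, aj = items[i][0], items[j][0]
            if ai.contig_id != aj.contig_id or ai.strand != aj.strand:
                continue
            if _exon_overlap(items[i][1], items[j][1]):
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(len(items)):
        groups.setdefault(find(i), []).append(i)

    loci = []
    for members in sorted(groups.values(),
                          key=lambda ms: (items[ms[0]][0].contig_id,
                                          min(items[m][1][0][0] for m in ms))):
        a0 = items[members[0]][0]
        variants: dict[tuple, LocusStructure] = {}
        for m in sorted(members,
                        key=lambda m: items[m][0].transcript_id):
            a, exons = items[m]
            key = tuple(exons)
            if key not in variants:
                variants[key] = LocusStructure(
                    structure_id="", contig_id=a.contig_id, strand=a.strand,
                    exons=list(exons))
            variants[key].transcript_ids.append(a.transcript_id)
        locus_id = f"locus_{len(loci) + 1:04d}"
        structures = sorted(variants.values(), key=lambda s: (s.span, s.exons))
        for si, s in enumerate(structures, 1):
            s.structure_id = f"{locus_id}.s{si}"
        loci.append(Locus(locus_id, a0.contig_id, a0.strand, structures))
    return loci
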