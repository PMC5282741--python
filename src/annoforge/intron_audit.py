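"""Micro-intron scan and genome-error audit with read-pileup evidence.

Splicing needs a two-base donor, a two-base acceptor and a branch point,
so an annotated intron shorter than 5 bp cannot be real: it is almost
always a compensating construct a curator (or pipeline) added to keep a
reading frame intact over a genome-sequence error. Two error mechanisms
are recognised from pileup evidence:

* a single-base insertion supported by the reads immediately at an intron
  boundary → the genome is missing a base (GENOME_DELETION); the intron
  bases plus the inserted base re-enter the CDS as in-frame codon(s);
* a unanimous (or near-unanimous) substitution inside the intron that
  abolishes an in-intron stop codon → a genome base is wrong
  (GENOME_SUBSTITUTION); the corrected intron bases re-enter the CDS.

Each call proposes a local repair and its protein-level consequence, and
the repaired CDS is re-translated to confirm the premature stop is gone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from Bio.SeqUtils import seq3

from .models import (GeneModel, Interval, STOP_CODONS, TranscriptModel,
                     revcomp, translate)

DEFAULT_MAX_INTRON_FLAG = 5
DEFAULT_MIN_SUPPORT = 0.8
DEFAULT_MIN_DEPTH = 5
BOUNDARY_WINDOW = 2      # bp around either intron boundary searched for
                         # insertion evidence ("immediately after the intron")


@dataclass
class MicroIntronSite:
    gene_id: str
    transcript_id: str
    contig_id: str
    strand: str
    interval: Interval
    sequence: str        # plus-strand genome slice
    donor: str           # read on the coding strand
    acceptor: str

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class GenomeErrorCall:
    site: MicroIntronSite
    call: str                        # GENOME_DELETION | GENOME_SUBSTITUTION | NO_CALL
    supporting_reads: int = 0
    covering_reads: int = 0
    inserted_base: str = ""          # plus-strand, for deletions
    substitution: Optional[tuple[int, str]] = None   # (offset in intron, alt base)
    reason: str = ""

    @property
    def support(self) -> float:
        return (self.supporting_reads / self.covering_reads
                if self.covering_reads else 0.0)


@dataclass
class RepairResult:
    status: str                      # REPAIRED | REPAIR_FAILED
    repaired_cds: str = ""
    consequence: str = ""
    fail_position: Optional[int] = None


# ----------------------------------------------------------------------

def find_micro_introns(models: Sequence[GeneModel], genome: dict[str, str],
                       max_intron_flag: int = DEFAULT_MAX_INTRON_FLAG
                       ) -> list[MicroIntronSite]:
    """All introns shorter than ``max_intron_flag`` bp (strict), sorted."""
    from .io import introns_of

    sites = []
    for gene in models:
        for t in gene.transcripts:
            for (s, e), donor, acceptor in introns_of(t, genome):
                if e - s < max_intron_flag:
                    sites.append(MicroIntronSite(
                        gene_id=gene.gene_id,
                        transcript_id=t.transcript_id,
                        contig_id=gene.contig_id, strand=gene.strand,
                        interval=(s, e),
                        sequence=genome[gene.contig_id][s:e],
                        donor=donor, acceptor=acceptor))
    sites.sort(key=lambda x: (x.contig_id, x.interval, x.transcript_id))
    return sites


def _pileup_lookup(pileup: pd.DataFrame) -> dict[tuple[str, int], pd.Series]:
    return {(row.contig, int(row.pos) - 1): row
            for row in pileup.itertuples(index=False)}


def _coding(seq: str, strand: str) -> str:
    return revcomp(seq) if strand == "-" else seq


def audit_site(site: MicroIntronSite, pileup: pd.DataFrame,
               min_support: float = DEFAULT_MIN_SUPPORT,
               min_depth: int = DEFAULT_MIN_DEPTH,
               _lookup: Optional[dict] = None) -> GenomeErrorCall:
    """Test one micro-intron site for genome-error evidence in the pileup.

    Support is recorded exactly as supporting/covering read counts; a call
    requires support >= min_support and coverage >= min_depth.
    """
    cols = _lookup if _lookup is not None else _pileup_lookup(pileup)
    s, e = site.interval
    contig = site.contig_id

    # insertion evidence within +-BOUNDARY_WINDOW of either boundary
    best = None
    for p in sorted(set(range(s - BOUNDARY_WINDOW, s + BOUNDARY_WINDOW + 1))
                    | set(range(e - BOUNDARY_WINDOW, e + BOUNDARY_WINDOW + 1))):
        row = cols.get((contig, p))
        if row is None:
            continue
        covering = row.A + row.C + row.G + row.T + row.N
        if row.ins > 0 and (best is None or row.ins / covering > best[0]):
            best = (row.ins / max(covering, 1), int(row.ins), int(covering),
                    str(row.ins_base))
    if best is not None and best[2] >= min_depth and best[0] >= min_support:
        return GenomeErrorCall(site, "GENOME_DELETION",
                               supporting_reads=best[1],
                               covering_reads=best[2],
                               inserted_base=best[3])

    # substitution evidence: an identical in-intron edit removing a stop
    depth_seen = 0
    for off in range(e - s):
        row = cols.get((contig, s + off))
        if row is None:
            continue
        covering = row.A + row.C + row.G + row.T + row.N
        depth_seen = max(depth_seen, covering)
        if covering < min_depth:
            continue
        for base in "ACGT":
            count = getattr(row, base)
            if base == row.ref or count / covering < min_support:
                continue
            fixed = site.sequence[:off] + base + site.sequence[off + 1:]
            if _removes_stop(site.sequence, fixed, site.strand):
                return GenomeErrorCall(site, "GENOME_SUBSTITUTION",
                                       supporting_reads=int(count),
                                       covering_reads=int(covering),
                                       substitution=(off, base))
            return GenomeErrorCall(
                site, "NO_CALL", supporting_reads=int(count),
                covering_reads=int(covering),
                reason="supported substitution does not remove an "
                       "in-intron stop codon")
    if depth_seen < min_depth:
        return GenomeErrorCall(site, "NO_CALL", covering_reads=depth_seen,
                               reason=f"covering reads {depth_seen} < "
                                      f"min_depth {min_depth}")
    return GenomeErrorCall(site, "NO_CALL", covering_reads=depth_seen,
                           reason="no supported edit at site")


def _removes_stop(original: str, fixed: str, strand: str) -> bool:
    """Did the edit abolish a stop codon read in-frame on the coding strand?"""
    orig, fix = _coding(original, strand), _coding(fixed, strand)
    if len(orig) % 3 != 0:
        return False
    for i in range(0, len(orig), 3):
        if orig[i:i + 3] in STOP_CODONS and fix[i:i + 3] not in STOP_CODONS:
            return True
    return False


# ----------------------------------------------------------------------

def propose_repair(call: GenomeErrorCall, genome: dict[str, str],
                   model: TranscriptModel) -> RepairResult:
    """Re-enter the intron bases into the CDS and translate the consequence.

    For a GENOME_DELETION the supported inserted base joins the intron
    bases; for a GENOME_SUBSTITUTION the corrected intron bases re-enter
    as-is. The repaired CDS must translate without a premature stop.
    """
    if call.call == "NO_CALL":
        raise ValueError("cannot repair a NO_CALL")
    site = call.site
    s, e = site.interval
    insert_plus = genome[site.contig_id][s:e]
    if call.call == "GENOME_DELETION":
        base = call.inserted_base
        if site.strand == "-":
            # pileup bases are plus-strand; insertion goes 3' of the intron
            # in transcript direction = genome-left of the interval
            insert_plus = revcomp(base) + insert_plus if base else insert_plus
        else:
            insert_plus = insert_plus + base
    else:
        off, alt = call.substitution
        insert_plus = insert_plus[:off] + alt + insert_plus[off + 1:]

    if len(insert_plus) % 3 != 0:
        return RepairResult("REPAIR_FAILED",
                            consequence="repair does not restore the frame",
                            fail_position=s)

    # rebuild the CDS with the repaired bases re-entered at the intron
    segs = model.cds_segments()
    parts = []
    for i, (cs, ce) in enumerate(segs):
        parts.append(genome[model.contig_id][cs:ce])
        if i + 1 < len(segs) and segs[i][1] <= s and e <= segs[i + 1][0]:
            parts.append(insert_plus)
    repaired_plus = "".join(parts)
    repaired = _coding(repaired_plus, model.strand)
    pep = translate(repaired)
    body = pep[:-1] if pep.endswith("*") else pep
    if "*" in body:
        return RepairResult("REPAIR_FAILED", repaired_cds=repaired,
                            consequence="premature stop remains after repair",
                            fail_position=body.index("*"))

    original = translate(model.cds_sequence(genome))
    original = original[:-1] if original.endswith("*") else original
    gained = _inserted_block(original, body)
    names = "".join(seq3(a) for a in gained) if gained else "?"
    consequence = f"+{len(gained)} {names}" if gained else "no residue gained"
    if call.call == "GENOME_SUBSTITUTION":
        orig_coding = _coding(genome[site.contig_id][s:e], site.strand)
        if any(orig_coding[i:i + 3] in STOP_CODONS
               for i in range(0, len(orig_coding), 3)):
            consequence += ", stop removed"
    return RepairResult("REPAIRED", repaired_cds=repaired,
                        consequence=consequence)


def _inserted_block(short: str, long: str) -> str:
    if len(long) <= len(short):
        return ""
    p = 0
    while p < len(short) and short[p] == long[p]:
        p += 1
    s = 0
    while s < len(short) - p and short[-1 - s] == long[-1 - s]:
        s += 1
    if p + s >= len(short):
        return long[p:len(long) - s]
    return ""


# ----------------------------------------------------------------------

def audit_report(models: Sequence[GeneModel], genome: dict[str, str],
                 pileup: pd.DataFrame,
                 max_intron_flag: int = DEFAULT_MAX_INTRON_FLAG,
                 min_support: float = DEFAULT_MIN_SUPPORT,
                 min_depth: int = DEFAULT_MIN_DEPTH
                 ) -> tuple[list[GenomeErrorCall], pd.DataFrame, dict]:
    """Audit every micro-intron; return calls, a site table and a rollup."""
    sites = find_micro_introns(models, genome, max_intron_flag)
    lookup = _pileup_lookup(pileup)
    calls = [audit_site(site, pileup, min_support, min_depth, _lookup=lookup)
             for site in sites]
    rows = []
    for c in calls:
        site = c.site
        repair = None
        if c.call != "NO_CALL":
            model = next(t for g in models if g.gene_id == site.gene_id
                         for t in g.transcripts
                         if t.transcript_id == site.transcript_id)
            repair = propose_repair(c, genome, model)
        rows.append({
            "contig": site.contig_id,
            "start": site.interval[0],
            "end": site.interval[1],
            "gene_id": site.gene_id,
            "transcript_id": site.transcript_id,
            "strand": site.strand,
            "length": site.length,
            "intron_seq": site.sequence,
            "donor": site.donor,
            "acceptor": site.acceptor,
            "call": c.call,
            "supporting": c.supporting_reads,
            "covering": c.covering_reads,
            "support": round(c.support, 4),
            "repair_status": repair.status if repair else "",
            "consequence": repair.consequence if repair else "",
            "reason": c.reason,
        })
    table = pd.DataFrame(rows)
    genes = {s.gene_id for s in sites}
    per_gene: dict[str, int] = {}
    for s in sites:
        per_gene[s.gene_id] = per_gene.get(s.gene_id, 0) + 1
    rollup = {
        "n_sites": len(sites),
        "n_genes": len(genes),
        "n_multi_site_genes": sum(1 for v in per_gene.values() if v > 1),
        "n_calls": sum(1 for c in calls if c.call != "NO_CALL"),
    }
    return calls, table, rollup
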