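"""Readers and writers for the on-disk formats the pipeline touches.

FASTA is handled through Biopython, GFF3 parsing through gffutils. The
GFF3 subset used is gene/mRNA/exon/CDS with ID/Parent/Name attributes;
file coordinates are 1-based inclusive and are converted to the in-memory
0-based half-open convention here and only here.

Tab-separated dialects (documented in the README):

* ``read_counts.tsv`` — transcript_id, count
* ``taxon.tsv`` — contig_id, taxon label
* ``pileup.tsv`` — contig, pos (1-based), ref, A, C, G, T, N, ins, del,
  ins_base (most frequent inserted base, ``.`` if none)
* ``alignments.tsv`` — a 12-column PSL-like table, one row per alignment
* ``ledger.tsv`` — the forge's planted-defect truth table
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (GeneModel, Interval, ModelError, SequenceRecord,
                     TranscriptModel, revcomp)

PILEUP_COLUMNS = [
    "contig", "pos", "ref", "A", "C", "G", "T", "N", "ins", "del", "ins_base",
]

ALIGNMENT_COLUMNS = [
    "transcript_id", "contig", "strand", "identity", "coverage",
    "qstart", "qend", "tstart", "tend", "blocks", "matches", "aligned",
]


class ParseError(ValueError):
    """Raised when an input file fails validation."""


# ----------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated, uppercased records.

    Duplicate ids, empty sequences and non-IUPAC characters raise
    :class:`ParseError` naming the offending record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        try:
            records.append(SequenceRecord(rec.id, str(rec.seq), desc))
        except ModelError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                wrap: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seqs)


def genome_dict(records: Iterable[SequenceRecord]) -> dict[str, str]:
    """Contig id → sequence mapping used throughout the pipeline."""
    return {r.id: r.sequence for r in records}


# ----------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into :class:`GeneModel` objects.

    Validates the gene → mRNA → exon/CDS hierarchy: orphan Parents, exons
    outside their gene span and CDS outside the exon union all raise
    :class:`ParseError`.
    """
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises plain exceptions on bad input
        raise ParseError(f"{path}: {exc}") from exc

    # orphan Parent check: gffutils silently tolerates them
    known_ids = {f.id for f in db.all_features()}
    for feat in db.all_features():
        for parent in feat.attributes.get("Parent", []):
            if parent not in known_ids:
                raise ParseError(
                    f"{path}: feature {feat.id!r} names unknown Parent {parent!r}"
                )

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts: list[TranscriptModel] = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons: list[Interval] = []
            cds_segs: list[Interval] = []
            for ex in db.children(mrna, featuretype="exon", order_by="start"):
                exons.append((ex.start - 1, ex.end))
            for cd in db.children(mrna, featuretype="CDS", order_by="start"):
                cds_segs.append((cd.start - 1, cd.end))
            if not exons:
                raise ParseError(f"{path}: mRNA {mrna.id!r} has no exons")
            gspan = (gene.start - 1, gene.end)
            for s, e in exons:
                if s < gspan[0] or e > gspan[1]:
                    raise ParseError(
                        f"{path}: exon [{s},{e}) of {mrna.id!r} outside gene span"
                    )
            cds: Interval | None = None
            if cds_segs:
                cds = (min(s for s, _ in cds_segs), max(e for _, e in cds_segs))
                exon_cover = _covered(exons, cds_segs)
                if not exon_cover:
                    raise ParseError(
                        f"{path}: CDS of {mrna.id!r} not contained in its exons"
                    )
            attrs = {
                k: v[0] for k, v in mrna.attributes.items()
                if k not in ("ID", "Parent") and v
            }
            try:
                transcripts.append(TranscriptModel(
                    transcript_id=mrna.id,
                    gene_id=gene.id,
                    contig_id=gene.seqid,
                    strand=mrna.strand,
                    exons=exons,
                    cds=cds,
                    attributes=attrs,
                ))
            except ModelError as exc:
                raise ParseError(f"{path}: {exc}") from exc
        if not transcripts:
            continue
        try:
            genes.append(GeneModel(gene.id, gene.seqid, gene.strand, transcripts))
        except ModelError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    return genes


def _covered(exons: list[Interval], segs: list[Interval]) -> bool:
    """True iff every CDS segment lies inside some exon."""
    for cs, ce in segs:
        if not any(s <= cs and ce <= e for s, e in exons):
            return False
    return True


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as a GFF3 subset (gene/mRNA/exon/CDS)."""
    lines = ["##gff-version 3"]
    for gene in sorted(models, key=lambda g: (g.contig_id, g.span[0], g.gene_id)):
        gs, ge = gene.span
        lines.append("\t".join([
            gene.contig_id, "annoforge", "gene", str(gs + 1), str(ge),
            ".", gene.strand, ".", f"ID={gene.gene_id};Name={gene.gene_id}",
        ]))
        for t in gene.transcripts:
            ts, te = t.span
            attrs = f"ID={t.transcript_id};Parent={gene.gene_id}"
            for k, v in t.attributes.items():
                attrs += f";{k}={v}"
            lines.append("\t".join([
                gene.contig_id, "annoforge", "mRNA", str(ts + 1), str(te),
                ".", t.strand, ".", attrs,
            ]))
            for i, (s, e) in enumerate(t.exons, 1):
                lines.append("\t".join([
                    gene.contig_id, "annoforge", "exon", str(s + 1), str(e),
                    ".", t.strand, ".",
                    f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}",
                ]))
            phase = 0
            segs = t.cds_segments()
            if t.strand == "-":
                segs = segs[::-1]
            for i, (s, e) in enumerate(segs, 1):
                lines.append("\t".join([
                    gene.contig_id, "annoforge", "CDS", str(s + 1), str(e),
                    ".", t.strand, str(phase),
                    f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}",
                ]))
                phase = (3 - ((e - s) - phase) % 3) % 3
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# introns

def introns_of(t: TranscriptModel,
               genome: dict[str, str]) -> list[tuple[Interval, str, str]]:
    """Introns of a transcript with donor/acceptor dinucleotides.

    Read 5'→3' on the coding strand. Introns shorter than 4 bp cannot hold
    both splice dinucleotides: they report donor = first ``min(2, len)``
    bases and acceptor = whatever remains (possibly empty), and are never
    canonical.
    """
    if t.contig_id not in genome:
        raise KeyError(f"contig {t.contig_id!r} not in genome")
    contig = genome[t.contig_id]
    out = []
    introns = t.introns
    if t.strand == "-":
        introns = introns[::-1]
    for s, e in introns:
        seq = contig[s:e]
        if t.strand == "-":
            seq = revcomp(seq)
        donor = seq[: min(2, len(seq))]
        acceptor = seq[max(len(donor), len(seq) - 2):]
        out.append(((s, e), donor, acceptor))
    return sorted(out)


# ----------------------------------------------------------------------
# tab-separated dialects

def read_counts(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=0,
                     names=["transcript_id", "count"],
                     dtype={"transcript_id": str, "count": int})
    return dict(zip(df["transcript_id"], df["count"]))


def write_counts(counts: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"transcript_id": list(counts), "count": [counts[k] for k in counts]}
    ).to_csv(path, sep="\t", index=False)


def read_taxon_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=0, names=["contig_id", "taxon"],
                     dtype=str)
    return dict(zip(df["contig_id"], df["taxon"]))


def write_taxon_map(taxa: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"contig_id": list(taxa), "taxon": [taxa[k] for k in taxa]}
    ).to_csv(path, sep="\t", index=False)


def read_pileup(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, names=PILEUP_COLUMNS,
                     dtype={"contig": str, "ref": str, "ins_base": str})
    return df


def write_pileup(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=PILEUP_COLUMNS)


def write_alignments(alignments, path: str | Path) -> None:
    rows = []
    for a in alignments:
        rows.append({
            "transcript_id": a.transcript_id,
            "contig": a.contig_id,
            "strand": a.strand,
            "identity": round(a.identity, 6),
            "coverage": round(a.coverage, 6),
            "qstart": a.blocks[0][0],
            "qend": a.blocks[-1][1],
            "tstart": a.blocks[0][2],
            "tend": a.blocks[-1][3],
            "blocks": ",".join(f"{qs}:{ts}:{qe - qs}"
                               for qs, qe, ts, te in a.blocks),
            "matches": int(round(a.identity * a.aligned_bases)),
            "aligned": a.aligned_bases,
        })
    pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS).to_csv(path, sep="\t",
                                                         index=False)


def read_alignments(path: str | Path):
    from .models import TranscriptAlignment

    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        blocks = []
        for part in str(row.blocks).split(","):
            qs, ts, ln = (int(x) for x in part.split(":"))
            blocks.append((qs, qs + ln, ts, ts + ln))
        out.append(TranscriptAlignment(
            transcript_id=row.transcript_id, contig_id=row.contig,
            strand=row.strand, blocks=blocks,
            identity=float(row.identity), coverage=float(row.coverage),
        ))
    return out


def write_ledger(entries, path: str | Path) -> None:
    rows = []
    for e in entries:
        rows.append({
            "kind": e.kind.value,
            "contig": e.contig_id,
            "start": e.start,
            "end": e.end,
            "gene_ids": ",".join(e.gene_ids),
            "transcript_ids": ",".join(e.transcript_ids),
            "expected_verdict": e.expected_verdict,
            "details": json.dumps(e.details, sort_keys=True),
        })
    pd.DataFrame(rows, columns=[
        "kind", "contig", "start", "end", "gene_ids", "transcript_ids",
        "expected_verdict", "details",
    ]).to_csv(path, sep="\t", index=False)


def read_ledger(path: str | Path):
    from .forge import DefectKind, LedgerEntry

    df = pd.read_csv(path, sep="\t", dtype={"contig": str}, keep_default_na=False)
    entries = []
    for row in df.itertuples(index=False):
        entries.append(LedgerEntry(
            kind=DefectKind(row.kind),
            contig_id=row.contig,
            start=int(row.start),
            end=int(row.end),
            gene_ids=[g for g in str(row.gene_ids).split(",") if g],
            transcript_ids=[t for t in str(row.transcript_ids).split(",") if t],
            expected_verdict=row.expected_verdict,
            details=json.loads(row.details) if row.details else {},
        ))
    return entries
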