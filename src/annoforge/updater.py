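"""Rule-based comparison of assembled gene structures against existing models.

The update taxonomy — UTR-only extension, new isoform, exon gain/loss,
intron change, merge, split, novel gene — is applied with an explicit,
documented rule order (first match wins per structure):

1. no overlapping model on either strand → NOVEL_GENE
2. structure whose ORF spans the CDS of ≥ 2 models in one reading →
   MERGE
3. ≥ 2 span-disjoint structures each covering part of one model whose own
   CDS reading is broken by an internal stop → SPLIT
4. identical intron chain over the CDS, termini extended/added only
   outside it → UTR_ONLY
5. intron chain differs but a sibling structure retains an existing
   isoform → NEW_ISOFORM
6. strictly more/fewer exons over the CDS → EXON_GAIN / EXON_LOSS
7. same exon count, junctions moved → INTRON_CHANGE
8. otherwise UNCHANGED

Intron chains are compared after canonicalisation (each intron slid to its
leftmost sequence-preserving placement), which makes the comparison
invariant to the junction-placement ambiguity spliced aligners face.
Structures overlapping models only on the opposite strand are reported as
NOVEL_GENE with a strand-conflict note, mirroring how assemblers can
report antisense contigs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .align import Locus, LocusStructure
from .models import GeneModel, Interval, TranscriptModel, translate
from .orphans import longest_orf

CATEGORIES = ("UTR_ONLY", "NEW_ISOFORM", "EXON_GAIN", "EXON_LOSS",
              "INTRON_CHANGE", "MERGE", "SPLIT", "NOVEL_GENE", "UNCHANGED")

PROTEIN_CHANGES = ("NONE", "N_TRUNCATION", "N_EXTENSION", "C_TRUNCATION",
                   "C_EXTENSION", "EXON_GAIN_PROTEIN", "EXON_LOSS_PROTEIN",
                   "INTERNAL_CHANGE")

TERMINUS_SLACK = 10     # bp of terminal wobble ignored when comparing chains
MIN_ORF_CODONS = 50     # structures without an ORF this long are not genes


class InternalStopError(ValueError):
    """A CDS contains an internal stop; see the intron/genome audit."""


class UpdateConflictError(ValueError):
    """Conflicting update records target the same locus."""


@dataclass
class UpdateRecord:
    locus_id: str
    category: str
    old_gene_ids: list[str] = field(default_factory=list)
    old_transcript_ids: list[str] = field(default_factory=list)
    new_structures: list[LocusStructure] = field(default_factory=list)
    protein_change: Optional[str] = None
    details: str = ""

    @property
    def new_structure_ids(self) -> list[str]:
        return [s.structure_id for s in self.new_structures]


# ----------------------------------------------------------------------
# chain utilities

def canonical_introns(exons: Sequence[Interval],
                      contig: str) -> tuple[Interval, ...]:
    """Introns slid to their leftmost sequence-preserving placement.

    Sliding an intron [s, e) one base left keeps the spliced product
    identical iff contig[s-1] == contig[e-1]; aligners may report any
    placement in that window, so comparisons use the leftmost one.
    """
    out = []
    for i in range(len(exons) - 1):
        s, e = exons[i][1], exons[i + 1][0]
        floor = exons[i][0] + 1
        while s > floor and contig[s - 1] == contig[e - 1]:
            s -= 1
            e -= 1
        out.append((s, e))
    return tuple(out)


def _introns_in(introns: Sequence[Interval], cds: Interval) -> tuple[Interval, ...]:
    return tuple(iv for iv in introns if cds[0] <= iv[0] and iv[1] <= cds[1])


def _span_overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def structure_orf(structure: LocusStructure, genome: dict[str, str],
                  min_len_aa: int = MIN_ORF_CODONS):
    """Longest start-initiated ORF of a structure's spliced sequence.

    The mRNA orientation is fixed by the splice orientation, so only the
    three forward frames of the spliced sequence are scanned.
    """
    return longest_orf(structure.spliced_sequence(genome), require_start=True,
                       min_len_aa=min_len_aa, forward_only=True)


def orf_genome_interval(structure: LocusStructure, genome: dict[str, str],
                        orf) -> Optional[Interval]:
    """Project an mRNA-level ORF back onto the genome (min/max interval)."""
    if orf is None:
        return None
    positions: list[int] = []
    for s, e in structure.exons:
        positions.extend(range(s, e))
    if structure.strand == "-":
        positions = positions[::-1]          # 5'→3' on the coding strand
    if orf.frame.startswith("-"):
        positions = positions[::-1]
    window = positions[orf.nt_start:orf.nt_end]
    return (min(window), max(window) + 1) if window else None


def orf_cds_sequence(structure: LocusStructure, genome: dict[str, str],
                     orf) -> str:
    from .models import revcomp

    seq = structure.spliced_sequence(genome)
    if orf.frame.startswith("-"):
        seq = revcomp(seq)
    return seq[orf.nt_start:orf.nt_end]


# ----------------------------------------------------------------------
# protein change classification

def _one_block_insertion(short: str, long: str) -> Optional[tuple[int, str]]:
    """If long == short with one contiguous block inserted, return (pos, block)."""
    if len(long) <= len(short):
        return None
    p = 0
    while p < len(short) and short[p] == long[p]:
        p += 1
    s = 0
    while s < len(short) - p and short[-1 - s] == long[-1 - s]:
        s += 1
    if p + s >= len(short):
        return (p, long[p:len(long) - s])
    return None


def classify_protein_change(old_cds: str, new_cds: str) -> str:
    """Relate two coding sequences at the protein level.

    Raises :class:`InternalStopError` when either translation carries an
    internal stop — such models are the intron/genome audit's business,
    not a protein-level update.
    """
    po, pn = translate(old_cds), translate(new_cds)
    po = po[:-1] if po.endswith("*") else po
    pn = pn[:-1] if pn.endswith("*") else pn
    for label, p in (("old", po), ("new", pn)):
        if "*" in p:
            raise InternalStopError(
                f"internal stop in {label} CDS at residue {p.index('*')}")
    if po == pn:
        return "NONE"
    if pn and po.endswith(pn):
        return "N_TRUNCATION"
    if po and pn.endswith(po):
        return "N_EXTENSION"
    if pn and po.startswith(pn):
        return "C_TRUNCATION"
    if po and pn.startswith(po):
        return "C_EXTENSION"
    if _one_block_insertion(po, pn):
        return "EXON_GAIN_PROTEIN"
    if _one_block_insertion(pn, po):
        return "EXON_LOSS_PROTEIN"
    return "INTERNAL_CHANGE"


# ----------------------------------------------------------------------
# classification driver

def _neighbourhoods(models: Sequence[GeneModel], loci: Sequence[Locus]
                    ) -> list[tuple[list[GeneModel], list[LocusStructure]]]:
    """Connected components of the span-overlap graph (strand-blind)."""
    structures = [s for locus in loci for s in locus.structures]
    nodes: list[tuple[str, Interval, int]] = []
    for i, g in enumerate(models):
        nodes.append((g.contig_id, g.span, i))
    for j, s in enumerate(structures):
        nodes.append((s.contig_id, s.span, len(models) + j))
    parent = list(range(len(nodes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_contig: dict[str, list[tuple[Interval, int]]] = {}
    for contig, span, idx in nodes:
        by_contig.setdefault(contig, []).append((span, idx))
    for entries in by_contig.values():
        entries.sort()
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                if entries[j][0][0] >= entries[i][0][1]:
                    break
                parent[find(entries[i][1])] = find(entries[j][1])
    # keep a locus' variants together even if spans were disjoint (they
    # never are in practice, but be safe)
    offset = len(models)
    j = 0
    for locus in loci:
        first = None
        for _ in locus.structures:
            if first is None:
                first = offset + j
            else:
                parent[find(first)] = find(offset + j)
            j += 1

    comps: dict[int, tuple[list[GeneModel], list[LocusStructure]]] = {}
    for i, g in enumerate(models):
        comps.setdefault(find(i), ([], []))[0].append(g)
    for j, s in enumerate(structures):
        comps.setdefault(find(len(models) + j), ([], []))[1].append(s)
    return [comps[k] for k in sorted(comps)]


def classify_update(models: Sequence[GeneModel],
                    structures: Sequence[LocusStructure],
                    genome: dict[str, str],
                    min_orf_codons: int = MIN_ORF_CODONS,
                    slack: int = TERMINUS_SLACK) -> list[UpdateRecord]:
    """Classify every structure of one neighbourhood against its models."""
    records: list[UpdateRecord] = []
    done: set[str] = set()

    def canon(exons: Sequence[Interval], contig_id: str) -> tuple:
        return canonical_introns(exons, genome[contig_id])

    model_chains: dict[str, list[tuple[TranscriptModel, tuple]]] = {}
    for g in models:
        model_chains[g.gene_id] = [
            (t, canon(t.exons, g.contig_id)) for t in g.transcripts
        ]

    orfs = {s.structure_id: structure_orf(s, genome, min_orf_codons)
            for s in structures}

    # rule 2: MERGE
    for s in structures:
        orf = orfs[s.structure_id]
        proj = orf_genome_interval(s, genome, orf)
        if proj is None:
            continue
        covered = [g for g in models
                   if g.strand == s.strand and g.contig_id == s.contig_id
                   and any(t.cds and _span_overlap(proj, t.cds) > 0
                           for t in g.transcripts)]
        if len(covered) >= 2:
            rec = UpdateRecord(
                locus_id=s.structure_id, category="MERGE",
                old_gene_ids=[g.gene_id for g in covered],
                old_transcript_ids=[t.transcript_id for g in covered
                                    for t in g.transcripts],
                new_structures=[s],
                details="single ORF spans multiple models")
            # protein change vs the old models, 5'-most first; models whose
            # own CDS reading is broken cannot be classified
            new_cds = orf_cds_sequence(s, genome, orf)
            ordered = sorted(covered, key=lambda g: g.span[0],
                             reverse=(s.strand == "-"))
            for g2 in ordered:
                t0 = g2.transcripts[0]
                if t0.cds is None:
                    continue
                try:
                    rec.protein_change = classify_protein_change(
                        t0.cds_sequence(genome), new_cds)
                    break
                except InternalStopError:
                    continue
            records.append(rec)
            done.add(s.structure_id)

    # rule 3: SPLIT
    for g in models:
        over = [s for s in structures
                if s.structure_id not in done
                and s.strand == g.strand and s.contig_id == g.contig_id
                and _span_overlap(s.span, g.span) > 0]
        if len(over) < 2:
            continue
        spans = sorted(s.span for s in over)
        disjoint = all(spans[i][1] <= spans[i + 1][0]
                       for i in range(len(spans) - 1))
        if not disjoint:
            continue
        t0 = g.transcripts[0]
        if t0.cds is None:
            continue
        cds_pep = translate(t0.cds_sequence(genome))
        broken = "*" in cds_pep[:-1]
        covers_cds = all(_span_overlap(s.span, t0.cds) > 0 for s in over)
        if broken and covers_cds:
            records.append(UpdateRecord(
                locus_id=over[0].structure_id, category="SPLIT",
                old_gene_ids=[g.gene_id],
                old_transcript_ids=[t.transcript_id for t in g.transcripts],
                new_structures=sorted(over, key=lambda s: s.span),
                details="model CDS broken by internal stop across structures"))
            done.update(s.structure_id for s in over)

    # rules 1, 4-8 per remaining structure
    for s in structures:
        if s.structure_id in done:
            continue
        same = [g for g in models
                if g.contig_id == s.contig_id and g.strand == s.strand
                and _span_overlap(g.span, s.span) > 0]
        anti = [g for g in models
                if g.contig_id == s.contig_id and g.strand != s.strand
                and _span_overlap(g.span, s.span) > 0]
        orf = orfs[s.structure_id]
        if not same:
            if anti:
                records.append(UpdateRecord(
                    s.structure_id, "NOVEL_GENE", new_structures=[s],
                    details="strand conflict with "
                            + ",".join(g.gene_id for g in anti)))
            elif orf is None:
                records.append(UpdateRecord(
                    s.structure_id, "UNCHANGED",
                    details=f"no ORF >= {min_orf_codons} codons; not reported "
                            "as a novel gene"))
            else:
                records.append(UpdateRecord(
                    s.structure_id, "NOVEL_GENE", new_structures=[s],
                    details="no overlapping model"))
            continue

        best = max(same, key=lambda g: _span_overlap(g.span, s.span))
        s_chain = canon(s.exons, s.contig_id)
        record = _classify_against_model(
            s, s_chain, best, model_chains[best.gene_id], structures, genome,
            canon, slack)
        if record.category not in ("UNCHANGED", "UTR_ONLY"):
            _attach_protein_change(record, best, s, orf, genome)
        records.append(record)
    return records


def _classify_against_model(s: LocusStructure, s_chain: tuple,
                            model: GeneModel,
                            chains: list[tuple[TranscriptModel, tuple]],
                            siblings: Sequence[LocusStructure],
                            genome: dict[str, str], canon, slack: int
                            ) -> UpdateRecord:
    rec = UpdateRecord(s.structure_id, "UNCHANGED",
                       old_gene_ids=[model.gene_id],
                       new_structures=[s], protein_change="NONE")
    # exact retention of any existing isoform → UNCHANGED
    for t, t_chain in chains:
        if s_chain == t_chain and \
                abs(s.span[0] - t.span[0]) <= slack and \
                abs(s.span[1] - t.span[1]) <= slack:
            rec.old_transcript_ids = [t.transcript_id]
            rec.details = f"matches {t.transcript_id}"
            return rec

    primary, primary_chain = chains[0]
    cds = primary.cds
    if cds is not None:
        covers = s.span[0] <= cds[0] and s.span[1] >= cds[1]
        same_cds_chain = _introns_in(s_chain, cds) == _introns_in(
            primary_chain, cds)
        extends = (primary.span[0] - s.span[0] > slack
                   or s.span[1] - primary.span[1] > slack)
        if covers and same_cds_chain and extends:
            rec.category = "UTR_ONLY"
            rec.old_transcript_ids = [primary.transcript_id]
            rec.protein_change = "NONE"
            rec.details = "termini extended outside the CDS"
            return rec
        if covers and same_cds_chain and not extends:
            # UTR-side introns may differ without touching the protein
            rec.category = ("NEW_ISOFORM"
                            if s_chain not in [c for _, c in chains]
                            else "UNCHANGED")
            if rec.category == "NEW_ISOFORM":
                rec.old_transcript_ids = [primary.transcript_id]
                rec.details = "UTR-side intron change"
            return rec

    # rule 5: a sibling structure retains an existing isoform
    retained = any(
        o.structure_id != s.structure_id
        and any(canon(o.exons, o.contig_id) == c for _, c in chains)
        for o in siblings)
    if retained:
        rec.category = "NEW_ISOFORM"
        rec.old_transcript_ids = [primary.transcript_id]
        rec.details = "existing isoform retained by sibling structure"
        return rec

    if cds is not None:
        n_s = len(_introns_in(s_chain, cds)) + 1
        n_t = len(_introns_in(primary_chain, cds)) + 1
        rec.old_transcript_ids = [primary.transcript_id]
        if n_s > n_t:
            rec.category = "EXON_GAIN"
        elif n_s < n_t:
            rec.category = "EXON_LOSS"
        elif _introns_in(s_chain, cds) != _introns_in(primary_chain, cds):
            rec.category = "INTRON_CHANGE"
        else:
            rec.category = "UNCHANGED"
        return rec
    rec.old_transcript_ids = [primary.transcript_id]
    rec.category = "UNCHANGED" if s_chain == primary_chain else "INTRON_CHANGE"
    return rec


def _attach_protein_change(record: UpdateRecord, model: GeneModel,
                           s: LocusStructure, orf,
                           genome: dict[str, str]) -> None:
    if record.category in ("NOVEL_GENE", "UNCHANGED"):
        record.protein_change = "NONE" if record.category == "UNCHANGED" else None
        return
    primary = model.transcripts[0]
    if primary.cds is None or orf is None:
        record.protein_change = None
        return
    old_cds = primary.cds_sequence(genome)
    new_cds = orf_cds_sequence(s, genome, orf)
    try:
        record.protein_change = classify_protein_change(old_cds, new_cds)
    except InternalStopError as exc:
        record.protein_change = None
        record.details = (record.details + "; " if record.details else "") + \
            f"flagged for intron/genome audit ({exc})"


def classify_all(models: Sequence[GeneModel], loci: Sequence[Locus],
                 genome: dict[str, str],
                 min_orf_codons: int = MIN_ORF_CODONS,
                 slack: int = TERMINUS_SLACK) -> list[UpdateRecord]:
    """Classify every assembled structure genome-wide.

    When several structures demand different modifications of the same
    gene (it happens with noisy junction placement), only the
    best-supported record is kept; the others are demoted to UNCHANGED
    with a note, so the resulting record set is always applicable.
    """
    records: list[UpdateRecord] = []
    for comp_models, comp_structures in _neighbourhoods(models, loci):
        if not comp_structures:
            continue
        records.extend(classify_update(comp_models, comp_structures, genome,
                                       min_orf_codons, slack))
    return _resolve_conflicts(records)


_EXCLUSIVE = ("UTR_ONLY", "EXON_GAIN", "EXON_LOSS", "INTRON_CHANGE",
              "MERGE", "SPLIT")


def _resolve_conflicts(records: list[UpdateRecord]) -> list[UpdateRecord]:
    by_gene: dict[str, list[UpdateRecord]] = {}
    for r in records:
        if r.category in _EXCLUSIVE:
            for gid in r.old_gene_ids:
                by_gene.setdefault(gid, []).append(r)
    demote: set[int] = set()
    for gid, rs in by_gene.items():
        if len(rs) < 2:
            continue
        def support(r: UpdateRecord) -> tuple:
            return (sum(len(s.transcript_ids) for s in r.new_structures),
                    r.locus_id)
        rs = sorted(rs, key=support, reverse=True)
        for r in rs[1:]:
            demote.add(id(r))
    for r in records:
        if id(r) in demote:
            r.details = (f"demoted from {r.category}: better-supported "
                         "update on the same gene" +
                         (f"; {r.details}" if r.details else ""))
            r.category = "UNCHANGED"
            r.protein_change = "NONE"
    return records


# ----------------------------------------------------------------------
# applying updates

def apply_updates(existing: Sequence[GeneModel],
                  records: Sequence[UpdateRecord],
                  genome: dict[str, str]
                  ) -> tuple[list[GeneModel], pd.DataFrame]:
    """Produce the updated annotation and a Table-3-style summary."""
    by_gene = {g.gene_id: g for g in existing}
    touched: dict[str, list[UpdateRecord]] = {}
    for r in records:
        if r.category in ("UNCHANGED", "NOVEL_GENE"):
            continue
        for gid in r.old_gene_ids:
            touched.setdefault(gid, []).append(r)
    conflicts = {g: rs for g, rs in touched.items()
                 if len({id(r) for r in rs}) > 1 and
                 sum(1 for r in rs if r.category != "NEW_ISOFORM") > 1}
    if conflicts:
        msg = "; ".join(
            f"{g}: {','.join(r.category for r in rs)}"
            for g, rs in sorted(conflicts.items()))
        raise UpdateConflictError(f"conflicting updates: {msg}")

    drop: set[str] = set()
    add: list[GeneModel] = []
    updated: dict[str, GeneModel] = {}
    novel_n = 0

    def _new_transcript(structure: LocusStructure, tid: str, gid: str
                        ) -> TranscriptModel:
        orf = structure_orf(structure, genome, 1)
        cds = orf_genome_interval(structure, genome, orf)
        return TranscriptModel(tid, gid, structure.contig_id,
                               structure.strand, list(structure.exons), cds)

    for r in records:
        if r.category == "UNCHANGED":
            continue
        if r.category == "NOVEL_GENE":
            novel_n += 1
            gid = f"novel_model_{novel_n}"
            s = r.new_structures[0]
            add.append(GeneModel(gid, s.contig_id, s.strand,
                                 [_new_transcript(s, f"{gid}.1", gid)]))
            continue
        gene = by_gene[r.old_gene_ids[0]]
        if r.category == "UTR_ONLY":
            g = updated.get(gene.gene_id) or copy_gene(gene)
            t = _find(g, r.old_transcript_ids[0])
            t.exons = sorted(r.new_structures[0].exons)
            updated[gene.gene_id] = g
        elif r.category == "NEW_ISOFORM":
            g = updated.get(gene.gene_id) or copy_gene(gene)
            n = len(g.transcripts) + 1
            g.transcripts.append(_new_transcript(
                r.new_structures[0], f"{gene.gene_id}.iso{n}", gene.gene_id))
            updated[gene.gene_id] = g
        elif r.category in ("EXON_GAIN", "EXON_LOSS", "INTRON_CHANGE"):
            g = updated.get(gene.gene_id) or copy_gene(gene)
            t = _find(g, r.old_transcript_ids[0])
            s = r.new_structures[0]
            repl = _new_transcript(s, t.transcript_id, gene.gene_id)
            g.transcripts[g.transcripts.index(t)] = repl
            updated[gene.gene_id] = g
        elif r.category == "MERGE":
            drop.update(r.old_gene_ids)
            gid = "_".join(r.old_gene_ids) + "_merged"
            s = r.new_structures[0]
            add.append(GeneModel(gid, s.contig_id, s.strand,
                                 [_new_transcript(s, f"{gid}.1", gid)]))
        elif r.category == "SPLIT":
            drop.update(r.old_gene_ids)
            for i, s in enumerate(r.new_structures, 1):
                gid = f"{r.old_gene_ids[0]}_part{i}"
                add.append(GeneModel(gid, s.contig_id, s.strand,
                                     [_new_transcript(s, f"{gid}.1", gid)]))

    out: list[GeneModel] = []
    for g in existing:
        if g.gene_id in drop:
            continue
        out.append(updated.get(g.gene_id, g))
    out.extend(add)

    counts = {c: 0 for c in CATEGORIES}
    for r in records:
        counts[r.category] += 1
    modified = sum(1 for r in records
                   if r.protein_change not in (None, "NONE"))
    flagged = sum(1 for r in records if r.protein_change is None
                  and r.category not in ("UNCHANGED", "NOVEL_GENE"))
    rows = [("Gene model updated",
             sum(counts[c] for c in CATEGORIES
                 if c not in ("UNCHANGED", "NOVEL_GENE", "NEW_ISOFORM")))]
    rows += [(f"  {c}", counts[c]) for c in CATEGORIES]
    rows.append(("New alternate splice isoforms", counts["NEW_ISOFORM"]))
    rows.append(("Novel genes", counts["NOVEL_GENE"]))
    rows.append(("Update results in modified protein", modified))
    rows.append(("Flagged for genome audit", flagged))
    summary = pd.DataFrame(rows, columns=["category", "count"])
    return out, summary


def copy_gene(g: GeneModel) -> GeneModel:
    return GeneModel(g.gene_id, g.contig_id, g.strand, [
        TranscriptModel(t.transcript_id, t.gene_id, t.contig_id, t.strand,
                        list(t.exons), t.cds, dict(t.attributes))
        for t in g.transcripts
    ])


def _find(g: GeneModel, tid: str) -> TranscriptModel:
    for t in g.transcripts:
        if t.transcript_id == tid:
            return t
    raise UpdateConflictError(f"transcript {tid} not found in {g.gene_id}")
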