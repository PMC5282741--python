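"""End-to-end audit pipeline and ledger-recovery scoring.

Stage order mirrors the annotation-refinement workflow the package
audits: spike-in removal → TAGC contamination filtering → spliced
alignment with the identity/coverage acceptance filter → locus assembly →
update classification against the existing annotation → orphan triage of
alignment failures → micro-intron genome-error audit. Orphan triage runs
on everything that failed genome alignment (not only on the TAGC-kept
set), matching how orphan tables are compiled from the full assembly.

``score_against_ledger`` compares the pipeline's verdicts with the
forge's planted-defect ledger and reports recall (planted defects
recovered) and precision (non-spurious positive calls).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import align, contamination, intron_audit, orphans, updater
from .forge import DefectKind, ForgeRun, LedgerEntry
from .models import GeneModel, SequenceRecord


@dataclass
class PipelineConfig:
    min_identity: float = 0.95
    min_coverage: float = 0.90
    max_intron: int = 5000
    spike_identity: float = 0.90
    spike_coverage: float = 0.50
    gc_band_k: float = 3.0
    read_length: int = 100
    target_lineage: tuple[str, ...] = ("Dictyostelium",)
    max_intron_flag: int = 5
    min_support: float = 0.8
    min_depth: int = 5


@dataclass
class PipelineResult:
    spike_removed_ids: set[str]
    tagc_records: list[contamination.TagcRecord]
    contaminant_ids: set[str]
    verdicts: list[align.AlignmentVerdict]
    loci: list[align.Locus]
    update_records: list[updater.UpdateRecord]
    updated_annotation: list[GeneModel]
    update_summary: pd.DataFrame
    orphan_records: list[orphans.OrphanRecord]
    orphan_matrix: pd.DataFrame
    audit_calls: list[intron_audit.GenomeErrorCall]
    audit_table: pd.DataFrame
    audit_rollup: dict
    stats: dict = field(default_factory=dict)


def run_pipeline(genome: dict[str, str],
                 observed: Sequence[GeneModel],
                 transcripts: Sequence[SequenceRecord],
                 read_counts: dict[str, int],
                 pileup: pd.DataFrame,
                 taxon_map: dict[str, str],
                 spikein_db: Sequence[SequenceRecord] = (),
                 cdna_db: Optional[Sequence[SequenceRecord]] = None,
                 related_db: Sequence[SequenceRecord] = (),
                 nonrelated_db: Sequence[SequenceRecord] = (),
                 config: Optional[PipelineConfig] = None) -> PipelineResult:
    cfg = config or PipelineConfig()

    # 1. spike-in removal
    if spikein_db:
        kept, spiked = contamination.remove_spikeins(
            transcripts, spikein_db, cfg.spike_identity, cfg.spike_coverage)
    else:
        kept, spiked = list(transcripts), []
    spike_ids = {r.id for r in spiked}

    # 2. TAGC contamination filter
    tagc = contamination.compute_tagc(kept, read_counts, taxon_map,
                                      cfg.read_length)
    kept_ids, removed_ids, tagc = contamination.filter_contaminants(
        tagc, cfg.target_lineage, cfg.gc_band_k)
    contaminant_ids = {r.contig_id for r in tagc
                       if r.verdict == "CONTAMINANT"}

    # 3. spliced alignment + acceptance filter (all non-spike transcripts,
    #    so orphan triage sees the contaminants too)
    index = align.GenomeIndex(genome)
    verdicts = align.filter_transcripts(kept, index, cfg.min_identity,
                                        cfg.min_coverage, cfg.max_intron)

    # 4. locus assembly + annotation update on the decontaminated GOOD set
    clean_good = [v for v in verdicts
                  if v.status == "GOOD" and v.transcript_id in set(kept_ids)]
    loci = align.assemble_loci(clean_good)
    records = updater.classify_all(observed, loci, genome)
    updated, summary = updater.apply_updates(observed, records, genome)

    # 5. orphan triage of alignment failures
    aligned_ids = {v.transcript_id for v in verdicts if v.status == "GOOD"}
    if cdna_db is None:
        cdna_db = [SequenceRecord(t.transcript_id,
                                  t.spliced_sequence(genome),
                                  "existing annotation")
                   for g in observed for t in g.transcripts]
    failed = [r for r in kept if r.id not in aligned_ids]
    orphan_records, orphan_matrix = orphans.classify_orphans(
        failed, aligned_ids=set(), cdna_db=cdna_db, related_db=related_db,
        nonrelated_db=nonrelated_db)

    # 6. micro-intron genome-error audit of the existing annotation
    calls, audit_table, rollup = intron_audit.audit_report(
        observed, genome, pileup, cfg.max_intron_flag, cfg.min_support,
        cfg.min_depth)

    return PipelineResult(
        spike_removed_ids=spike_ids,
        tagc_records=tagc,
        contaminant_ids=contaminant_ids,
        verdicts=verdicts,
        loci=loci,
        update_records=records,
        updated_annotation=updated,
        update_summary=summary,
        orphan_records=orphan_records,
        orphan_matrix=orphan_matrix,
        audit_calls=calls,
        audit_table=audit_table,
        audit_rollup=rollup,
    )


# ----------------------------------------------------------------------
# ledger recovery

@dataclass
class RecoveryReport:
    per_entry: list[tuple[LedgerEntry, str, bool]]   # (entry, recovered, ok)
    recall: float
    precision: float
    spurious: list[str]

    @property
    def accuracy(self) -> float:
        return self.recall


def score_against_ledger(run: ForgeRun, result: PipelineResult
                         ) -> RecoveryReport:
    """Compare pipeline verdicts with the forge's planted-defect ledger."""
    orphan_by_id = {r.transcript_id: r for r in result.orphan_records}
    audit_by_site = {(c.site.contig_id, c.site.interval): c
                     for c in result.audit_calls}
    matched_records: set[int] = set()
    matched_calls: set[tuple] = set()
    matched_orphans: set[str] = set()

    def update_match(entry: LedgerEntry, category: str,
                     old_gene_ids: set[str]) -> Optional[updater.UpdateRecord]:
        for r in result.update_records:
            if id(r) in matched_records or r.category != category:
                continue
            if old_gene_ids and set(r.old_gene_ids) != old_gene_ids:
                continue
            if not old_gene_ids:
                # NOVEL_GENE: match by genomic overlap with the ledger locus
                s = r.new_structures[0]
                if s.contig_id != entry.contig_id:
                    continue
                if s.span[1] <= entry.start or s.span[0] >= entry.end:
                    continue
            matched_records.add(id(r))
            return r
        return None

    per_entry: list[tuple[LedgerEntry, str, bool]] = []
    for e in run.ledger:
        recovered, ok = "", False
        kind = e.kind
        if kind is DefectKind.SPIKEIN_CONTIG:
            ok = e.transcript_ids[0] in result.spike_removed_ids
            recovered = "SPIKEIN_REMOVED" if ok else "kept"
        elif kind is DefectKind.CONTAMINANT_CONTIG:
            ok = e.transcript_ids[0] in result.contaminant_ids
            recovered = "CONTAMINANT" if ok else "kept"
        elif kind is DefectKind.ARTEFACT_TRANSCRIPT:
            rec = orphan_by_id.get(e.transcript_ids[0])
            recovered = rec.category if rec else "aligned"
            ok = recovered == "ARTEFACT"
            if ok:
                matched_orphans.add(e.transcript_ids[0])
        elif kind in (DefectKind.GENOME_BASE_DELETION,
                      DefectKind.GENOME_BASE_SUBSTITUTION):
            call = audit_by_site.get((e.contig_id, (e.start, e.end)))
            recovered = call.call if call else "no site"
            ok = recovered == e.expected_verdict
            if ok:
                matched_calls.add((e.contig_id, (e.start, e.end)))
        elif kind is DefectKind.NOVEL_GENE_UNANNOTATED:
            if e.details.get("in_gap"):
                rec = orphan_by_id.get(e.transcript_ids[0])
                recovered = rec.category if rec else "aligned"
                ok = recovered == "NOVEL"
                if ok:
                    matched_orphans.add(e.transcript_ids[0])
            else:
                r = update_match(e, "NOVEL_GENE", set())
                recovered = "NOVEL_GENE" if r else "missed"
                ok = r is not None
        elif kind is DefectKind.UTR_MISSING:
            r = update_match(e, "UTR_ONLY", set(e.gene_ids))
            recovered = "UTR_ONLY" if r else "missed"
            ok = r is not None
        elif kind is DefectKind.HIDDEN_ISOFORM:
            r = update_match(e, "NEW_ISOFORM", set(e.gene_ids))
            recovered = "NEW_ISOFORM" if r else "missed"
            ok = r is not None
        elif kind is DefectKind.SPLIT_MODEL:
            halves = {f"{e.gene_ids[0]}_a", f"{e.gene_ids[0]}_b"}
            r = update_match(e, "MERGE", halves)
            recovered = "MERGE" if r else "missed"
            ok = r is not None
        elif kind is DefectKind.FUSED_MODEL:
            fused = {"_".join(e.gene_ids) + "_fused"}
            r = update_match(e, "SPLIT", fused)
            recovered = "SPLIT" if r else "missed"
            ok = r is not None
        per_entry.append((e, recovered, ok))

    n_ok = sum(1 for _, _, ok in per_entry if ok)
    recall = n_ok / len(per_entry) if per_entry else 1.0

    spurious: list[str] = []
    for r in result.update_records:
        if r.category != "UNCHANGED" and id(r) not in matched_records:
            spurious.append(f"update:{r.category}:{r.locus_id}")
    for c in result.audit_calls:
        key = (c.site.contig_id, c.site.interval)
        if c.call != "NO_CALL" and key not in matched_calls:
            spurious.append(f"audit:{c.call}:{key}")
    planted_positive = {e.transcript_ids[0] for e in run.ledger
                        if e.kind in (DefectKind.ARTEFACT_TRANSCRIPT,
                                      DefectKind.CONTAMINANT_CONTIG,
                                      DefectKind.SPIKEIN_CONTIG)
                        or e.details.get("in_gap")}
    for rec in result.orphan_records:
        if rec.category in ("ARTEFACT", "NOVEL") \
                and rec.transcript_id not in planted_positive:
            spurious.append(f"orphan:{rec.category}:{rec.transcript_id}")
    extra_contams = result.contaminant_ids - {
        e.transcript_ids[0] for e in run.ledger
        if e.kind is DefectKind.CONTAMINANT_CONTIG}
    spurious.extend(f"contaminant:{c}" for c in sorted(extra_contams))
    extra_spikes = result.spike_removed_ids - {
        e.transcript_ids[0] for e in run.ledger
        if e.kind is DefectKind.SPIKEIN_CONTIG}
    spurious.extend(f"spikein:{s}" for s in sorted(extra_spikes))

    n_pos = n_ok + len(spurious)
    precision = n_ok / n_pos if n_pos else 1.0
    return RecoveryReport(per_entry, recall, precision, spurious)
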