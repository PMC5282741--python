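"""Synthetic genome forge: determinism, ledger conservation, defect geometry."""

import pytest

from annoforge import io
from annoforge.forge import (DefectKind, ForgeConfig, ForgeError,
                             generate_genome, plant_annotation_defects,
                             run_forge, simulate_transcripts_and_evidence)
from annoforge.metrics import gc_fraction
from annoforge.orphans import flag_artefact


def test_same_config_same_seed_is_byte_identical(tmp_path, full_config):
    import dataclasses
    paths = []
    for tag in ("a", "b"):
        run = run_forge(dataclasses.replace(full_config), error_rate=0.005)
        d = tmp_path / tag
        d.mkdir()
        io.write_fasta(run.output.genome_records, d / "genome.fasta")
        io.write_gff3(run.truth, d / "truth.gff3")
        io.write_gff3(run.observed, d / "observed.gff3")
        io.write_fasta(run.evidence.transcripts, d / "transcripts.fasta")
        io.write_counts(run.evidence.read_counts, d / "counts.tsv")
        io.write_pileup(run.evidence.pileup, d / "pileup.tsv")
        io.write_ledger(run.ledger, d / "ledger.tsv")
        paths.append(d)
    for name in ("genome.fasta", "truth.gff3", "observed.gff3",
                 "transcripts.fasta", "counts.tsv", "pileup.tsv",
                 "ledger.tsv"):
        assert (paths[0] / name).read_bytes() == (paths[1] / name).read_bytes()


def test_zero_defects_yields_empty_ledger_and_identical_annotations(clean_run):
    assert clean_run.ledger == []
    truth = {g.gene_id: g for g in clean_run.truth}
    assert set(g.gene_id for g in clean_run.observed) == set(truth)
    for g in clean_run.observed:
        o = truth[g.gene_id]
        assert [t.exons for t in g.transcripts] == \
               [t.exons for t in o.transcripts]


def test_ledger_counts_match_defect_spec(full_run, full_config):
    from collections import Counter
    counts = Counter(e.kind for e in full_run.ledger)
    assert dict(counts) == full_config.defect_spec


def test_deletion_defects_sit_inside_cds_exons():
    cfg = ForgeConfig(seed=3, n_genes=20, defect_spec={
        DefectKind.GENOME_BASE_DELETION: 2})
    out = generate_genome(cfg)
    entries = [e for e in out.ledger
               if e.kind is DefectKind.GENOME_BASE_DELETION]
    assert len(entries) == 2
    truth = {g.gene_id: g for g in out.truth}
    for e in entries:
        t = truth[e.gene_ids[0]].transcripts[0]
        cs, ce = t.cds
        assert cs <= e.start < e.end <= ce      # micro-intron within the CDS
        assert e.end - e.start == 2


def test_infeasible_defect_spec_is_rejected():
    with pytest.raises(ForgeError, match="consumes"):
        generate_genome(ForgeConfig(seed=0, n_genes=3, defect_spec={
            DefectKind.UTR_MISSING: 2, DefectKind.FUSED_MODEL: 1}))


def test_config_invariants_are_enforced():
    with pytest.raises(ForgeError):
        ForgeConfig(seed=0, gc_target=0.0).validate()
    with pytest.raises(ForgeError):
        ForgeConfig(seed=0, intron_length_range=(2, 10)).validate()
    with pytest.raises(ForgeError):
        ForgeConfig(seed=0, exons_per_gene_range=(3, 2)).validate()


def test_utr_missing_observed_model_spans_exactly_the_cds(full_run):
    observed = {g.gene_id: g for g in full_run.observed}
    for e in full_run.ledger:
        if e.kind is not DefectKind.UTR_MISSING:
            continue
        t = observed[e.gene_ids[0]].transcripts[0]
        assert t.span == t.cds


def test_split_model_partitions_the_truth_cds(full_run):
    truth = {g.gene_id: g for g in full_run.truth}
    observed = {g.gene_id: g for g in full_run.observed}
    for e in full_run.ledger:
        if e.kind is not DefectKind.SPLIT_MODEL:
            continue
        gid = e.gene_ids[0]
        a, b = observed[f"{gid}_a"], observed[f"{gid}_b"]
        cs, ce = truth[gid].transcripts[0].cds
        ca, cb = a.transcripts[0].cds, b.transcripts[0].cds
        assert ca[0] == cs and cb[1] == ce
        assert ca[1] <= cb[0]                      # disjoint halves
        segs_truth = truth[gid].transcripts[0].cds_segments()
        segs_halves = (a.transcripts[0].cds_segments()
                       + b.transcripts[0].cds_segments())
        assert sorted(segs_halves) == sorted(segs_truth)


def test_micro_intron_abuts_the_planted_deletion(full_run):
    truth = {g.gene_id: g for g in full_run.truth}
    for e in full_run.ledger:
        if e.kind is not DefectKind.GENOME_BASE_DELETION:
            continue
        t = truth[e.gene_ids[0]].transcripts[0]
        micro = [iv for iv in t.introns if iv[1] - iv[0] <= 3]
        assert micro == [(e.start, e.end)]


def test_error_free_transcripts_splice_exactly_from_the_genome(clean_run):
    genome = clean_run.genome
    by_id = {r.id: r for r in clean_run.evidence.transcripts}
    for gene in clean_run.truth:
        for t in gene.transcripts:
            assert by_id[t.transcript_id].sequence == \
                t.spliced_sequence(genome)


def test_pileup_shows_planted_insertion_support(full_run):
    pile = full_run.evidence.pileup
    for e in full_run.ledger:
        if e.kind is not DefectKind.GENOME_BASE_DELETION:
            continue
        rows = pile[(pile["contig"] == e.contig_id)
                    & (pile["pos"] == e.end + 1)]
        assert len(rows) == 1
        row = rows.iloc[0]
        covering = int(row[["A", "C", "G", "T", "N"]].sum())
        assert (int(row["ins"]), covering) == tuple(e.details["support"])
        assert row["ins_base"] == e.details["inserted_base"]


def test_contaminants_have_offset_gc_and_taxon_label(full_run):
    cfg = full_run.config
    for rec in full_run.output.contaminants:
        assert abs(gc_fraction([rec.sequence]) - cfg.gc_target) >= 0.15
        assert full_run.evidence.taxon_map[rec.id] == cfg.contaminant_taxon


def test_artefacts_have_stops_in_all_six_frames(full_run):
    for rec in full_run.output.artefacts:
        assert flag_artefact(rec.sequence)
        assert len(rec) == full_run.config.artefact_length


def test_genome_gc_is_controlled(full_run):
    genome_gc = gc_fraction(full_run.genome.values())
    assert abs(genome_gc - full_run.config.gc_target) <= 0.03
    assert sum(len(s) for s in full_run.genome.values()) >= 50_000


def test_non_defect_introns_are_canonical_gt_ag(clean_run):
    for gene in clean_run.truth:
        for t in gene.transcripts:
            for _, donor, acceptor in io.introns_of(t, clean_run.genome):
                assert (donor, acceptor) == ("GT", "AG")


def test_planting_rejects_unknown_gene():
    cfg = ForgeConfig(seed=2, n_genes=10,
                      defect_spec={DefectKind.UTR_MISSING: 1})
    out = generate_genome(cfg)
    out.ledger[0].gene_ids = ["gene_999"]
    with pytest.raises(ForgeError, match="gene_999"):
        plant_annotation_defects(out.truth, out.ledger)


def test_error_rate_out_of_range_rejected(clean_run):
    with pytest.raises(ForgeError):
        simulate_transcripts_and_evidence(clean_run.output, error_rate=0.2)
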