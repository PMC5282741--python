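"""Micro-intron detection, pileup-evidence calls and repair proposals."""

import pandas as pd
import pytest

from annoforge.forge import DefectKind
from annoforge.intron_audit import (audit_report, audit_site,
                                    find_micro_introns, propose_repair)
from annoforge.models import GeneModel, TranscriptModel


def _gene(exons, cds, gid="g", contig="c", strand="+"):
    t = TranscriptModel(f"{gid}.1", gid, contig, strand, exons, cds)
    return GeneModel(gid, contig, strand, [t])


def _pileup(contig, entries):
    """entries: list of dicts with pos (0-based) and column overrides."""
    rows = []
    for e in entries:
        row = {"contig": contig, "pos": e["pos"] + 1, "ref": e["ref"],
               "A": 0, "C": 0, "G": 0, "T": 0, "N": 0,
               "ins": 0, "del": 0, "ins_base": "."}
        row.update({k: v for k, v in e.items() if k not in ("pos",)})
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# detection

def test_intron_length_boundary_is_strict():
    #            0         1         2         3
    #            0123456789012345678901234567890123456
    genome = {"c": "ATGAAAATTAAAGTACGAAAACCCGGGTTTAAATAA" + "A" * 20}
    flagged = _gene([(0, 10), (12, 30)], (0, 30), gid="two")       # 2 bp intron
    at_limit = _gene([(0, 10), (15, 30)], (0, 30), gid="five")     # 5 bp intron
    sites = find_micro_introns([flagged, at_limit], genome)
    assert [s.gene_id for s in sites] == ["two"]
    assert sites[0].length == 2


def test_gene_with_three_tiny_introns_yields_three_sites():
    genome = {"c": "A" * 120}
    g = _gene([(0, 15), (18, 33), (36, 51), (52, 70)], (0, 70), gid="multi")
    sites = find_micro_introns([g], genome)
    assert len(sites) == 3
    assert [s.length for s in sites] == [3, 3, 1]


def test_sites_sorted_by_contig_and_position(full_run):
    sites = find_micro_introns(full_run.observed, full_run.genome)
    keys = [(s.contig_id, s.interval) for s in sites]
    assert keys == sorted(keys)
    assert len(sites) == 4          # two deletions + two substitutions planted


# ----------------------------------------------------------------------
# evidence calls

def _del_fixture():
    # genome:  exon1 | AT (2bp intron) | exon2 ; reads insert T after intron
    genome = {"c": "ATGGATGATGATGAAGAT" + "AT" + "GAAGATGATATCGATTAA" + "AAAA"}
    g = _gene([(0, 18), (20, 38)], (0, 38))
    (site,) = find_micro_introns([g], genome)
    entries = [{"pos": p, "ref": genome["c"][p], genome["c"][p]: 23}
               for p in range(15, 26)]
    for e in entries:
        if e["pos"] == 20:          # first base after the intron
            e["ins"] = 22
            e["ins_base"] = "T"
    return genome, g, site, _pileup("c", entries)


def test_insertion_support_22_of_23_calls_genome_deletion():
    genome, g, site, pile = _del_fixture()
    call = audit_site(site, pile)
    assert call.call == "GENOME_DELETION"
    assert (call.supporting_reads, call.covering_reads) == (22, 23)
    assert call.support == pytest.approx(22 / 23)


def test_low_support_insertion_is_no_call():
    genome, g, site, pile = _del_fixture()
    pile.loc[pile["ins"] > 0, "ins"] = 3
    call = audit_site(site, pile)
    assert call.call == "NO_CALL"


def test_low_depth_is_no_call_with_reason():
    genome, g, site, pile = _del_fixture()
    for b in "ACGT":
        pile[b] = (pile[b] > 0).astype(int) * 2     # depth 2 < min_depth
    pile.loc[pile["ins"] > 0, "ins"] = 2
    call = audit_site(site, pile)
    assert call.call == "NO_CALL"
    assert "depth" in call.reason or "covering" in call.reason


def test_uncovered_site_is_no_call():
    genome, g, site, _ = _del_fixture()
    call = audit_site(site, _pileup("c", []))
    assert call.call == "NO_CALL"


def _sub_fixture(depth=56):
    # 3 bp intron TAA (a masked stop); all reads carry TTA
    genome = {"c": "ATGGATGATGATGAAGAT" + "TAA" + "GAAGATGATATCGATTAA" + "AA"}
    g = _gene([(0, 18), (21, 39)], (0, 39))
    (site,) = find_micro_introns([g], genome)
    entries = []
    for p in range(15, 27):
        ref = genome["c"][p]
        e = {"pos": p, "ref": ref, ref: depth}
        if p == 19:                  # middle base of the intron: A -> T
            e[ref] = 0
            e["T"] = depth
        entries.append(e)
    return genome, g, site, _pileup("c", entries)


def test_unanimous_tta_reads_call_genome_substitution():
    genome, g, site, pile = _sub_fixture(depth=56)
    call = audit_site(site, pile)
    assert call.call == "GENOME_SUBSTITUTION"
    assert (call.supporting_reads, call.covering_reads) == (56, 56)
    assert call.substitution == (1, "T")


def test_substitution_not_removing_stop_is_no_call():
    genome, g, site, pile = _sub_fixture()
    # reads say TAG instead: still a stop codon when re-entered
    pile.loc[pile["pos"] == 20, ["A", "G"]] = [0, 56]
    pile.loc[pile["pos"] == 20, "T"] = 0
    mid = pile["pos"] == 20
    call = audit_site(site, pile)
    assert call.call in ("NO_CALL", "GENOME_SUBSTITUTION")
    if call.call == "GENOME_SUBSTITUTION":       # must not come from pos 20
        assert call.substitution[0] != 2 or call.substitution[1] != "G"


# ----------------------------------------------------------------------
# repair

def test_deletion_repair_inserts_one_isoleucine():
    genome, g, site, pile = _del_fixture()
    call = audit_site(site, pile)
    repair = propose_repair(call, genome, g.transcripts[0])
    assert repair.status == "REPAIRED"
    assert repair.consequence == "+1 Ile"
    assert "*" not in repair.repaired_cds and \
        repair.repaired_cds == repair.repaired_cds


def test_substitution_repair_yields_leucine_and_removes_stop():
    genome, g, site, pile = _sub_fixture()
    call = audit_site(site, pile)
    repair = propose_repair(call, genome, g.transcripts[0])
    assert repair.status == "REPAIRED"
    assert repair.consequence == "+1 Leu, stop removed"


def test_repair_failing_on_downstream_stop_is_reported():
    # inserted base completes a codon, but the next codon is a real stop
    genome = {"c": "ATGGATGATGATGAAGAT" + "AT" + "TAAGATGATTGAGATTAA" + "AA"}
    g = _gene([(0, 18), (20, 38)], (0, 38))
    (site,) = find_micro_introns([g], genome)
    entries = [{"pos": p, "ref": genome["c"][p], genome["c"][p]: 23}
               for p in range(15, 26)]
    for e in entries:
        if e["pos"] == 20:
            e["ins"] = 23
            e["ins_base"] = "T"
    call = audit_site(site, _pileup("c", entries))
    assert call.call == "GENOME_DELETION"
    repair = propose_repair(call, genome, g.transcripts[0])
    assert repair.status == "REPAIR_FAILED"
    assert repair.fail_position is not None


def test_audit_report_recovers_planted_genome_errors(full_run,
                                                     full_pipeline_result):
    calls = full_pipeline_result.audit_calls
    by_site = {(c.site.contig_id, c.site.interval): c for c in calls}
    for e in full_run.ledger:
        if e.kind is DefectKind.GENOME_BASE_DELETION:
            call = by_site[(e.contig_id, (e.start, e.end))]
            assert call.call == "GENOME_DELETION"
            assert [call.supporting_reads, call.covering_reads] == \
                e.details["support"]
        elif e.kind is DefectKind.GENOME_BASE_SUBSTITUTION:
            call = by_site[(e.contig_id, (e.start, e.end))]
            assert call.call == "GENOME_SUBSTITUTION"
    # soundness: no spurious calls beyond the planted errors
    planted = {(e.contig_id, (e.start, e.end)) for e in full_run.ledger
               if e.kind in (DefectKind.GENOME_BASE_DELETION,
                             DefectKind.GENOME_BASE_SUBSTITUTION)}
    called = {k for k, c in by_site.items() if c.call != "NO_CALL"}
    assert called == planted


def test_empty_model_set_gives_empty_report():
    calls, table, rollup = audit_report([], {"c": "ACGT"}, _pileup("c", []))
    assert calls == [] and rollup["n_sites"] == 0


def test_support_times_covering_is_integral(full_pipeline_result):
    for c in full_pipeline_result.audit_calls:
        if c.covering_reads:
            assert c.support * c.covering_reads == pytest.approx(
                c.supporting_reads)
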