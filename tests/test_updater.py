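"""Update-category rules, protein-change classification, re-annotation."""

import numpy as np
import pytest

from annoforge.align import LocusStructure
from annoforge.models import GeneModel, TranscriptModel, revcomp
from annoforge.updater import (InternalStopError, UpdateConflictError,
                               apply_updates, canonical_introns, classify_all,
                               classify_protein_change, classify_update)


def _codons(rng, n):
    stops = {"TAA", "TAG", "TGA"}
    out = []
    while len(out) < n:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in stops:
            out.append(c)
    return out


def _mini_locus(seed=0, n_exons=3, codons=90, utr5=60, utr3=60, intron=40):
    """A tiny synthetic gene on one contig; returns (genome, gene, mrna exons)."""
    rng = np.random.default_rng(seed)
    cods = ["ATG"] + _codons(rng, codons - 2) + ["TAA"]
    per = codons // n_exons
    chunks = [cods[i * per:(i + 1) * per] for i in range(n_exons - 1)]
    chunks.append(cods[(n_exons - 1) * per:])
    u5 = "".join(rng.choice(list("ACGT"), size=utr5))
    u3 = "".join(rng.choice(list("ACGT"), size=utr3))
    parts, pos, exons = [], 0, []
    cds_start = cds_end = 0
    for i, chunk in enumerate(chunks):
        start = pos
        if i == 0:
            parts.append(u5)
            pos += utr5
            cds_start = pos
        seq = "".join(chunk)
        parts.append(seq)
        pos += len(seq)
        if i == n_exons - 1:
            cds_end = pos
            parts.append(u3)
            pos += utr3
        exons.append((start, pos))
        if i < n_exons - 1:
            iseq = "GT" + "".join(rng.choice(list("ACGT"), size=intron - 4)) + "AG"
            parts.append(iseq)
            pos += intron
    genome = {"c": "A" * 50 + "".join(parts) + "A" * 50}
    exons = [(s + 50, e + 50) for s, e in exons]
    cds = (cds_start + 50, cds_end + 50)
    t = TranscriptModel("g1.1", "g1", "c", "+", exons, cds)
    return genome, GeneModel("g1", "c", "+", [t]), exons


def _structure(exons, sid="s1", strand="+", contig="c"):
    return LocusStructure(sid, contig, strand, [tuple(e) for e in exons],
                          transcript_ids=[sid])


def test_identical_structure_is_unchanged():
    genome, gene, exons = _mini_locus()
    (rec,) = classify_update([gene], [_structure(exons)], genome)
    assert rec.category == "UNCHANGED"


def test_utr_extension_of_cds_only_model_is_utr_only():
    genome, gene, exons = _mini_locus()
    t = gene.transcripts[0]
    cs, ce = t.cds
    trimmed = [(max(s, cs), min(e, ce)) for s, e in exons
               if min(e, ce) > max(s, cs)]
    observed = GeneModel("g1", "c", "+", [
        TranscriptModel("g1.1", "g1", "c", "+", trimmed, (cs, ce))])
    (rec,) = classify_update([observed], [_structure(exons)], genome)
    assert rec.category == "UTR_ONLY"
    assert rec.protein_change == "NONE"


def test_structure_at_empty_locus_is_novel_gene():
    genome, gene, exons = _mini_locus()
    (rec,) = classify_update([], [_structure(exons)], genome)
    assert rec.category == "NOVEL_GENE"
    assert rec.old_gene_ids == []


def test_antisense_structure_reports_strand_conflict():
    genome, gene, exons = _mini_locus()
    (rec,) = classify_update([gene], [_structure(exons, strand="-")], genome)
    assert rec.category == "NOVEL_GENE"
    assert "strand conflict" in rec.details


def test_structure_spanning_two_models_with_one_orf_is_merge():
    genome, gene, exons = _mini_locus()
    t = gene.transcripts[0]
    # observed: the gene wrongly split in two at the first intron
    a = GeneModel("g1_a", "c", "+", [TranscriptModel(
        "g1_a.1", "g1_a", "c", "+", exons[:1], (t.cds[0], exons[0][1]))])
    b = GeneModel("g1_b", "c", "+", [TranscriptModel(
        "g1_b.1", "g1_b", "c", "+", exons[1:], (exons[1][0], t.cds[1]))])
    (rec,) = classify_update([a, b], [_structure(exons)], genome)
    assert rec.category == "MERGE"
    assert set(rec.old_gene_ids) == {"g1_a", "g1_b"}


def test_disjoint_structures_over_broken_fused_model_is_split():
    g1, gene1, exons1 = _mini_locus(seed=1)
    rng = np.random.default_rng(9)
    contig = g1["c"]
    # a second, independent gene downstream on the same contig
    g2, gene2, exons2 = _mini_locus(seed=2)
    shift = len(contig) + 20
    contig2 = contig + "".join(rng.choice(list("ACGT"), size=20)) + g2["c"]
    genome = {"c": contig2}
    exons2 = [(s + shift, e + shift) for s, e in exons2]
    t1, t2 = gene1.transcripts[0], gene2.transcripts[0]
    fused = GeneModel("fused", "c", "+", [TranscriptModel(
        "fused.1", "fused", "c", "+", exons1 + exons2,
        (t1.cds[0], t2.cds[1] + shift))])
    s1, s2 = _structure(exons1, "s1"), _structure(exons2, "s2")
    records = classify_update([fused], [s1, s2], genome)
    (rec,) = [r for r in records if r.category == "SPLIT"]
    assert rec.old_gene_ids == ["fused"]
    assert len(rec.new_structures) == 2


def test_exon_skip_with_retained_sibling_is_new_isoform():
    genome, gene, exons = _mini_locus()
    skipped = [exons[0], exons[2]]
    records = classify_update([gene],
                              [_structure(exons, "s1"),
                               _structure(skipped, "s2")], genome)
    cats = {r.new_structures[0].structure_id: r.category for r in records}
    assert cats["s1"] == "UNCHANGED"
    assert cats["s2"] == "NEW_ISOFORM"


def test_junction_shift_is_neutralised_by_canonicalisation():
    genome, gene, exons = _mini_locus()
    contig = genome["c"]
    (i_s, i_e) = gene.transcripts[0].introns[0]
    # shift the first junction right wherever the sequence allows
    shifted = list(exons)
    if contig[i_s] == contig[i_e]:
        shifted[0] = (exons[0][0], exons[0][1] + 1)
        shifted[1] = (exons[1][0] + 1, exons[1][1])
    assert canonical_introns(exons, contig) == \
        canonical_introns(shifted, contig)


# ----------------------------------------------------------------------
# protein change

AA = {"A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
      "E": "GAA", "Q": "CAA", "G": "GGT", "H": "CAT", "I": "ATT",
      "L": "TTA", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
      "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT"}


def _cds(protein):
    return "".join(AA[a] for a in protein) + "TAA"


def test_protein_change_classes():
    base = "M" + "ACDEFGHIKLNPQRSTVWY" * 5
    assert classify_protein_change(_cds(base), _cds(base)) == "NONE"
    assert classify_protein_change(_cds(base), _cds(base[45:])) == \
        "N_TRUNCATION"                      # shortened by 45 residues
    assert classify_protein_change(_cds(base[45:]), _cds(base)) == \
        "N_EXTENSION"
    assert classify_protein_change(_cds(base), _cds(base[:-20])) == \
        "C_TRUNCATION"
    assert classify_protein_change(_cds(base), _cds(base + "WYV" * 10)) == \
        "C_EXTENSION"
    inserted = base[:40] + "GHIKLMNPQRSTVWYACDEFGHIKLMNPQR" + base[40:]
    assert classify_protein_change(_cds(base), _cds(inserted)) == \
        "EXON_GAIN_PROTEIN"                 # one 30-residue block gained
    assert classify_protein_change(_cds(inserted), _cds(base)) == \
        "EXON_LOSS_PROTEIN"
    scrambled = base[:20] + base[25:20:-1] + base[25:]
    assert classify_protein_change(_cds(base), _cds(scrambled)) == \
        "INTERNAL_CHANGE"


def test_internal_stop_is_flagged_not_classified():
    good = _cds("M" + "ACDEF" * 12)
    broken = "ATG" + "TAA" + good[6:]
    with pytest.raises(InternalStopError):
        classify_protein_change(broken, good)


# ----------------------------------------------------------------------
# apply_updates

def test_zero_records_leave_annotation_unchanged():
    genome, gene, _ = _mini_locus()
    updated, summary = apply_updates([gene], [], genome)
    assert updated == [gene]
    assert summary.loc[summary["category"] == "Novel genes", "count"].item() == 0


def test_forge_recovery_summary_counts(full_pipeline_result, full_run):
    summary = full_pipeline_result.update_summary
    get = lambda label: summary.loc[summary["category"] == label,
                                    "count"].item()
    assert get("  UTR_ONLY") == 10
    assert get("  MERGE") == 3
    assert get("New alternate splice isoforms") == 4
    assert get("Novel genes") == 5


def test_merge_applies_one_gene_where_two_existed(full_pipeline_result,
                                                  full_run, tmp_path):
    from annoforge import io
    path = tmp_path / "updated.gff3"
    io.write_gff3(full_pipeline_result.updated_annotation, path)
    updated = {g.gene_id for g in io.read_gff3(path)}
    for r in full_pipeline_result.update_records:
        if r.category == "MERGE":
            assert all(g not in updated for g in r.old_gene_ids)
            assert any(g.startswith(r.old_gene_ids[0]) and
                       g.endswith("_merged") for g in updated)


def test_updater_is_idempotent(full_pipeline_result, full_run):
    res = full_pipeline_result
    records = classify_all(res.updated_annotation, res.loci, full_run.genome)
    assert {r.category for r in records} == {"UNCHANGED"}


def test_conflicting_records_are_rejected():
    genome, gene, exons = _mini_locus()
    (r1,) = classify_update([gene], [_structure(exons[:2], "s1")], genome)
    (r2,) = classify_update([gene], [_structure([exons[0]], "s2")], genome)
    assert r1.category != "UNCHANGED" and r2.category != "UNCHANGED"
    with pytest.raises(UpdateConflictError):
        apply_updates([gene], [r1, r2], genome)
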