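"""ORF extraction, artefact flagging and the orphan elimination ladder."""

import numpy as np
import pytest

from annoforge.models import SequenceRecord, revcomp
from annoforge.orphans import (classify_orphans, flag_artefact, longest_orf)


def test_minimal_orf_is_found_and_translated():
    orf = longest_orf("ATGAAATAG", min_len_aa=1)
    assert orf is not None
    assert orf.peptide == "MK" and orf.aa_length == 2
    assert not orf.partial


def test_orf_running_off_the_end_is_partial():
    seq = "ATG" + "GAT" * 99          # no stop before the sequence ends
    orf = longest_orf(seq, min_len_aa=1)
    assert orf.partial
    assert orf.aa_length == 100


def test_all_stop_sequence_has_no_orf():
    assert longest_orf("TAA" * 40, min_len_aa=1) is None


def test_orf_found_on_reverse_frames():
    fwd = "ATG" + "GAT" * 60 + "TAA"
    orf = longest_orf(revcomp(fwd), min_len_aa=50)
    assert orf is not None and orf.frame.startswith("-")
    assert orf.peptide == "M" + "D" * 60


def test_below_threshold_orf_returns_none():
    assert longest_orf("ATGAAATAG", min_len_aa=50) is None


def test_flag_artefact_on_coding_and_short_sequences():
    coding = "ATG" + "GAT" * 120 + "TAA"
    assert not flag_artefact(coding)
    assert flag_artefact("AC" * 60)          # < 150 bp, no plausible ORF


def test_forge_artefacts_flagged_real_transcripts_not(full_run):
    for rec in full_run.output.artefacts:
        assert flag_artefact(rec.sequence)
    genomic = [t for g in full_run.truth for t in g.transcripts]
    for t in genomic[:20]:
        seq = t.spliced_sequence(full_run.genome)
        if len(seq) >= 300:
            assert not flag_artefact(seq)


# ----------------------------------------------------------------------
# ladder

def _seq(rng, n, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _coding_seq(rng, n_codons):
    stops = {"TAA", "TAG", "TGA"}
    out = ["ATG"]
    while len(out) < n_codons - 1:
        c = _seq(rng, 3)
        if c not in stops:
            out.append(c)
    return "".join(out) + "TAA"


@pytest.fixture(scope="module")
def ladder():
    rng = np.random.default_rng(77)
    related = [SequenceRecord(f"rel{i}", _coding_seq(rng, 150))
               for i in range(3)]
    nonrel = [SequenceRecord(f"bac{i}", _seq(rng, 700, gc=0.55))
              for i in range(3)]
    cdna = [SequenceRecord(f"cdna{i}", _coding_seq(rng, 200))
            for i in range(2)]
    return rng, cdna, related, nonrel


def test_ladder_assigns_each_rung(ladder):
    rng, cdna, related, nonrel = ladder
    novel = SequenceRecord("nov", _coding_seq(rng, 120))
    tx = [
        SequenceRecord("t_aligned", _seq(rng, 400)),
        SequenceRecord("t_cdna", cdna[0].sequence),
        SequenceRecord("t_known", related[1].sequence),
        SequenceRecord("t_artefact", nonrel[2].sequence),
        novel,
    ]
    records, matrix = classify_orphans(tx, {"t_aligned"}, cdna_db=cdna,
                                       related_db=related,
                                       nonrelated_db=nonrel)
    cats = {r.transcript_id: r.category for r in records}
    assert cats == {"t_aligned": "ANNOTATED", "t_cdna": "ANNOTATED",
                    "t_known": "KNOWN", "t_artefact": "ARTEFACT",
                    "nov": "NOVEL"}
    assert matrix.to_numpy().sum() == len(tx)


def test_translated_rung_rescues_synonymous_homologue(ladder):
    rng, cdna, related, nonrel = ladder
    # recode a related protein with maximally different synonymous codons:
    # no shared nucleotide 11-mer, same peptide
    syn = {"GCT": "GCA", "GCA": "GCT", "GAT": "GAC", "GAC": "GAT",
           "AAA": "AAG", "AAG": "AAA", "GGT": "GGA", "GGA": "GGT"}
    from annoforge.models import translate
    src = related[0].sequence
    recoded = "".join(
        syn.get(src[i:i + 3], src[i:i + 3]) for i in range(0, len(src), 3))
    assert translate(recoded) == translate(src)
    records, _ = classify_orphans(
        [SequenceRecord("t", recoded)], set(), related_db=related)
    assert records[0].category == "KNOWN"
    assert records[0].best_hit[0] in ("related", "related-protein")


def test_growing_related_db_only_moves_toward_known(ladder):
    rng, cdna, related, nonrel = ladder
    tx = [SequenceRecord("a", nonrel[0].sequence),
          SequenceRecord("b", _coding_seq(rng, 120))]
    before, _ = classify_orphans(tx, set(), nonrelated_db=nonrel)
    grown = list(related) + [SequenceRecord("new1", tx[0].sequence),
                             SequenceRecord("new2", tx[1].sequence)]
    after, _ = classify_orphans(tx, set(), related_db=grown,
                                nonrelated_db=nonrel)
    for b, a in zip(before, after):
        assert b.category in ("ARTEFACT", "NOVEL")
        assert a.category == "KNOWN"


def test_partition_is_exhaustive_on_forge_orphans(full_pipeline_result):
    records = full_pipeline_result.orphan_records
    matrix = full_pipeline_result.orphan_matrix
    assert matrix.to_numpy().sum() == len(records)
    assert all(r.category in ("ANNOTATED", "KNOWN", "ARTEFACT", "NOVEL")
               for r in records)


def test_gap_withheld_novel_gene_classifies_as_novel():
    """A gene whose locus sits in an assembly gap fails alignment and must
    come out of the ladder as NOVEL, not ARTEFACT."""
    from annoforge.forge import DefectKind, ForgeConfig, run_forge
    from annoforge.pipeline import run_pipeline

    cfg = ForgeConfig(seed=21, n_genes=30, novel_gap_count=2, defect_spec={
        DefectKind.NOVEL_GENE_UNANNOTATED: 2,
        DefectKind.CONTAMINANT_CONTIG: 2,
        DefectKind.SPIKEIN_CONTIG: 1,
    })
    run = run_forge(cfg)
    res = run_pipeline(run.genome, run.observed, run.evidence.transcripts,
                       run.evidence.read_counts, run.evidence.pileup,
                       run.evidence.taxon_map,
                       spikein_db=run.output.spikein_db,
                       nonrelated_db=run.output.contaminants)
    by_id = {r.transcript_id: r for r in res.orphan_records}
    for e in run.ledger:
        if e.kind is DefectKind.NOVEL_GENE_UNANNOTATED:
            assert e.details.get("in_gap")
            assert by_id[e.transcript_ids[0]].category == "NOVEL"
        elif e.kind is DefectKind.CONTAMINANT_CONTIG:
            assert by_id[e.transcript_ids[0]].category == "ARTEFACT"
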