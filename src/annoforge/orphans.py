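"""Triage of transcripts that fail genome alignment.

Orphan transcripts are either genuine mRNAs whose genomic locus sits in an
assembly gap, sequences from other organisms (library contamination), or
mis-assembled chimeras. A process-of-elimination ladder sorts them:

1. hit to the reference genome or a cDNA database → ANNOTATED
2. nucleotide hit to a related-species database → KNOWN
3. nucleotide hit to a non-related-species database → ARTEFACT
4. translated search of the longest predicted ORF against the related
   database → KNOWN
5. multiple stop codons in every reading frame (no ORF of plausible
   length anywhere) → ARTEFACT, the signature of an assembly error
6. otherwise → NOVEL
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .models import STOP_CODONS, SequenceRecord, revcomp
from .search import LocalHit, search_db, translated_search

CATEGORIES = ("ANNOTATED", "KNOWN", "ARTEFACT", "NOVEL")

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")


@dataclass
class Orf:
    frame: str          # +1..+3 / -1..-3
    nt_start: int       # [nt_start, nt_end) on the frame-oriented sequence
    nt_end: int
    peptide: str
    partial: bool       # ran off the end of the sequence without a stop

    @property
    def aa_length(self) -> int:
        return len(self.peptide)


@dataclass
class SearchThresholds:
    """Acceptance thresholds for the internal similarity searches."""

    cdna_identity: float = 0.90
    cdna_coverage: float = 0.50
    nt_identity: float = 0.75
    nt_coverage: float = 0.50
    prot_identity: float = 0.30
    prot_coverage: float = 0.50
    orf_min_aa: int = 50


@dataclass
class OrphanRecord:
    transcript_id: str
    aligned_to_reference: bool
    category: str
    best_hit: Optional[tuple[str, str, float]] = None   # (db, subject, identity)
    longest_orf: Optional[Orf] = None
    multi_stop_flag: bool = False


_CODON_TABLE = {}


def _aa(codon: str) -> str:
    from Bio.Seq import Seq
    if codon not in _CODON_TABLE:
        _CODON_TABLE[codon] = str(Seq(codon).translate())
    return _CODON_TABLE[codon]


def _frame_iter(sequence: str, forward_only: bool = False):
    for frame in FRAMES[:3] if forward_only else FRAMES:
        oriented = sequence if frame[0] == "+" else revcomp(sequence)
        off = int(frame[1]) - 1
        yield frame, oriented, off


def longest_orf(sequence: str, require_start: bool = True,
                min_len_aa: int = 50,
                forward_only: bool = False) -> Optional[Orf]:
    """Longest open reading frame over all six frames.

    With ``require_start`` the ORF must begin at ATG; it ends at the first
    stop codon or, marked partial, at the end of the sequence (assemblies
    truncate transcripts, so running off the end is informative rather
    than disqualifying). Ties break by frame order (+1..+3, -1..-3), then
    by position.
    """
    if len(sequence) < 3:
        return None
    best: Optional[Orf] = None
    for frame, oriented, off in _frame_iter(sequence, forward_only):
        start: Optional[int] = None
        i = off
        while i + 3 <= len(oriented):
            codon = oriented[i:i + 3]
            if start is None and (not require_start or codon == "ATG"):
                start = i
            if start is not None and codon in STOP_CODONS:
                best = _better(best, _make_orf(frame, oriented, start, i,
                                               partial=False), min_len_aa)
                start = None
            i += 3
        if start is not None:
            best = _better(best, _make_orf(frame, oriented, start,
                                           len(oriented) - (len(oriented)
                                                            - start) % 3,
                                           partial=True), min_len_aa)
    return best


def _make_orf(frame: str, oriented: str, start: int, stop_at: int,
              partial: bool) -> Orf:
    from .models import translate
    end = stop_at if partial else stop_at + 3     # include the stop codon
    pep = translate(oriented[start:end])
    if pep.endswith("*"):
        pep = pep[:-1]
    return Orf(frame, start, end, pep, partial)


def _better(best: Optional[Orf], cand: Orf, min_len_aa: int) -> Optional[Orf]:
    if cand.aa_length < min_len_aa:
        return best
    if best is None or cand.aa_length > best.aa_length:
        return cand
    return best


def flag_artefact(sequence: str, min_len_aa: int = 50) -> bool:
    """True iff no reading frame holds a stop-free stretch of min_len_aa codons.

    Such sequences carry multiple stop codons in all reading frames — the
    signature of shuffled, mis-assembled contigs rather than real mRNA.
    """
    for _, oriented, off in _frame_iter(sequence):
        run = 0
        for i in range(off, len(oriented) - 2, 3):
            if oriented[i:i + 3] in STOP_CODONS:
                run = 0
            else:
                run += 1
                if run >= min_len_aa:
                    return False
    return True


def classify_orphans(transcripts: Sequence[SequenceRecord],
                     aligned_ids: set[str],
                     cdna_db: Sequence[SequenceRecord] = (),
                     related_db: Sequence[SequenceRecord] = (),
                     nonrelated_db: Sequence[SequenceRecord] = (),
                     thresholds: Optional[SearchThresholds] = None
                     ) -> tuple[list[OrphanRecord], pd.DataFrame]:
    """Run the elimination ladder and tabulate categories by alignment status.

    Empty databases simply skip their rung. The count matrix has one row
    per alignment status and one column per category; it always sums to
    the number of input transcripts.
    """
    thr = thresholds or SearchThresholds()
    records: list[OrphanRecord] = []
    for rec in transcripts:
        aligned = rec.id in aligned_ids
        orf = longest_orf(rec.sequence, require_start=True, min_len_aa=1)
        multi_stop = flag_artefact(rec.sequence, thr.orf_min_aa)
        category = None
        best_hit = None
        if aligned:
            category = "ANNOTATED"
            best_hit = ("genome", "reference", 1.0)
        if category is None and cdna_db:
            hit = search_db(rec.sequence, cdna_db,
                            thr.cdna_identity, thr.cdna_coverage)
            if hit:
                category = "ANNOTATED"
                best_hit = ("cdna", hit.subject_id, hit.identity)
        if category is None and related_db:
            hit = search_db(rec.sequence, related_db,
                            thr.nt_identity, thr.nt_coverage)
            if hit:
                category = "KNOWN"
                best_hit = ("related", hit.subject_id, hit.identity)
        if category is None and nonrelated_db:
            hit = search_db(rec.sequence, nonrelated_db,
                            thr.nt_identity, thr.nt_coverage)
            if hit:
                category = "ARTEFACT"
                best_hit = ("nonrelated", hit.subject_id, hit.identity)
        if category is None and related_db and orf is not None \
                and orf.aa_length >= thr.orf_min_aa:
            hit = translated_search(orf.peptide, related_db,
                                    thr.prot_identity, thr.prot_coverage)
            if hit:
                category = "KNOWN"
                best_hit = ("related-protein", hit.subject_id, hit.identity)
        if category is None:
            category = "ARTEFACT" if multi_stop else "NOVEL"
        records.append(OrphanRecord(rec.id, aligned, category, best_hit,
                                    orf, multi_stop))

    matrix = pd.DataFrame(0, index=["aligned", "not_aligned"],
                          columns=list(CATEGORIES))
    for r in records:
        row = "aligned" if r.aligned_to_reference else "not_aligned"
        matrix.loc[row, r.category] += 1
    return records, matrix
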