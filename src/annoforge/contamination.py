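"""Spike-in removal and GC/coverage/taxon (TAGC) contamination filtering.

Cultures grown on a bacterial food source carry bacterial transcripts into
the assembly; spike-in controls (ERCC-style) must also come out before any
biological interpretation. Spike-ins are removed by local alignment
against the spike-in sequence database. Contaminants are resolved by the
taxon-annotated GC-coverage rule: a transcript with a taxon inside the
target lineage is kept, one with a foreign taxon is removed, and an
unassigned transcript is kept only while its GC content stays within
``mean ± k·sd`` of the taxon-confirmed target transcripts (the explicit
counterpart of eyeballing a blob plot).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Optional, Sequence

from .metrics import gc_fraction
from .models import SequenceRecord
from .search import search_db

DEFAULT_SPIKE_IDENTITY = 0.90
DEFAULT_SPIKE_COVERAGE = 0.50
DEFAULT_GC_BAND_K = 3.0
DEFAULT_READ_LENGTH = 100


@dataclass
class TagcRecord:
    contig_id: str
    gc: float
    coverage: float
    taxon: str                    # label or "UNASSIGNED"
    verdict: str = ""             # TARGET | CONTAMINANT | UNASSIGNED_KEPT |
                                  # UNASSIGNED_REMOVED


def remove_spikeins(transcripts: Sequence[SequenceRecord],
                    spikein_db: Sequence[SequenceRecord],
                    min_identity: float = DEFAULT_SPIKE_IDENTITY,
                    min_coverage: float = DEFAULT_SPIKE_COVERAGE
                    ) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Partition transcripts into (kept, removed-as-spike-in).

    A transcript is removed when it has a local alignment to any spike-in
    at >= min_identity over >= min_coverage of the transcript — chimeras
    that are half spike-in are removed at the defaults.
    """
    if not spikein_db:
        raise ValueError("spike-in database is empty")
    kept, removed = [], []
    for rec in transcripts:
        hit = search_db(rec.sequence, spikein_db, min_identity, min_coverage)
        (removed if hit else kept).append(rec)
    return kept, removed


def compute_tagc(transcripts: Sequence[SequenceRecord],
                 read_counts: dict[str, int],
                 taxon_map: dict[str, str],
                 read_length: int = DEFAULT_READ_LENGTH) -> list[TagcRecord]:
    """One GC/coverage/taxon record per transcript.

    Coverage is the read-count proxy count × read_length / contig_length;
    transcripts absent from the taxon map are UNASSIGNED.
    """
    records = []
    for rec in transcripts:
        if rec.id not in read_counts:
            raise ValueError(f"no read count for transcript {rec.id!r}")
        records.append(TagcRecord(
            contig_id=rec.id,
            gc=gc_fraction([rec.sequence]),
            coverage=read_counts[rec.id] * read_length / len(rec),
            taxon=taxon_map.get(rec.id, "UNASSIGNED"),
        ))
    return records


def filter_contaminants(records: Sequence[TagcRecord],
                        target_lineage: Sequence[str],
                        gc_band_k: float = DEFAULT_GC_BAND_K
                        ) -> tuple[list[str], list[str], list[TagcRecord]]:
    """Assign TAGC verdicts; return (kept ids, removed ids, annotated records).

    ``target_lineage`` entries match as label prefixes ("Dictyostelium"
    matches "Dictyostelium discoideum").
    """
    def in_lineage(taxon: str) -> bool:
        return any(taxon.startswith(p) for p in target_lineage)

    target_gc = [r.gc for r in records
                 if r.taxon != "UNASSIGNED" and in_lineage(r.taxon)]
    if not target_gc:
        raise ValueError("no record carries a target-lineage taxon; "
                         "the GC band is undefined")
    mean = sum(target_gc) / len(target_gc)
    sd = sqrt(sum((x - mean) ** 2 for x in target_gc) / len(target_gc))
    lo, hi = mean - gc_band_k * sd, mean + gc_band_k * sd

    kept, removed = [], []
    for r in records:
        if r.taxon != "UNASSIGNED":
            r.verdict = "TARGET" if in_lineage(r.taxon) else "CONTAMINANT"
        else:
            r.verdict = ("UNASSIGNED_KEPT" if lo <= r.gc <= hi
                         else "UNASSIGNED_REMOVED")
        (kept if r.verdict in ("TARGET", "UNASSIGNED_KEPT")
         else removed).append(r.contig_id)
    return kept, removed, list(records)
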