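"""Protein-coding consequence of splice events.

An event is a direct CDS change when its alternatively included region
overlaps an annotated CDS interval of the gene's transcripts (≥1 bp,
strand-aware, same gene only).  Otherwise it is a likely CDS change when the
protein-sequence sets of the inclusion and exclusion isoforms are disjoint
(exact string comparison; an empty side against a non-empty side counts as
disjoint, since the two forms then necessarily differ in coding output).
Direct changes take precedence over likely changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .events import SpliceEvent

VERDICTS = ("cds_change", "likely_cds_change", "no_change")


@dataclass
class CdsAnnotation:
    """CDS intervals (0-based half-open, genome coordinates) and protein
    sequences, indexed by transcript, with the gene → transcript map."""

    cds_by_transcript: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    protein_by_transcript: dict[str, str] = field(default_factory=dict)
    transcripts_by_gene: dict[str, list[str]] = field(default_factory=dict)
    strand_by_transcript: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_gtf(cls, gtf_path, proteins: pd.Series | None = None) -> "CdsAnnotation":
        """Load from a GTF with CDS features (gffutils), optionally joined
        with a transcript → protein-sequence table."""
        import gffutils

        db = gffutils.create_db(
            str(gtf_path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        ann = cls()
        for tx in db.features_of_type("transcript"):
            tid = tx.attributes["transcript_id"][0]
            gid = tx.attributes["gene_id"][0]
            ann.transcripts_by_gene.setdefault(gid, []).append(tid)
            ann.strand_by_transcript[tid] = tx.strand
            ann.cds_by_transcript.setdefault(tid, [])
        for cds in db.features_of_type("CDS"):
            tid = cds.attributes["transcript_id"][0]
            # GTF is 1-based closed; internal is 0-based half-open
            ann.cds_by_transcript.setdefault(tid, []).append((cds.start - 1, cds.end))
        if proteins is not None:
            ann.protein_by_transcript = {
                t: p for t, p in proteins.items() if isinstance(p, str) and p
            }
        return ann


@dataclass
class CdsVerdict:
    event_id: str
    verdict: str
    detail: str = ""


def classify_direct(event: SpliceEvent, ann: CdsAnnotation) -> bool:
    """True iff the alternative region overlaps (≥1 bp) any CDS interval of
    the gene's transcripts on the same strand."""
    if event.gene_id not in ann.transcripts_by_gene:
        raise KeyError(f"gene {event.gene_id} absent from annotation")
    a0, a1 = event.alt_region
    for tid in ann.transcripts_by_gene[event.gene_id]:
        if ann.strand_by_transcript.get(tid, event.strand) != event.strand:
            continue
        for c0, c1 in ann.cds_by_transcript.get(tid, ()):
            if max(a0, c0) < min(a1, c1):
                return True
    return False


def classify_likely(event: SpliceEvent, ann: CdsAnnotation) -> bool:
    """True iff the protein-sequence sets of the inclusion and exclusion
    isoforms share no sequence string."""
    if not event.inclusion_isoforms or not event.exclusion_isoforms:
        raise ValueError(f"{event.event_id}: empty isoform set")
    inc = {
        ann.protein_by_transcript[t]
        for t in event.inclusion_isoforms
        if t in ann.protein_by_transcript
    }
    exc = {
        ann.protein_by_transcript[t]
        for t in event.exclusion_isoforms
        if t in ann.protein_by_transcript
    }
    if not inc and not exc:
        return False  # no coding output on either side: nothing changes
    return not (inc & exc)


def classify(event: SpliceEvent, ann: CdsAnnotation) -> CdsVerdict:
    if classify_direct(event, ann):
        return CdsVerdict(event.event_id, "cds_change", "alt region overlaps annotated CDS")
    if classify_likely(event, ann):
        return CdsVerdict(
            event.event_id, "likely_cds_change", "disjoint inclusion/exclusion protein sets"
        )
    return CdsVerdict(event.event_id, "no_change", "")


def classify_events(events, ann: CdsAnnotation) -> pd.DataFrame:
    rows = [classify(ev, ann) for ev in events]
    return pd.DataFrame(
        {
            "event_id": [r.event_id for r in rows],
            "verdict": [r.verdict for r in rows],
            "detail": [r.detail for r in rows],
        }
    ).set_index("event_id")
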