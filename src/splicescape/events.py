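"""Splice-event model shared by every stage.

An event is one of the four basic alternative-splicing classes — skipped
exon (SE), alternative 5'/3' splice site (A5SS/A3SS), retained intron (RI) —
defined by the junctions that support its inclusion and exclusion forms and
by the transcript isoforms that realize each form.  All internal coordinates
are 0-based half-open; GTF output is converted to 1-based closed at the I/O
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

EVENT_TYPES = ("SE", "A5SS", "A3SS", "RI")

#: junction multiplicity used to length-normalize inclusion support
INCLUSION_MULTIPLICITY = {"SE": 2, "A5SS": 1, "A3SS": 1, "RI": 1}


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event.

    ``alt_region`` is the alternatively included interval (the skipped exon,
    the extended splice-site region, or the retained intron).  ``splice_sites``
    are the genomic coordinates of every donor/acceptor defining the event
    (4 for SE, 2 for A5SS/A3SS/RI).
    """

    event_id: str
    etype: str
    gene_id: str
    chrom: str
    strand: str
    inclusion_junctions: tuple[str, ...]
    exclusion_junctions: tuple[str, ...]
    inclusion_isoforms: frozenset = field(default_factory=frozenset)
    exclusion_isoforms: frozenset = field(default_factory=frozenset)
    alt_region: tuple[int, int] = (0, 0)
    splice_sites: tuple[int, ...] = ()

    def __post_init__(self):
        if self.etype not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.etype!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.alt_region[0] > self.alt_region[1]:
            raise ValueError("alt_region coordinates out of order")
        if self.inclusion_isoforms & self.exclusion_isoforms:
            raise ValueError("inclusion and exclusion isoform sets overlap")

    @property
    def identity_key(self) -> tuple:
        """Cross-method identity: type + location + ordered splice sites."""
        return (self.etype, self.chrom, self.strand, tuple(sorted(self.splice_sites)))

    @property
    def first_splice_site(self) -> int:
        """5'-most splice site in transcriptional orientation (strand-aware)."""
        return min(self.splice_sites) if self.strand == "+" else max(self.splice_sites)

    @property
    def inclusion_multiplicity(self) -> int:
        return INCLUSION_MULTIPLICITY[self.etype]


def events_to_frame(events: Iterable[SpliceEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(
            {
                "event_id": ev.event_id,
                "type": ev.etype,
                "gene_id": ev.gene_id,
                "chrom": ev.chrom,
                "strand": ev.strand,
                "alt_start": ev.alt_region[0],
                "alt_end": ev.alt_region[1],
                "splice_sites": ",".join(map(str, ev.splice_sites)),
                "inclusion_junctions": ",".join(ev.inclusion_junctions),
                "exclusion_junctions": ",".join(ev.exclusion_junctions),
                "inclusion_isoforms": ",".join(sorted(ev.inclusion_isoforms)),
                "exclusion_isoforms": ",".join(sorted(ev.exclusion_isoforms)),
            }
        )
    return pd.DataFrame(rows)


def events_from_frame(df: pd.DataFrame) -> list[SpliceEvent]:
    def _split(s) -> tuple[str, ...]:
        if pd.isna(s) or s == "":
            return ()
        return tuple(str(s).split(","))

    out = []
    for row in df.itertuples(index=False):
        out.append(
            SpliceEvent(
                event_id=row.event_id,
                etype=row.type,
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                inclusion_junctions=_split(row.inclusion_junctions),
                exclusion_junctions=_split(row.exclusion_junctions),
                inclusion_isoforms=frozenset(_split(row.inclusion_isoforms)),
                exclusion_isoforms=frozenset(_split(row.exclusion_isoforms)),
                alt_region=(int(row.alt_start), int(row.alt_end)),
                splice_sites=tuple(int(x) for x in _split(row.splice_sites)),
            )
        )
    return out


def write_events(events: Sequence[SpliceEvent], path) -> None:
    events_to_frame(events).to_csv(path, sep="\t", index=False)


def read_events(path) -> list[SpliceEvent]:
    return events_from_frame(pd.read_csv(path, sep="\t"))
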