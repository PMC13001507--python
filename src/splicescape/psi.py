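"""Percent-spliced-in (PSI) quantification, filtering and two-track merging.

Two complementary quantifiers are supported, mirroring the junction-count and
isoform-abundance dialects of splicing quantification:

* junction track — PSI from junction read counts, with inclusion support
  length-normalized by junction multiplicity (a skipped exon has two
  inclusion junctions but one exclusion junction);
* isoform track — PSI as the TPM ratio of inclusion isoforms over all
  isoforms of the event.

Events quantified by both tracks keep both PSI matrices; downstream testing
runs on each track and an event is significant if either track is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import SpliceEvent

JUNCTION_EVIDENCE_CUTOFF = 5.0   # reads
ISOFORM_EVIDENCE_CUTOFF = 0.5    # TPM
MIN_SAMPLE_FRACTION = 0.2

DEFAULT_CUTOFFS = {"junction": JUNCTION_EVIDENCE_CUTOFF, "isoform": ISOFORM_EVIDENCE_CUTOFF}


@dataclass
class PsiMatrix:
    """Events × samples PSI with a companion evidence matrix.

    ``psi`` holds values in [0, 1] or NaN where the event has no supporting
    reads/abundance in that sample.  ``evidence`` is total junction reads
    (junction track) or summed event TPM (isoform track).
    """

    psi: pd.DataFrame
    evidence: pd.DataFrame
    method: str  # 'junction' or 'isoform'
    events: dict[str, SpliceEvent] = field(default_factory=dict)

    def __post_init__(self):
        vals = self.psi.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            raise ValueError("PSI values outside [0, 1]")

    @property
    def event_ids(self) -> pd.Index:
        return self.psi.index

    @property
    def samples(self) -> pd.Index:
        return self.psi.columns

    def subset(self, event_ids) -> "PsiMatrix":
        ids = [e for e in event_ids if e in self.psi.index]
        return PsiMatrix(
            self.psi.loc[ids],
            self.evidence.loc[ids],
            self.method,
            {e: self.events[e] for e in ids if e in self.events},
        )


@dataclass
class MergedPsi:
    """Union of the two method tracks with per-event provenance.

    ``provenance`` maps event id to 'junction', 'isoform' or 'both'.  Events
    with provenance 'both' retain one PSI row in each track — the values are
    never averaged.
    """

    junction: PsiMatrix | None
    isoform: PsiMatrix | None
    provenance: pd.Series

    @property
    def event_ids(self) -> pd.Index:
        return self.provenance.index

    def tracks(self):
        """Yield (method name, PsiMatrix) for the non-empty tracks."""
        for name, pm in (("junction", self.junction), ("isoform", self.isoform)):
            if pm is not None and len(pm.psi):
                yield name, pm

    def events(self) -> dict[str, SpliceEvent]:
        out: dict[str, SpliceEvent] = {}
        for _, pm in self.tracks():
            out.update(pm.events)
        return out


def _check_nonnegative(table: pd.DataFrame, what: str) -> None:
    if (table.to_numpy(dtype=float) < 0).any():
        raise ValueError(f"negative {what} encountered")


def compute_psi_from_junctions(
    counts: pd.DataFrame, events: list[SpliceEvent]
) -> PsiMatrix:
    """PSI from a junction count table (junctions × samples, or long form
    with columns junction_id/sample/count).

    PSI = (I / m_inc) / (I / m_inc + S / m_exc) where I and S are summed
    inclusion and exclusion junction reads and m the junction multiplicity of
    each form.  Missing when I + S = 0.
    """
    if {"junction_id", "sample", "count"}.issubset(counts.columns):
        counts = counts.pivot_table(
            index="junction_id", columns="sample", values="count", aggfunc="sum"
        ).fillna(0.0)
    _check_nonnegative(counts, "junction counts")

    missing = {
        j
        for ev in events
        for j in (*ev.inclusion_junctions, *ev.exclusion_junctions)
        if j not in counts.index
    }
    if missing:
        raise KeyError(f"junctions absent from count table: {sorted(missing)[:5]} ...")

    psi_rows, ev_rows = {}, {}
    for ev in events:
        inc = counts.loc[list(ev.inclusion_junctions)].sum(axis=0)
        exc = counts.loc[list(ev.exclusion_junctions)].sum(axis=0)
        inc_norm = inc / ev.inclusion_multiplicity
        denom = inc_norm + exc
        with np.errstate(invalid="ignore", divide="ignore"):
            psi = np.where(denom > 0, inc_norm / denom, np.nan)
        psi_rows[ev.event_id] = psi
        ev_rows[ev.event_id] = (inc + exc).to_numpy()

    samples = counts.columns
    return PsiMatrix(
        psi=pd.DataFrame(psi_rows, index=samples).T,
        evidence=pd.DataFrame(ev_rows, index=samples).T,
        method="junction",
        events={ev.event_id: ev for ev in events},
    )


def compute_psi_from_isoforms(
    tpm: pd.DataFrame, events: list[SpliceEvent]
) -> PsiMatrix:
    """PSI from a transcript TPM table (transcripts × samples).

    PSI = Σ TPM(inclusion isoforms) / Σ TPM(all event isoforms); missing when
    the event's total abundance is 0.
    """
    _check_nonnegative(tpm, "TPM")
    psi_rows, ev_rows = {}, {}
    for ev in events:
        inc_ids = sorted(ev.inclusion_isoforms)
        exc_ids = sorted(ev.exclusion_isoforms)
        if not inc_ids or not exc_ids:
            raise ValueError(f"{ev.event_id}: isoform-based PSI needs both isoform sets")
        absent = [t for t in (*inc_ids, *exc_ids) if t not in tpm.index]
        if absent:
            raise KeyError(f"isoforms absent from TPM table: {absent[:5]}")
        inc = tpm.loc[inc_ids].sum(axis=0)
        tot = inc + tpm.loc[exc_ids].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            psi = np.where(tot > 0, inc / tot, np.nan)
        psi_rows[ev.event_id] = psi
        ev_rows[ev.event_id] = tot.to_numpy()

    samples = tpm.columns
    return PsiMatrix(
        psi=pd.DataFrame(psi_rows, index=samples).T,
        evidence=pd.DataFrame(ev_rows, index=samples).T,
        method="isoform",
        events={ev.event_id: ev for ev in events},
    )


def filter_events(
    psi: PsiMatrix,
    cutoff: float | None = None,
    min_sample_fraction: float = MIN_SAMPLE_FRACTION,
    also_detected_by_other: set[str] | None = None,
) -> PsiMatrix:
    """Keep events with evidence ≥ cutoff in at least ``min_sample_fraction``
    of samples (inclusive boundary), unless the event was also detected by
    the other quantifier.

    Default cutoffs: 5 reads for the junction track, 0.5 TPM for the isoform
    track.
    """
    if cutoff is None:
        cutoff = DEFAULT_CUTOFFS[psi.method]
    rescue = also_detected_by_other or set()
    n = psi.evidence.shape[1]
    frac = (psi.evidence >= cutoff).sum(axis=1) / n
    keep = frac >= min_sample_fraction
    kept_ids = [e for e in psi.event_ids if keep[e] or e in rescue]
    return psi.subset(kept_ids)


def merge_methods(psi_junction: PsiMatrix | None, psi_isoform: PsiMatrix | None) -> MergedPsi:
    """Union the two method tracks, matching events by identity key
    (type, chromosome, strand, ordered splice sites).

    The same event id appearing in both tracks with different coordinates is
    an error; events present in both keep both PSI tracks (provenance 'both').
    """
    j_ids = set(psi_junction.event_ids) if psi_junction is not None else set()
    i_ids = set(psi_isoform.event_ids) if psi_isoform is not None else set()
    shared = j_ids & i_ids
    for eid in shared:
        ej = psi_junction.events.get(eid)
        ei = psi_isoform.events.get(eid)
        if ej is not None and ei is not None and ej.identity_key != ei.identity_key:
            raise ValueError(f"{eid}: conflicting coordinates between method tracks")
    prov = {}
    for eid in sorted(j_ids | i_ids):
        prov[eid] = "both" if eid in shared else ("junction" if eid in j_ids else "isoform")
    return MergedPsi(psi_junction, psi_isoform, pd.Series(prov, name="provenance", dtype=object))


def write_psi(merged: MergedPsi, path) -> None:
    """Long-form TSV: one row per event × track × sample, with provenance."""
    frames = []
    for name, pm in merged.tracks():
        long = pm.psi.reset_index(names="event_id").melt(
            id_vars="event_id", var_name="sample", value_name="psi"
        )
        long["track"] = name
        frames.append(long)
    out = pd.concat(frames, ignore_index=True)
    out["provenance"] = out["event_id"].map(merged.provenance)
    out.to_csv(path, sep="\t", index=False)


def read_psi(path) -> MergedPsi:
    long = pd.read_csv(path, sep="\t")
    tracks: dict[str, PsiMatrix] = {}
    for name, sub in long.groupby("track"):
        wide = sub.pivot(index="event_id", columns="sample", values="psi")
        tracks[name] = PsiMatrix(wide, wide.notna().astype(float), name)
    prov = long.drop_duplicates("event_id").set_index("event_id")["provenance"]
    return MergedPsi(tracks.get("junction"), tracks.get("isoform"), prov.sort_index())
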