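"""Synthetic cohort, splicing and regulatory data with planted ground truth.

The generator emulates a three-arm exercise study — endurance (EE),
resistance (RE) and non-exercise control — with pre/post timepoints and the
sample covariates the differential-splicing model adjusts for.  Per-event
latent logit-PSI values are drawn from

    logit(PSI) = baseline + planted delta + participant intercept + noise,

and observed in two dialects: binomial junction read counts at the induced
PSI, and inclusion/exclusion isoform TPMs scaled to the same PSI.  On top of
the splicing layer it plants RNA-binding-protein target sets, ATAC peaks
whose accessibility is coupled to event PSI (regulatory circuits), decoy
exercise-responsive peaks, and phosphosites whose within-participant fold
changes track PSI changes at a target correlation.

Everything is deterministic given the seed; a single generator instance
drives all randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .events import SpliceEvent, write_events

CHROM = "chrS"
EVENT_SPACING = 20_000
ARMS = ("EE", "RE", "Control")


# ---------------------------------------------------------------------------
# cohort

@dataclass
class CohortSpec:
    """Design of the synthetic cohort.

    Defaults emulate an adult exercise study: three arms, a pre-exercise
    baseline and post-exercise timepoints, with demographic (age, BMI, sex,
    clinical site) and technical (RIN, UMI duplication rate, sequencing
    batch) covariates.
    """

    n_per_arm: int = 40
    arms: tuple[str, ...] = ARMS
    timepoints: tuple[str, ...] = ("Pre", "P15M", "P3.5H", "P24H")
    n_sites: int = 4
    n_batches: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be ≥ 2 (mixed model unfittable otherwise)")
        if list(self.timepoints).count("Pre") != 1 or self.timepoints[0] != "Pre":
            raise ValueError("timepoints must contain 'Pre' exactly once, first")


@dataclass
class PlantedEffect:
    """A logit-scale PSI shift planted at (event, arm, timepoint).

    kind 'das' is a genuine exercise effect; 'control_confounded' addionally
    plants the same-direction shift in the Control arm (a circadian-style
    confound that the control rule must reject); 'null' plants nothing.
    """

    event_id: str
    arm: str
    timepoint: str
    delta: float
    kind: str = "das"

    def __post_init__(self):
        if not np.isfinite(self.delta):
            raise ValueError("delta must be finite")
        if self.kind not in ("das", "null", "control_confounded"):
            raise ValueError(f"unknown effect kind {self.kind!r}")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    effects: list = field(default_factory=list)
    rbp_targets: dict = field(default_factory=dict)    # rbp -> list of event ids
    planted_rbp: str | None = None
    phospho_pairs: list = field(default_factory=list)  # (site, event, target r)
    circuits: list = field(default_factory=list)       # (tf, peak, event, r)

    @property
    def das_events(self) -> set[str]:
        return {e.event_id for e in self.effects if e.kind in ("das", "control_confounded")}

    def to_json(self, path) -> None:
        d = {
            "effects": [asdict(e) for e in self.effects],
            "rbp_targets": {k: sorted(v) for k, v in self.rbp_targets.items()},
            "planted_rbp": self.planted_rbp,
            "phospho_pairs": [list(p) for p in self.phospho_pairs],
            "circuits": [list(c) for c in self.circuits],
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


def generate_cohort(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One row per participant × timepoint, with all model covariates."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    rows = []
    for arm in spec.arms:
        for i in range(spec.n_per_arm):
            pid = f"{arm}{i:03d}"
            age = float(np.clip(rng.normal(40, 8), 18, 65))
            bmi = float(np.clip(rng.normal(26.5, 3.5), 18, 40))
            sex = "F" if rng.random() < 0.5 else "M"
            site = f"site{rng.integers(spec.n_sites)}"
            for tp in spec.timepoints:
                rows.append(
                    {
                        "sample_id": f"{pid}_{tp}",
                        "pid": pid,
                        "arm": arm,
                        "Timepoint": tp,
                        "calculatedAge": age,
                        "BMI": bmi,
                        "Sex": sex,
                        "codedsiteid": site,
                        "RIN": float(np.clip(rng.normal(8.0, 0.5), 5, 10)),
                        "pct_umi_dup": float(rng.uniform(0.3, 0.6)),
                        "Batch": f"batch{rng.integers(spec.n_batches)}",
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# splice events and their genomic layout

def _junction(chrom, start, end, strand, ri=False) -> str:
    tag = ":ri" if ri else ""
    return f"{chrom}:{start}-{end}:{strand}{tag}"


def build_event(index: int, base: int | None = None) -> tuple[SpliceEvent, dict]:
    """Deterministic event layout: types cycle SE→A5SS→A3SS→RI along chrS.

    Returns the event plus a structure dict with per-transcript exon lists
    (0-based half-open) used for GTF output and CDS assignment.
    """
    etype = ("SE", "A5SS", "A3SS", "RI")[index % 4]
    s = (10_000 + index * EVENT_SPACING) if base is None else base
    strand = "+" if index % 2 == 0 else "-"
    gid = f"gene{index:05d}"
    eid = f"ev{index:05d}"
    inc_tx, exc_tx = f"{gid}.inc", f"{gid}.exc"

    if etype == "SE":
        e1, e2, e3 = (s, s + 200), (s + 1000, s + 1200), (s + 2000, s + 2200)
        inc_j = (_junction(CHROM, e1[1], e2[0], strand), _junction(CHROM, e2[1], e3[0], strand))
        exc_j = (_junction(CHROM, e1[1], e3[0], strand),)
        sites = (e1[1], e2[0], e2[1], e3[0])
        alt = e2
        exons = {inc_tx: [e1, e2, e3], exc_tx: [e1, e3]}
    elif etype == "A5SS":
        e1l, e1s, e2 = (s, s + 300), (s, s + 200), (s + 1000, s + 1200)
        inc_j = (_junction(CHROM, e1l[1], e2[0], strand),)
        exc_j = (_junction(CHROM, e1s[1], e2[0], strand),)
        sites = (s + 200, s + 300)
        alt = (s + 200, s + 300)
        exons = {inc_tx: [e1l, e2], exc_tx: [e1s, e2]}
    elif etype == "A3SS":
        e1, e2l, e2s = (s, s + 200), (s + 1000, s + 1300), (s + 1100, s + 1300)
        inc_j = (_junction(CHROM, e1[1], e2l[0], strand),)
        exc_j = (_junction(CHROM, e1[1], e2s[0], strand),)
        sites = (s + 1000, s + 1100)
        alt = (s + 1000, s + 1100)
        exons = {inc_tx: [e1, e2l], exc_tx: [e1, e2s]}
    else:  # RI — inclusion form retains the intron
        e1, e2 = (s, s + 200), (s + 1000, s + 1200)
        inc_j = (_junction(CHROM, e1[1], e2[0], strand, ri=True),)
        exc_j = (_junction(CHROM, e1[1], e2[0], strand),)
        sites = (e1[1], e2[0])
        alt = (e1[1], e2[0])
        exons = {inc_tx: [(s, s + 1200)], exc_tx: [e1, e2]}

    ev = SpliceEvent(
        event_id=eid,
        etype=etype,
        gene_id=gid,
        chrom=CHROM,
        strand=strand,
        inclusion_junctions=inc_j,
        exclusion_junctions=exc_j,
        inclusion_isoforms=frozenset([inc_tx]),
        exclusion_isoforms=frozenset([exc_tx]),
        alt_region=alt,
        splice_sites=sites,
    )
    return ev, {"exons": exons, "span": (s, max(e[1] for ex in exons.values() for e in ex))}


AMINO = "ACDEFGHIKLMNPQRSTVWY"


def _protein(rng: np.random.Generator, length: int = 30) -> str:
    return "".join(rng.choice(list(AMINO), size=length))


def assign_cds(events, structures, rng) -> tuple[dict, dict]:
    """CDS intervals and protein sequences realizing three impact classes.

    Events cycle through: alt region inside CDS (direct CDS change); alt
    region outside CDS but disjoint inclusion/exclusion proteins (likely CDS
    change); alt region outside CDS with identical proteins (no change).
    """
    cds_by_tx: dict[str, list[tuple[int, int]]] = {}
    protein_by_tx: dict[str, str] = {}
    for k, (ev, st) in enumerate(zip(events, structures)):
        cls = k % 3  # 0 direct, 1 likely, 2 none
        a0, a1 = ev.alt_region
        for tx, exons in st["exons"].items():
            if cls == 0:
                # CDS covers every exon interior, including the alt region
                cds = [(max(e[0] + 20, e[0]), e[1] - 20 if e[1] - 20 > e[0] + 20 else e[1])
                       for e in exons]
                cds = [c for c in cds if c[1] > c[0]]
            else:
                # CDS confined to the first 150 bp of the gene (never the alt region)
                first = min(e[0] for e in exons)
                cds = [(first + 20, first + 150)]
            cds_by_tx[tx] = cds
        inc_tx = next(iter(ev.inclusion_isoforms))
        exc_tx = next(iter(ev.exclusion_isoforms))
        if cls == 2:
            prot = _protein(rng)
            protein_by_tx[inc_tx] = prot
            protein_by_tx[exc_tx] = prot
        else:
            protein_by_tx[inc_tx] = _protein(rng)
            protein_by_tx[exc_tx] = _protein(rng)
    return cds_by_tx, protein_by_tx


def write_gtf(events, structures, cds_by_tx, path) -> None:
    """Minimal GTF (1-based closed) with gene/transcript/exon/CDS features."""
    with open(path, "w") as fh:
        for ev, st in zip(events, structures):
            g0, g1 = st["span"]
            attrs = f'gene_id "{ev.gene_id}";'
            fh.write(
                f"{ev.chrom}\tsynthetic\tgene\t{g0 + 1}\t{g1}\t.\t{ev.strand}\t.\t{attrs}\n"
            )
            for tx, exons in st["exons"].items():
                t0 = min(e[0] for e in exons)
                t1 = max(e[1] for e in exons)
                ta = f'gene_id "{ev.gene_id}"; transcript_id "{tx}";'
                fh.write(
                    f"{ev.chrom}\tsynthetic\ttranscript\t{t0 + 1}\t{t1}\t.\t{ev.strand}\t.\t{ta}\n"
                )
                for e in exons:
                    fh.write(
                        f"{ev.chrom}\tsynthetic\texon\t{e[0] + 1}\t{e[1]}\t.\t{ev.strand}\t.\t{ta}\n"
                    )
                for c in cds_by_tx.get(tx, ()):
                    fh.write(
                        f"{ev.chrom}\tsynthetic\tCDS\t{c[0] + 1}\t{c[1]}\t.\t{ev.strand}\t0\t{ta}\n"
                    )


# ---------------------------------------------------------------------------
# splicing layer

@dataclass
class SpliceData:
    junctions: pd.DataFrame     # junctions × samples read counts
    tpm: pd.DataFrame           # transcripts × samples
    events: list
    structures: list
    latent_logit_psi: pd.DataFrame  # events × samples (ground truth)
    truth: SyntheticTruth


def plan_effects(
    events,
    n_das: int = 50,
    delta: float = 1.5,
    arm: str = "EE",
    timepoint: str = "P15M",
    n_confounded: int = 0,
    kind: str = "das",
) -> list[PlantedEffect]:
    """Plant `delta` on the first `n_das` events at (arm, timepoint); the
    first `n_confounded` of them also carry the confound kind."""
    out = []
    for i, ev in enumerate(events[:n_das]):
        k = "control_confounded" if i < n_confounded else kind
        out.append(PlantedEffect(ev.event_id, arm, timepoint, delta, k))
    return out


def generate_splice_data(
    cohort: pd.DataFrame,
    n_events: int,
    effects: list[PlantedEffect] | None = None,
    noise_sd: float = 0.5,
    rand_intercept_sd: float = 0.3,
    mean_depth: float = 50.0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> SpliceData:
    """Draw latent logit-PSI per event × sample and observe it as junction
    counts (binomial at the induced PSI, total ~ Poisson(mean_depth)) and as
    isoform TPMs scaled to the same PSI."""
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    effects = effects or []

    built = [build_event(i) for i in range(n_events)]
    events = [b[0] for b in built]
    structures = [b[1] for b in built]
    eid_to_row = {ev.event_id: i for i, ev in enumerate(events)}
    for eff in effects:
        if eff.event_id not in eid_to_row:
            raise KeyError(f"planted effect references unknown event {eff.event_id}")

    samples = cohort["sample_id"].to_numpy()
    pids = cohort["pid"].to_numpy()
    upids, pid_idx = np.unique(pids, return_inverse=True)
    n_s = len(samples)

    baseline = logit(rng.uniform(0.25, 0.75, size=n_events))
    u = rng.normal(0.0, rand_intercept_sd, size=(n_events, len(upids)))
    eps = rng.normal(0.0, noise_sd, size=(n_events, n_s))
    eta = baseline[:, None] + u[:, pid_idx] + eps

    arm_arr = cohort["arm"].to_numpy()
    tp_arr = cohort["Timepoint"].to_numpy()
    for eff in effects:
        if eff.kind == "null":
            continue
        r = eid_to_row[eff.event_id]
        eta[r, (arm_arr == eff.arm) & (tp_arr == eff.timepoint)] += eff.delta
        if eff.kind == "control_confounded":
            eta[r, (arm_arr == "Control") & (tp_arr == eff.timepoint)] += eff.delta

    psi = expit(eta)

    # junction counts: a read supports inclusion with probability
    # m·psi / (m·psi + (1 - psi)), so the multiplicity-normalized PSI
    # recomputed from counts recovers the latent value in expectation
    mult = np.array([ev.inclusion_multiplicity for ev in events], dtype=float)[:, None]
    total = rng.poisson(mean_depth, size=(n_events, n_s))
    w = mult * psi / (mult * psi + (1.0 - psi))
    inc_reads = rng.binomial(total, w)
    exc_reads = total - inc_reads

    jrows: dict[str, np.ndarray] = {}
    for i, ev in enumerate(events):
        if len(ev.inclusion_junctions) == 2:
            first = rng.binomial(inc_reads[i], 0.5)
            jrows[ev.inclusion_junctions[0]] = first
            jrows[ev.inclusion_junctions[1]] = inc_reads[i] - first
        else:
            jrows[ev.inclusion_junctions[0]] = inc_reads[i]
        jrows[ev.exclusion_junctions[0]] = exc_reads[i]
    junctions = pd.DataFrame(jrows, index=samples).T
    junctions.index.name = "junction_id"

    base_expr = rng.uniform(2.0, 20.0, size=n_events)
    sample_factor = rng.lognormal(0.0, 0.2, size=(n_events, n_s))
    tot_tpm = base_expr[:, None] * sample_factor
    trows: dict[str, np.ndarray] = {}
    for i, ev in enumerate(events):
        trows[next(iter(ev.inclusion_isoforms))] = tot_tpm[i] * psi[i]
        trows[next(iter(ev.exclusion_isoforms))] = tot_tpm[i] * (1.0 - psi[i])
    tpm = pd.DataFrame(trows, index=samples).T
    tpm.index.name = "transcript_id"

    latent = pd.DataFrame(eta, index=[ev.event_id for ev in events], columns=samples)
    truth = SyntheticTruth(effects=list(effects))
    return SpliceData(junctions, tpm, events, structures, latent, truth)


# ---------------------------------------------------------------------------
# regulatory layer

@dataclass
class RegulatoryParams:
    n_background_rbps: int = 6
    planted_das_coverage: float = 0.8   # fraction of planted DAS events bound
    background_rbp_coverage: float = 0.10
    n_circuits: int = 10
    circuit_r: float = 0.9
    circuit_peak_shift: float = 1.5  # intrinsic exercise response of circuit peaks
    support_peaks_per_tf: int = 2
    n_decoy_peaks: int = 40
    n_decoy_tfs: int = 5
    decoy_shift: float = 1.0
    n_phospho_pairs: int = 5
    phospho_r: float = 0.8
    n_null_phospho: int = 20
    phospho_fc_sd: float = 0.5


@dataclass
class RegulatoryData:
    eclip: pd.DataFrame        # BED6-style frame: chrom,start,end,name(RBP),score,strand
    atac_bed: pd.DataFrame     # chrom,start,end,peak_id,score,strand
    atac: pd.DataFrame         # peaks × samples accessibility
    phospho: pd.DataFrame      # sites × samples log2 abundance
    peak_tf_hits: pd.DataFrame  # columns peak_id, tf


def _window_rows(rbp, ev, rng, pad=20):
    site = ev.first_splice_site
    start = site - int(rng.integers(0, 80))
    return {
        "chrom": ev.chrom,
        "start": max(0, start),
        "end": start + 2 * pad,
        "name": rbp,
        "score": 100,
        "strand": ev.strand,
    }


def generate_regulatory_data(
    cohort: pd.DataFrame,
    splice: SpliceData,
    psi_observed: pd.DataFrame,
    params: RegulatoryParams | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 1,
) -> RegulatoryData:
    """eCLIP intervals, ATAC peaks + accessibility, phospho matrix and
    peak–TF motif hits, with planted RBP enrichment, circuits and
    phospho–PSI correlations recorded in ``splice.truth``."""
    params = params or RegulatoryParams()
    if not splice.events:
        raise ValueError("no events to build regulatory data around")
    if not (-1.0 < params.circuit_r < 1.0) or not (-1.0 < params.phospho_r < 1.0):
        raise ValueError("planted correlations must lie in (-1, 1)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    truth = splice.truth
    events = {ev.event_id: ev for ev in splice.events}
    das_ids = sorted(truth.das_events)
    bg_ids = [e for e in events if e not in set(das_ids)]
    samples = cohort["sample_id"].to_numpy()
    n_s = len(samples)

    # --- eCLIP: one planted RBP enriched at DAS splice sites, plus background
    eclip_rows, rbp_targets = [], {}
    planted_rbp = "RBP01"
    n_cov = int(round(params.planted_das_coverage * len(das_ids)))
    covered = list(das_ids[:n_cov])
    n_bg_cov = int(round(params.background_rbp_coverage * len(bg_ids)))
    covered_bg = list(rng.choice(bg_ids, size=n_bg_cov, replace=False)) if n_bg_cov else []
    for eid in covered + covered_bg:
        eclip_rows.append(_window_rows(planted_rbp, events[eid], rng))
    rbp_targets[planted_rbp] = covered + covered_bg
    for k in range(params.n_background_rbps):
        rbp = f"RBP{k + 2:02d}"
        n_hit = int(round(params.background_rbp_coverage * len(events)))
        hit = list(rng.choice(sorted(events), size=n_hit, replace=False))
        for eid in hit:
            eclip_rows.append(_window_rows(rbp, events[eid], rng))
        rbp_targets[rbp] = hit
    truth.rbp_targets = rbp_targets
    truth.planted_rbp = planted_rbp
    eclip = pd.DataFrame(eclip_rows)

    # --- ATAC: planted circuit peaks + far support peaks + decoy responders
    def zrow(eid):
        v = psi_observed.loc[eid].to_numpy(dtype=float)
        v = np.where(np.isnan(v), np.nanmean(v), v)
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    atac_rows, atac_bed_rows, hits = {}, [], []
    r = params.circuit_r
    circuit_events = das_ids[: params.n_circuits]
    arm_arr = cohort["arm"].to_numpy()
    tp_arr = cohort["Timepoint"].to_numpy()
    post_shift = ((arm_arr != "Control") & (tp_arr != "Pre")).astype(float)
    far_base = 10_000 + (len(events) + 50) * EVENT_SPACING  # gene desert: never a candidate
    for k, eid in enumerate(circuit_events):
        tf = f"TF{k + 1:02d}"
        ev = events[eid]
        peak_id = f"peak_circ{k:02d}"
        offset = int(rng.integers(5_000, 50_000)) * (1 if rng.random() < 0.5 else -1)
        start = max(0, ev.first_splice_site + offset)
        atac_bed_rows.append((CHROM, start, start + 500, peak_id, 100, "."))
        z = zrow(eid)
        # circuit peaks are themselves exercise-responsive — a peak mediating
        # an exercise-driven splicing change is differentially accessible by
        # construction of the candidate definition
        atac_rows[peak_id] = (
            r * z
            + np.sqrt(1 - r**2) * rng.normal(0, 1, n_s)
            + params.circuit_peak_shift * post_shift
        )
        hits.append((peak_id, tf))
        for j in range(params.support_peaks_per_tf):
            sp_id = f"peak_sup{k:02d}_{j}"
            s0 = far_base + (k * params.support_peaks_per_tf + j) * 5_000
            atac_bed_rows.append((CHROM, s0, s0 + 500, sp_id, 100, "."))
            atac_rows[sp_id] = r * z + np.sqrt(1 - r**2) * rng.normal(0, 1, n_s)
            hits.append((sp_id, tf))
        truth.circuits.append((tf, peak_id, eid, r))

    # decoy peaks: exercise-responsive but uncoupled to any event's PSI
    pids = cohort["pid"].to_numpy()
    upids, pid_idx = np.unique(pids, return_inverse=True)
    anchor_pool = das_ids if das_ids else sorted(events)
    for k in range(params.n_decoy_peaks):
        peak_id = f"peak_decoy{k:03d}"
        anchor = events[anchor_pool[int(rng.integers(len(anchor_pool)))]]
        offset = int(rng.integers(1_000, 150_000)) * (1 if rng.random() < 0.5 else -1)
        start = max(0, anchor.first_splice_site + offset)
        atac_bed_rows.append((CHROM, start, start + 500, peak_id, 50, "."))
        u = rng.normal(0, 0.3, len(upids))[pid_idx]
        atac_rows[peak_id] = (
            params.decoy_shift * post_shift + u + rng.normal(0, 0.5, n_s)
        )
        tf = f"decoyTF{k % params.n_decoy_tfs:02d}"
        hits.append((peak_id, tf))

    atac = pd.DataFrame(atac_rows, index=samples).T
    atac.index.name = "peak_id"
    atac_bed = pd.DataFrame(
        atac_bed_rows, columns=["chrom", "start", "end", "peak_id", "score", "strand"]
    )
    peak_tf_hits = pd.DataFrame(hits, columns=["peak_id", "tf"])

    # --- phospho: planted sites tracking ΔPSI of target DAS events
    post_tps = [t for t in cohort["Timepoint"].unique() if t != "Pre"]
    ex_pids = cohort.loc[cohort["arm"] != "Control", "pid"].unique()
    pair_index = [(p, t) for p in ex_pids for t in post_tps]

    def dpsi_vector(eid):
        row = psi_observed.loc[eid]
        out = np.array(
            [row.get(f"{p}_{t}", np.nan) - row.get(f"{p}_Pre", np.nan) for p, t in pair_index]
        )
        return out

    phospho_rows = {}
    pid_of_sample = dict(zip(cohort["sample_id"], cohort["pid"]))
    tp_of_sample = dict(zip(cohort["sample_id"], cohort["Timepoint"]))
    rp = params.phospho_r
    phospho_events = das_ids[: params.n_phospho_pairs]
    for k, eid in enumerate(phospho_events):
        site = f"{planted_rbp}:S{300 + k}"
        d = dpsi_vector(eid)
        dz = (d - np.nanmean(d)) / (np.nanstd(d) if np.nanstd(d) > 0 else 1.0)
        fc = params.phospho_fc_sd * (rp * dz + np.sqrt(1 - rp**2) * rng.normal(0, 1, len(d)))
        fc_map = {pt: v for pt, v in zip(pair_index, fc)}
        base = dict(zip(ex_pids, rng.normal(0.0, 0.5, len(ex_pids))))
        vals = np.empty(n_s)
        for si, sid in enumerate(samples):
            p, t = pid_of_sample[sid], tp_of_sample[sid]
            b = base.get(p, 0.0)
            if t == "Pre" or (p, t) not in fc_map or np.isnan(fc_map[(p, t)]):
                vals[si] = b + rng.normal(0, 0.05)
            else:
                vals[si] = b + fc_map[(p, t)]
        phospho_rows[site] = vals
        truth.phospho_pairs.append((site, eid, rp))

    for k in range(params.n_null_phospho):
        site = f"RBP{(k % params.n_background_rbps) + 2:02d}:S{100 + k}"
        base = dict(zip(ex_pids, rng.normal(0.0, 0.5, len(ex_pids))))
        vals = np.array(
            [
                base.get(pid_of_sample[sid], 0.0)
                + (0.0 if tp_of_sample[sid] == "Pre" else rng.normal(0, params.phospho_fc_sd))
                + rng.normal(0, 0.05)
                for sid in samples
            ]
        )
        phospho_rows[site] = vals

    phospho = pd.DataFrame(phospho_rows, index=samples).T
    phospho.index.name = "site_id"

    return RegulatoryData(eclip, atac_bed, atac, phospho, peak_tf_hits)


# ---------------------------------------------------------------------------
# one-call dataset + writers

@dataclass
class SyntheticDataset:
    cohort: pd.DataFrame
    splice: SpliceData
    regulatory: RegulatoryData
    psi_observed: pd.DataFrame  # junction-derived PSI used for planting
    cds_by_tx: dict
    protein_by_tx: dict

    @property
    def truth(self) -> SyntheticTruth:
        return self.splice.truth


def simulate_dataset(
    seed: int = 0,
    cohort_spec: CohortSpec | None = None,
    n_events: int = 200,
    n_das: int = 30,
    delta: float = 1.5,
    das_arm: str = "EE",
    das_timepoint: str | None = None,
    noise_sd: float = 0.5,
    rand_intercept_sd: float = 0.3,
    mean_depth: float = 50.0,
    regulatory_params: RegulatoryParams | None = None,
) -> SyntheticDataset:
    """Generate a complete coherent dataset: cohort, splicing (both
    quantification dialects), annotation and the regulatory layer."""
    from .psi import compute_psi_from_junctions  # local import to avoid cycle

    rng = np.random.default_rng(seed)
    spec = cohort_spec or CohortSpec(seed=seed)
    cohort = generate_cohort(spec, rng)
    tp = das_timepoint or spec.timepoints[1]
    pre_events = [build_event(i)[0] for i in range(n_events)]
    effects = plan_effects(pre_events, n_das=n_das, delta=delta, arm=das_arm, timepoint=tp)
    splice = generate_splice_data(
        cohort, n_events, effects, noise_sd, rand_intercept_sd, mean_depth, rng
    )
    psi_obs = compute_psi_from_junctions(splice.junctions, splice.events).psi
    reg = generate_regulatory_data(cohort, splice, psi_obs, regulatory_params, rng)
    cds_by_tx, protein_by_tx = assign_cds(splice.events, splice.structures, rng)
    return SyntheticDataset(cohort, splice, reg, psi_obs, cds_by_tx, protein_by_tx)


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write every pipeline input as plain-text files; returns path map."""
    import os

    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(outdir, name)
    ds.cohort.to_csv(p("metadata.tsv"), sep="\t", index=False)
    ds.splice.junctions.reset_index().melt(
        id_vars="junction_id", var_name="sample", value_name="count"
    ).to_csv(p("junctions.tsv"), sep="\t", index=False)
    ds.splice.tpm.to_csv(p("tpm.tsv"), sep="\t")
    write_events(ds.splice.events, p("events.tsv"))
    write_gtf(ds.splice.events, ds.splice.structures, ds.cds_by_tx, p("annotation.gtf"))
    pd.Series(ds.protein_by_tx, name="protein").rename_axis("transcript_id").to_csv(
        p("proteins.tsv"), sep="\t"
    )
    ds.regulatory.eclip.to_csv(p("eclip.bed"), sep="\t", header=False, index=False)
    ds.regulatory.atac_bed.to_csv(p("atac_peaks.bed"), sep="\t", header=False, index=False)
    ds.regulatory.atac.to_csv(p("atac_matrix.tsv"), sep="\t")
    ds.regulatory.phospho.to_csv(p("phospho.tsv"), sep="\t")
    ds.regulatory.peak_tf_hits.to_csv(p("peak_tf_hits.tsv"), sep="\t", index=False)
    ds.truth.to_json(p("truth.json"))
    return {
        "metadata": p("metadata.tsv"),
        "junctions": p("junctions.tsv"),
        "tpm": p("tpm.tsv"),
        "events": p("events.tsv"),
        "gtf": p("annotation.gtf"),
        "proteins": p("proteins.tsv"),
        "eclip": p("eclip.bed"),
        "atac_bed": p("atac_peaks.bed"),
        "atac": p("atac_matrix.tsv"),
        "phospho": p("phospho.tsv"),
        "hits": p("peak_tf_hits.tsv"),
        "truth": p("truth.json"),
    }
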