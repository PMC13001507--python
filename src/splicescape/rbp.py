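"""RNA-binding-protein target enrichment and phospho–PSI correlation.

An event is a target of an RBP when any of its splice sites, extended by a
±100 bp window, overlaps a (merged) binding interval of that RBP.
Enrichment of targets among DAS events against the background of all
characterized events is an upper-tail hypergeometric test, Bonferroni-
corrected across RBPs within each arm × timepoint; an RBP is called enriched
at adjusted p < 0.05 and target-frequency fold change > 1.5.

Phospho coupling: per participant and post-exercise timepoint, the
phosphosite log2 fold change vs Pre and the PSI difference vs Pre are pooled
across all exercise timepoints and modalities; Pearson r with its t-test p
is computed per (phosphosite, target event) pair and FDR-adjusted across
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .das import benjamini_hochberg

DEFAULT_WINDOW = 100
BONFERRONI_ALPHA = 0.05
FOLD_CHANGE_MIN = 1.5


@dataclass
class GenomicIntervalSet:
    """Per-RBP merged binding intervals, 0-based half-open, indexed for
    overlap queries."""

    trees: dict[str, dict[str, IntervalTree]] = field(default_factory=dict)

    @classmethod
    def from_bed(cls, bed: pd.DataFrame) -> "GenomicIntervalSet":
        """Build from a BED-like frame with columns chrom/start/end/name
        (name = RBP); intervals of the same RBP are merged."""
        out = cls()
        for (rbp, chrom), grp in bed.groupby(["name", "chrom"]):
            tree = IntervalTree.from_tuples(
                (int(s), int(e)) for s, e in zip(grp["start"], grp["end"]) if e > s
            )
            tree.merge_overlaps()
            out.trees.setdefault(rbp, {})[chrom] = tree
        return out

    @classmethod
    def read_bed(cls, path) -> "GenomicIntervalSet":
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=range(6),
        )
        return cls.from_bed(bed)

    @property
    def rbps(self) -> list[str]:
        return sorted(self.trees)

    def overlaps(self, rbp: str, chrom: str, start: int, end: int) -> bool:
        tree = self.trees.get(rbp, {}).get(chrom)
        return bool(tree.overlap(start, end)) if tree is not None else False


def map_rbp_targets(
    events, sites: GenomicIntervalSet, window: int = DEFAULT_WINDOW
) -> dict[str, set[str]]:
    """Per RBP, the set of events with a binding site within ±window of any
    splice site.  Events on chromosomes absent from an RBP's interval set are
    simply not targets."""
    if window < 0:
        raise ValueError("window must be ≥ 0")
    targets: dict[str, set[str]] = {rbp: set() for rbp in sites.rbps}
    for ev in events:
        for rbp in sites.rbps:
            for ss in ev.splice_sites:
                if sites.overlaps(rbp, ev.chrom, ss - window, ss + window + 1):
                    targets[rbp].add(ev.event_id)
                    break
    return targets


def hypergeom_enrichment_p(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X ≥ k) for X ~ Hypergeom(N population, K marked, n drawn)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_rbp(
    targets: dict[str, set[str]],
    das_events: set[str],
    background: set[str],
    arm: str = "",
    timepoint: str = "",
    alpha: float = BONFERRONI_ALPHA,
    fc_min: float = FOLD_CHANGE_MIN,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each RBP's targets among DAS events.

    Bonferroni multiplicity is the number of RBPs with at least one target
    in the background."""
    if not das_events <= background:
        raise ValueError("das_events must be a subset of the background")
    N = len(background)
    n = len(das_events)
    rows = []
    tested = [rbp for rbp in sorted(targets) if targets[rbp] & background]
    m = len(tested)
    for rbp in tested:
        tg = targets[rbp] & background
        K = len(tg)
        k = len(tg & das_events)
        if n == 0 or K == 0:
            p, fc = 1.0, 0.0
        else:
            p = hypergeom_enrichment_p(k, N, K, n)
            fc = (k / n) / (K / N)
        rows.append(
            {
                "rbp": rbp,
                "arm": arm,
                "timepoint": timepoint,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": p,
                "p_bonferroni": min(1.0, p * m),
                "fold_change": fc,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["significant"] = (out["p_bonferroni"] < alpha) & (out["fold_change"] > fc_min)
    return out


def _site_rbp(site_id: str) -> str:
    return str(site_id).split(":")[0]


def delta_vs_pre(
    matrix: pd.DataFrame, samples: pd.DataFrame, arms=("EE", "RE")
) -> pd.DataFrame:
    """Within-participant differences vs Pre, one column per
    (participant, post timepoint) in the exercise arms."""
    meta = samples[samples["arm"].isin(arms)]
    pre = {p: s for p, s, t in zip(meta["pid"], meta["sample_id"], meta["Timepoint"]) if t == "Pre"}
    cols = {}
    for pid, sid, tp in zip(meta["pid"], meta["sample_id"], meta["Timepoint"]):
        if tp == "Pre" or pid not in pre:
            continue
        if sid in matrix.columns and pre[pid] in matrix.columns:
            cols[(pid, tp)] = matrix[sid] - matrix[pre[pid]]
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["pid", "timepoint"])
    return out


def correlate_phospho_psi(
    phospho: pd.DataFrame,
    psi: pd.DataFrame,
    samples: pd.DataFrame,
    das_events: set[str],
    targets: dict[str, set[str]],
    min_pairs: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation between phosphosite log2 fold changes and PSI
    differences, pooled across participants, post timepoints and exercise
    modalities, per (site, target DAS event) pair; FDR across pairs."""
    dphos = delta_vs_pre(phospho, samples)
    dpsi = delta_vs_pre(psi, samples)
    common = dphos.columns.intersection(dpsi.columns)
    dphos, dpsi = dphos[common], dpsi[common]

    rows = []
    for site in phospho.index:
        rbp = _site_rbp(site)
        evs = sorted((targets.get(rbp, set()) & das_events) & set(psi.index))
        for eid in evs:
            x = dphos.loc[site].to_numpy(dtype=float)
            y = dpsi.loc[eid].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < min_pairs:
                continue
            if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                continue
            r, p = stats.pearsonr(x[ok], y[ok])
            rows.append(
                {"site": site, "rbp": rbp, "event_id": eid, "r": r, "p": p, "n": int(ok.sum())}
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = benjamini_hochberg(out["p"].to_numpy())
        out["significant"] = out["fdr"] < alpha
    return out
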