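"""End-to-end orchestration: simulate → PSI → DAS → CDS → RBP → circuits.

Each stage logs its input/output row counts so every filter is auditable,
and the run manifest records the seed and a checksum per written file —
identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cds as cds_mod
from . import circuits as circ_mod
from . import das as das_mod
from . import psi as psi_mod
from . import rbp as rbp_mod
from .config import PipelineConfig
from .simulate import CohortSpec, simulate_dataset, write_dataset

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: pd.DataFrame = None
    merged_psi: psi_mod.MergedPsi = None
    das: pd.DataFrame = None            # long per-track results
    das_calls: pd.DataFrame = None      # consolidated verdicts
    cds_verdicts: pd.DataFrame = None
    rbp_enrichment: pd.DataFrame = None
    phospho_pairs: pd.DataFrame = None
    circuits: pd.DataFrame = None
    deg_genes: set = field(default_factory=set)
    manifest: dict = field(default_factory=dict)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on a synthetic dataset defined by the config.

    Raises with the failing stage named; writes all stage outputs plus a
    manifest under ``config.outdir``.
    """
    os.makedirs(config.outdir, exist_ok=True)
    res = PipelineResult(config=config)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}
    stage = "simulate"
    try:
        ds = simulate_dataset(
            seed=config.seed,
            cohort_spec=CohortSpec(
                n_per_arm=config.n_per_arm,
                timepoints=tuple(config.timepoints),
                seed=config.seed,
            ),
            n_events=config.n_events,
            n_das=config.n_das,
            delta=config.delta,
            das_arm=config.das_arm,
            noise_sd=config.noise_sd,
            rand_intercept_sd=config.rand_intercept_sd,
            mean_depth=config.mean_depth,
        )
        inputs_dir = os.path.join(config.outdir, "inputs")
        paths = write_dataset(ds, inputs_dir)
        res.cohort = ds.cohort
        manifest["stages"][stage] = {
            "n_samples": len(ds.cohort),
            "n_events": len(ds.splice.events),
            "n_planted_das": len(ds.truth.das_events),
        }

        stage = "psi"
        pj = psi_mod.compute_psi_from_junctions(ds.splice.junctions, ds.splice.events)
        pi = psi_mod.compute_psi_from_isoforms(ds.splice.tpm, ds.splice.events)
        fj = psi_mod.filter_events(
            pj, config.junction_cutoff, config.min_sample_fraction, set(pi.event_ids)
        )
        fi = psi_mod.filter_events(
            pi, config.tpm_cutoff, config.min_sample_fraction, set(pj.event_ids)
        )
        merged = psi_mod.merge_methods(fj, fi)
        res.merged_psi = merged
        psi_path = os.path.join(config.outdir, "psi.tsv")
        psi_mod.write_psi(merged, psi_path)
        manifest["stages"][stage] = {
            "junction_events_in": len(pj.event_ids),
            "junction_events_kept": len(fj.event_ids),
            "isoform_events_in": len(pi.event_ids),
            "isoform_events_kept": len(fi.event_ids),
            "merged_events": len(merged.event_ids),
        }

        stage = "das"
        spec = das_mod.DasModelSpec(adjust=config.logit_adjust, alpha=config.alpha)
        das_long = das_mod.das_pipeline(merged, ds.cohort, spec=spec)
        calls = das_mod.consolidate_verdicts(das_long)
        res.das, res.das_calls = das_long, calls
        das_path = os.path.join(config.outdir, "das.tsv")
        das_long.to_csv(das_path, sep="\t", index=False)
        manifest["stages"][stage] = {
            "fits": len(das_long),
            "das_calls": int((calls["verdict"] == "DAS").sum()),
        }

        stage = "cds"
        ann = cds_mod.CdsAnnotation.from_gtf(
            paths["gtf"], pd.read_csv(paths["proteins"], sep="\t", index_col=0)["protein"]
        )
        all_events = ds.splice.events
        verdicts = cds_mod.classify_events(all_events, ann)
        res.cds_verdicts = verdicts
        cds_path = os.path.join(config.outdir, "cds.tsv")
        verdicts.to_csv(cds_path, sep="\t")
        manifest["stages"][stage] = {
            "events": len(verdicts),
            **verdicts["verdict"].value_counts().to_dict(),
        }

        stage = "rbp"
        sites = rbp_mod.GenomicIntervalSet.from_bed(ds.regulatory.eclip)
        targets = rbp_mod.map_rbp_targets(all_events, sites, config.rbp_window)
        das_ids = set(calls.loc[calls["verdict"] == "DAS", "event_id"])
        background = set(merged.event_ids)
        enr = rbp_mod.enrich_rbp(
            targets,
            das_ids & background,
            background,
            alpha=config.bonferroni_alpha,
            fc_min=config.fold_change_min,
        )
        psi_any = merged.junction.psi if merged.junction is not None else merged.isoform.psi
        pairs = rbp_mod.correlate_phospho_psi(
            ds.regulatory.phospho, psi_any, ds.cohort, das_ids, targets
        )
        res.rbp_enrichment, res.phospho_pairs = enr, pairs
        enr_path = os.path.join(config.outdir, "rbp_enrichment.tsv")
        enr.to_csv(enr_path, sep="\t", index=False)
        pairs_path = os.path.join(config.outdir, "phospho_psi_pairs.tsv")
        pairs.to_csv(pairs_path, sep="\t", index=False)
        manifest["stages"][stage] = {
            "rbps_tested": len(enr),
            "rbps_enriched": int(enr["significant"].sum()) if len(enr) else 0,
            "phospho_pairs": len(pairs),
        }

        stage = "deg"
        gene_expr = np.log2(ds.splice.tpm + 1.0)
        gene_of_tx = {
            tx: ev.gene_id
            for ev in all_events
            for tx in (*ev.inclusion_isoforms, *ev.exclusion_isoforms)
        }
        expr_by_gene = gene_expr.groupby(gene_expr.index.map(gene_of_tx)).sum()
        deg_genes: set[str] = set()
        post_tps = [t for t in config.timepoints if t != "Pre"]
        diff_atac_frames = []
        for tp in post_tps:
            for arm in ("EE", "RE"):
                dg = das_mod.differential_omics(expr_by_gene, ds.cohort, arm, tp, spec=spec)
                deg_genes |= set(dg.index[dg["fdr"] < config.alpha])
                da = das_mod.differential_omics(
                    ds.regulatory.atac, ds.cohort, arm, tp, spec=spec
                )
                diff_atac_frames.append(da["p"].rename(f"{arm}:{tp}"))
        res.deg_genes = deg_genes
        manifest["stages"][stage] = {"deg_genes": len(deg_genes)}

        stage = "src"
        peak_pvals = pd.concat(diff_atac_frames, axis=1)
        event_by_id = {ev.event_id: ev for ev in all_events}
        das_event_objs = [event_by_id[e] for e in sorted(das_ids) if e in event_by_id]
        cand = circ_mod.select_candidates(
            ds.regulatory.atac_bed,
            peak_pvals,
            das_event_objs,
            config.candidate_window,
            config.candidate_p_cutoff,
        )
        peak_tf = circ_mod.map_peak_tf(ds.regulatory.atac_bed, ds.regulatory.peak_tf_hits)
        logit_psi = pd.DataFrame(
            das_mod.logit_transform(psi_any.to_numpy(), config.logit_adjust),
            index=psi_any.index,
            columns=psi_any.columns,
        )
        scored = circ_mod.score_circuits(
            cand,
            peak_tf,
            ds.regulatory.atac,
            logit_psi,
            ds.cohort,
            n_draws=config.n_draws,
            seed=config.seed,
        )
        kept = circ_mod.filter_circuits(
            scored, config.looping_threshold, config.binding_threshold, deg_genes
        )
        res.circuits = kept
        circ_path = os.path.join(config.outdir, "circuits.tsv")
        kept.to_csv(circ_path, sep="\t", index=False)
        manifest["stages"][stage] = {
            "candidate_pairs": len(cand),
            "triads_scored": len(scored),
            "circuits": len(kept),
        }
    except Exception as exc:  # noqa: BLE001 — re-raise with the stage named
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    for root, _, files in os.walk(config.outdir):
        for f in sorted(files):
            if f == "manifest.json":
                continue
            fp = os.path.join(root, f)
            manifest["files"][os.path.relpath(fp, config.outdir)] = _sha256(fp)
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    res.manifest = manifest
    return res


def landscape_summary(
    das_calls: pd.DataFrame,
    cds_verdicts: pd.DataFrame,
    event_types: dict[str, str],
    deg_genes: set[str] | None = None,
    gene_of_event: dict[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Landscape tables: DAS counts by arm × timepoint × event type, the
    DAS-only vs DAS-DEG partition, and CDS-verdict proportions among DAS
    events."""
    das = das_calls[das_calls["verdict"] == "DAS"].copy()
    das["event_type"] = das["event_id"].map(event_types)
    counts = (
        das.groupby(["arm", "timepoint", "event_type"]).size().rename("n_das").reset_index()
    )

    das_ids = sorted(set(das["event_id"]))
    if gene_of_event and deg_genes is not None:
        das_genes = {gene_of_event.get(e) for e in das_ids} - {None}
        n_deg = len(das_genes & deg_genes)
        partition = pd.DataFrame(
            {
                "class": ["DAS-only", "DAS-DEG"],
                "n_genes": [len(das_genes) - n_deg, n_deg],
            }
        )
    else:
        partition = pd.DataFrame(columns=["class", "n_genes"])

    sub = cds_verdicts.reindex(das_ids).dropna(subset=["verdict"])
    if len(sub):
        vc = sub["verdict"].value_counts()
        cds_prop = pd.DataFrame(
            {
                "verdict": vc.index,
                "n": vc.to_numpy(),
                "proportion": (vc / vc.sum()).to_numpy(),
            }
        )
    else:
        cds_prop = pd.DataFrame(columns=["verdict", "n", "proportion"])
    return {"das_counts": counts, "deg_partition": partition, "cds_proportions": cds_prop}
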