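# splicescape

Exercise changes not only how much genes are expressed but *which isoforms*
they produce. `splicescape` is an analysis pipeline for exercise-responsive
alternative splicing in a three-arm human study design — endurance exercise
(EE), resistance exercise (RE) and a non-exercise control arm — sampled
before and after an exercise bout. It is written for computational
biologists who want to quantify percent-spliced-in (PSI), call differential
splicing with proper repeated-measures statistics and a circadian control
correction, and connect splicing changes to their upstream regulators
(RNA-binding proteins, chromatin, phosphosignalling).

Because cohort-level human multi-omic data are typically access-controlled,
the package ships a first-class synthetic-data generator that emulates the
full study — cohort covariates, junction counts, isoform TPMs, eCLIP
binding intervals, ATAC peaks, phosphosite abundances and TF motif hits —
with planted ground truth, so every stage is testable end to end.

## What it computes

1. **PSI quantification** from two complementary dialects, for four event
   classes (SE, A5SS, A3SS, RI):
   junction counts, `PSI = (I/m_inc) / (I/m_inc + S/m_exc)` with
   multiplicity normalization, and isoform abundances,
   `PSI = Σ TPM_inclusion / Σ TPM_all`. Events are filtered on evidence
   (≥5 reads / ≥0.5 TPM in ≥20% of samples, with a cross-method rescue) and
   the two tracks are merged without averaging — both PSI values of a
   shared event are tested downstream.
2. **Differential alternative splicing (DAS)** per event × arm × timepoint
   with a linear mixed model on boundary-adjusted logit PSI:

   ```
   logit(PSI) ~ Timepoint + Batch + BMI + calculatedAge + codedsiteid
                + pct_umi_dup + RIN + Sex + (1 | participant)
   ```

   FDR (Benjamini–Hochberg) is controlled within each arm × timepoint, and
   an event is DAS only if it is *not* significant in the control arm at
   the same timepoint, or changes there in the opposite direction
   (circadian correction).
3. **CDS impact**: direct CDS change (alternative region overlaps annotated
   CDS), likely CDS change (inclusion- and exclusion-isoform protein sets
   disjoint), or no change.
4. **RBP target enrichment**: hypergeometric enrichment of eCLIP binding
   sites within ±100 bp of DAS splice sites against all characterized
   events (Bonferroni p < 0.05, fold change > 1.5), plus Pearson
   correlation of RBP phosphosite log2 fold changes with PSI changes
   across participants (FDR < 0.05).
5. **Splice regulatory circuits (SRC)**: (TF, ATAC peak, splice event)
   triads from differentially accessible peaks (raw p < 0.005) within
   ±200 kb of the event's first splice site, scored by a Bayesian
   spike-and-slab coupling model; circuits are kept at posterior looping
   probability ≥ 0.9 and TF binding probability ≥ 0.9.
6. A **difference-in-changes** (delta-delta) mixed-model contrast for the
   companion omics (accessibility, phosphoproteome, expression), and a
   multi-level regulation summary over a gene list.

## Worked example

```python
from splicescape.config import PipelineConfig
from splicescape.pipeline import run_pipeline

cfg = PipelineConfig(outdir="demo_out", seed=7, n_per_arm=10,
                     n_events=60, n_das=10, n_draws=500)
res = run_pipeline(cfg)
for stage, info in res.manifest["stages"].items():
    print(stage, info)
```

prints (numbers from this exact run):

```
simulate {'n_samples': 60, 'n_events': 60, 'n_planted_das': 10}
psi {'junction_events_in': 60, 'junction_events_kept': 60, 'isoform_events_in': 60, 'isoform_events_kept': 60, 'merged_events': 60}
das {'fits': 240, 'das_calls': 11}
cds {'events': 60, 'cds_change': 20, 'likely_cds_change': 20, 'no_change': 20}
rbp {'rbps_tested': 7, 'rbps_enriched': 1, 'phospho_pairs': 64}
deg {'deg_genes': 0}
src {'candidate_pairs': 306, 'triads_scored': 306, 'circuits': 8}
```

Reading this: the generator planted 10 DAS events in a 60-sample cohort
(10 participants/arm, Pre + 15-minutes-post); the mixed model called 11
event × arm × timepoint DAS rows; the planted RBP was the one enriched
regulator; and 8 circuits passed both 0.9 posterior thresholds — 7 of the
10 planted triads (the rest fell below the differential-accessibility gate
at this small sample size) and at most one spurious triad.

The same pipeline is available from the shell:

```bash
splicescape run --seed 7 --outdir demo_out
splicescape simulate --outdir sim --seed 1     # inputs + truth.json only
splicescape psi --junctions sim/junctions.tsv --tpm sim/tpm.tsv \
    --events sim/events.tsv --out psi.tsv
```

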