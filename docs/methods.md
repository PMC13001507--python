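# Methods

## Study design being modelled

The pipeline targets a three-arm repeated-measures exercise study: endurance
(EE), resistance (RE) and non-exercise control arms, each participant
sampled at a pre-exercise baseline ("Pre") and one or more during/post
timepoints (defaults `P15M`, `P3.5H`, `P24H`). Molecular readouts are bulk
RNA-seq (junction counts and transcript TPMs), chromatin accessibility
(ATAC peak counts), and phosphoproteomics (log2 reporter-ion ratios).
Because such cohort data are access-controlled, the synthetic-data module is
a first-class component: it generates every input with planted ground truth
so that each downstream claim is verifiable by recovery tests.

## PSI quantification

Two quantification dialects are implemented and merged:

* **Junction track.** For an event with inclusion reads I spread over
  m_inc junctions and exclusion reads S over m_exc junctions,
  PSI = (I/m_inc) / (I/m_inc + S/m_exc). A skipped exon has m_inc = 2,
  m_exc = 1; the other classes are 1/1. The retained-intron inclusion form
  is supported by an intron-coverage pseudo-junction. PSI is missing when
  I + S = 0. Evidence = total junction reads.
* **Isoform track.** PSI = Σ TPM(inclusion isoforms) / Σ TPM(all event
  isoforms); missing when the denominator is 0. Evidence = the denominator.

Filtering keeps an event when its evidence reaches the cutoff (5 reads
junction / 0.5 TPM isoform) in at least 20% of samples — the boundary is
inclusive — unless the event was also detected by the other method.
Merging matches events by (type, chromosome, strand, ordered splice-site
tuple); shared events keep both PSI tracks and both are tested downstream;
an event is significant if either track is, with the source track recorded.
Missing PSI values are dropped pairwise in model fits, never imputed.
Internal coordinates are 0-based half-open; GTF I/O converts to 1-based
closed, BED stays 0-based half-open.

## Differential alternative splicing

Per event, arm G and timepoint T, samples at T are concatenated with the
arm's Pre samples and

    logit(PSI) ~ Timepoint + Batch + BMI + calculatedAge + codedsiteid
                 + pct_umi_dup + RIN + Sex + (1 | pid)

is fit by REML (statsmodels MixedLM). The logit uses the boundary remap
p' = a + (1 − 2a)·PSI with a = 0.001 so that PSI ∈ {0, 1} stays finite.
Categorical covariates observed at a single level are dropped. If the
random-intercept fit does not converge, the optimizer is retried (Powell);
a still-failing or degenerate fit (zero response variance, fewer than two
participants with both timepoints, vanishing standard error) is marked
*unfittable* rather than silently falling back to OLS.

**Reference distribution.** The Timepoint coefficient is tested against a
t distribution with containment-style within-participant degrees of
freedom: df = n_obs − n_participants − p_within, where p_within counts the
design columns that vary within participants (Timepoint and the per-sample
batch dummies; participant-level covariates do not consume within-
participant information). For the paired two-timepoint design this is
essentially the Satterthwaite df, and a 2000-event null simulation at
40 participants/arm gives a raw p < 0.05 rate of 0.050; the large-sample
normal reference (available as `df_mode="normal"`) gives 0.059 at this
size, which is why the t reference is the default. Satterthwaite itself is
not implemented because the underlying fitter does not expose the
REML-information quantities it needs.

P values are BH-adjusted within each arm × timepoint (statsmodels
`multipletests`; the test suite checks it against a brute-force step-up
oracle). The control rule: an event is DAS at (G, T), G ∈ {EE, RE}, iff
FDR_G < 0.05 and (FDR_Control ≥ 0.05 or the control direction differs).
Events untested in the control arm are treated as non-significant there.
For both-track events, track-level verdicts are combined by "either track
calls it", with direction conflicts reported, not resolved.

The same machinery provides the **difference-in-changes** contrast for the
companion omics: a cell-means mixed model over arm × timepoint with a
participant random intercept and the standard covariates, testing
(T − Pre in exercise) − (T − Pre in control) per feature.

## CDS impact

Direct change: the event's alternative region overlaps (≥1 bp, strand-aware,
same gene only) an annotated CDS interval. Likely change: the protein
sequence sets of the inclusion and exclusion isoforms are disjoint (exact
string comparison, no alignment); a side with no coding output against a
coding side counts as disjoint, since the two forms then necessarily differ
in coding output; two non-coding sides are "no change". Direct takes
precedence over likely.

## RBP target enrichment and phospho coupling

Binding intervals per RBP are merged. An event is a target when any of its
splice sites (all donors/acceptors defining the event: 4 for SE, 2
otherwise), extended ±100 bp, overlaps a binding interval
(strand-agnostic). Enrichment among DAS events against all characterized
events is the upper-tail hypergeometric probability; fold change is the
target-frequency ratio (k/n)/(K/N); Bonferroni multiplicity is the number
of RBPs with ≥1 background target at that arm × timepoint; significance
requires adjusted p < 0.05 and fold change > 1.5.

Phospho–PSI coupling: per participant and post timepoint, phosphosite log2
fold change vs Pre and PSI difference vs Pre are pooled across the exercise
arms and all post timepoints; Pearson r and its t-test p are computed per
(site, target DAS event) pair with ≥3 complete pairs; FDR across pairs,
significance at FDR < 0.05.

## Splice regulatory circuits

Candidates are (peak, event) pairs with the peak differentially accessible
at raw p < 0.005 in ≥1 arm × timepoint (difference-in-changes contrast) and
within ±200 kb of the event's first splice site (5'-most site in
transcriptional orientation), for events DAS somewhere; motif hits supply
the peak → TF edges.

Each triad is scored by two Bayesian regressions on standardized,
cell-mean-residualized vectors (arm × timepoint means are projected out
first, so the posteriors measure cross-individual covariation, not the
shared exercise response):

    logit-PSI = I·β·A + ε        A = J·δ·T̂ + ε'

with T̂ the leave-one-out mean accessibility of the TF's other mapped peaks,
I, J ~ Bernoulli(1/4), β, δ ~ N(0, 1), σ² ~ inverse-gamma(1, 1). Gibbs
sampling collapses the slope out of the indicator update (conjugate Bayes
factor); 100 burn-in iterations precede the retained draws. The looping
probability is max over sign of P(I = 1, sign β = that sign), likewise
binding for (J, δ); circuits pass at ≥ 0.9 for both (inclusive).

Two numerical points. First, a pure sign-stability posterior without the
indicator is, under the null, equivalent to a one-sided p < 0.1 test —
about 20% of uncoupled pairs would reach 0.9 — so the inclusion indicator
is what makes the 0.9 threshold meaningful; with the sparse 1/4 prior an
uncoupled standardized pair of 60 samples passes in well under 1% of
permutation replicates, while a coupling of r = 0.9 saturates the
posterior. Second, the standardization makes the posteriors exactly
invariant under affine rescaling of the accessibility matrix, and all draws
flow from a single seeded generator over triads in sorted order, so scoring
is deterministic given (inputs, seed, n_draws). TFs mapped to a single
peak have no leave-one-out proxy; the peak itself is used and the binding
probability is then uninformative (documented limitation). Motif scanning
is out of scope; the mapping is consumed as a precomputed table.

## Synthetic-data generator

Latent logit-PSI per event × sample is
baseline + planted delta + participant intercept + noise, with baseline
PSI ~ U(0.25, 0.75), participant-intercept sd 0.3 and residual sd 0.5 by
default — at 40 participants/arm these give > 0.8 recall for a planted
delta of 1.5, verified by simulation in the test suite, and a calibrated
null. Junction counts are binomial draws: a read supports inclusion with
probability m·ψ/(m·ψ + 1 − ψ), total ~ Poisson(mean depth 50), so the
multiplicity-normalized PSI recomputed from counts recovers the latent
value; isoform TPMs are the event total (base U(2, 20) × lognormal sample
noise, sd 0.2) split exactly as ψ : 1 − ψ. Covariates are drawn
independently of arm (no confounding), so type-I error tests are clean.
Events are laid out every 20 kb on a single synthetic chromosome `chrS`,
types cycling SE → A5SS → A3SS → RI, alternating strands; CDS and protein
annotation cycle through the three impact classes.

The regulatory layer plants: one RBP whose merged intervals cover 80% of
the planted DAS events (plus 10% background); circuit peaks whose
accessibility is r·z(PSI) + √(1−r²)·noise with r = 0.9 near their event,
plus an intrinsic post-exercise shift of 1.5 — a peak planted as a
regulatory candidate is differentially accessible by definition of the
candidate gate; per-TF support peaks placed in a distal gene desert (so
they feed the TF-activity proxy without ever becoming candidates
themselves); decoy peaks that respond to exercise (shift 1.0) but are
uncoupled to any PSI, to populate the candidate set with realistic nulls;
and phosphosites whose pooled fold changes track a target event's PSI
changes at r = 0.8, plus null sites. `control_confounded` effects plant the
same-direction shift in the control arm to exercise the rejection path of
the control rule.

Everything derives from one `numpy` Generator seeded once; identical spec +
seed reproduces byte-identical output files.

What the generator does **not** emulate: read-level sequencing artefacts,
realistic transcriptome structure or event density, correlated covariates,
linkage to real genome builds, mutually-exclusive-exon and first/last-exon
events, or batch structure in the regulatory assays. Passing recovery
tests therefore demonstrates correctness of the statistical machinery under
the stated generative model, not robustness to every artefact of real data.

## Problem sizes used in tests and the acceptance script

Oracle checks enumerate all hypergeometric configurations to N = 25 and BH
vectors to length 10 on a 0.01 grid; null calibration uses 2000 events at
40 participants/arm; recovery uses 100 planted + 100 null events at
40/arm; the control-rule fixture 50 events at 20/arm (delta 2.0, noise
0.3); circuit recovery 10 planted triads among ~120 events and ~55 peaks in
a 60-sample cohort with 1000 Gibbs draws and a 100-replicate permutation
control; phospho coupling 60 participant-timepoint pairs. These sizes are
the package's default demonstration conditions; all scale linearly if
enlarged.

## Known limitations

* The coupling model is a deliberately simple stand-in for full multi-level
  Bayesian circuit frameworks: linear, bulk-level, two probabilities per
  triad, no joint modelling across triads and no explicit TF-binding prior
  from footprinting.
* The containment-df t test is an approximation; at very small cohorts
  (< 10 participants/arm) its calibration degrades together with the REML
  variance estimates.
* Logit-transforming a binomial PSI estimate at finite read depth carries a
  convexity bias away from PSI = 0.5: at mean depth 50 the recovered
  timepoint coefficient for a planted shift of 1.5 averages ~1.6 (fits on
  the noiseless latent PSI are unbiased), shrinking as depth grows. This is
  a property of ratio-based PSI quantification itself, shared by any
  logit-scale analysis of junction-count PSI.
* RBP window overlap is strand-agnostic and fold change is a proportion
  ratio, both the simplest readings of the procedure they implement.
* Events whose isoforms are all non-coding are classified "no change"; an
  asymmetric coding/non-coding pair counts as a likely change.
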