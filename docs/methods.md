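# Methods

`ctdyn` analyzes paired cerebrospinal-fluid (CSF) and plasma circulating
tumor DNA (ctDNA) profiles from patients with brain metastases: it filters
somatic calls, quantifies tumor DNA load per body fluid, measures how well
the two compartments agree, tracks clonal composition across treatment, calls
molecular response, and relates all of it to progression-free and overall
survival. A synthetic cohort generator with fully known ground truth closes
the loop, so every stage can be validated end to end without patient data.

## Data model and filtering

A *sample* is one (patient, compartment, timepoint) profile: a set of somatic
calls plus the fluid's total cell-free DNA (cfDNA) concentration in pg/mL.
Variant identity is the tuple (chrom, pos, ref, alt, class); gene symbols are
annotation only, so cross-sample matching is immune to annotation drift.

Read-backed calls (SNV/indel/fusion) are retained when

* VAF ≥ `min_vaf` (default 0.002),
* alt reads ≥ `min_alt_reads` (default 3),
* population frequency, when annotated, ≤ `max_pop_freq` (default 0.01).

Thresholds are inclusive on the passing side so that a call sitting exactly
at a printed cutoff passes. CNV calls carry no per-read support in this model
and bypass the read-level rules; a user-supplied blacklist of identity keys
(recurrent-artifact lists are lab-specific and unpublished) applies to every
class. Samples with zero passing calls are kept as ctDNA-negative rather
than dropped — detection-rate denominators need them.

## ctDNA quantification

Two per-sample summaries:

* **maxVAF** — the largest VAF among passing read-backed calls (0 if none), a
  proxy for the dominant clone's share of the cfDNA pool;
* **concentration** in haploid genome equivalents (hGE) per mL:
  `mean VAF × cfDNA (pg/mL) / 3.3`, taking one haploid genome as 3.3 pg.

The mean runs over SNV/indel/fusion calls only. CNVs are excluded because a
copy-number call has no allele fraction on the same scale; including a
pseudo-VAF for them would make the concentration depend on an arbitrary
encoding choice.

## Concordance

Two granularities are deliberately distinct and must be selected explicitly:

* **variant level** (identity keys) for the directional consistency measure
  `consistency(A→B) = 100·|A∩B|/|A|` and for three-way Venn partitions.
  Consistency is undefined (an error, not 0) when A is mutant-negative;
  cohort summaries are unweighted means over mutant-positive patients. A flag
  excludes CNV-class keys for mutation-only comparisons.
* **gene level** (presence/absence of any passing alteration in a gene) for
  per-gene 2×2 contingency tables scored with Cohen's kappa,
  `κ = (p_o − p_e)/(1 − p_e)`, with `κ = 1` at the degenerate
  `p_o = p_e = 1` limit. `table_from_marginals` reconstructs a 2×2 table
  from its marginals and overall percent agreement, and raises when the
  implied cell counts are non-integer — a useful integrity check when only
  summary numbers are available.

## Clonality and clonal evolution

At baseline, a mutation is **clonal** when its VAF is at least 25% of the
sample's maxVAF, otherwise **subclonal** — a relative threshold, not a
phylogenetic reconstruction. The tie at exactly 25% is labeled clonal by
default (`strict=True` flips it; the maxVAF variant is clonal either way).
Labels are invariant under common rescaling of all VAFs, so compartment-wide
attenuation does not move them. Clonality is assessed per compartment: CSF
and plasma each have their own maxVAF.

Across timepoints, variants are matched by exact identity key (same panel
and pipeline assumed across draws; no fuzzy matching). Every baseline variant
is *retained* or *cleared*; every follow-up-only variant is *acquired* and
always subclonal regardless of its VAF. Complete clearance is flagged, with
the post-treatment clonal fraction reported as 0, so cohort summaries remain
computable. A patient shows **high clonal retention** when clonal mutations
are strictly more than 80% of follow-up mutations. Cohort-level clonal
fractions are reported both pooled (every mutation counted once) and as
per-patient means, since composition plots can be read either way.

## Molecular response and survival

A **ctDNA response** is a ≥ 50% drop (inclusive) in hGE/mL concentration from
baseline to follow-up in the same compartment. Baseline-negative patients are
non-evaluable and excluded from response-group contrasts; a follow-up that
turns negative is a 100% reduction. Radiographic response enters as RECIST
categories binarized CR/PR → responder, SD/PD → non-responder (the mapping is
configurable); molecular-vs-radiographic agreement reuses the kappa
machinery.

Survival uses right-censored Kaplan–Meier estimates (median = smallest event
time with S ≤ 0.5, undefined if never reached), the two-group log-rank test
(1-df chi-square, hypergeometric variance, no continuity correction), and a
univariate hazard ratio with Wald 95% CI from a single-covariate Cox
proportional-hazards fit. These standard estimators are delegated to
lifelines behind the module's own validated interfaces; the test suite
checks them against independent brute-force risk-set implementations to
1e-10 on random small instances, and checks log-rank type-I error (n = 200
per arm, 1000 replicates) stays within [0.03, 0.07] at α = 0.05. A zero-event
contrast returns statistic 0, p = 1 rather than an error.

## Synthetic cohorts

The generator emulates the data structure the pipeline assumes, at the
variant-call level (no reads):

* **Clone architecture.** 1–3 clonal variants with true VAF uniform on
  [0.10, 0.40] and 0–5 subclonal variants on [0.005, 0.05], with the
  subclonal tier capped at 80% of the 25%-of-max threshold so tier membership
  coincides with the clonality rule even after compartment scaling and
  rounding. The first clonal variant is a driver (EGFR-weighted categorical
  over lung-cancer drivers); TP53 joins the clonal tier with probability
  0.65.
* **Detection.** A per-patient, per-compartment shedding indicator —
  Bernoulli at the compartment's sample-positivity target (defaults 0.637
  CSF, 0.911 plasma, 1.0 tissue), persistent across timepoints — gates
  whether a fluid carries ctDNA at all; given shedding, each variant is
  detected independently (defaults 0.6 CSF, 0.85 plasma per variant),
  conditioned on at least one detection. Positivity therefore lands on its
  configured target while per-variant co-detection produces realistic
  cross-compartment consistency (~55–65% plasma→CSF). A pure per-variant
  thinning calibrated only to sample positivity was rejected: it implies
  ~12% per-variant CSF detection and collapses concordance.
* **Compartment scaling and noise.** Observed VAF = true VAF × compartment
  scale (1.0 CSF, 0.5 plasma, 1.5 tissue) × lognormal noise (σ = 0.1),
  rounded to 4 decimals; alt reads follow from a nominal 2000× depth. CNVs
  (EGFR-gain-weighted; STK11 as the loss) are emitted per positive sample at
  39.3% (CSF) vs 21.4% (plasma) — only in mutation-positive samples, since
  calling copy number from a fluid without detectable ctDNA is not
  realistic and positivity must stay at its target.
* **Treatment effect.** Latent responder indicators (48% CSF, 68% plasma)
  scale week-8 VAFs by 0.3 (responders) or 1.1 (non-responders); week-8
  cfDNA is baseline × lognormal jitter (σ = 0.1); new subclonal mutations
  are acquired Poisson(1.5) in CSF and Poisson(0.5) in plasma. Clearance of
  low-VAF variants emerges from the detection filter rather than being
  simulated directly.
* **Outcomes.** Event times are exponential per endpoint and group with
  independent exponential censoring (rate 0.03/month). Default hazards come
  from the reported group medians (intracranial PFS 13.27 vs 6.13 months,
  extracranial 11.57 vs 6.20); overall-survival medians by baseline CSF
  positivity are not published, so 11.7 vs 30 months were chosen to match
  the reported adverse hazard ratio of ~2.6. Radiographic labels are the
  latent group flipped with probability 0.12.

A single seed drives per-patient `SeedSequence` substreams, so identical
config + seed yields byte-identical files and cohorts extend without
rewriting earlier patients. `CohortConfig.noiseless()` switches off every
noise source (and raises the subclonal floor to 0.015 so responder-scaled
VAFs cannot fall through the detection filter); under it the pipeline
recovers every latent clonality and responder label exactly, which is the
package's main self-consistency check.

**What the generator does not emulate:** sequencing reads and their error
modes, germline contamination, clone phylogenies (tiers are independent
draws, not trees), VAF-dependent detection sensitivity, correlated
censoring, or non-proportional hazards. Passing tests therefore validate the
statistical machinery and its bookkeeping, not the biology of any particular
cohort.

## Numerical and design choices

* Float VCF INFO fields are rounded to 6 decimals on parse to undo htslib's
  float32 storage; the generator emits 4-decimal VAFs, so write→read round
  trips are exact.
* The Cox fit uses lifelines' Newton solver rather than a hand-rolled 1-D
  search; for a single binary covariate both maximize the same partial
  likelihood and lifelines adds a tested Wald CI.
* Problem sizes in the validation suite — 500-patient cohorts for
  calibration and hazard-ratio recovery (100 replicate cohorts), 1000
  replicates for log-rank type-I error — were chosen so Monte-Carlo standard
  errors are several times smaller than the tolerances being checked.
* Degenerate inputs have defined behavior throughout: empty profiles are
  ctDNA-negative (concentration 0), consistency with an empty numerator set
  is an error, kappa of an empty table is an error, complete clearance is a
  flag, zero-event log-rank returns the null result, and a zero-patient
  cohort writes valid empty tables.

## Known limitations

Gene-level kappa treats a gene as a binary presence/absence call, discarding
multiplicity within the gene. The clonality rule inherits maxVAF's
sensitivity to detection dropout: if the dominant variant is missed, the
threshold shifts and labels move with it (visible in the default-noise
truth-recovery agreement of ~95%). Hazard-ratio recovery assumes
proportional hazards by construction. Tissue profiles carry no meaningful
cfDNA concentration and are excluded from concentration-based analyses.
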