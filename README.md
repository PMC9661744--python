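# ctdyn

Paired CSF/plasma circulating-tumor-DNA (ctDNA) dynamics for patients with
brain metastases. Plasma liquid biopsy under-samples intracranial disease
because the blood–brain barrier limits tumor-DNA shedding into blood;
cerebrospinal fluid (CSF) is the natural compartment for brain lesions.
`ctdyn` is a tested pipeline for the analyses this setting requires:

* **Variant filtering** — somatic calls retained at VAF ≥ 0.2%, ≥ 3 unique
  mutant reads, population frequency ≤ 1%, plus a user blacklist; CNV calls
  bypass the read-level rules.
* **ctDNA quantification** — per sample, maxVAF and the concentration
  `mean VAF × cfDNA (pg/mL) / 3.3` in haploid genome equivalents (hGE) per
  mL.
* **Cross-compartment concordance** — directional consistency
  `100·|A∩B|/|A|`, three-way Venn partitions, and per-gene 2×2 tables with
  Cohen's kappa `κ = (p_o − p_e)/(1 − p_e)`.
* **Clonality and clonal evolution** — a variant is clonal when its VAF ≥
  25% of the sample's maxVAF; across timepoints variants are retained,
  cleared or acquired (acquired ⇒ subclonal), and patients whose follow-up
  mutations are > 80% clonal are flagged as high-retention.
* **Molecular response** — a ≥ 50% drop in ctDNA concentration from
  baseline; agreement with radiographic (RECIST) response via kappa.
* **Survival** — Kaplan–Meier estimates, log-rank tests and univariate Cox
  hazard ratios contrasting molecular-response and ctDNA-positivity groups.
* **Synthetic cohorts** — a seeded generator with known ground truth
  (clone tiers, compartment-asymmetric detection, treatment effects,
  group-dependent exponential survival) for end-to-end validation.

Inputs are VCF v4.2 variant files (INFO keys `VAF`, `ALT_READS`, `POP_FREQ`,
`CLASS`, `GENE`; CNVs as symbolic `<DUP>`/`<DEL>`), a TSV sample manifest and
a TSV clinical table; see `docs/methods.md` for the full model description.

## Worked example

```python
from ctdyn import (CohortConfig, PipelineConfig, run_pipeline,
                   table_from_marginals, cohens_kappa)

# Agreement between CSF and plasma EGFR status, reconstructed from summary
# numbers alone: 24/56 CSF-positive, 29/56 plasma-positive, 87.5% agreement.
table = table_from_marginals(56, 24, 29, 87.5)
print("cells:", (table.both_pos, table.a_only, table.b_only, table.both_neg))
print("kappa:", round(cohens_kappa(table), 3))

# Full pipeline on a simulated 200-patient cohort.
report = run_pipeline(PipelineConfig(simulate=CohortConfig(n_patients=200, seed=7)),
                      "demo_run")
s = report["stages"]
print("CSF baseline positivity:", round(100 * s["detection_rates"]["CSF:baseline"], 1), "%")
print("plasma baseline positivity:", round(100 * s["detection_rates"]["plasma:baseline"], 1), "%")
print("mean consistency plasma->CSF:",
      round(s["concordance"]["mean_consistency_plasma_to_csf_pct"], 1), "%")
ic = s["survival"]["icPFS_by_csf_response"]
print("icPFS medians (responders vs non):", ic["median_a"], "vs", ic["median_b"], "months")
print("icPFS HR:", round(ic["hr"], 3), "logrank p:", round(ic["logrank_p"], 4))
```

prints

```
cells: (23, 1, 6, 26)
kappa: 0.751
CSF baseline positivity: 61.0 %
plasma baseline positivity: 91.0 %
mean consistency plasma->CSF: 61.9 %
icPFS medians (responders vs non): 14.86 vs 6.74 months
icPFS HR: 0.409 logrank p: 0.0001
```

Reading it: the reconstructed 2×2 table gives substantial chance-corrected
CSF/plasma agreement for EGFR (κ = 0.751). In the simulated cohort, CSF is
ctDNA-positive in ~61% of baseline samples versus ~91% for plasma (the
configured compartment asymmetry), about 62% of plasma alterations are
re-found in paired CSF, and patients whose CSF ctDNA concentration halved by
week 8 progress intracranially much later than those whose did not
(HR ≈ 0.41, log-rank p ≈ 1e-4).

The same stages are available from the shell:

```bash
ctdyn simulate --out cohort/ --seed 7
ctdyn concordance --manifest cohort/manifest.tsv --out conc/ --granularity gene --gene EGFR
ctdyn respond --manifest cohort/manifest.tsv --out resp/
ctdyn survive --manifest cohort/manifest.tsv --clinical cohort/clinical.tsv \
              --endpoint icPFS --group-by csf_response --out surv/
ctdyn run --out full_run/ --seed 7        # everything, one report.json
```

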