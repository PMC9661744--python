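"""Synthetic paired CSF/plasma/tissue ctDNA cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, at the variant-call level (no sequencing reads):

* per-patient clone architecture: a clonal VAF tier (containing the maxVAF
  variant by construction) and a subclonal tier kept safely below 25% of the
  clonal maximum, so tier membership coincides with the clonality rule;
* compartment-asymmetric detection: a patient-level shedding factor — a
  Bernoulli draw at the configured sample-level positivity target, persistent
  across timepoints — gates whether a fluid carries any ctDNA; given
  shedding, each true variant is detected by independent binomial thinning
  at the compartment's per-variant rate, conditioned on at least one
  detection (a shedding sample with zero detectable variants is a
  contradiction). Sample positivity therefore lands on its configured
  target while per-variant co-detection drives the concordance statistics;
* CNV calls enriched in CSF, emitted only in mutation-positive samples
  (copy-number calling from a fluid with no detectable ctDNA is not
  realistic, and this keeps sample positivity at its configured target);
* treatment effect: latent responder groups scale week-8 VAFs by a group
  multiplier; new subclonal mutations are acquired at a Poisson rate,
  preferentially in CSF;
* group-dependent survival: exponential event times per endpoint and group,
  with independent exponential censoring; radiographic response labels are
  the latent group passed through a configurable misclassification rate.

A single global seed drives per-patient substreams (``SeedSequence.spawn``),
so identical config + seed yields byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import concordance
from .clonality import assign_baseline_clonality
from .survival import (
    Endpoint,
    ResponseCall,
    SurvivalRecord,
    call_response,
    response_vs_radiology,
    univariate_hr,
)
from .variants import (
    Compartment,
    FilterConfig,
    SampleProfile,
    Timepoint,
    VariantCall,
    VariantClass,
    write_manifest,
    write_variant_file,
)

__all__ = [
    "GENE_PANEL",
    "CohortConfig",
    "Cohort",
    "simulate_cohort",
    "write_cohort",
    "truth_recovery_report",
]

# Panel genes with approximate hg19 anchor coordinates; positions of simulated
# variants are offsets from these anchors.
GENE_PANEL: dict[str, tuple[str, int]] = {
    "EGFR": ("chr7", 55086714),
    "TP53": ("chr17", 7571720),
    "KRAS": ("chr12", 25358180),
    "ALK": ("chr2", 29415640),
    "MET": ("chr7", 116312444),
    "BRAF": ("chr7", 140419127),
    "ROS1": ("chr6", 117609463),
    "RET": ("chr10", 43572517),
    "ERBB2": ("chr17", 37844393),
    "NTRK1": ("chr1", 156785541),
    "STK11": ("chr19", 1205798),
    "PIK3CA": ("chr3", 178866311),
    "CDKN2A": ("chr9", 21967751),
    "RB1": ("chr13", 48877883),
    "SMO": ("chr7", 128828713),
    "CDK6": ("chr7", 92234235),
    "NKX2-1": ("chr14", 36985603),
    "PTEN": ("chr10", 89623195),
    "MYC": ("chr8", 128748315),
    "NF1": ("chr17", 29421945),
}

_DRIVER_GENES = ["EGFR", "KRAS", "ALK", "MET", "BRAF", "ROS1", "RET", "ERBB2", "NTRK1"]
_DRIVER_WEIGHTS = [0.45, 0.15, 0.12, 0.08, 0.06, 0.05, 0.04, 0.03, 0.02]
_FUSION_GENES = {"ALK", "ROS1", "RET", "NTRK1"}

_CNV_GENES = ["EGFR", "MET", "CDK6", "SMO", "NKX2-1", "NTRK1", "STK11"]
_CNV_WEIGHTS = [0.40, 0.12, 0.10, 0.10, 0.10, 0.08, 0.10]

_BASES = np.array(list("ACGT"))

_LN2 = math.log(2.0)


class LogNormalParams(BaseModel):
    """Parameters of a lognormal on the natural-log scale."""

    mu: float
    sigma: float


class CohortConfig(BaseModel):
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror a metastatic-NSCLC brain-metastasis cohort profiled with
    a deep targeted panel: ~64% of baseline CSF and ~91% of baseline plasma
    samples ctDNA-positive, CNVs enriched in CSF (39% vs 21% of positive
    samples), roughly half of CSF-evaluable patients responding molecularly,
    and exponential progression hazards set from the reported median
    intracranial (13.27 vs 6.13 months) and extracranial (11.57 vs 6.20
    months) progression-free survivals of responder vs non-responder groups.
    """

    n_patients: int = 56
    seed: int = 0

    # clone architecture
    n_clonal_range: tuple[int, int] = (1, 3)
    n_subclonal_range: tuple[int, int] = (0, 5)
    clonal_vaf_range: tuple[float, float] = (0.10, 0.40)
    subclonal_vaf_range: tuple[float, float] = (0.005, 0.05)
    tp53_prob: float = 0.65

    # compartment physics
    detection_target: dict[str, float] = Field(
        default_factory=lambda: {"CSF": 0.637, "plasma": 0.911, "tissue": 1.0}
    )
    per_variant_detection: dict[str, float] = Field(
        default_factory=lambda: {"CSF": 0.6, "plasma": 0.85, "tissue": 1.0}
    )
    vaf_scale: dict[str, float] = Field(
        default_factory=lambda: {"CSF": 1.0, "plasma": 0.5, "tissue": 1.5}
    )
    vaf_noise_sigma: float = 0.10
    p_cnv: dict[str, float] = Field(
        default_factory=lambda: {"CSF": 0.393, "plasma": 0.214, "tissue": 0.30}
    )
    cfdna_lognormal: dict[str, LogNormalParams] = Field(
        default_factory=lambda: {
            "CSF": LogNormalParams(mu=7.3, sigma=0.8),
            "plasma": LogNormalParams(mu=8.85, sigma=0.6),
        }
    )
    depth: int = 2000

    # treatment effect
    responder_fraction_csf: float = 0.48
    responder_fraction_plasma: float = 0.68
    responder_vaf_multiplier: float = 0.3
    nonresponder_vaf_multiplier: float = 1.1
    week8_cfdna_sigma: float = 0.10
    acquired_mean: dict[str, float] = Field(
        default_factory=lambda: {"CSF": 1.5, "plasma": 0.5}
    )

    # outcome model: exponential rate per month, keyed "<endpoint>:<group>"
    hazard_per_month: dict[str, float] = Field(
        default_factory=lambda: {
            "icPFS:responder": _LN2 / 13.27,
            "icPFS:nonresponder": _LN2 / 6.13,
            "ecPFS:responder": _LN2 / 11.57,
            "ecPFS:nonresponder": _LN2 / 6.20,
            "OS:csf_positive": _LN2 / 11.7,
            "OS:csf_negative": _LN2 / 30.0,
        }
    )
    censoring_rate_per_month: float = 0.03
    radiographic_flip_prob: float = 0.12

    @model_validator(mode="after")
    def _check_probs(self) -> "CohortConfig":
        probs = [
            self.tp53_prob,
            self.responder_fraction_csf,
            self.responder_fraction_plasma,
            self.radiographic_flip_prob,
            *self.detection_target.values(),
            *self.p_cnv.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(not 0.0 < p <= 1.0 for p in self.per_variant_detection.values()):
            raise ValueError("per-variant detection rates must lie in (0, 1]")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if not self.responder_vaf_multiplier < 0.5 <= self.nonresponder_vaf_multiplier:
            raise ValueError(
                "responder multiplier must be < 0.5 <= non-responder multiplier"
            )
        if any(r <= 0 for r in self.hazard_per_month.values()):
            raise ValueError("hazard rates must be positive")
        return self

    @classmethod
    def noiseless(cls, **overrides) -> "CohortConfig":
        """A degenerate configuration in which every latent label is recoverable.

        Detection is certain, VAF and cfDNA noise are off, no mutations are
        acquired and radiographic labels match the latent groups. The
        subclonal floor is raised so that responder-scaled subclonal VAFs
        stay above the default detection filter in every compartment.
        """
        base = dict(
            detection_target={"CSF": 1.0, "plasma": 1.0, "tissue": 1.0},
            per_variant_detection={"CSF": 1.0, "plasma": 1.0, "tissue": 1.0},
            vaf_noise_sigma=0.0,
            week8_cfdna_sigma=0.0,
            acquired_mean={"CSF": 0.0, "plasma": 0.0},
            radiographic_flip_prob=0.0,
            subclonal_vaf_range=(0.015, 0.05),
        )
        base.update(overrides)
        return cls(**base)

    def true_hr(self, endpoint: str, group_a: str, group_b: str) -> float:
        return self.hazard_per_month[f"{endpoint}:{group_a}"] / self.hazard_per_month[
            f"{endpoint}:{group_b}"
        ]


@dataclass
class Cohort:
    """In-memory synthetic cohort: observed profiles plus latent truth."""

    config: CohortConfig
    profiles: list[SampleProfile]
    clinical: pd.DataFrame
    truth_patients: pd.DataFrame
    truth_variants: pd.DataFrame

    def profile(
        self, patient_id: str, compartment: Compartment, timepoint: Timepoint
    ) -> SampleProfile | None:
        for p in self.profiles:
            if (
                p.patient_id == patient_id
                and p.compartment == compartment
                and p.timepoint == timepoint
            ):
                return p
        return None

    def survival_records(
        self, endpoint: Endpoint, groups: Mapping[str, str] | None = None
    ) -> list[SurvivalRecord]:
        sub = self.clinical[self.clinical["endpoint"] == endpoint.value]
        records = []
        for row in sub.itertuples(index=False):
            group = groups.get(row.patient_id, "") if groups else ""
            records.append(
                SurvivalRecord(
                    patient_id=row.patient_id,
                    endpoint=endpoint,
                    time_months=float(row.time_months),
                    event=bool(row.event),
                    group=group,
                )
            )
        return records


def _rand_substitution(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(0, 4)]
    alt = _BASES[(np.where(_BASES == ref)[0][0] + rng.integers(1, 4)) % 4]
    return str(ref), str(alt)


def _observed_vaf(true_vaf: float, scale: float, rng, sigma: float) -> float:
    noise = math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
    return float(np.clip(round(true_vaf * scale * noise, 4), 0.0001, 0.98))


@dataclass
class _TrueVariant:
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    true_vaf: float
    tier: str  # "clonal" | "subclonal"
    is_driver: bool
    is_oncogenic: bool


def _draw_true_variants(rng: np.random.Generator, cfg: CohortConfig) -> list[_TrueVariant]:
    n_clonal = int(rng.integers(cfg.n_clonal_range[0], cfg.n_clonal_range[1] + 1))
    n_sub = int(rng.integers(cfg.n_subclonal_range[0], cfg.n_subclonal_range[1] + 1))

    clonal_vafs = np.sort(
        rng.uniform(cfg.clonal_vaf_range[0], cfg.clonal_vaf_range[1], n_clonal)
    )[::-1]
    clonal_vafs = np.round(clonal_vafs, 4)
    max_clonal = float(clonal_vafs[0])

    # keep the subclonal tier at a 20% safety margin below the 25% threshold so
    # tier membership survives compartment scaling and 4-dp rounding
    sub_hi = min(cfg.subclonal_vaf_range[1], 0.8 * 0.25 * max_clonal)
    sub_lo = min(cfg.subclonal_vaf_range[0], 0.5 * sub_hi)
    sub_vafs = np.round(rng.uniform(sub_lo, sub_hi, n_sub), 4)

    genes_used: set[str] = set()
    variants: list[_TrueVariant] = []

    def add(gene: str, vaf: float, tier: str, driver: bool) -> None:
        chrom, anchor = GENE_PANEL[gene]
        pos = int(anchor + rng.integers(0, 5000))
        if gene in _FUSION_GENES and driver and rng.random() < 0.5:
            vclass = VariantClass.FUSION
            ref, alt = "N", "N"
        else:
            u = rng.random()
            if u < 0.15:
                vclass = VariantClass.INDEL
                ref, alt_base = _rand_substitution(rng)
                ref, alt = ref + "A", ref[0]
            else:
                vclass = VariantClass.SNV
                ref, alt = _rand_substitution(rng)
        variants.append(
            _TrueVariant(
                gene=gene,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                variant_class=vclass,
                true_vaf=float(vaf),
                tier=tier,
                is_driver=driver,
                is_oncogenic=driver or rng.random() < 0.3,
            )
        )
        genes_used.add(gene)

    driver_gene = str(rng.choice(_DRIVER_GENES, p=_DRIVER_WEIGHTS))
    add(driver_gene, clonal_vafs[0], "clonal", True)
    slot = 1
    if slot < n_clonal and rng.random() < cfg.tp53_prob and "TP53" not in genes_used:
        add("TP53", clonal_vafs[slot], "clonal", False)
        slot += 1
    pool = [g for g in GENE_PANEL if g not in genes_used]
    extra = rng.choice(pool, size=(n_clonal - slot) + n_sub, replace=False)
    idx = 0
    for i in range(slot, n_clonal):
        add(str(extra[idx]), clonal_vafs[i], "clonal", False)
        idx += 1
    for i in range(n_sub):
        add(str(extra[idx]), sub_vafs[i], "subclonal", False)
        idx += 1
    return variants


def _emit_calls(
    truth: Sequence[_TrueVariant],
    detected: np.ndarray,
    multiplier: float,
    compartment: str,
    patient_id: str,
    sample_id: str,
    rng: np.random.Generator,
    cfg: CohortConfig,
) -> list[VariantCall]:
    scale = cfg.vaf_scale[compartment] * multiplier
    calls = []
    for tv, keep in zip(truth, detected):
        if not keep:
            continue
        vaf = _observed_vaf(tv.true_vaf, scale, rng, cfg.vaf_noise_sigma)
        calls.append(
            VariantCall(
                patient_id=patient_id,
                sample_id=sample_id,
                gene=tv.gene,
                chrom=tv.chrom,
                pos=tv.pos,
                ref=tv.ref,
                alt=tv.alt,
                variant_class=tv.variant_class,
                vaf=vaf,
                alt_reads=int(round(vaf * cfg.depth)),
                pop_freq=None,
                is_driver=tv.is_driver,
                is_oncogenic=tv.is_oncogenic,
            )
        )
    return calls


def _maybe_cnv(
    calls: list[VariantCall],
    compartment: str,
    patient_id: str,
    sample_id: str,
    rng: np.random.Generator,
    cfg: CohortConfig,
) -> None:
    # CNVs only ever called from mutation-positive samples; this keeps
    # sample-level positivity at the configured detection target
    if not calls or rng.random() >= cfg.p_cnv.get(compartment, 0.0):
        return
    gene = str(rng.choice(_CNV_GENES, p=_CNV_WEIGHTS))
    vclass = VariantClass.CNV_LOSS if gene == "STK11" else VariantClass.CNV_GAIN
    chrom, anchor = GENE_PANEL[gene]
    calls.append(
        VariantCall(
            patient_id=patient_id,
            sample_id=sample_id,
            gene=gene,
            chrom=chrom,
            pos=anchor,  # gene-anchored so the same CNV shares a key across samples
            ref="N",
            alt="<DUP>" if vclass is VariantClass.CNV_GAIN else "<DEL>",
            variant_class=vclass,
            vaf=None,
            alt_reads=None,
            is_driver=gene == "EGFR",
            is_oncogenic=True,
        )
    )


def _acquired_calls(
    compartment: str,
    used_genes: set[str],
    patient_id: str,
    sample_id: str,
    rng: np.random.Generator,
    cfg: CohortConfig,
) -> list[VariantCall]:
    n = int(rng.poisson(cfg.acquired_mean.get(compartment, 0.0)))
    if n == 0:
        return []
    pool = [g for g in GENE_PANEL if g not in used_genes]
    n = min(n, len(pool))
    genes = rng.choice(pool, size=n, replace=False)
    calls = []
    for gene in genes:
        chrom, anchor = GENE_PANEL[str(gene)]
        ref, alt = _rand_substitution(rng)
        true_vaf = float(rng.uniform(*cfg.subclonal_vaf_range))
        vaf = _observed_vaf(true_vaf, cfg.vaf_scale[compartment], rng, cfg.vaf_noise_sigma)
        calls.append(
            VariantCall(
                patient_id=patient_id,
                sample_id=sample_id,
                gene=str(gene),
                chrom=chrom,
                pos=int(anchor + rng.integers(5000, 10000)),
                ref=ref,
                alt=alt,
                variant_class=VariantClass.SNV,
                vaf=vaf,
                alt_reads=int(round(vaf * cfg.depth)),
            )
        )
    return calls


def _sample_id(pid: str, compartment: str, timepoint: str) -> str:
    return f"{pid}_{compartment}_{timepoint}"


def _detect(
    rng: np.random.Generator, m: int, sheds: bool, p_var: float
) -> np.ndarray:
    """Per-variant detection mask: thinning given shedding, >= 1 hit guaranteed."""
    if not sheds or m == 0:
        return np.zeros(m, dtype=bool)
    while True:
        detected = rng.random(m) < p_var
        if detected.any():
            return detected


def simulate_cohort(cfg: CohortConfig) -> Cohort:
    """Draw a full synthetic cohort under the configured study conditions."""
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(max(cfg.n_patients, 1))

    profiles: list[SampleProfile] = []
    clinical_rows: list[dict] = []
    truth_patient_rows: list[dict] = []
    truth_variant_rows: list[dict] = []

    for i in range(cfg.n_patients):
        rng = np.random.default_rng(streams[i])
        pid = f"P{i + 1:04d}"
        truth = _draw_true_variants(rng, cfg)
        m = len(truth)
        for tv in truth:
            truth_variant_rows.append(
                {
                    "patient_id": pid,
                    "gene": tv.gene,
                    "chrom": tv.chrom,
                    "pos": tv.pos,
                    "ref": tv.ref,
                    "alt": tv.alt,
                    "variant_class": tv.variant_class.value,
                    "true_vaf": tv.true_vaf,
                    "tier": tv.tier,
                }
            )

        csf_responder = bool(rng.random() < cfg.responder_fraction_csf)
        plasma_responder = bool(rng.random() < cfg.responder_fraction_plasma)
        used_genes = {tv.gene for tv in truth}

        # shedding is a per-patient, per-compartment property, persistent
        # across timepoints
        sheds = {
            c: bool(rng.random() < cfg.detection_target[c])
            for c in ("CSF", "plasma", "tissue")
        }

        baseline_cfdna: dict[str, float] = {}
        csf_positive = False
        for compartment in ("CSF", "plasma", "tissue"):
            detected = _detect(
                rng, m, sheds[compartment], cfg.per_variant_detection[compartment]
            )
            sid = _sample_id(pid, compartment, "baseline")
            calls = _emit_calls(truth, detected, 1.0, compartment, pid, sid, rng, cfg)
            _maybe_cnv(calls, compartment, pid, sid, rng, cfg)
            if compartment == "tissue":
                cfdna = 0.0
            else:
                params = cfg.cfdna_lognormal[compartment]
                cfdna = round(float(rng.lognormal(params.mu, params.sigma)), 1)
            baseline_cfdna[compartment] = cfdna
            if compartment == "CSF":
                csf_positive = any(c.has_vaf for c in calls)
            profiles.append(
                SampleProfile(
                    sample_id=sid,
                    patient_id=pid,
                    compartment=Compartment(compartment),
                    timepoint=Timepoint.BASELINE,
                    cfdna_pg_per_ml=cfdna,
                    variants=tuple(calls),
                )
            )

        for compartment, responder in (("CSF", csf_responder), ("plasma", plasma_responder)):
            detected = _detect(
                rng, m, sheds[compartment], cfg.per_variant_detection[compartment]
            )
            mult = (
                cfg.responder_vaf_multiplier
                if responder
                else cfg.nonresponder_vaf_multiplier
            )
            sid = _sample_id(pid, compartment, "week8")
            calls = _emit_calls(truth, detected, mult, compartment, pid, sid, rng, cfg)
            calls.extend(_acquired_calls(compartment, used_genes, pid, sid, rng, cfg))
            jitter = (
                math.exp(rng.normal(0.0, cfg.week8_cfdna_sigma))
                if cfg.week8_cfdna_sigma > 0
                else 1.0
            )
            cfdna = round(baseline_cfdna[compartment] * jitter, 1)
            profiles.append(
                SampleProfile(
                    sample_id=sid,
                    patient_id=pid,
                    compartment=Compartment(compartment),
                    timepoint=Timepoint.WEEK8,
                    cfdna_pg_per_ml=cfdna,
                    variants=tuple(calls),
                )
            )

        groups = {
            "icPFS": "responder" if csf_responder else "nonresponder",
            "ecPFS": "responder" if plasma_responder else "nonresponder",
            "OS": "csf_positive" if csf_positive else "csf_negative",
        }
        ic_label = csf_responder ^ (rng.random() < cfg.radiographic_flip_prob)
        ec_label = plasma_responder ^ (rng.random() < cfg.radiographic_flip_prob)
        radiographic = {
            "icPFS": "PR" if ic_label else "SD",
            "ecPFS": "PR" if ec_label else "SD",
            "OS": "NA",
        }
        for endpoint, group in groups.items():
            rate = cfg.hazard_per_month[f"{endpoint}:{group}"]
            t_event = rng.exponential(1.0 / rate)
            t_censor = rng.exponential(1.0 / cfg.censoring_rate_per_month)
            time = max(round(min(t_event, t_censor), 2), 0.03)
            clinical_rows.append(
                {
                    "patient_id": pid,
                    "endpoint": endpoint,
                    "time_months": time,
                    "event": bool(t_event <= t_censor),
                    "radiographic_response": radiographic[endpoint],
                }
            )

        truth_patient_rows.append(
            {
                "patient_id": pid,
                "csf_responder": csf_responder,
                "plasma_responder": plasma_responder,
                "csf_positive_baseline": csf_positive,
                "ic_radiographic": radiographic["icPFS"],
                "ec_radiographic": radiographic["ecPFS"],
            }
        )

    clinical = pd.DataFrame(
        clinical_rows,
        columns=["patient_id", "endpoint", "time_months", "event", "radiographic_response"],
    )
    truth_patients = pd.DataFrame(
        truth_patient_rows,
        columns=[
            "patient_id",
            "csf_responder",
            "plasma_responder",
            "csf_positive_baseline",
            "ic_radiographic",
            "ec_radiographic",
        ],
    )
    truth_variants = pd.DataFrame(
        truth_variant_rows,
        columns=[
            "patient_id",
            "gene",
            "chrom",
            "pos",
            "ref",
            "alt",
            "variant_class",
            "true_vaf",
            "tier",
        ],
    )
    return Cohort(
        config=cfg,
        profiles=profiles,
        clinical=clinical,
        truth_patients=truth_patients,
        truth_variants=truth_variants,
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write manifest, per-sample VCFs, clinical table, truth tables and config."""
    outdir = Path(outdir)
    (outdir / "vcf").mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    for p in cohort.profiles:
        rel = f"vcf/{p.sample_id}.vcf"
        write_variant_file(list(p.variants), outdir / rel)
        manifest_rows.append(
            {
                "patient_id": p.patient_id,
                "sample_id": p.sample_id,
                "compartment": p.compartment.value,
                "timepoint": p.timepoint.value,
                "cfdna_pg_per_ml": p.cfdna_pg_per_ml,
                "vcf_path": rel,
            }
        )
    manifest = pd.DataFrame(
        manifest_rows,
        columns=[
            "patient_id",
            "sample_id",
            "compartment",
            "timepoint",
            "cfdna_pg_per_ml",
            "vcf_path",
        ],
    )
    write_manifest(manifest, outdir / "manifest.tsv")
    cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    cohort.truth_patients.to_csv(outdir / "truth_patients.tsv", sep="\t", index=False)
    cohort.truth_variants.to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
    with open(outdir / "config.json", "w") as fh:
        fh.write(cohort.config.model_dump_json(indent=2))
    return outdir


# ---------------------------------------------------------------------------
# Truth recovery
# ---------------------------------------------------------------------------


def _truth_tier_map(cohort: Cohort) -> dict[str, dict]:
    tiers: dict[str, dict] = {}
    for row in cohort.truth_variants.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.ref, row.alt, row.variant_class)
        tiers.setdefault(row.patient_id, {})[key] = row.tier
    return tiers


def truth_recovery_report(
    cohort: Cohort, filter_cfg: FilterConfig | None = None
) -> dict:
    """Run the analysis pipeline on a simulated cohort and score it against truth.

    Reports baseline clonality-label agreement, molecular responder-call
    agreement, the estimated intracranial-PFS hazard ratio (true responder
    groups) with its coverage of the configured true ratio, and the kappa
    between molecular CSF response and the simulated radiographic labels.
    """
    cfg = filter_cfg or FilterConfig()
    filtered = {
        (p.patient_id, p.compartment, p.timepoint): p.filtered(cfg)
        for p in cohort.profiles
    }
    tiers = _truth_tier_map(cohort)
    truth_pat = cohort.truth_patients.set_index("patient_id")

    clonality_match = clonality_total = 0
    response_match = response_total = 0
    csf_calls: list[ResponseCall] = []

    for pid in truth_pat.index:
        for compartment in (Compartment.CSF, Compartment.PLASMA):
            base = filtered.get((pid, compartment, Timepoint.BASELINE))
            week8 = filtered.get((pid, compartment, Timepoint.WEEK8))
            if base is not None and base.vaf_bearing:
                for a in assign_baseline_clonality(base):
                    true_tier = tiers.get(pid, {}).get(a.key)
                    if true_tier is None:
                        continue
                    clonality_total += 1
                    clonality_match += a.status.value == true_tier
            if base is None or week8 is None:
                continue
            call = call_response(base, week8)
            if not call.evaluable:
                continue
            truth_col = "csf_responder" if compartment is Compartment.CSF else "plasma_responder"
            response_total += 1
            response_match += call.responder == bool(truth_pat.loc[pid, truth_col])
            if compartment is Compartment.CSF:
                csf_calls.append(call)

    report: dict = {
        "clonality_agreement": clonality_match / clonality_total if clonality_total else float("nan"),
        "n_clonality_labels": clonality_total,
        "responder_agreement": response_match / response_total if response_total else float("nan"),
        "n_response_calls": response_total,
    }

    # HR recovery on intracranial PFS, grouped by the latent responder label
    groups = {
        pid: ("responder" if truth_pat.loc[pid, "csf_responder"] else "nonresponder")
        for pid in truth_pat.index
    }
    records = cohort.survival_records(Endpoint.INTRACRANIAL_PFS, groups)
    resp = [r for r in records if r.group == "responder"]
    nonresp = [r for r in records if r.group == "nonresponder"]
    true_hr = cohort.config.true_hr("icPFS", "responder", "nonresponder")
    if resp and nonresp and any(r.event for r in resp + nonresp):
        hr, ci = univariate_hr(resp, nonresp)
        report["icpfs_hr"] = {
            "estimate": hr,
            "ci95": list(ci),
            "true": true_hr,
            "covered": bool(ci[0] <= true_hr <= ci[1]),
        }
    else:
        report["icpfs_hr"] = {"estimate": None, "ci95": None, "true": true_hr, "covered": None}

    if csf_calls:
        labels = truth_pat["ic_radiographic"].to_dict()
        table = response_vs_radiology(csf_calls, labels)
        report["csf_response_vs_radiology"] = {
            "concordance_pct": 100.0 * table.observed_agreement_po,
            "kappa": concordance.cohens_kappa(table),
            "n": table.n,
        }
    return report
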