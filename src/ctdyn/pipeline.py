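"""End-to-end orchestration: simulate or load a cohort, then run every stage.

The pipeline runs: input acquisition -> filtering (with a per-rule audit of
discarded calls) -> per-sample ctDNA metrics -> detection rates ->
cross-compartment concordance -> clonal evolution -> molecular response ->
survival contrasts, and emits a self-contained machine-readable report. All
randomness lives in the synthetic-cohort generator; every analysis stage is
deterministic, and the report carries the config snapshot and seed needed to
reproduce it byte-for-byte (no timestamps are embedded).
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .clonality import cohort_clonal_fractions, map_evolution
from .concordance import cohens_kappa, gene_level_2x2, paired_consistency, venn_partition
from .simulate import Cohort, CohortConfig, simulate_cohort, write_cohort
from .survival import (
    DEFAULT_RECIST_MAP,
    Endpoint,
    ResponseCall,
    SurvivalRecord,
    call_response,
    km_fit,
    logrank_test,
    response_vs_radiology,
    univariate_hr,
)
from .variants import (
    Compartment,
    FilterConfig,
    SampleProfile,
    Timepoint,
    VariantCall,
    load_profiles,
)

__all__ = ["PipelineConfig", "run_pipeline", "filter_audit"]


class PipelineConfig(BaseModel):
    """Configuration of a full run.

    Either ``manifest``/``clinical`` point at existing inputs, or ``simulate``
    describes a synthetic cohort to generate (the default).
    """

    simulate: CohortConfig | None = Field(default_factory=CohortConfig)
    manifest: str | None = None
    clinical: str | None = None
    filters: FilterConfig = Field(default_factory=FilterConfig)
    kappa_genes: list[str] = Field(default_factory=lambda: ["EGFR", "TP53", "KRAS"])

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


def filter_audit(calls: Sequence[VariantCall], cfg: FilterConfig) -> dict[str, int]:
    """Count calls discarded by each filtering rule (first failing rule wins)."""
    audit = Counter(
        {"input": len(calls), "blacklist": 0, "low_vaf": 0, "low_alt_reads": 0, "high_pop_freq": 0}
    )
    kept = 0
    for call in calls:
        if call.key in cfg.blacklist:
            audit["blacklist"] += 1
        elif call.has_vaf and call.vaf < cfg.min_vaf:
            audit["low_vaf"] += 1
        elif call.has_vaf and call.alt_reads < cfg.min_alt_reads:
            audit["low_alt_reads"] += 1
        elif call.has_vaf and call.pop_freq is not None and call.pop_freq > cfg.max_pop_freq:
            audit["high_pop_freq"] += 1
        else:
            kept += 1
    audit["passed"] = kept
    return dict(audit)


def _index(profiles: Sequence[SampleProfile]):
    return {(p.patient_id, p.compartment, p.timepoint): p for p in profiles}


def _survival_records(
    clinical: pd.DataFrame, endpoint: Endpoint, groups: Mapping[str, str]
) -> dict[str, list[SurvivalRecord]]:
    sub = clinical[clinical["endpoint"] == endpoint.value]
    out: dict[str, list[SurvivalRecord]] = {}
    for row in sub.itertuples(index=False):
        group = groups.get(row.patient_id)
        if group is None:
            continue
        out.setdefault(group, []).append(
            SurvivalRecord(
                patient_id=row.patient_id,
                endpoint=endpoint,
                time_months=float(row.time_months),
                event=bool(row.event),
                group=group,
            )
        )
    return out


def _survival_contrast(
    clinical: pd.DataFrame, endpoint: Endpoint, groups: Mapping[str, str], a: str, b: str
) -> dict:
    by_group = _survival_records(clinical, endpoint, groups)
    rec_a, rec_b = by_group.get(a, []), by_group.get(b, [])
    result: dict = {
        "endpoint": endpoint.value,
        "group_a": a,
        "group_b": b,
        "n_a": len(rec_a),
        "n_b": len(rec_b),
    }
    if not rec_a or not rec_b:
        result["error"] = "a group is empty; contrast not estimable"
        return result
    result["median_a"] = km_fit(rec_a).median
    result["median_b"] = km_fit(rec_b).median
    stat, p = logrank_test(rec_a, rec_b)
    result["logrank_statistic"] = stat
    result["logrank_p"] = p
    if any(r.event for r in rec_a + rec_b):
        hr, ci = univariate_hr(rec_a, rec_b)
        result["hr"] = hr
        result["hr_ci95"] = list(ci)
    return result


def run_pipeline(
    config: PipelineConfig | str | Path, out_dir: str | Path, seed: int | None = None
) -> dict:
    """Execute every stage and write ``report.json`` plus per-stage TSVs.

    ``seed`` overrides the seed of a simulated cohort. Returns the report.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_json(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- stage: inputs -----------------------------------------------------
    if config.manifest is not None:
        if config.clinical is None or not Path(config.clinical).exists():
            raise FileNotFoundError(
                "survival stage requires a clinical table: "
                f"clinical path {config.clinical!r} not found"
            )
        raw_profiles = load_profiles(config.manifest)
        clinical = pd.read_csv(config.clinical, sep="\t")
        sim_cfg = None
    else:
        sim_cfg = config.simulate or CohortConfig()
        if seed is not None:
            sim_cfg = sim_cfg.model_copy(update={"seed": seed})
        cohort = simulate_cohort(sim_cfg)
        write_cohort(cohort, out_dir / "cohort")
        raw_profiles = cohort.profiles
        clinical = cohort.clinical

    # --- stage: filtering --------------------------------------------------
    all_calls = [c for p in raw_profiles for c in p.variants]
    audit = filter_audit(all_calls, config.filters)
    profiles = [p.filtered(config.filters) for p in raw_profiles]
    idx = _index(profiles)

    # --- stage: per-sample metrics ----------------------------------------
    metrics = pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in profiles],
            "patient_id": [p.patient_id for p in profiles],
            "compartment": [p.compartment.value for p in profiles],
            "timepoint": [p.timepoint.value for p in profiles],
            "n_variants": [len(p.variants) for p in profiles],
            "max_vaf": [p.max_vaf for p in profiles],
            "mean_vaf": [p.mean_vaf for p in profiles],
            "cfdna_pg_per_ml": [p.cfdna_pg_per_ml for p in profiles],
            "ctdna_hge_per_ml": [p.ctdna_hge_per_ml for p in profiles],
            "is_positive": [p.is_positive for p in profiles],
        }
    )
    metrics.to_csv(out_dir / "sample_metrics.tsv", sep="\t", index=False)

    detection = (
        metrics.groupby(["compartment", "timepoint"])["is_positive"].mean()
        if len(metrics)
        else pd.Series(dtype=float)
    )
    detection_rates = {f"{c}:{t}": float(v) for (c, t), v in detection.items()}

    # --- stage: concordance -------------------------------------------------
    baseline_pairs = []
    for (pid, comp, tp), prof in idx.items():
        if comp is Compartment.CSF and tp is Timepoint.BASELINE:
            plasma = idx.get((pid, Compartment.PLASMA, Timepoint.BASELINE))
            if plasma is not None and prof.is_positive and plasma.is_positive:
                baseline_pairs.append((prof, plasma))

    concordance_report: dict = {"n_double_positive_pairs": len(baseline_pairs)}
    if baseline_pairs:
        plasma_to_csf = paired_consistency([(b, a) for a, b in baseline_pairs])
        csf_to_plasma = paired_consistency(baseline_pairs)
        plasma_to_csf.to_csv(out_dir / "consistency_plasma_to_csf.tsv", sep="\t", index=False)
        csf_to_plasma.to_csv(out_dir / "consistency_csf_to_plasma.tsv", sep="\t", index=False)
        concordance_report["mean_consistency_plasma_to_csf_pct"] = (
            float(plasma_to_csf["consistency_pct"].mean()) if len(plasma_to_csf) else None
        )
        concordance_report["mean_consistency_csf_to_plasma_pct"] = (
            float(csf_to_plasma["consistency_pct"].mean()) if len(csf_to_plasma) else None
        )
        gene_tables = {}
        for gene in config.kappa_genes:
            table = gene_level_2x2(baseline_pairs, gene)
            gene_tables[gene] = {
                "both_pos": table.both_pos,
                "csf_only": table.a_only,
                "plasma_only": table.b_only,
                "both_neg": table.both_neg,
                "concordance_pct": 100.0 * table.observed_agreement_po,
                "kappa": cohens_kappa(table),
            }
        concordance_report["gene_kappa"] = gene_tables

    triple = {
        pid: (csf, plasma, tissue)
        for pid in {p.patient_id for p in profiles}
        if (csf := idx.get((pid, Compartment.CSF, Timepoint.BASELINE))) is not None
        and (plasma := idx.get((pid, Compartment.PLASMA, Timepoint.BASELINE))) is not None
        and (tissue := idx.get((pid, Compartment.TISSUE, Timepoint.BASELINE))) is not None
    }
    if triple:
        # pool alterations across patients, keeping per-patient identity
        pooled = {
            label: {
                (pid, key)
                for pid, profs in triple.items()
                for key in profs[i].keys()
            }
            for i, label in enumerate(("CSF", "plasma", "tissue"))
        }
        part = venn_partition(pooled)
        concordance_report["venn_baseline"] = {
            "labels": list(part.labels),
            "only_csf": part.only_a,
            "only_plasma": part.only_b,
            "only_tissue": part.only_c,
            "csf_plasma_only": part.ab_only,
            "csf_tissue_only": part.ac_only,
            "plasma_tissue_only": part.bc_only,
            "all_three": part.abc,
        }

    # --- stage: clonal evolution -------------------------------------------
    evolution_rows = []
    summaries_by_comp: dict[str, list] = {"CSF": [], "plasma": []}
    for (pid, comp, tp), base in idx.items():
        if tp is not Timepoint.BASELINE or comp is Compartment.TISSUE:
            continue
        week8 = idx.get((pid, comp, Timepoint.WEEK8))
        if week8 is None or not base.vaf_bearing:
            continue
        summary = map_evolution(base, week8)
        summaries_by_comp[comp.value].append(summary)
        evolution_rows.append(
            {
                "patient_id": summary.patient_id,
                "compartment": summary.compartment,
                "n_baseline_clonal": summary.n_baseline_clonal,
                "n_baseline_subclonal": summary.n_baseline_subclonal,
                "n_retained_clonal": summary.n_retained_clonal,
                "n_cleared_clonal": summary.n_cleared_clonal,
                "n_retained_subclonal": summary.n_retained_subclonal,
                "n_cleared_subclonal": summary.n_cleared_subclonal,
                "n_acquired": summary.n_acquired,
                "post_clonal_fraction": summary.post_clonal_fraction,
                "complete_clearance": summary.complete_clearance,
                "high_retention": summary.high_retention,
            }
        )
    evolution = pd.DataFrame(evolution_rows)
    evolution.to_csv(out_dir / "evolution.tsv", sep="\t", index=False)
    evolution_report = {
        comp: cohort_clonal_fractions(summaries)
        for comp, summaries in summaries_by_comp.items()
        if summaries
    }
    for comp, summaries in summaries_by_comp.items():
        if summaries:
            evolution_report[comp]["n_high_retention"] = float(
                sum(s.high_retention for s in summaries)
            )

    # --- stage: molecular response ------------------------------------------
    response_rows = []
    calls_by_comp: dict[str, list[ResponseCall]] = {"CSF": [], "plasma": []}
    missing_week8 = {"CSF": 0, "plasma": 0}
    for (pid, comp, tp), base in idx.items():
        if tp is not Timepoint.BASELINE or comp is Compartment.TISSUE:
            continue
        week8 = idx.get((pid, comp, Timepoint.WEEK8))
        if week8 is None:
            # positive-baseline patients lacking a follow-up sample are
            # excluded from response analyses; their count is reported
            if base.ctdna_hge_per_ml > 0:
                missing_week8[comp.value] += 1
            continue
        call = call_response(base, week8)
        calls_by_comp[comp.value].append(call)
        response_rows.append(
            {
                "patient_id": call.patient_id,
                "compartment": call.compartment,
                "baseline_hge_per_ml": call.baseline_conc,
                "followup_hge_per_ml": call.followup_conc,
                "pct_change": call.pct_change,
                "evaluable": call.evaluable,
                "responder": call.responder,
            }
        )
    pd.DataFrame(response_rows).to_csv(out_dir / "responses.tsv", sep="\t", index=False)

    radiographic = {
        "CSF": _radiographic_labels(clinical, "icPFS"),
        "plasma": _radiographic_labels(clinical, "ecPFS"),
    }
    response_report: dict = {"excluded_missing_week8": missing_week8}
    groups_by_comp: dict[str, dict[str, str]] = {}
    for comp, calls in calls_by_comp.items():
        evaluable = [c for c in calls if c.evaluable]
        entry = {
            "n_pairs": len(calls),
            "n_evaluable": len(evaluable),
            "n_responders": sum(c.responder for c in evaluable),
        }
        labels = radiographic[comp]
        if evaluable and labels:
            known = [c for c in evaluable if c.patient_id in labels]
            if known:
                table = response_vs_radiology(known, labels)
                entry["vs_radiology"] = {
                    "concordance_pct": 100.0 * table.observed_agreement_po,
                    "kappa": cohens_kappa(table),
                    "n": table.n,
                }
        response_report[comp] = entry
        groups_by_comp[comp] = {
            c.patient_id: ("responder" if c.responder else "nonresponder")
            for c in evaluable
        }

    # --- stage: survival ------------------------------------------------------
    survival_report = {}
    if len(clinical):
        if groups_by_comp.get("CSF"):
            survival_report["icPFS_by_csf_response"] = _survival_contrast(
                clinical, Endpoint.INTRACRANIAL_PFS, groups_by_comp["CSF"], "responder", "nonresponder"
            )
        if groups_by_comp.get("plasma"):
            survival_report["ecPFS_by_plasma_response"] = _survival_contrast(
                clinical, Endpoint.EXTRACRANIAL_PFS, groups_by_comp["plasma"], "responder", "nonresponder"
            )
        positivity_groups = {
            p.patient_id: ("csf_positive" if p.is_positive else "csf_negative")
            for p in profiles
            if p.compartment is Compartment.CSF and p.timepoint is Timepoint.BASELINE
        }
        if positivity_groups:
            survival_report["OS_by_baseline_csf_positivity"] = _survival_contrast(
                clinical, Endpoint.OS, positivity_groups, "csf_positive", "csf_negative"
            )

    report = {
        "version": __version__,
        "seed": (sim_cfg.seed if sim_cfg is not None else None),
        "config": json.loads(config.model_dump_json()),
        "stages": {
            "inputs": {"n_samples": len(raw_profiles), "n_calls": len(all_calls)},
            "filtering": audit,
            "detection_rates": detection_rates,
            "concordance": concordance_report,
            "evolution": evolution_report,
            "response": response_report,
            "survival": survival_report,
        },
    }
    # blacklist keys are tuples; make the snapshot JSON-stable
    report["config"]["filters"]["blacklist"] = sorted(
        list(k) for k in config.filters.blacklist
    )
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _radiographic_labels(clinical: pd.DataFrame, endpoint: str) -> dict[str, str]:
    sub = clinical[clinical["endpoint"] == endpoint]
    labels = {}
    for row in sub.itertuples(index=False):
        label = str(row.radiographic_response)
        if label in DEFAULT_RECIST_MAP:
            labels[row.patient_id] = label
    return labels
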