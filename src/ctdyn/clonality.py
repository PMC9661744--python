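"""Clonality assignment and longitudinal clonal-evolution bookkeeping.

At baseline, a mutation is *clonal* when its VAF is at least 25% of the
sample's maxVAF and *subclonal* otherwise — a relative-threshold definition
(a proxy for membership in the dominant clone), not a phylogenetic one. The
tie at exactly 25% is labeled clonal by default; ``strict=True`` labels it
subclonal (the maxVAF variant itself is clonal either way). CNV calls carry
no VAF and are excluded from clonality labeling.

Across timepoints, variants are matched by exact identity key. Every
baseline variant is either *retained* or *cleared* at follow-up; every
follow-up-only variant is *acquired* and is always subclonal, regardless of
its VAF. A patient shows *high clonal retention* when clonal mutations make
up more than 80% of the follow-up sample's mutations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .variants import SampleProfile, Timepoint, VariantKey

__all__ = [
    "CLONAL_VAF_FRACTION",
    "HIGH_RETENTION_THRESHOLD",
    "ClonalStatus",
    "ClonalityAssignment",
    "EvolutionSummary",
    "assign_baseline_clonality",
    "map_evolution",
    "classify_retention",
    "cohort_clonal_fractions",
]

#: Clonal means VAF >= this fraction of the baseline maxVAF.
CLONAL_VAF_FRACTION = 0.25

#: High retention means post-treatment clonal fraction strictly above this.
HIGH_RETENTION_THRESHOLD = 0.80


class ClonalStatus(str, enum.Enum):
    CLONAL = "clonal"
    SUBCLONAL = "subclonal"
    ACQUIRED = "acquired"


@dataclass(frozen=True)
class ClonalityAssignment:
    key: VariantKey
    gene: str
    baseline_vaf: float | None
    status: ClonalStatus
    timepoint_observed: Timepoint


def assign_baseline_clonality(
    profile: SampleProfile, strict: bool = False
) -> list[ClonalityAssignment]:
    """Label each read-backed baseline variant clonal or subclonal.

    The threshold is ``0.25 * maxVAF`` of this profile, so labels are
    invariant to a common rescaling of all VAFs. Raises ``ValueError`` when
    the profile carries no read-backed variant.
    """
    bearing = profile.vaf_bearing
    if not bearing:
        raise ValueError(
            f"clonality undefined: sample {profile.sample_id} has no VAF-bearing variant"
        )
    threshold = CLONAL_VAF_FRACTION * max(v.vaf for v in bearing)
    out = []
    for v in bearing:
        if strict:
            clonal = v.vaf > threshold or v.vaf == max(x.vaf for x in bearing)
        else:
            clonal = v.vaf >= threshold
        out.append(
            ClonalityAssignment(
                key=v.key,
                gene=v.gene,
                baseline_vaf=v.vaf,
                status=ClonalStatus.CLONAL if clonal else ClonalStatus.SUBCLONAL,
                timepoint_observed=profile.timepoint,
            )
        )
    return out


@dataclass(frozen=True)
class EvolutionSummary:
    """Per-patient, per-compartment clonal composition across two timepoints."""

    patient_id: str
    compartment: str
    n_baseline_clonal: int
    n_baseline_subclonal: int
    n_retained_clonal: int
    n_cleared_clonal: int
    n_retained_subclonal: int
    n_cleared_subclonal: int
    n_acquired: int
    complete_clearance: bool

    @property
    def n_followup(self) -> int:
        return self.n_retained_clonal + self.n_retained_subclonal + self.n_acquired

    @property
    def post_clonal_fraction(self) -> float:
        """Clonal share of follow-up mutations; 0 under complete clearance."""
        if self.n_followup == 0:
            return 0.0
        return self.n_retained_clonal / self.n_followup

    @property
    def high_retention(self) -> bool:
        return classify_retention(self)


def map_evolution(
    baseline: SampleProfile, followup: SampleProfile, strict: bool = False
) -> EvolutionSummary:
    """Track each baseline variant's fate and count acquisitions at follow-up.

    Profiles must share patient and compartment. Matching uses the exact
    identity key; clonality of retained variants is their baseline label.
    Complete clearance (empty follow-up) is flagged, not an error, so cohort
    summaries stay computable.
    """
    if baseline.patient_id != followup.patient_id:
        raise ValueError("baseline and follow-up profiles must share a patient")
    if baseline.compartment != followup.compartment:
        raise ValueError("baseline and follow-up profiles must share a compartment")
    assignments = assign_baseline_clonality(baseline, strict=strict)
    followup_keys = {v.key for v in followup.vaf_bearing}
    baseline_keys = {a.key for a in assignments}

    retained_clonal = cleared_clonal = retained_sub = cleared_sub = 0
    for a in assignments:
        retained = a.key in followup_keys
        if a.status is ClonalStatus.CLONAL:
            retained_clonal += retained
            cleared_clonal += not retained
        else:
            retained_sub += retained
            cleared_sub += not retained
    n_acquired = len(followup_keys - baseline_keys)

    return EvolutionSummary(
        patient_id=baseline.patient_id,
        compartment=baseline.compartment.value,
        n_baseline_clonal=retained_clonal + cleared_clonal,
        n_baseline_subclonal=retained_sub + cleared_sub,
        n_retained_clonal=retained_clonal,
        n_cleared_clonal=cleared_clonal,
        n_retained_subclonal=retained_sub,
        n_cleared_subclonal=cleared_sub,
        n_acquired=n_acquired,
        complete_clearance=len(followup_keys) == 0,
    )


def classify_retention(summary: EvolutionSummary) -> bool:
    """True when clonal mutations exceed 80% of follow-up mutations (strict)."""
    return summary.post_clonal_fraction > HIGH_RETENTION_THRESHOLD


def cohort_clonal_fractions(summaries: list[EvolutionSummary]) -> dict[str, float]:
    """Post-treatment clonal fraction, both pooled and per-patient averaged.

    Pooling counts every follow-up mutation across patients once; the
    per-patient mean weights each patient equally (clearance patients are
    excluded from the mean, since their fraction is undefined). Both views
    are reported because cohort-level composition plots can be read either way.
    """
    total_clonal = sum(s.n_retained_clonal for s in summaries)
    total = sum(s.n_followup for s in summaries)
    per_patient = [s.post_clonal_fraction for s in summaries if s.n_followup > 0]
    return {
        "pooled": total_clonal / total if total else 0.0,
        "per_patient_mean": sum(per_patient) / len(per_patient) if per_patient else 0.0,
        "n_patients": float(len(summaries)),
        "n_with_followup_mutations": float(len(per_patient)),
    }
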