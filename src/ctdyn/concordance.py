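"""Cross-compartment agreement statistics.

Two granularities are deliberately separate and must be selected explicitly:

* **variant-level** identity keys (chrom, pos, ref, alt, class) feed the
  directional consistency measure and the three-way Venn partition;
* **gene-level** presence/absence feeds the per-gene 2x2 contingency tables
  and Cohen's kappa (the EGFR/TP53-style analyses).

Consistency of sample A to sample B is ``100 * |A ∩ B| / |A|`` — asymmetric
by construction, defined only for mutant-positive A. Cohen's kappa is the
chance-corrected agreement ``(po - pe) / (1 - pe)`` with ``po`` the observed
and ``pe`` the marginal-independence expected agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variants import SampleProfile, VariantKey

__all__ = [
    "ConcordanceResult",
    "ContingencyTable",
    "VennPartition",
    "consistency",
    "cohens_kappa",
    "table_from_marginals",
    "gene_level_2x2",
    "venn_partition",
    "paired_consistency",
]


@dataclass(frozen=True)
class ConcordanceResult:
    set_a_label: str
    set_b_label: str
    n_a: int
    n_b: int
    n_shared: int
    consistency_a_to_b: float  # percent in [0, 100]


def consistency(
    a: set[VariantKey] | frozenset,
    b: set[VariantKey] | frozenset,
    label_a: str = "A",
    label_b: str = "B",
) -> ConcordanceResult:
    """Directional consistency of set ``a`` to set ``b`` in percent.

    Raises ``ValueError`` for empty ``a``: the measure is defined only for
    mutant-positive samples.
    """
    if not a:
        raise ValueError(
            f"consistency of {label_a} to {label_b} undefined: {label_a} has no alterations"
        )
    shared = len(set(a) & set(b))
    return ConcordanceResult(
        set_a_label=label_a,
        set_b_label=label_b,
        n_a=len(a),
        n_b=len(b),
        n_shared=shared,
        consistency_a_to_b=100.0 * shared / len(a),
    )


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 agreement counts for paired binary calls (A rows, B columns)."""

    both_pos: int
    a_only: int
    b_only: int
    both_neg: int

    def __post_init__(self) -> None:
        if min(self.both_pos, self.a_only, self.b_only, self.both_neg) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.both_pos + self.a_only + self.b_only + self.both_neg

    @property
    def observed_agreement_po(self) -> float:
        if self.n == 0:
            raise ValueError("empty contingency table")
        return (self.both_pos + self.both_neg) / self.n

    @property
    def expected_agreement_pe(self) -> float:
        if self.n == 0:
            raise ValueError("empty contingency table")
        a_pos = self.both_pos + self.a_only
        b_pos = self.both_pos + self.b_only
        a_neg = self.n - a_pos
        b_neg = self.n - b_pos
        return (a_pos * b_pos + a_neg * b_neg) / (self.n * self.n)

    @property
    def kappa(self) -> float:
        return cohens_kappa(self)

    def swapped(self) -> "ContingencyTable":
        """Relabel A<->B (transpose); kappa is invariant under this."""
        return ContingencyTable(self.both_pos, self.b_only, self.a_only, self.both_neg)


def cohens_kappa(table: ContingencyTable) -> float:
    """Cohen's kappa for a 2x2 table; 1.0 at the degenerate po = pe = 1 limit."""
    if table.n == 0:
        raise ValueError("kappa undefined for an empty table")
    po = table.observed_agreement_po
    pe = table.expected_agreement_pe
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def table_from_marginals(
    n: int, a_pos: int, b_pos: int, concordance_pct: float
) -> ContingencyTable:
    """Reconstruct a 2x2 table from its marginals and overall percent agreement.

    With ``agreements = round(n * concordance_pct / 100)`` the cell counts are
    fixed: ``both_pos + both_neg = agreements`` and
    ``both_pos - both_neg = a_pos + b_pos - n``.
    """
    agreements = round(n * concordance_pct / 100.0)
    diff = a_pos + b_pos - n
    if (agreements + diff) % 2 != 0:
        raise ValueError(
            f"inconsistent marginals: {agreements} agreements with margins "
            f"{a_pos}/{n} and {b_pos}/{n} do not yield integer cells"
        )
    both_pos = (agreements + diff) // 2
    both_neg = agreements - both_pos
    return ContingencyTable(
        both_pos=both_pos,
        a_only=a_pos - both_pos,
        b_only=b_pos - both_pos,
        both_neg=both_neg,
    )


def gene_level_2x2(
    pairs: Sequence[tuple[SampleProfile, SampleProfile]], gene: str
) -> ContingencyTable:
    """Per-gene presence/absence agreement across paired profiles.

    Each pair is classified by whether any passing alteration in ``gene``
    (any class) is present in each member. Pairs must share a patient.
    """
    if not pairs:
        raise ValueError("gene_level_2x2 requires at least one profile pair")
    counts = {"both_pos": 0, "a_only": 0, "b_only": 0, "both_neg": 0}
    for prof_a, prof_b in pairs:
        if prof_a.patient_id != prof_b.patient_id:
            raise ValueError(
                f"paired profiles must share a patient: "
                f"{prof_a.patient_id} vs {prof_b.patient_id}"
            )
        in_a = any(v.gene == gene for v in prof_a.variants)
        in_b = any(v.gene == gene for v in prof_b.variants)
        if in_a and in_b:
            counts["both_pos"] += 1
        elif in_a:
            counts["a_only"] += 1
        elif in_b:
            counts["b_only"] += 1
        else:
            counts["both_neg"] += 1
    return ContingencyTable(**counts)


@dataclass(frozen=True)
class VennPartition:
    """Exact 7-region partition of three labeled key sets."""

    labels: tuple[str, str, str]
    only_a: int
    only_b: int
    only_c: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int

    @property
    def set_totals(self) -> dict[str, int]:
        a, b, c = self.labels
        return {
            a: self.only_a + self.ab_only + self.ac_only + self.abc,
            b: self.only_b + self.ab_only + self.bc_only + self.abc,
            c: self.only_c + self.ac_only + self.bc_only + self.abc,
        }

    @property
    def union_size(self) -> int:
        return (
            self.only_a + self.only_b + self.only_c
            + self.ab_only + self.ac_only + self.bc_only + self.abc
        )


def venn_partition(
    sets: Mapping[str, set] | Sequence[tuple[str, set]],
) -> VennPartition:
    """Partition three labeled sets into their 7 exclusive Venn regions."""
    items = list(sets.items()) if isinstance(sets, Mapping) else list(sets)
    if len(items) != 3:
        raise ValueError("venn_partition requires exactly three labeled sets")
    (la, sa), (lb, sb), (lc, sc) = [(lab, set(s)) for lab, s in items]
    abc = sa & sb & sc
    return VennPartition(
        labels=(la, lb, lc),
        only_a=len(sa - sb - sc),
        only_b=len(sb - sa - sc),
        only_c=len(sc - sa - sb),
        ab_only=len((sa & sb) - abc),
        ac_only=len((sa & sc) - abc),
        bc_only=len((sb & sc) - abc),
        abc=len(abc),
    )


def paired_consistency(
    pairs: Sequence[tuple[SampleProfile, SampleProfile]],
    exclude_cnv: bool = False,
) -> pd.DataFrame:
    """Per-patient directional consistency of profile A to profile B.

    Patients whose A-profile has no passing alterations are skipped (the
    measure is computed for mutant-positive samples only); cohort summaries
    are unweighted means over the remaining patients.
    """
    rows = []
    for prof_a, prof_b in pairs:
        if prof_a.patient_id != prof_b.patient_id:
            raise ValueError("paired profiles must share a patient")
        keys_a = prof_a.keys(exclude_cnv=exclude_cnv)
        if not keys_a:
            continue
        keys_b = prof_b.keys(exclude_cnv=exclude_cnv)
        res = consistency(keys_a, keys_b, prof_a.compartment.value, prof_b.compartment.value)
        rows.append(
            {
                "patient_id": prof_a.patient_id,
                "n_a": res.n_a,
                "n_b": res.n_b,
                "n_shared": res.n_shared,
                "consistency_pct": res.consistency_a_to_b,
            }
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "n_a", "n_b", "n_shared", "consistency_pct"]
    )
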