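"""Variant-call data model, VCF/manifest I/O, filtering, and per-sample ctDNA metrics.

A sample here is one (patient, compartment, timepoint) liquid- or tissue-biopsy
profile: a set of somatic calls plus the total cell-free DNA concentration of
the fluid. The tumor-derived DNA level of a sample is summarized two ways:

* ``maxVAF`` — the largest variant allele fraction among detected mutations,
  a proxy for the dominant clone's fraction of the cfDNA pool;
* ctDNA concentration in haploid genome equivalents per mL,
  ``mean VAF x cfDNA (pg/mL) / 3.3``, taking one haploid genome as 3.3 pg.

Copy-number calls carry no per-read allele fraction in this data model, so
they are excluded from both summaries and bypass the read-level filters.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from pydantic import BaseModel, Field, field_validator

__all__ = [
    "HGE_PG",
    "VariantClass",
    "Compartment",
    "Timepoint",
    "VariantCall",
    "VariantKey",
    "FilterConfig",
    "SampleProfile",
    "VariantFileError",
    "read_variant_file",
    "write_variant_file",
    "apply_filters",
    "max_vaf",
    "mean_vaf",
    "ctdna_concentration",
    "read_manifest",
    "write_manifest",
    "load_profiles",
]

#: Mass of one haploid genome equivalent, in picograms.
HGE_PG = 3.3

#: Decimal places kept when parsing float INFO fields. VCF stores INFO floats
#: in 32-bit precision; rounding to 6 places removes the float32 noise while
#: comfortably exceeding the precision of a VAF measured at ~2000x depth.
_FLOAT_DECIMALS = 6


class VariantClass(str, enum.Enum):
    """Class of somatic alteration."""

    SNV = "SNV"
    INDEL = "indel"
    FUSION = "fusion"
    CNV_GAIN = "CNV_gain"
    CNV_LOSS = "CNV_loss"

    @property
    def is_cnv(self) -> bool:
        return self in (VariantClass.CNV_GAIN, VariantClass.CNV_LOSS)


class Compartment(str, enum.Enum):
    CSF = "CSF"
    PLASMA = "plasma"
    TISSUE = "tissue"


class Timepoint(str, enum.Enum):
    BASELINE = "baseline"
    WEEK8 = "week8"
    PROGRESSION = "progression"


#: Identity of a variant across samples: (chrom, pos, ref, alt, class value).
#: The gene symbol is annotation, not identity.
VariantKey = tuple[str, int, str, str, str]


class VariantFileError(ValueError):
    """Raised for malformed variant files or records missing required annotations."""


@dataclass(frozen=True)
class VariantCall:
    """One somatic alteration observed in one sample.

    ``vaf`` and ``alt_reads`` are required for read-backed classes
    (SNV/indel/fusion) and must be absent for CNV classes.
    """

    patient_id: str
    sample_id: str
    gene: str
    chrom: str
    pos: int  # 1-based, per VCF convention
    ref: str
    alt: str
    variant_class: VariantClass
    vaf: float | None = None
    alt_reads: int | None = None
    pop_freq: float | None = None
    is_driver: bool = False
    is_oncogenic: bool = False

    def __post_init__(self) -> None:
        if self.variant_class.is_cnv:
            if self.vaf is not None or self.alt_reads is not None:
                raise ValueError(
                    f"CNV call {self.chrom}:{self.pos} must not carry vaf/alt_reads"
                )
        else:
            if self.vaf is None:
                raise ValueError(
                    f"{self.variant_class.value} call {self.chrom}:{self.pos} requires a VAF"
                )
            if not 0.0 <= self.vaf <= 1.0:
                raise ValueError(f"vaf {self.vaf} outside [0, 1] at {self.chrom}:{self.pos}")
            if self.alt_reads is None or self.alt_reads < 0:
                raise ValueError(
                    f"alt_reads must be a non-negative integer at {self.chrom}:{self.pos}"
                )
        if self.pop_freq is not None and not 0.0 <= self.pop_freq <= 1.0:
            raise ValueError(f"pop_freq {self.pop_freq} outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"positions are 1-based; got {self.pos}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt, self.variant_class.value)

    @property
    def has_vaf(self) -> bool:
        return not self.variant_class.is_cnv


class FilterConfig(BaseModel):
    """Somatic-call retention rules.

    Thresholds are inclusive on the passing side: a call survives with
    ``vaf >= min_vaf``, ``alt_reads >= min_alt_reads`` and (when a population
    frequency is annotated) ``pop_freq <= max_pop_freq``. The blacklist holds
    identity keys of recurrent artifacts and applies to every class; the
    read-level rules apply only to VAF-bearing calls.
    """

    min_vaf: float = 0.002
    min_alt_reads: int = 3
    max_pop_freq: float = 0.01
    blacklist: set[VariantKey] = Field(default_factory=set)

    @field_validator("min_vaf")
    @classmethod
    def _vaf_range(cls, v: float) -> float:
        if not 0.0 <= v < 1.0:
            raise ValueError("min_vaf must be in [0, 1)")
        return v

    @field_validator("min_alt_reads")
    @classmethod
    def _reads_nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("min_alt_reads must be non-negative")
        return v

    @field_validator("max_pop_freq")
    @classmethod
    def _popfreq_range(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("max_pop_freq must be in [0, 1]")
        return v

    @field_validator("blacklist", mode="before")
    @classmethod
    def _coerce_keys(cls, v):
        if v is None:
            return set()
        return {tuple(k) if not isinstance(k, tuple) else k for k in v}

    @classmethod
    def from_json(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        payload = self.model_dump()
        payload["blacklist"] = sorted(list(k) for k in self.blacklist)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def apply_filters(
    calls: Iterable[VariantCall], cfg: FilterConfig | None = None
) -> list[VariantCall]:
    """Retain calls passing the read-level and population-frequency rules.

    CNV calls bypass the vaf/alt_reads/pop_freq criteria (they carry no read
    support in this model) but are still removed when blacklisted. Input
    order is preserved; filtering is idempotent.
    """
    cfg = cfg or FilterConfig()
    kept: list[VariantCall] = []
    for call in calls:
        if call.key in cfg.blacklist:
            continue
        if call.variant_class.is_cnv:
            kept.append(call)
            continue
        if call.vaf < cfg.min_vaf:
            continue
        if call.alt_reads < cfg.min_alt_reads:
            continue
        if call.pop_freq is not None and call.pop_freq > cfg.max_pop_freq:
            continue
        kept.append(call)
    return kept


@dataclass(frozen=True)
class SampleProfile:
    """All calls for one (patient, compartment, timepoint) plus cfDNA level."""

    sample_id: str
    patient_id: str
    compartment: Compartment
    timepoint: Timepoint
    cfdna_pg_per_ml: float
    variants: tuple[VariantCall, ...] = ()

    def __post_init__(self) -> None:
        if self.cfdna_pg_per_ml < 0:
            raise ValueError(
                f"cfDNA concentration must be non-negative (sample {self.sample_id})"
            )
        object.__setattr__(self, "variants", tuple(self.variants))

    def filtered(self, cfg: FilterConfig | None = None) -> "SampleProfile":
        return dataclasses.replace(self, variants=tuple(apply_filters(self.variants, cfg)))

    @property
    def vaf_bearing(self) -> tuple[VariantCall, ...]:
        return tuple(v for v in self.variants if v.has_vaf)

    @property
    def max_vaf(self) -> float:
        return max_vaf(self)

    @property
    def mean_vaf(self) -> float:
        return mean_vaf(self)

    @property
    def ctdna_hge_per_ml(self) -> float:
        return ctdna_concentration(self)

    @property
    def is_positive(self) -> bool:
        """True when at least one call (of any class) is present."""
        return len(self.variants) > 0

    def keys(self, exclude_cnv: bool = False) -> set[VariantKey]:
        return {
            v.key for v in self.variants if not (exclude_cnv and v.variant_class.is_cnv)
        }


def max_vaf(profile: SampleProfile) -> float:
    """Largest VAF among read-backed calls; 0 when none are present."""
    vafs = [v.vaf for v in profile.vaf_bearing]
    return max(vafs) if vafs else 0.0


def mean_vaf(profile: SampleProfile) -> float:
    """Mean VAF over read-backed calls (CNVs excluded); 0 when none."""
    vafs = [v.vaf for v in profile.vaf_bearing]
    return float(sum(vafs) / len(vafs)) if vafs else 0.0


def ctdna_concentration(profile: SampleProfile) -> float:
    """ctDNA concentration in hGE/mL: mean VAF x cfDNA (pg/mL) / 3.3 pg.

    Returns 0 when the sample carries no read-backed variant.
    """
    if profile.cfdna_pg_per_ml < 0:
        raise ValueError("cfDNA concentration must be non-negative")
    mv = mean_vaf(profile)
    if mv == 0.0 and not profile.vaf_bearing:
        return 0.0
    return mv * profile.cfdna_pg_per_ml / HGE_PG


# ---------------------------------------------------------------------------
# VCF I/O
#
# Dialect: VCF v4.2 with per-record INFO annotations VAF (Float fraction),
# ALT_READS (Integer), POP_FREQ (Float), CLASS (String), GENE (String) and
# DRIVER / ONCOGENIC flags. CNVs are encoded as symbolic ALT <DUP>/<DEL>
# with CLASS=CNV_gain/CNV_loss and no VAF/ALT_READS.
# ---------------------------------------------------------------------------

_SYMBOLIC_ALT = {VariantClass.CNV_GAIN: "<DUP>", VariantClass.CNV_LOSS: "<DEL>"}


def _chrom_sort_key(chrom: str):
    m = re.match(r"^(chr)?(\d+|X|Y|MT?)$", chrom)
    if m:
        token = m.group(2)
        order = {"X": 23, "Y": 24, "M": 25, "MT": 25}.get(token)
        return (0, order if order is not None else int(token), chrom)
    return (1, 0, chrom)


def _build_header(contigs: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in sorted(set(contigs), key=_chrom_sort_key):
        header.contigs.add(contig)
    header.info.add("GENE", 1, "String", "HGNC gene symbol")
    header.info.add("CLASS", 1, "String", "Variant class: SNV|indel|fusion|CNV_gain|CNV_loss")
    header.info.add("VAF", 1, "Float", "Variant allele fraction")
    header.info.add("ALT_READS", 1, "Integer", "Unique mutant read count")
    header.info.add("POP_FREQ", 1, "Float", "Population allele frequency")
    header.info.add("DRIVER", 0, "Flag", "Alteration in a lung-cancer driver gene")
    header.info.add("ONCOGENIC", 0, "Flag", "Oncogenic per knowledge-base annotation")
    header.info.add("END", 1, "Integer", "End position of a symbolic-ALT segment")
    return header


def write_variant_file(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Write calls as an uncompressed VCF v4.2 in the package dialect."""
    path = Path(path)
    header = _build_header([c.chrom for c in calls])
    ordered = sorted(calls, key=lambda c: (_chrom_sort_key(c.chrom), c.pos, c.alt))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in ordered:
            alt = _SYMBOLIC_ALT.get(call.variant_class, call.alt)
            # symbolic ALTs get a nominal 1-kb segment; htslib needs END >= POS
            stop = call.pos + 999 if call.variant_class.is_cnv else call.pos - 1 + len(call.ref)
            rec = vcf.new_record(
                contig=call.chrom, start=call.pos - 1, stop=stop, alleles=(call.ref, alt)
            )
            rec.info["GENE"] = call.gene
            rec.info["CLASS"] = call.variant_class.value
            if call.has_vaf:
                rec.info["VAF"] = call.vaf
                rec.info["ALT_READS"] = call.alt_reads
            if call.pop_freq is not None:
                rec.info["POP_FREQ"] = call.pop_freq
            if call.is_driver:
                rec.info["DRIVER"] = True
            if call.is_oncogenic:
                rec.info["ONCOGENIC"] = True
            vcf.write(rec)


def _round_info_float(value) -> float:
    return round(float(value), _FLOAT_DECIMALS)


def _info_flag(info, name: str) -> bool:
    # tolerate headers that do not declare the optional flags
    try:
        return bool(info.get(name, False))
    except (KeyError, ValueError):
        return False


def read_variant_file(
    path: str | Path, sample_id: str, patient_id: str | None = None
) -> list[VariantCall]:
    """Parse a VCF in the package dialect into :class:`VariantCall` records.

    Positions are kept 1-based. A read-backed record missing its VAF or
    ALT_READS annotation raises :class:`VariantFileError` naming the record.
    ``patient_id`` defaults to ``sample_id`` when the caller has no manifest.
    """
    path = Path(path)
    if patient_id is None:
        patient_id = sample_id
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VariantFileError(f"cannot parse variant file {path}: {exc}") from exc
    calls: list[VariantCall] = []
    with vcf:
        for rec in vcf:
            where = f"{rec.chrom}:{rec.pos} in {path.name}"
            info = rec.info
            try:
                vclass = VariantClass(info["CLASS"])
            except KeyError:
                raise VariantFileError(f"record {where} lacks CLASS annotation") from None
            except ValueError as exc:
                raise VariantFileError(f"record {where}: {exc}") from None
            gene = info.get("GENE", "")
            alt = rec.alts[0] if rec.alts else ""
            if vclass.is_cnv:
                # restore the class-coded alt so the identity key is stable
                alt = _SYMBOLIC_ALT[vclass]
                vaf = None
                alt_reads = None
            else:
                if "VAF" not in info:
                    raise VariantFileError(f"record {where} lacks VAF annotation")
                if "ALT_READS" not in info:
                    raise VariantFileError(f"record {where} lacks ALT_READS annotation")
                vaf = _round_info_float(info["VAF"])
                alt_reads = int(info["ALT_READS"])
            pop_freq = (
                _round_info_float(info["POP_FREQ"]) if "POP_FREQ" in info else None
            )
            calls.append(
                VariantCall(
                    patient_id=patient_id,
                    sample_id=sample_id,
                    gene=str(gene),
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    variant_class=vclass,
                    vaf=vaf,
                    alt_reads=alt_reads,
                    pop_freq=pop_freq,
                    is_driver=_info_flag(info, "DRIVER"),
                    is_oncogenic=_info_flag(info, "ONCOGENIC"),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Sample manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "patient_id",
    "sample_id",
    "compartment",
    "timepoint",
    "cfdna_pg_per_ml",
    "vcf_path",
]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in MANIFEST_COLUMNS[:4]})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise VariantFileError(f"manifest {path} missing columns {missing}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=MANIFEST_COLUMNS)


def load_profiles(
    manifest_path: str | Path, filter_cfg: FilterConfig | None = None
) -> list[SampleProfile]:
    """Read a manifest and every referenced VCF into sample profiles.

    Relative ``vcf_path`` entries resolve against the manifest's directory.
    When ``filter_cfg`` is given, each profile is filtered on load; samples
    with zero passing variants are retained (``is_positive`` False) because
    detection-rate statistics need them.
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    profiles: list[SampleProfile] = []
    for row in df.itertuples(index=False):
        vcf_path = Path(row.vcf_path)
        if not vcf_path.is_absolute():
            vcf_path = manifest_path.parent / vcf_path
        calls = read_variant_file(vcf_path, row.sample_id, row.patient_id)
        profile = SampleProfile(
            sample_id=row.sample_id,
            patient_id=row.patient_id,
            compartment=Compartment(row.compartment),
            timepoint=Timepoint(row.timepoint),
            cfdna_pg_per_ml=float(row.cfdna_pg_per_ml),
            variants=tuple(calls),
        )
        if filter_cfg is not None:
            profile = profile.filtered(filter_cfg)
        profiles.append(profile)
    return profiles
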