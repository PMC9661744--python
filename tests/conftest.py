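from __future__ import annotations

import itertools

import pytest

from ctdyn.variants import (
    Compartment,
    SampleProfile,
    Timepoint,
    VariantCall,
    VariantClass,
)

_counter = itertools.count(1)


def make_call(
    vaf: float | None = 0.05,
    alt_reads: int | None = None,
    pop_freq: float | None = None,
    variant_class: VariantClass = VariantClass.SNV,
    gene: str = "EGFR",
    chrom: str = "chr7",
    pos: int | None = None,
    patient_id: str = "P1",
    sample_id: str = "S1",
    ref: str = "A",
    alt: str = "T",
) -> VariantCall:
    """A VariantCall with sensible defaults; positions auto-increment."""
    if pos is None:
        pos = 1000 + next(_counter)
    if variant_class.is_cnv:
        vaf = None
        alt_reads = None
        ref, alt = "N", "<DUP>" if variant_class is VariantClass.CNV_GAIN else "<DEL>"
    elif alt_reads is None:
        alt_reads = max(int(round((vaf or 0) * 2000)), 1)
    return VariantCall(
        patient_id=patient_id,
        sample_id=sample_id,
        gene=gene,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        variant_class=variant_class,
        vaf=vaf,
        alt_reads=alt_reads,
        pop_freq=pop_freq,
    )


def make_profile(
    vafs=(0.05,),
    patient_id: str = "P1",
    compartment: Compartment = Compartment.CSF,
    timepoint: Timepoint = Timepoint.BASELINE,
    cfdna: float = 1000.0,
    calls=None,
) -> SampleProfile:
    sample_id = f"{patient_id}_{compartment.value}_{timepoint.value}"
    if calls is None:
        calls = [
            make_call(vaf=v, patient_id=patient_id, sample_id=sample_id, pos=2000 + i)
            for i, v in enumerate(vafs)
        ]
    return SampleProfile(
        sample_id=sample_id,
        patient_id=patient_id,
        compartment=compartment,
        timepoint=timepoint,
        cfdna_pg_per_ml=cfdna,
        variants=tuple(calls),
    )


@pytest.fixture
def toy_vcf_text() -> str:
    """Minimal hand-written VCF in the package dialect: 2 SNVs + 1 CNV gain."""
    return (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=GENE,Number=1,Type=String,Description="gene">\n'
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="class">\n'
        '##INFO=<ID=VAF,Number=1,Type=Float,Description="vaf">\n'
        '##INFO=<ID=ALT_READS,Number=1,Type=Integer,Description="reads">\n'
        '##INFO=<ID=POP_FREQ,Number=1,Type=Float,Description="popfreq">\n'
        "##contig=<ID=chr7>\n"
        "##contig=<ID=chr17>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr7\t55249071\t.\tC\tT\t.\t.\tGENE=EGFR;CLASS=SNV;VAF=0.12;ALT_READS=240\n"
        "chr7\t55086714\t.\tN\t<DUP>\t.\t.\tEND=55087713;GENE=EGFR;CLASS=CNV_gain\n"
        "chr17\t7577538\t.\tG\tA\t.\t.\tGENE=TP53;CLASS=SNV;VAF=0.034;ALT_READS=68;POP_FREQ=0.0001\n"
    )
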