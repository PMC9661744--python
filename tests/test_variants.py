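import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_call, make_profile
from ctdyn.variants import (
    Compartment,
    FilterConfig,
    SampleProfile,
    Timepoint,
    VariantCall,
    VariantClass,
    VariantFileError,
    apply_filters,
    ctdna_concentration,
    max_vaf,
    mean_vaf,
    read_variant_file,
    write_variant_file,
)


class TestVcfParsing:
    def test_toy_vcf_parses_three_calls(self, toy_vcf_text, tmp_path):
        path = tmp_path / "toy.vcf"
        path.write_text(toy_vcf_text)
        calls = read_variant_file(path, "S1", "P1")
        assert len(calls) == 3
        assert sorted(c.variant_class.value for c in calls) == ["CNV_gain", "SNV", "SNV"]
        snv = next(c for c in calls if c.gene == "EGFR" and c.has_vaf)
        assert snv.pos == 55249071  # 1-based position preserved
        assert snv.vaf == pytest.approx(0.12, abs=1e-6)
        cnv = next(c for c in calls if c.variant_class.is_cnv)
        assert cnv.vaf is None and cnv.alt_reads is None
        tp53 = next(c for c in calls if c.gene == "TP53")
        assert tp53.pop_freq == pytest.approx(0.0001, abs=1e-7)

    def test_empty_body_vcf_yields_empty_collection(self, toy_vcf_text, tmp_path):
        header = "".join(
            line + "\n" for line in toy_vcf_text.splitlines() if line.startswith("#")
        )
        path = tmp_path / "empty.vcf"
        path.write_text(header)
        assert read_variant_file(path, "S1") == []

    def test_snv_without_vaf_is_a_parse_error_naming_the_record(self, toy_vcf_text, tmp_path):
        broken = toy_vcf_text.replace("VAF=0.12;", "")
        path = tmp_path / "broken.vcf"
        path.write_text(broken)
        with pytest.raises(VariantFileError, match="55249071"):
            read_variant_file(path, "S1")

    def test_malformed_file_is_a_format_error(self, tmp_path):
        path = tmp_path / "garbage.vcf"
        path.write_text("this is not a vcf\n")
        with pytest.raises(VariantFileError):
            read_variant_file(path, "S1")

    def test_round_trip_preserves_keys_vafs_and_classes(self, tmp_path):
        rng = np.random.default_rng(0)
        calls = [
            make_call(vaf=round(float(v), 4), pos=5000 + i, gene="EGFR")
            for i, v in enumerate(rng.uniform(0.002, 0.9, 25))
        ]
        calls.append(make_call(variant_class=VariantClass.CNV_GAIN, pos=99))
        calls.append(make_call(variant_class=VariantClass.CNV_LOSS, pos=77, gene="STK11"))
        path = tmp_path / "rt.vcf"
        write_variant_file(calls, path)
        back = read_variant_file(path, "S1", "P1")
        assert {c.key for c in back} == {c.key for c in calls}
        assert {(c.key, c.vaf, c.alt_reads) for c in back} == {
            (c.key, c.vaf, c.alt_reads) for c in calls
        }


class TestVariantCallInvariants:
    def test_cnv_must_not_carry_read_support(self):
        with pytest.raises(ValueError):
            VariantCall(
                patient_id="P1", sample_id="S1", gene="EGFR", chrom="chr7", pos=1,
                ref="N", alt="<DUP>", variant_class=VariantClass.CNV_GAIN,
                vaf=0.1, alt_reads=10,
            )

    def test_snv_requires_vaf_and_reads(self):
        with pytest.raises(ValueError):
            VariantCall(
                patient_id="P1", sample_id="S1", gene="EGFR", chrom="chr7", pos=1,
                ref="A", alt="T", variant_class=VariantClass.SNV, vaf=None,
            )

    @pytest.mark.parametrize("vaf", [-0.1, 1.5])
    def test_vaf_bounds(self, vaf):
        with pytest.raises(ValueError):
            make_call(vaf=vaf)


class TestFiltering:
    def test_five_row_rule_table(self):
        """Each rule eliminates exactly one call of the hand-built table."""
        vafs = [0.05, 0.001, 0.003, 0.02, 0.04]
        reads = [10, 5, 2, 8, 6]
        popf = [0.0, 0.0, 0.0, 0.02, 0.0]
        calls = [
            make_call(vaf=v, alt_reads=r, pop_freq=p, pos=100 + i)
            for i, (v, r, p) in enumerate(zip(vafs, reads, popf))
        ]
        kept = apply_filters(calls, FilterConfig())
        assert [c.vaf for c in kept] == [0.05, 0.04]

    def test_all_passing_is_identity(self):
        calls = [make_call(vaf=0.05, alt_reads=100, pos=i) for i in range(1, 6)]
        assert apply_filters(calls, FilterConfig()) == calls

    def test_cnv_bypasses_read_level_rules(self):
        cnv = make_call(variant_class=VariantClass.CNV_GAIN)
        assert apply_filters([cnv], FilterConfig()) == [cnv]

    def test_blacklist_applies_to_every_class(self):
        cnv = make_call(variant_class=VariantClass.CNV_GAIN)
        snv = make_call(vaf=0.3)
        cfg = FilterConfig(blacklist={cnv.key, snv.key})
        assert apply_filters([cnv, snv], cfg) == []

    def test_inclusive_thresholds_pass_at_the_printed_cutoffs(self):
        boundary = make_call(vaf=0.002, alt_reads=3, pop_freq=0.01)
        assert apply_filters([boundary], FilterConfig()) == [boundary]

    @given(
        data=st.lists(
            st.tuples(
                st.floats(0.0, 0.2), st.integers(0, 20),
                st.one_of(st.none(), st.floats(0.0, 0.05)),
            ),
            max_size=30,
        )
    )
    @settings(max_examples=60, derandomize=True)
    def test_filtering_is_idempotent_and_every_exclusion_has_a_reason(self, data):
        cfg = FilterConfig()
        calls = [
            make_call(vaf=round(v, 5), alt_reads=r, pop_freq=p, pos=10_000 + i)
            for i, (v, r, p) in enumerate(data)
        ]
        kept = apply_filters(calls, cfg)
        assert apply_filters(kept, cfg) == kept
        assert set(c.key for c in kept) <= set(c.key for c in calls)
        for call in calls:
            if call in kept:
                continue
            assert (
                call.vaf < cfg.min_vaf
                or call.alt_reads < cfg.min_alt_reads
                or (call.pop_freq is not None and call.pop_freq > cfg.max_pop_freq)
            )


class TestCtdnaMetrics:
    def test_unit_cancelling_example(self):
        prof = make_profile(vafs=(0.10,), cfdna=33.0)
        assert ctdna_concentration(prof) == pytest.approx(1.0)

    def test_three_vaf_hand_arithmetic(self):
        prof = make_profile(vafs=(0.02, 0.04, 0.06), cfdna=330.0)
        assert ctdna_concentration(prof) == pytest.approx(4.0)

    def test_no_vaf_bearing_variant_means_zero_concentration(self):
        cnv_only = make_profile(calls=[make_call(variant_class=VariantClass.CNV_GAIN)], cfdna=500.0)
        assert ctdna_concentration(cnv_only) == 0.0
        assert max_vaf(cnv_only) == 0.0

    def test_negative_cfdna_is_a_domain_error(self):
        with pytest.raises(ValueError):
            make_profile(vafs=(0.1,), cfdna=-1.0)

    @pytest.mark.parametrize(
        "vafs,expected", [((0.02, 0.04, 0.06), 0.06), ((0.002,), 0.002)]
    )
    def test_max_vaf(self, vafs, expected):
        assert max_vaf(make_profile(vafs=vafs)) == pytest.approx(expected)

    @given(
        vafs=st.lists(st.floats(0.001, 0.9), min_size=1, max_size=10),
        cfdna=st.floats(0.0, 1e5),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=60, derandomize=True)
    def test_concentration_scales_linearly_in_cfdna(self, vafs, cfdna, scale):
        vafs = tuple(round(v, 5) for v in vafs)
        base = ctdna_concentration(make_profile(vafs=vafs, cfdna=cfdna))
        scaled = ctdna_concentration(make_profile(vafs=vafs, cfdna=cfdna * scale))
        assert scaled == pytest.approx(base * scale, rel=1e-9, abs=1e-12)
        prof = make_profile(vafs=vafs)
        assert max_vaf(prof) >= mean_vaf(prof) >= 0.0


class TestSampleProfile:
    def test_zero_passing_samples_are_retained_as_negative(self):
        prof = make_profile(calls=[make_call(vaf=0.0005, alt_reads=1)])
        filtered = prof.filtered(FilterConfig())
        assert not filtered.is_positive
        assert filtered.sample_id == prof.sample_id

    def test_key_sets_can_exclude_cnvs(self):
        calls = [make_call(vaf=0.1), make_call(variant_class=VariantClass.CNV_GAIN)]
        prof = make_profile(calls=calls)
        assert len(prof.keys()) == 2
        assert len(prof.keys(exclude_cnv=True)) == 1
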