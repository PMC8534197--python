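"""Variant filter chain: boundaries, rescue semantics, conservation, oracle."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thyroclass as tc
from thyroclass.variants import (
    NormalVariantSet,
    VariantRecord,
    audit_table,
    filter_by_population_frequency,
    filter_by_quality,
    read_maf,
    read_vcf,
    rescue_cosmic_variants,
    run_variant_filter_chain,
    subtract_normal_variants,
    write_maf,
)


def rec(**kw):
    base = dict(sample_id="S1", chrom="1", pos=100, ref="A", alt="T",
                gene="GENE1", qc=50.0)
    base.update(kw)
    return VariantRecord(**base)


class TestQualityFilter:
    @pytest.mark.parametrize("qc,flagged", [(19, True), (20, False), (35, False)])
    def test_strict_boundary_at_20(self, qc, flagged):
        (out,) = filter_by_quality([rec(qc=qc)])
        assert ("low_quality" in out.removal_reasons) is flagged

    def test_empty_input(self):
        assert filter_by_quality([]) == []

    def test_zero_threshold_flags_nothing(self):
        out = filter_by_quality([rec(qc=0.0), rec(qc=5.0)], min_qc=0)
        assert all(not r.removal_reasons for r in out)

    def test_missing_qc_is_an_error(self):
        with pytest.raises(tc.ValidationError):
            filter_by_quality([rec(qc=None)])


class TestPopulationFilter:
    def test_or_semantics_one_database_suffices(self):
        (out,) = filter_by_population_frequency([rec(af_gnomad=0.002, af_abraom=None)])
        assert "common_population" in out.removal_reasons

    def test_boundary_exactly_at_threshold_passes(self):
        (out,) = filter_by_population_frequency([rec(af_gnomad=0.001)])
        assert not out.removal_reasons

    def test_missing_frequencies_treated_as_rare(self):
        (out,) = filter_by_population_frequency([rec(af_gnomad=None, af_abraom=None)])
        assert not out.removal_reasons

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(tc.ValidationError):
            rec(af_gnomad=1.5)


class TestNormalSubtraction:
    def test_matching_key_flagged(self):
        normal = NormalVariantSet({("1", 100, "A", "T")})
        (out,) = subtract_normal_variants([rec()], normal)
        assert "normal_shared" in out.removal_reasons

    def test_same_position_different_alt_not_flagged(self):
        normal = NormalVariantSet({("1", 100, "A", "G")})
        (out,) = subtract_normal_variants([rec(alt="T")], normal)
        assert not out.removal_reasons

    def test_empty_normal_set(self):
        (out,) = subtract_normal_variants([rec()], NormalVariantSet())
        assert not out.removal_reasons


class TestRescue:
    def test_flagged_tsg_rescued_with_reasons_retained(self):
        r = rec(cosmic_role="TSG")
        r.removal_reasons.add("common_population")
        (out,) = rescue_cosmic_variants([r])
        assert out.status == "rescued"
        assert out.removal_reasons == {"common_population"}

    def test_flagged_noncosmic_removed(self):
        r = rec()
        r.removal_reasons.add("low_quality")
        (out,) = rescue_cosmic_variants([r])
        assert out.status == "removed"

    def test_unflagged_passes(self):
        (out,) = rescue_cosmic_variants([rec()])
        assert out.status == "pass"

    def test_low_quality_rescue_carries_audit_warning(self):
        r = rec(cosmic_role="oncogene", qc=5.0)
        staged = rescue_cosmic_variants(filter_by_quality([r]))
        audit = audit_table(staged)
        assert audit.loc[0, "warning"] == "rescued_low_quality"


def five_stratum_table():
    return [
        rec(pos=1),                                        # clean
        rec(pos=2, qc=10.0),                               # low QC
        rec(pos=3, af_gnomad=0.01),                        # common
        rec(pos=4),                                        # normal-shared (key below)
        rec(pos=5, af_abraom=0.05, cosmic_role="TSG"),     # common but COSMIC
    ]


class TestChain:
    def test_five_stratum_truth_table(self):
        normal = NormalVariantSet({("1", 4, "A", "T")})
        retained, audit = run_variant_filter_chain(five_stratum_table(), normal)
        assert sorted(r.pos for r in retained) == [1, 5]
        assert audit.shape[0] == 5
        statuses = dict(zip(audit["Start_Position"], audit["status"]))
        assert statuses == {1: "pass", 2: "removed", 3: "removed", 4: "removed", 5: "rescued"}

    def test_all_clean_input_passes_through(self):
        records = [rec(pos=p) for p in range(1, 6)]
        retained, audit = run_variant_filter_chain(records)
        assert len(retained) == 5
        assert (audit["status"] == "pass").all()

    def test_idempotent_on_retained_set(self):
        normal = NormalVariantSet({("1", 4, "A", "T")})
        retained, _ = run_variant_filter_chain(five_stratum_table(), normal)
        again, _ = run_variant_filter_chain(retained, normal)
        assert sorted(r.pos for r in again) == sorted(r.pos for r in retained)

    def test_conservation_of_record_count(self):
        normal = NormalVariantSet({("1", 4, "A", "T")})
        records = five_stratum_table()
        _, audit = run_variant_filter_chain(records, normal)
        assert audit["status"].isin(["pass", "removed", "rescued"]).all()
        assert audit.shape[0] == len(records)


# --- randomized properties ---------------------------------------------------

record_strategy = st.builds(
    rec,
    pos=st.integers(min_value=1, max_value=20),
    qc=st.floats(min_value=0, max_value=60, allow_nan=False),
    af_gnomad=st.one_of(st.none(), st.floats(min_value=0, max_value=0.1, allow_nan=False)),
    af_abraom=st.one_of(st.none(), st.floats(min_value=0, max_value=0.1, allow_nan=False)),
    cosmic_role=st.sampled_from(["none", "oncogene", "TSG"]),
    variant_class=st.sampled_from(["missense", "silent", "nonsense"]),
)

NORMAL = NormalVariantSet({("1", p, "A", "T") for p in range(1, 10, 2)})


def brute_force_status(r: VariantRecord) -> str:
    """Independent per-record predicate for the whole chain."""
    reasons = set()
    if r.qc < 20:
        reasons.add("low_quality")
    if (r.af_gnomad is not None and r.af_gnomad > 0.001) or (
        r.af_abraom is not None and r.af_abraom > 0.001
    ):
        reasons.add("common_population")
    if r.key() in NORMAL:
        reasons.add("normal_shared")
    if not reasons:
        return "pass"
    return "rescued" if r.cosmic_role in ("oncogene", "TSG") else "removed"


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(record_strategy, max_size=50))
def test_chain_matches_brute_force_oracle(records):
    retained, audit = run_variant_filter_chain(records, NORMAL)
    expected = [brute_force_status(r) for r in records]
    assert list(audit["status"]) == expected
    assert len(retained) == sum(s in ("pass", "rescued") for s in expected)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(record_strategy, max_size=30))
def test_flagging_operations_commute(records):
    ops = [
        lambda rs: filter_by_quality(rs),
        lambda rs: filter_by_population_frequency(rs),
        lambda rs: subtract_normal_variants(rs, NORMAL),
    ]
    outcomes = []
    for perm in itertools.permutations(ops):
        staged = list(records)
        for op in perm:
            staged = op(staged)
        staged = rescue_cosmic_variants(staged)
        outcomes.append([(r.status, tuple(sorted(r.removal_reasons))) for r in staged])
    assert all(o == outcomes[0] for o in outcomes)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(record_strategy, max_size=30))
def test_rescued_subset_of_cosmic(records):
    _, audit = run_variant_filter_chain(records, NORMAL)
    roles = [r.cosmic_role for r in records]
    for status, role in zip(audit["status"], roles):
        if status == "rescued":
            assert role in ("oncogene", "TSG")


# --- IO ----------------------------------------------------------------------


class TestIO:
    def test_maf_roundtrip(self, tmp_path):
        records = five_stratum_table()
        records[3].normal_shared = True
        path = tmp_path / "cohort.maf.tsv"
        write_maf(records, path)
        back = read_maf(path)
        assert [(r.key(), r.qc, r.af_gnomad, r.cosmic_role, r.normal_shared) for r in back] == [
            (r.key(), r.qc, r.af_gnomad, r.cosmic_role, r.normal_shared) for r in records
        ]

    def test_minimal_vcf_reader(self, tmp_path):
        vcf = tmp_path / "s1.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE,Number=1,Type=String,Description="gene">\n'
            '##INFO=<ID=VC,Number=1,Type=String,Description="class">\n'
            '##INFO=<ID=AF_GNOMAD,Number=1,Type=Float,Description="af">\n'
            '##INFO=<ID=AF_ABRAOM,Number=1,Type=Float,Description="af">\n'
            '##INFO=<ID=COSMIC_ROLE,Number=1,Type=String,Description="role">\n'
            "##contig=<ID=7>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "7\t140453136\t.\tA\tT\t88.0\t.\tGENE=BRAF;VC=missense;COSMIC_ROLE=oncogene\n"
            "7\t1000\t.\tG\tC\t10.0\t.\tGENE=OTHER;VC=silent;AF_GNOMAD=0.05\n"
        )
        records = read_vcf(vcf)
        assert len(records) == 2
        assert records[0].gene == "BRAF" and records[0].qc == 88.0
        assert records[0].cosmic_role == "oncogene"
        assert records[1].af_gnomad == pytest.approx(0.05)
        assert records[1].variant_class == "silent"
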