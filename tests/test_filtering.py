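"""Hard filters, control subtraction, prevalence filter, colony consensus,
ploidy inference and genotype confirmation."""

import random

import pytest

from replimut.filtering import (
    FilterConfig,
    apply_hard_filters,
    check_genotype,
    dedup_line_mutations,
    filter_cohort,
    infer_ploidy,
    intersect_colonies,
    prevalence_quality_filter,
    subtract_controls,
)
from replimut.io import MutationRecord, SampleMeta


def _rec(pos=100, ref="A", alt="T", qual=150.0, dp=30, dv=15, gq=60.0,
         sample="S1", line="L1", chrom="chrI"):
    return MutationRecord(chrom, pos, ref, alt, qual=qual, depth=dp,
                          alt_depth=dv, gq=gq, sample_id=sample, line_id=line)


# ---------------------------------------------------------------------------
# Hard filters


def test_hard_filter_thresholds_are_strict():
    cfg = FilterConfig()
    recs = apply_hard_filters(
        [
            _rec(pos=1, dp=9),  # below DP threshold
            _rec(pos=2, qual=100.0, dp=30, dv=15, gq=60.0),  # exactly at QUAL limit
            _rec(pos=3, dv=2),
            _rec(pos=4, gq=39.0),
            _rec(pos=5, qual=99.9),
        ],
        cfg,
    )
    assert recs[0].flags == {"low_dp"}
    assert recs[1].flags == set()  # thresholds are strict '<'
    assert recs[2].flags == {"low_dv"}
    assert recs[3].flags == {"low_gq"}
    assert recs[4].flags == {"low_qual"}


def test_indel_qual_threshold_is_lower():
    cfg = FilterConfig()
    ins = _rec(pos=10, ref="A", alt="AT", qual=35.0)
    (out,) = apply_hard_filters([ins], cfg)
    assert "low_qual" not in out.flags  # 35 >= indel threshold 30


def test_snp_gap_flags_snvs_near_indels_same_sample_only():
    cfg = FilterConfig()
    recs = apply_hard_filters(
        [
            _rec(pos=100, ref="A", alt="AT", qual=80.0),  # indel
            _rec(pos=105),  # distance 5 <= 7 -> flagged
            _rec(pos=110),  # distance 10 -> clean
            _rec(pos=105, sample="S2"),  # other sample -> clean
        ],
        cfg,
    )
    assert "snp_gap" in recs[1].flags
    assert "snp_gap" not in recs[2].flags
    assert "snp_gap" not in recs[3].flags


def test_missing_quality_fields_fail_conservatively():
    cfg = FilterConfig()
    r = MutationRecord("chrI", 1, "A", "T", qual=150.0, sample_id="S1")
    (out,) = apply_hard_filters([r], cfg)
    assert {"low_dp", "low_dv", "low_gq"} <= out.flags
    cfg2 = FilterConfig(missing_fails=False)
    r2 = MutationRecord("chrI", 1, "A", "T", qual=150.0, sample_id="S1")
    (out2,) = apply_hard_filters([r2], cfg2)
    assert out2.flags == set()


# ---------------------------------------------------------------------------
# Control subtraction


def test_subtract_controls_exact_key_and_idempotence():
    recs = [_rec(pos=100, alt="T"), _rec(pos=100, alt="C"), _rec(pos=200)]
    controls = [_rec(pos=100, alt="T", sample="CTRL")]
    out = subtract_controls(recs, controls)
    assert [(r.pos, r.alt) for r in out] == [(100, "C"), (200, "T")]
    assert subtract_controls(out, controls) == out  # idempotent
    assert subtract_controls(recs, []) == recs  # empty control set


# ---------------------------------------------------------------------------
# Prevalence filter


def test_prevalence_filter_removes_recurrent_low_quality_calls():
    cfg = FilterConfig(stringency="single_cell")  # threshold 60 + 15 * prevalence
    shared = [
        _rec(pos=500, qual=150.0, sample=f"S{i}", line=f"L{i}") for i in range(10)
    ]
    unique = [_rec(pos=900, qual=150.0)]
    kept, removed = prevalence_quality_filter(shared + unique, cfg)
    # prevalence 10 -> threshold 210 > 150: all carriers removed
    assert {r.pos for r in removed} == {500} and len(removed) == 10
    # prevalence 1 -> threshold 75 < 150: retained
    assert [r.pos for r in kept] == [900]


def test_small_population_slope_is_shallower():
    sc = FilterConfig(stringency="single_cell")
    sp = FilterConfig(stringency="small_population")
    assert sp.slope < sc.slope
    assert sp.prevalence_threshold(10) < sc.prevalence_threshold(10)


# ---------------------------------------------------------------------------
# Colony intersection and dedup


def test_intersection_requires_all_colonies():
    a = [_rec(pos=1, sample="C1"), _rec(pos=2, sample="C1")]
    b = [_rec(pos=1, sample="C2")]
    out = intersect_colonies({"C1": a, "C2": b}, "single_cell")
    assert [r.pos for r in out] == [1]


def test_intersection_drops_passage0_keys():
    a = [_rec(pos=1, sample="C1"), _rec(pos=2, sample="C1")]
    b = [_rec(pos=1, sample="C2"), _rec(pos=2, sample="C2")]
    out = intersect_colonies({"C1": a, "C2": b}, "single_cell",
                             passage0_keys={("chrI", 1, "A", "T")})
    assert [r.pos for r in out] == [2]


def test_sole_colony_keeps_everything():
    a = [_rec(pos=1, sample="C1"), _rec(pos=2, sample="C1")]
    out = intersect_colonies({"C1": a}, "single_cell")
    assert [r.pos for r in out] == [1, 2]


def test_small_population_mode_applies_no_intersection():
    a = [_rec(pos=1, sample="C1")]
    b = [_rec(pos=2, sample="C2")]
    out = intersect_colonies({"C1": a, "C2": b}, "small_population")
    assert [r.pos for r in out] == [1, 2]


def test_intersection_requires_at_least_one_colony():
    with pytest.raises(ValueError):
        intersect_colonies({}, "single_cell")


def test_dedup_keeps_one_per_line_with_qual_then_sample_tiebreak():
    recs = [
        _rec(pos=1, qual=100.0, sample="C2", line="L1"),
        _rec(pos=1, qual=120.0, sample="C3", line="L1"),
        _rec(pos=1, qual=120.0, sample="C1", line="L1"),
        _rec(pos=1, qual=90.0, sample="C1", line="L2"),
    ]
    out = dedup_line_mutations(recs)
    assert len(out) == 2  # one per line
    rep = next(r for r in out if r.line_id == "L1")
    assert (rep.qual, rep.sample_id) == (120.0, "C1")  # tie -> smallest sample
    assert dedup_line_mutations([]) == []


# ---------------------------------------------------------------------------
# Ploidy and genotype QC


def test_infer_ploidy_from_median_af():
    hap = [_rec(pos=i, dp=100, dv=dv) for i, dv in enumerate([95, 100, 97, 100, 99], 1)]
    assert infer_ploidy(hap).call == "haploid"
    dip = [_rec(pos=i, dp=100, dv=dv) for i, dv in enumerate([48, 55, 50, 46, 51], 1)]
    assert infer_ploidy(dip).call == "diploid"
    few = [_rec(pos=1, dp=100, dv=60), _rec(pos=2, dp=100, dv=70)]
    assert infer_ploidy(few, min_alleles=5).call == "indeterminate"


@pytest.mark.parametrize(
    "codon,expected,verdict",
    [
        ("AGA", "R", "pass"),
        ("CCA", "R", "fail"),  # CCA encodes P
        ("TAA", "K", "fail"),  # stop codon
        ("ANA", "R", "indeterminate"),
    ],
)
def test_check_genotype(codon, expected, verdict):
    got, note = check_genotype(codon, expected)
    assert got == verdict
    if codon == "TAA":
        assert "stop" in note


# ---------------------------------------------------------------------------
# Order stability of the whole chain


def test_filter_cohort_is_order_stable():
    sheet = {}
    records = {}
    rnd = random.Random(0)
    for li in range(2):
        line = f"L{li}"
        for ci in range(2):
            sid = f"{line}C{ci}"
            sheet[sid] = SampleMeta(sid, line, passages=26, ploidy="diploid")
            records[sid] = [
                _rec(pos=10 * k + 1, qual=150.0 + k, sample=sid, line=line)
                for k in range(20)
            ]
        p0 = f"{line}P0"
        sheet[p0] = SampleMeta(p0, line, role="passage0", passages=0)
        records[p0] = [_rec(pos=1, qual=150.0, sample=p0, line=line)]
    sheet["CTRL"] = SampleMeta("CTRL", "CTRL", role="control", passages=0)
    records["CTRL"] = [_rec(pos=11, qual=150.0, sample="CTRL", line="CTRL")]

    def run(shuffled: bool):
        recs = {
            sid: [
                MutationRecord(r.chrom, r.pos, r.ref, r.alt, qual=r.qual,
                               depth=r.depth, alt_depth=r.alt_depth, gq=r.gq,
                               sample_id=r.sample_id, line_id=r.line_id)
                for r in v
            ]
            for sid, v in records.items()
        }
        if shuffled:
            for v in recs.values():
                rnd.shuffle(v)
        out = filter_cohort(recs, sheet, FilterConfig())
        return [(r.line_id, *r.key, r.qual) for r in out.final_records]

    assert run(False) == run(True)


def test_filter_cohort_drops_controls_and_passage0():
    sheet = {
        "C1": SampleMeta("C1", "L1", passages=26),
        "C2": SampleMeta("C2", "L1", passages=26),
        "P0": SampleMeta("P0", "L1", role="passage0", passages=0),
        "CT": SampleMeta("CT", "CTRL", role="control", passages=0),
    }
    common = dict(qual=150.0, dp=30, dv=15, gq=60.0)
    records = {
        "C1": [_rec(pos=1, sample="C1", **common), _rec(pos=2, sample="C1", **common),
               _rec(pos=3, sample="C1", **common)],
        "C2": [_rec(pos=1, sample="C2", **common), _rec(pos=2, sample="C2", **common),
               _rec(pos=3, sample="C2", **common)],
        "P0": [_rec(pos=2, sample="P0", line="L1", **common)],
        "CT": [_rec(pos=3, sample="CT", line="CTRL", **common)],
    }
    out = filter_cohort(records, sheet, FilterConfig())
    assert [r.pos for r in out.final_records] == [1]
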