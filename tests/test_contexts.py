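"""Sequence-context matrices and indel classification."""

import numpy as np
import pytest

from replimut.contexts import (
    build_context_matrices,
    classify_indel,
    homopolymer_run,
    indel_spectrum,
)
from replimut.io import Genome, MutationRecord, OriginTable, revcomp
from replimut.replicon import build_model, locate


def _loc(model, chrom, pos, ref, alt):
    return locate(MutationRecord(chrom, pos, ref, alt), model)


def test_context_matrix_single_mutation_one_hot():
    g = Genome({"c": "G" * 300 + "ACTGA" + "G" * 1700})
    model = build_model(OriginTable({"c": [(90, 110), (1890, 1910)]}))
    lm = _loc(model, "c", 303, "T", "A")  # centre of ACTGA, rel_dist ~11 -> first
    mats = build_context_matrices([lm], g, restrict_thirds=True)
    cm = mats[("T>A", "right")]
    assert cm.n == 1
    expect = {(-2, "A"), (-1, "C"), (0, "T"), (1, "G"), (2, "A")}
    freq = cm.to_frame()
    for offset, base in expect:
        assert freq.loc[offset, base] == 1.0
    assert freq.to_numpy().sum() == pytest.approx(5.0)  # rows sum to 1 each


def test_middle_third_dropped_when_restricted():
    g = Genome({"c": "A" * 2000})
    model = build_model(OriginTable({"c": [(90, 110), (1890, 1910)]}))
    lm = _loc(model, "c", 1000, "A", "C")  # rel_dist 50 -> middle third
    assert build_context_matrices([lm], g, restrict_thirds=True) == {}
    assert build_context_matrices([lm], g, restrict_thirds=False)


def test_thirds_partition_counts(toy, toy_model, neutral_simulator, rng):
    pairs = neutral_simulator.draw(2000, rng)
    located = [locate(rec, toy_model) for rec, _ in pairs]
    located = [lm for lm in located if lm is not None]
    with_r = build_context_matrices(located, toy.genome, restrict_thirds=False)
    total = sum(cm.n for cm in with_r.values())
    restricted = build_context_matrices(located, toy.genome, restrict_thirds=True)
    n_middle = sum(1 for lm in located if lm.third == "middle")
    assert total - sum(cm.n for cm in restricted.values()) == n_middle


def test_strand_bookkeeping_mirror_symmetry(toy, toy_model, neutral_simulator, rng):
    """Re-expressing every mutation on the complementary strand (mirrored
    genome and origins) swaps sides and complements/reverses contexts but
    leaves the matrices identical."""
    chrom = "chr01"
    L = toy.genome.lengths[chrom]
    mirror_genome = Genome({chrom: revcomp(toy.genome.sequences[chrom])})
    mirror_origins = OriginTable(
        {chrom: sorted((L - e + 1, L - s + 1) for s, e in toy.origins.origins[chrom])}
    )
    mirror_model = build_model(mirror_origins)
    comp = str.maketrans("ACGT", "TGCA")
    pairs = neutral_simulator.draw(500, rng)
    fwd, rev = [], []
    for rec, _ in pairs:
        if rec.chrom != chrom:
            continue
        fwd.append(locate(rec, toy_model))
        rev.append(
            locate(
                MutationRecord(chrom, L - rec.pos + 1,
                               rec.ref.translate(comp), rec.alt.translate(comp)),
                mirror_model,
            )
        )
    fwd = [x for x in fwd if x is not None]
    rev = [x for x in rev if x is not None]
    m_f = build_context_matrices(fwd, toy.genome, restrict_thirds=False)
    m_r = build_context_matrices(rev, mirror_genome, restrict_thirds=False)
    for (cls, side), cm in m_f.items():
        comp_cls = f"{cls[0].translate(comp)}>{cls[2].translate(comp)}"
        other_side = "left" if side == "right" else "right"
        cm2 = m_r[(comp_cls, other_side)]
        assert cm2.n == cm.n
        # positions reverse and bases complement under the mirror
        assert np.array_equal(cm2.counts, cm.counts[::-1, ::-1])


def test_classify_indel_examples():
    g = Genome({"c": "GTAAAAC"})
    model = None
    ins = MutationRecord("c", 2, "T", "TA")
    call = classify_indel(ins, g, model)
    assert (call.unit_class, call.hp_base, call.hp_len) == ("+A", "A", 4)
    dele = MutationRecord("c", 2, "TA", "T")
    call = classify_indel(dele, g, model)
    assert (call.unit_class, call.hp_base, call.hp_len) == ("-A", "A", 4)
    di = MutationRecord("c", 1, "G", "GTA")
    assert classify_indel(di, g, model).unit_class == "+TA"
    tri = MutationRecord("c", 1, "G", "GTAC")
    assert classify_indel(tri, g, model).unit_class == "+other"
    with pytest.raises(ValueError):
        classify_indel(MutationRecord("c", 2, "T", "A"), g, model)


def test_homopolymer_run_matches_bruteforce_oracle(toy, rng):
    chrom = "chr01"
    seq = toy.genome.sequences[chrom]
    for _ in range(1000):
        start = int(rng.integers(1, len(seq) + 1))
        base, length = homopolymer_run(toy.genome, chrom, start)
        # brute-force scan
        expect = 0
        b = seq[start - 1]
        i = start - 1
        while i < len(seq) and seq[i] == b:
            expect += 1
            i += 1
        assert (base, length) == (b, expect)


def test_indel_spectrum_fractions_and_strand_split(toy, toy_model, rng):
    from replimut.simulate import SimConfig, simulate_indels

    cfg = SimConfig(seed=30, ins_rate_homopolymer=0.08, del_rate=0.0)
    recs, truth = simulate_indels(toy.genome, toy_model, cfg, rng)
    calls = [classify_indel(r, toy.genome, toy_model) for r in recs]
    df = indel_spectrum(calls, by_strand=True)
    assert set(df["unit_class"]) <= {"+A", "+T"}
    assert df["fraction_of_kind"].sum() == pytest.approx(1.0)
    # +A insertions are emitted only in leading territory
    plus_a = df[df["unit_class"] == "+A"]
    if len(plus_a):
        assert int(plus_a["n_lagging"].iloc[0]) == 0
    plus_t = df[df["unit_class"] == "+T"]
    if len(plus_t):
        assert int(plus_t["n_leading"].iloc[0]) == 0


def test_indel_spectrum_simple_fractions():
    g = Genome({"c": "GTAAAACTTTTG"})
    recs = [MutationRecord("c", 2, "T", "TA") for _ in range(7)] + [
        MutationRecord("c", 7, "C", "CT") for _ in range(3)
    ]
    calls = [classify_indel(r, g) for r in recs]
    df = indel_spectrum(calls).set_index("unit_class")
    assert df.loc["+A", "fraction_of_kind"] == pytest.approx(0.7)
    assert indel_spectrum([]).empty
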