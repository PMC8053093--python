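"""Synthetic cohort generator: determinism, planted structure, recovery."""

from collections import Counter

import numpy as np
import pytest

from replimut.io import CHANNELS96, MutationRecord, left_align
from replimut.replicon import build_model
from replimut.simulate import (
    SimConfig,
    SimConfigError,
    SnvSimulator,
    make_toy_genome,
    simulate_cohort,
    simulate_indels,
    simulate_snvs,
    write_cohort,
)


def test_toy_genome_is_seed_deterministic():
    a = make_toy_genome(SimConfig(seed=1))
    b = make_toy_genome(SimConfig(seed=1))
    assert a.genome.sequences == b.genome.sequences
    assert a.origins.origins == b.origins.origins
    assert a.homopolymers == b.homopolymers


def test_toy_genome_origin_density():
    toy = make_toy_genome(SimConfig(seed=2, n_chromosomes=2,
                                    chromosome_length=50_000, origin_spacing=10_000))
    for chrom, rows in toy.origins.origins.items():
        assert len(rows) >= 4


def test_registered_homopolymers_are_t_runs(toy):
    for chrom, start, length in toy.homopolymers:
        assert length >= 3
        run = toy.genome.sequences[chrom][start - 1 : start - 1 + length]
        assert run == "T" * length


def test_config_validation():
    with pytest.raises(SimConfigError):
        SimConfig(chromosome_length=20_000, origin_spacing=15_000)
    with pytest.raises(SimConfigError):
        SimConfig(colonies_per_line=0)
    with pytest.raises(SimConfigError):
        SimConfig(channel_probs=np.ones(96))  # sums to 96


def test_concentrated_channel_probs_yield_single_channel(toy, toy_model):
    probs = np.zeros(96)
    probs[17] = 1.0
    cfg = SimConfig(seed=3, channel_probs=probs)
    recs, truth = simulate_snvs(toy.genome, toy_model, cfg, n=200)
    assert {t.channel for t in truth} == {CHANNELS96[17]}


def test_neutral_asymmetry_gives_half_leading(neutral_simulator, rng):
    """With odds 1 everywhere the leading fraction matches the leading
    genome fraction (1/2 under the midpoint-termination model) to 3 SE."""
    n = 6000
    pairs = neutral_simulator.draw(n, rng)
    n_lead = sum(1 for _, e in pairs if e.strand == "leading")
    se = np.sqrt(0.25 / n)
    assert abs(n_lead / n - 0.5) < 3 * se


def test_configured_asymmetry_is_recovered(toy, toy_model, rng):
    probs = np.zeros(96)
    # all T>G channels (the A>C complement class)
    idx = [i for i, ch in enumerate(CHANNELS96) if ch[2:5] == "T>G"]
    probs[idx] = 1.0 / len(idx)
    cfg = SimConfig(seed=4, channel_probs=probs, asymmetry={"A>C": 3.0})
    sim = SnvSimulator(toy.genome, toy_model, cfg)
    pairs = sim.draw(6000, rng)
    counts = Counter()
    for rec, e in pairs:
        if rec.snv_class == "A>C":
            counts[e.strand] += 1
    odds = counts["leading"] / counts["lagging"]
    # 3 SE on the log-odds scale
    se_log = np.sqrt(1 / counts["leading"] + 1 / counts["lagging"])
    assert abs(np.log(odds) - np.log(3.0)) < 3 * se_log


def test_indels_only_insertions_when_del_rate_zero(toy, toy_model, rng):
    cfg = SimConfig(seed=5, ins_rate_homopolymer=0.05, del_rate=0.0)
    recs, truth = simulate_indels(toy.genome, toy_model, cfg, rng)
    assert recs, "expected some insertions"
    assert all(r.kind == "INS" for r in recs)


def test_insertions_flank_homopolymer_and_are_left_aligned(toy, toy_model, rng):
    cfg = SimConfig(seed=6, ins_rate_homopolymer=0.05, del_rate=0.02)
    recs, _ = simulate_indels(toy.genome, toy_model, cfg, rng)
    assert recs
    for r in recs:
        unit = r.alt[1:] if r.kind == "INS" else r.ref[1:]
        run = toy.genome.sequences[r.chrom][r.pos : r.pos + 3]
        assert run == unit[0] * 3  # >=3 identical template bases 3' of event
        assert left_align(r.chrom, r.pos, r.ref, r.alt, toy.genome) == (
            r.pos, r.ref, r.alt,
        )


def test_single_cell_colonies_identical_without_false_positives():
    cfg = SimConfig(seed=7, n_lines=2, n_false_positives=0, artifact_count=0)
    coh = simulate_cohort(cfg)
    for line in ("L01", "L02"):
        keys = [
            {r.key for r in coh.records[f"{line}C{c}"]} for c in (1, 2)
        ]
        assert keys[0] == keys[1]


def test_artifacts_recur_in_exactly_prevalence_samples():
    cfg = SimConfig(seed=8, n_lines=6, artifact_count=20, artifact_prevalence=5)
    coh = simulate_cohort(cfg)
    carriers = Counter()
    for (sid, *key), e in coh.truth.entries.items():
        if e.category == "artifact":
            carriers[tuple(key)] += 1
    assert len(carriers) == 20
    assert set(carriers.values()) == {5}


def test_small_population_jaccard_matches_sharing_model():
    f = 0.5
    cfg = SimConfig(seed=9, n_lines=5, colonies_per_line=4,
                    propagation="small_population", shared_fraction=f,
                    passages=40, n_snv_per_sample=200,
                    artifact_count=0, n_false_positives=0)
    coh = simulate_cohort(cfg)
    truth = coh.truth
    jaccards = []
    for line in {m.line_id for m in coh.samples if m.role == "evolved"}:
        ids = [m.sample_id for m in coh.samples
               if m.line_id == line and m.role == "evolved"]
        sets = []
        for sid in ids:
            keys = {
                r.key for r in coh.records[sid]
                if truth.lookup(sid, r).category in ("true_snv", "true_indel")
            }
            sets.append(keys)
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                inter = len(sets[i] & sets[j])
                union = len(sets[i] | sets[j])
                jaccards.append(inter / union)
    expected = f / (2 - f)  # shared s over s + 2 privates, sizes ~ f*n, (1-f)*n
    # Monte-Carlo tolerance: binomial-ish spread of the mean over pairs
    assert np.mean(jaccards) == pytest.approx(expected, abs=0.03)


def test_truth_joins_one_to_one_with_emitted_records():
    coh = simulate_cohort(SimConfig(seed=10, n_lines=2))
    n_records = sum(len(v) for v in coh.records.values())
    assert n_records == len(coh.truth.entries)
    for sid, recs in coh.records.items():
        for r in recs:
            assert coh.truth.lookup(sid, r) is not None


def test_cohort_vcfs_are_bit_identical_under_fixed_seed(tmp_path):
    for d in ("a", "b"):
        write_cohort(simulate_cohort(SimConfig(seed=11, n_lines=2)), tmp_path / d)
    for p in sorted((tmp_path / "a").rglob("*.vcf")):
        q = tmp_path / "b" / p.relative_to(tmp_path / "a")
        assert p.read_bytes() == q.read_bytes()


def test_truth_json_round_trip(tmp_path):
    coh = simulate_cohort(SimConfig(seed=12, n_lines=2))
    path = tmp_path / "truth.json"
    coh.truth.to_json(path)
    from replimut.simulate import SimTruth

    back = SimTruth.from_json(path)
    assert back.entries == coh.truth.entries
    assert back.config.seed == 12
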