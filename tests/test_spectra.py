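"""Channel classification, spectra, normalisation and signature comparison."""

import numpy as np
import pytest

from replimut.io import (
    CHANNELS96,
    Genome,
    MutationRecord,
    SignatureMatrix,
    TrinucFreq,
    revcomp,
    trinucleotide_census,
)
from replimut.spectra import (
    SpectrumError,
    class_frequencies,
    classify_snv,
    compare_to_signatures,
    cosine_similarity,
    spectrum96,
)


def _snv(chrom, pos, ref, alt, line="L1"):
    return MutationRecord(chrom, pos, ref, alt, line_id=line)


def test_classify_purine_reference_is_reverse_complemented():
    g = Genome({"c": "AGT"})
    ch, flipped = classify_snv(_snv("c", 2, "G", "T"), g)
    assert ch == "A[C>A]T"  # AGT revcomp ACT, G>T -> C>A
    assert flipped


def test_classify_pyrimidine_reference_unflipped():
    g = Genome({"c": "ACA"})
    ch, flipped = classify_snv(_snv("c", 2, "C", "T"), g)
    assert (ch, flipped) == ("A[C>T]A", False)


def test_complementary_mutations_share_a_channel():
    ga = Genome({"c": "TTA"})
    gb = Genome({"c": "TAA"})
    ch_a, _ = classify_snv(_snv("c", 2, "T", "A"), ga)
    ch_b, _ = classify_snv(_snv("c", 2, "A", "T"), gb)
    assert ch_a == ch_b == "T[T>A]A"


def test_classify_is_strand_involution_invariant(toy, rng):
    """Re-expressing a mutation on the complementary strand (reverse
    complemented genome, mirrored coordinate) yields the same channel."""
    chrom = "chr01"
    seq = toy.genome.sequences[chrom]
    mirrored = Genome({chrom: revcomp(seq)})
    L = len(seq)
    for _ in range(50):
        pos = int(rng.integers(2, L - 1))
        ref = seq[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        ch1, _ = classify_snv(_snv(chrom, pos, ref, alt), toy.genome)
        comp = str.maketrans("ACGT", "TGCA")
        ch2, _ = classify_snv(
            _snv(chrom, L - pos + 1, ref.translate(comp), alt.translate(comp)),
            mirrored,
        )
        assert ch1 == ch2


def test_classify_errors_and_exclusions():
    g = Genome({"c": "ACGT"})
    with pytest.raises(SpectrumError, match="REF mismatch"):
        classify_snv(_snv("c", 2, "G", "T"), g)
    assert classify_snv(_snv("c", 1, "A", "T"), g) is None  # no 5' flank
    gn = Genome({"c": "NCA"})
    assert classify_snv(_snv("c", 2, "C", "T"), gn) is None  # N in context


def test_spectrum_basics():
    g = Genome({"c": "AACAA"})
    spec = spectrum96([], g)
    assert spec.total == 0 and not spec.frequencies.any()
    spec = spectrum96([_snv("c", 3, "C", "T")], g)
    assert spec.total == 1
    assert spec.frequencies[CHANNELS96.index("A[C>T]A")] == 1.0


def test_normalization_corrects_for_context_availability():
    # genome rich in ACA: raw frequencies inflate A[C>*]A; normalisation
    # divides by abundance, so two channels with equal per-site intensity
    # end up equal after correction
    g = Genome({"c": "ACAACAACAGCG"})
    tf = trinucleotide_census(g, collapsed=True)
    recs = [_snv("c", p, "C", "T") for p in (2, 5, 8)] + [_snv("c", 11, "C", "T")]
    raw = spectrum96(recs, g)
    norm = spectrum96(recs, g, tf, normalize=True)
    i_aca = CHANNELS96.index("A[C>T]A")
    i_gcg = CHANNELS96.index("G[C>T]G")
    assert raw.frequencies[i_aca] > raw.frequencies[i_gcg]
    # per-site rates are equal (3 hits over 3 ACA sites, 1 over 1 GCG site)
    assert norm.frequencies[i_aca] == pytest.approx(norm.frequencies[i_gcg])


def test_normalization_with_uniform_abundance_preserves_order():
    g = Genome({"c": "AACAATCAA"})
    recs = [_snv("c", 3, "C", "T"), _snv("c", 3, "C", "T"), _snv("c", 7, "C", "A")]
    uniform = TrinucFreq({t: 1 / 32 for t in sorted(
        {f"{a}{c}{b}" for a in "ACGT" for c in "CT" for b in "ACGT"})}, collapsed=True)
    raw = spectrum96(recs, g)
    norm = spectrum96(recs, g, uniform, normalize=True)
    assert np.argsort(raw.frequencies).tolist() == np.argsort(norm.frequencies).tolist()


def test_class_frequencies_sums_complementary_pairs():
    g_ref = [("A", "C")] * 2 + [("T", "G")] * 3
    recs = [_snv("c", i + 1, r, a) for i, (r, a) in enumerate(g_ref)]
    cs = class_frequencies(recs)
    assert cs.counts["T>G"] == 5
    twelve = [_snv("c", i + 1, r, a) for i, (r, a) in enumerate(
        [(r, a) for r in "ACGT" for a in "ACGT" if r != a])]
    cs12 = class_frequencies(twelve)
    assert all(v == pytest.approx(1 / 6) for v in cs12.frequencies.values())
    assert class_frequencies([]).total == 0


def test_cosine_similarity_closed_forms():
    assert cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert cosine_similarity([1, 0, 0], [0, 1, 0]) == pytest.approx(0.0)
    assert cosine_similarity([1, 1, 0], [1, 0, 0]) == pytest.approx(1 / np.sqrt(2))
    with pytest.raises(SpectrumError):
        cosine_similarity([0, 0], [1, 0])


def _sig_matrix(cols: dict[str, np.ndarray]) -> SignatureMatrix:
    probs = np.column_stack([v / v.sum() for v in cols.values()])
    return SignatureMatrix(CHANNELS96, tuple(cols), probs)


def test_compare_to_signatures_ranks_exact_match_first(toy, rng):
    # build a spectrum from simulated-looking counts and append it as a column
    counts = rng.integers(0, 50, size=96).astype(float)
    counts[0] += 1  # ensure non-zero
    spec_vec = counts / counts.sum()
    sigs = _sig_matrix({"flat": np.ones(96), "self": counts.copy()})
    from replimut.spectra import Spectrum96

    spec = Spectrum96(counts.astype(np.int64))
    df = compare_to_signatures(spec, sigs)
    assert df.iloc[0]["signature"] == "self"
    assert df.iloc[0]["cosine_similarity"] == pytest.approx(1.0)
    # hand-computed similarity for the flat column
    flat = np.full(96, 1 / 96)
    expect = float(spec_vec @ flat / (np.linalg.norm(spec_vec) * np.linalg.norm(flat)))
    got = float(df.set_index("signature").loc["flat", "cosine_similarity"])
    assert got == pytest.approx(expect)


def test_compare_to_signatures_rejects_zero_spectrum():
    from replimut.spectra import Spectrum96

    sigs = _sig_matrix({"flat": np.ones(96)})
    with pytest.raises(SpectrumError):
        compare_to_signatures(Spectrum96(np.zeros(96, dtype=np.int64)), sigs)
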