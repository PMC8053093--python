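"""Mutation spectra: 6-class frequencies, 96-channel trinucleotide spectra
with genome-abundance normalisation, and cosine-similarity comparison with
COSMIC-style signatures.

Channels are pyrimidine-centred: a purine-reference SNV is reverse
complemented together with its flanking context and assigned to the
complementary channel.  Context is always taken from the reference genome,
never from the VCF line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import (
    CHANNELS96,
    CHANNEL_INDEX,
    CLASSES6,
    Genome,
    MutationRecord,
    PYRIMIDINES,
    SignatureMatrix,
    TrinucFreq,
    channel_label,
    complement_class,
    revcomp,
)

__all__ = [
    "ClassSpectrum6",
    "Spectrum96",
    "classify_snv",
    "spectrum96",
    "class_frequencies",
    "cosine_similarity",
    "compare_to_signatures",
]


class SpectrumError(ValueError):
    pass


def classify_snv(m: MutationRecord, genome: Genome) -> tuple[str, bool] | None:
    """Channel label for an SNV, plus whether it was reverse complemented.

    Returns None when the mutation sits at a chromosome end (no full
    trinucleotide context) or the context contains N; raises when the VCF REF
    disagrees with the genome.
    """
    if m.kind != "SNV":
        raise SpectrumError(f"not an SNV: {m.chrom}:{m.pos} {m.ref}>{m.alt}")
    ref_base = genome.base(m.chrom, m.pos)
    if ref_base != m.ref:
        raise SpectrumError(
            f"REF mismatch at {m.chrom}:{m.pos}: VCF {m.ref}, genome {ref_base}"
        )
    ctx = genome.context(m.chrom, m.pos, flank=1)
    if ctx is None or "N" in ctx:
        return None
    if m.ref in PYRIMIDINES:
        return channel_label(f"{m.ref}>{m.alt}", ctx), False
    flipped_cls = complement_class(f"{m.ref}>{m.alt}")
    return channel_label(flipped_cls, revcomp(ctx)), True


@dataclass
class Spectrum96:
    """Counts and frequencies over the 96 trinucleotide channels."""

    counts: np.ndarray  # int, length 96, CHANNELS96 order
    normalized: bool = False
    n_excluded: int = 0  # mutations without usable context
    _freqs: np.ndarray | None = field(default=None, repr=False)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        if self._freqs is not None:
            return self._freqs
        if self.total == 0:
            return np.zeros(96)
        return self.counts / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"channel": CHANNELS96, "count": self.counts, "frequency": self.frequencies}
        )


def spectrum96(
    records: Iterable[MutationRecord],
    genome: Genome,
    trinuc_freq: TrinucFreq | None = None,
    normalize: bool = False,
) -> Spectrum96:
    """Build the 96-channel spectrum of a (per-line deduplicated) SNV set.

    With ``normalize=True`` each channel frequency is divided by the genome
    abundance of its trinucleotide and the result renormalised to sum to 1,
    correcting for unequal context availability.
    """
    counts = np.zeros(96, dtype=np.int64)
    excluded = 0
    for m in records:
        if m.kind != "SNV":
            continue
        hit = classify_snv(m, genome)
        if hit is None:
            excluded += 1
            continue
        counts[CHANNEL_INDEX[hit[0]]] += 1
    spec = Spectrum96(counts, normalized=False, n_excluded=excluded)
    if not normalize:
        return spec
    if trinuc_freq is None:
        raise SpectrumError("normalization requires a genome trinucleotide census")
    freqs = spec.frequencies.copy()
    abund = np.array(
        [trinuc_freq.channel_abundance(ch[0] + ch[2] + ch[-1]) for ch in CHANNELS96]
    )
    zero_bad = (abund == 0) & (counts > 0)
    if zero_bad.any():
        bad = [CHANNELS96[i] for i in np.flatnonzero(zero_bad)]
        raise SpectrumError(f"nonzero counts in zero-abundance channel(s): {bad[:5]}")
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(abund > 0, freqs / np.where(abund > 0, abund, 1.0), 0.0)
    total = corrected.sum()
    if total > 0:
        corrected = corrected / total
    return Spectrum96(counts, normalized=True, n_excluded=excluded, _freqs=corrected)


@dataclass
class ClassSpectrum6:
    """Six-class SNV spectrum after complementary-pair summation."""

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> dict[str, float]:
        n = self.total
        return {c: (v / n if n else 0.0) for c, v in self.counts.items()}


def class_frequencies(records: Iterable[MutationRecord]) -> ClassSpectrum6:
    """Count SNVs per pyrimidine-referenced class, summing complementary
    pairs (e.g. A>C counted with T>G)."""
    counts = {c: 0 for c in CLASSES6}
    for m in records:
        if m.kind != "SNV":
            continue
        cls = f"{m.ref}>{m.alt}"
        if m.ref not in PYRIMIDINES:
            cls = complement_class(cls)
        counts[cls] += 1
    return ClassSpectrum6(counts)


def cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """Cosine of the angle between two spectra; undefined for zero vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise SpectrumError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def compare_to_signatures(spectrum: Spectrum96, sigs: SignatureMatrix) -> pd.DataFrame:
    """Cosine similarity of a spectrum against every signature column.

    Channels are reconciled by label; the result is sorted by descending
    similarity with ties broken by signature name.
    """
    vec = spectrum.frequencies
    if not np.any(vec):
        raise SpectrumError("cannot compare an all-zero spectrum")
    probs = sigs.reindexed(CHANNELS96)
    sims = [cosine_similarity(vec, probs[:, k]) for k in range(probs.shape[1])]
    df = pd.DataFrame({"signature": sigs.names, "cosine_similarity": sims})
    return df.sort_values(
        ["cosine_similarity", "signature"], ascending=[False, True]
    ).reset_index(drop=True)
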