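"""Strand-resolved sequence-context matrices and indel classification.

Context matrices summarise the five-nucleotide reference context (-2..+2)
around each SNV, split by raw mutation type (as read on the reference
strand) and by which side of the nearest origin the mutation fell: "right"
(first half of the span, leading side) or "left" (second half, lagging
side).  To limit contamination from synthesis continuing past the presumed
termination midpoint, only mutations in the first and last third of each
replicon are kept by default.

Indels are classified by their inserted/deleted unit (mono-/di-nucleotide
classes such as +A, -T, +TA) together with the reference homopolymer run
immediately 3' of the left-aligned event — the slippage fingerprint.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import Genome, MutationRecord
from .replicon import LocatedMutation, RepliconModel

__all__ = [
    "ContextMatrix",
    "IndelCall",
    "build_context_matrices",
    "classify_indel",
    "homopolymer_run",
    "indel_spectrum",
]

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class ContextMatrix:
    """Position-frequency matrix of the 5-nt context of one mutation type."""

    cls: str  # raw type as read on the reference strand, e.g. "T>A"
    side: str  # "right" (leading side) | "left" (lagging side)
    counts: np.ndarray  # shape (5, 4): positions -2..+2 x bases ACGT
    n: int

    @property
    def frequencies(self) -> np.ndarray:
        if self.n == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.frequencies, index=[-2, -1, 0, 1, 2], columns=list(_BASES)
        )


def build_context_matrices(
    located: Sequence[LocatedMutation],
    genome: Genome,
    restrict_thirds: bool = True,
    flank: int = 2,
) -> dict[tuple[str, str], ContextMatrix]:
    """Per-(raw type, side) context matrices from located SNVs.

    Mutations in the middle third are dropped when ``restrict_thirds``;
    mutations whose 5-nt context is truncated by a chromosome end or
    contains N are excluded.
    """
    size = 2 * flank + 1
    counts: dict[tuple[str, str], np.ndarray] = defaultdict(
        lambda: np.zeros((size, 4), dtype=np.int64)
    )
    totals: dict[tuple[str, str], int] = defaultdict(int)
    for lm in located:
        m = lm.record
        if m.kind != "SNV":
            continue
        if restrict_thirds and lm.third == "middle":
            continue
        ctx = genome.context(m.chrom, m.pos, flank=flank)
        if ctx is None or "N" in ctx:
            continue
        key = (f"{m.ref}>{m.alt}", lm.side)
        for offset, base in enumerate(ctx):
            counts[key][offset, _BASE_IDX[base]] += 1
        totals[key] += 1
    return {
        key: ContextMatrix(key[0], key[1], counts[key], totals[key]) for key in counts
    }


def homopolymer_run(genome: Genome, chrom: str, start: int) -> tuple[str, int]:
    """Base and length of the reference homopolymer starting at ``start``
    (1-based); length 0 when start is past the chromosome end."""
    seq = genome.sequences[chrom]
    if start > len(seq):
        return "", 0
    base = seq[start - 1]
    i = start - 1
    while i < len(seq) and seq[i] == base:
        i += 1
    return base, i - (start - 1)


@dataclass
class IndelCall:
    """One classified insertion/deletion."""

    record: MutationRecord
    kind: str  # INS | DEL
    unit: str  # inserted/deleted bases
    unit_class: str  # e.g. "+A", "-TA", "+other"
    hp_base: str  # base of the homopolymer run 3' of the event
    hp_len: int
    strand_class: str | None  # leading | lagging | None (not locatable)


def classify_indel(
    m: MutationRecord, genome: Genome, model: RepliconModel | None = None
) -> IndelCall:
    """Classify a left-aligned indel by unit and 3' homopolymer context.

    The run is measured on the reference strand starting at the base
    immediately 3' of the anchor position (for deletions this includes the
    deleted bases themselves, which precede the conserved run).  Units longer
    than 2 nt are classed "+other"/"-other" but retained in totals.
    """
    if m.kind not in ("INS", "DEL"):
        raise ValueError(f"not an indel: {m.chrom}:{m.pos} {m.ref}>{m.alt}")
    unit = m.alt[len(m.ref):] if m.kind == "INS" else m.ref[len(m.alt):]
    sign = "+" if m.kind == "INS" else "-"
    unit_class = f"{sign}{unit}" if len(unit) <= 2 else f"{sign}other"
    hp_base, hp_len = homopolymer_run(genome, m.chrom, m.pos + 1)
    strand = None
    if model is not None:
        hit = model.locate_pos(m.chrom, m.pos)
        if hit is not None:
            strand = "leading" if hit[1] < 50.0 else "lagging"
    return IndelCall(m, m.kind, unit, unit_class, hp_base, hp_len, strand)


def indel_spectrum(
    calls: Iterable[IndelCall],
    by_strand: bool = False,
    total_passages: float | None = None,
) -> pd.DataFrame:
    """Counts (and fractions within INS/DEL) per indel unit class.

    With ``by_strand`` the table adds leading/lagging columns.  When
    ``total_passages`` is given (summed over contributing samples) a
    per-passage rate column is included.
    """
    calls = list(calls)
    rows: dict[str, dict] = {}
    kind_totals = {"INS": 0, "DEL": 0}
    for c in calls:
        kind_totals[c.kind] += 1
        row = rows.setdefault(
            c.unit_class,
            {"unit_class": c.unit_class, "kind": c.kind, "count": 0,
             "n_leading": 0, "n_lagging": 0},
        )
        row["count"] += 1
        if c.strand_class == "leading":
            row["n_leading"] += 1
        elif c.strand_class == "lagging":
            row["n_lagging"] += 1
    out = []
    for row in rows.values():
        total = kind_totals[row["kind"]]
        row["fraction_of_kind"] = row["count"] / total if total else 0.0
        if total_passages:
            row["rate_per_passage"] = row["count"] / total_passages
        if not by_strand:
            row.pop("n_leading")
            row.pop("n_lagging")
        out.append(row)
    df = pd.DataFrame(out)
    if df.empty:
        cols = ["unit_class", "kind", "count", "fraction_of_kind"]
        if by_strand:
            cols += ["n_leading", "n_lagging"]
        if total_passages:
            cols += ["rate_per_passage"]
        return pd.DataFrame(columns=cols)
    return df.sort_values(["kind", "count"], ascending=[True, False]).reset_index(drop=True)
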