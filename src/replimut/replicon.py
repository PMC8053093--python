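"""Two-step replicon model: origins -> inter-origin spans -> strand classes.

Each chromosome's confirmed origins are reduced to their ARS midpoints; the
interval between two adjacent midpoints is one inter-origin span whose own
midpoint is taken as the replication-termination point.  A position inside a
span is summarised by its distance from the origin to its immediate left,
expressed as a percentage of the span length: 0% is that origin, 50% the
termination zone, 100% the next origin.  Positions left of the first or right
of the last origin of a chromosome cannot be assigned and are discarded.

The first half of a span (rel_dist < 50) is the leading-strand side of the
left origin ("right-of-origin"); the second half is the lagging-strand side
of the right origin ("left-of-origin").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import MutationRecord, OriginTable

log = logging.getLogger(__name__)

__all__ = [
    "RepliconModel",
    "LocatedMutation",
    "build_model",
    "locate",
    "locate_all",
    "pair_density_profile",
]

THIRD_LO = 100.0 / 3.0
THIRD_HI = 200.0 / 3.0


@dataclass(frozen=True)
class LocatedMutation:
    """A mutation assigned to an inter-origin span."""

    record: MutationRecord
    chrom: str
    span: int  # index of the span on its chromosome (0-based)
    rel_dist: float  # percentage in [0, 100)
    strand_class: str  # "leading" | "lagging"
    third: str  # "first" | "middle" | "last"

    @property
    def side(self) -> str:
        """Alias used by the sequence-context analysis: right-of-origin for
        the leading half, left-of-origin for the lagging half."""
        return "right" if self.strand_class == "leading" else "left"


class RepliconModel:
    """Per-chromosome origin midpoints and inter-origin spans."""

    def __init__(self, midpoints: dict[str, np.ndarray]):
        self.midpoints = {c: np.asarray(m, dtype=np.int64) for c, m in midpoints.items()}
        for chrom, mids in self.midpoints.items():
            if np.any(np.diff(mids) <= 0):
                raise ValueError(f"midpoints on {chrom} not strictly increasing")

    def spans(self, chrom: str) -> list[tuple[int, float, int]]:
        """(left origin, termination, right origin) triples for a chromosome."""
        mids = self.midpoints.get(chrom)
        if mids is None or len(mids) < 2:
            return []
        return [
            (int(mids[i]), (int(mids[i]) + int(mids[i + 1])) / 2.0, int(mids[i + 1]))
            for i in range(len(mids) - 1)
        ]

    @property
    def n_spans(self) -> int:
        return sum(max(0, len(m) - 1) for m in self.midpoints.values())

    def covered_length(self, chrom: str) -> int:
        mids = self.midpoints.get(chrom)
        if mids is None or len(mids) < 2:
            return 0
        return int(mids[-1] - mids[0])

    def locate_pos(self, chrom: str, pos: int) -> tuple[int, float] | None:
        """Span index and relative distance (%) for a position, or None when
        the position falls outside ``[first origin, last origin)`` or the
        chromosome has fewer than two origins.  Spans are half-open: a
        position equal to an interior origin midpoint starts the next span.
        """
        mids = self.midpoints.get(chrom)
        if mids is None or len(mids) < 2:
            return None
        if pos < mids[0] or pos >= mids[-1]:
            return None
        i = int(np.searchsorted(mids, pos, side="right")) - 1
        left, right = int(mids[i]), int(mids[i + 1])
        rel = 100.0 * (pos - left) / (right - left)
        return i, rel


def build_model(table: OriginTable) -> RepliconModel:
    """Build the replicon model from an origin table.

    Origin location = floor of the ARS interval midpoint; duplicate midpoints
    are collapsed.  Chromosomes with fewer than two origins yield no spans
    (a warning is logged).
    """
    midpoints: dict[str, np.ndarray] = {}
    for chrom, rows in table.origins.items():
        mids = sorted({(start + end) // 2 for start, end in rows})
        if len(mids) < 2:
            log.warning("chromosome %s has <2 origins: no spans", chrom)
        midpoints[chrom] = np.asarray(mids, dtype=np.int64)
    return RepliconModel(midpoints)


def _classify(rel: float) -> tuple[str, str]:
    strand = "leading" if rel < 50.0 else "lagging"
    if rel < THIRD_LO:
        third = "first"
    elif rel > THIRD_HI:
        third = "last"
    else:
        third = "middle"
    return strand, third


def locate(m: MutationRecord, model: RepliconModel) -> LocatedMutation | None:
    """Localise one mutation; None when it cannot be assigned to a span."""
    hit = model.locate_pos(m.chrom, m.pos)
    if hit is None:
        return None
    span, rel = hit
    strand, third = _classify(rel)
    return LocatedMutation(m, m.chrom, span, rel, strand, third)


def locate_all(
    records: Iterable[MutationRecord], model: RepliconModel
) -> tuple[list[LocatedMutation], list[MutationRecord]]:
    """Localise a collection; returns (located, discarded)."""
    located: list[LocatedMutation] = []
    discarded: list[MutationRecord] = []
    for m in records:
        hit = locate(m, model)
        if hit is None:
            discarded.append(m)
        else:
            located.append(hit)
    if discarded:
        log.info("discarded %d mutation(s) outside origin-bounded territory", len(discarded))
    return located, discarded


def pair_density_profile(
    located: Sequence[LocatedMutation],
    pair: tuple[str, str],
    n_bins: int = 10,
) -> dict[str, np.ndarray]:
    """Density histograms of rel_dist over [0, 100) for each member of a
    complementary mutation pair, as read on the reference strand.

    Densities integrate to 1 over [0, 100] for non-empty members; empty
    members give a zero vector.
    """
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    out: dict[str, np.ndarray] = {}
    for cls in pair:
        dists = np.array(
            [lm.rel_dist for lm in located if lm.record.snv_class == cls], dtype=float
        )
        if len(dists) == 0:
            out[cls] = np.zeros(n_bins)
        else:
            hist, _ = np.histogram(dists, bins=edges, density=True)
            out[cls] = hist
    return out
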