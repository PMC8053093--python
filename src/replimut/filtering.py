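"""Post-calling variant filters and sample QC for MA cohorts.

Stage order (order-stable on permuted input):

1. hard filters — flag records failing DP/DV/QUAL/GQ thresholds or SNVs
   within ``snp_gap`` bp of an indel in the same sample (records are flagged,
   not removed, mirroring ``bcftools filter -m+``);
2. control subtraction — exact (chrom, pos, ref, alt) matches against
   control-sample variants are dropped;
3. prevalence-scaled quality filter — a record is removed when its QUAL is
   below ``intercept + slope x prevalence``, prevalence being the number of
   distinct samples carrying the identical variant.  Recurrent low-quality
   calls are systematic sequencing errors in a bottleneck design, so the
   threshold climbs with sharing; the small-population mode uses a shallower
   slope because genuine mutations are shared through colony ancestry;
4. colony intersection — single-cell lines keep a variant only when every
   sequenced colony of the line carries it (a sole colony keeps everything);
   variants present at passage 0 are dropped in both modes;
5. per-line deduplication — one representative (max QUAL, ties to the
   lexicographically smallest sample) per variant per line.

Also provides allele-frequency ploidy inference and codon-level genotype
confirmation.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import MutationRecord, SampleMeta

__all__ = [
    "FilterConfig",
    "PloidyCall",
    "apply_hard_filters",
    "subtract_controls",
    "prevalence_quality_filter",
    "intersect_colonies",
    "dedup_line_mutations",
    "infer_ploidy",
    "check_genotype",
    "filter_cohort",
    "FilterOutcome",
]

#: Default prevalence-threshold slopes per stringency mode (QUAL units per
#: carrier sample), calibrated so a typical cohort loses ~1-10% of calls.
DEFAULT_SLOPES = {"single_cell": 15.0, "small_population": 2.0}


@dataclass
class FilterConfig:
    """Thresholds for the hard and prevalence filters."""

    min_dp: int = 10
    min_dv: int = 3
    min_qual_snv: float = 100.0
    min_qual_indel: float = 30.0
    min_gq: float = 40.0
    snp_gap: int = 7
    stringency: str = "single_cell"  # single_cell | small_population
    prevalence_intercept: float = 60.0
    prevalence_slope: float | None = None  # None -> stringency default
    missing_fails: bool = True  # records lacking DP/DV/GQ fail those checks

    def __post_init__(self) -> None:
        if self.stringency not in DEFAULT_SLOPES:
            raise ValueError(f"unknown stringency {self.stringency!r}")
        for name in ("min_dp", "min_dv", "min_qual_snv", "min_qual_indel", "min_gq", "snp_gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def slope(self) -> float:
        if self.prevalence_slope is not None:
            return self.prevalence_slope
        return DEFAULT_SLOPES[self.stringency]

    def prevalence_threshold(self, prevalence: int) -> float:
        return self.prevalence_intercept + self.slope * prevalence


def apply_hard_filters(
    records: Iterable[MutationRecord], cfg: FilterConfig
) -> list[MutationRecord]:
    """Flag (never remove) records failing the hard thresholds.

    Thresholds are strict ``<`` comparisons.  SNVs within ``snp_gap`` bp of
    any indel in the same sample are flagged ``snp_gap`` regardless of the
    indel's own flags.
    """
    recs = list(records)
    indels_by_sample: dict[str, list[MutationRecord]] = defaultdict(list)
    for r in recs:
        if r.kind in ("INS", "DEL"):
            indels_by_sample[r.sample_id].append(r)
    for r in recs:
        if r.depth is None:
            if cfg.missing_fails:
                r.flags.add("low_dp")
        elif r.depth < cfg.min_dp:
            r.flags.add("low_dp")
        if r.alt_depth is None:
            if cfg.missing_fails:
                r.flags.add("low_dv")
        elif r.alt_depth < cfg.min_dv:
            r.flags.add("low_dv")
        min_qual = cfg.min_qual_snv if r.kind == "SNV" else cfg.min_qual_indel
        if not (r.qual == r.qual) or r.qual < min_qual:  # NaN fails
            r.flags.add("low_qual")
        if r.gq is None:
            if cfg.missing_fails:
                r.flags.add("low_gq")
        elif r.gq < cfg.min_gq:
            r.flags.add("low_gq")
    for r in recs:
        if r.kind != "SNV":
            continue
        for ind in indels_by_sample.get(r.sample_id, ()):
            lo, hi = ind.pos, ind.pos + len(ind.ref) - 1
            dist = 0 if lo <= r.pos <= hi else min(abs(r.pos - lo), abs(r.pos - hi))
            if dist <= cfg.snp_gap:
                r.flags.add("snp_gap")
                break
    return recs


def passing(records: Iterable[MutationRecord]) -> list[MutationRecord]:
    """Records carrying no filter-failure flags."""
    return [r for r in records if not r.flags]


def subtract_controls(
    records: Iterable[MutationRecord],
    controls: Iterable[MutationRecord] | set[tuple[str, int, str, str]],
) -> list[MutationRecord]:
    """Drop records whose (chrom, pos, ref, alt) key occurs in the controls.

    Same position with a different ALT is retained.  Idempotent.
    """
    if isinstance(controls, set):
        keys = controls
    else:
        keys = {c.key for c in controls}
    return [r for r in records if r.key not in keys]


def prevalence_quality_filter(
    records: Iterable[MutationRecord], cfg: FilterConfig
) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Remove records whose QUAL falls below the prevalence-scaled threshold.

    Prevalence counts distinct samples carrying the identical variant among
    the supplied records (i.e. after the preceding stages).  Returns
    (kept, removed).
    """
    recs = list(records)
    carriers: dict[tuple, set[str]] = defaultdict(set)
    for r in recs:
        carriers[r.key].add(r.sample_id)
    kept, removed = [], []
    for r in recs:
        threshold = cfg.prevalence_threshold(len(carriers[r.key]))
        if r.qual < threshold:
            r.flags.add("prevalence")
            removed.append(r)
        else:
            kept.append(r)
    return kept, removed


def intersect_colonies(
    line_records: Mapping[str, Sequence[MutationRecord]],
    mode: str,
    passage0_keys: set[tuple[str, int, str, str]] | None = None,
) -> list[MutationRecord]:
    """Colony-level consensus for one MA line.

    ``line_records`` maps colony sample_id -> its records.  single_cell mode
    keeps a variant only when every colony carries it (all variants of a sole
    colony are retained); small_population mode applies no intersection.
    Variants present at passage 0 are dropped in both modes.  The returned
    representative per key is the max-QUAL record (ties to the smallest
    sample_id).
    """
    if not line_records:
        raise ValueError("line has no colonies")
    passage0_keys = passage0_keys or set()
    by_key: dict[tuple, list[MutationRecord]] = defaultdict(list)
    for recs in line_records.values():
        for r in recs:
            by_key[r.key].append(r)
    n_colonies = len(line_records)
    out = []
    for key, recs in by_key.items():
        if key in passage0_keys:
            continue
        carriers = {r.sample_id for r in recs}
        if mode == "single_cell" and n_colonies > 1 and len(carriers) < n_colonies:
            continue
        out.append(max(recs, key=lambda r: (r.qual, _neg_str(r.sample_id))))
    out.sort(key=lambda r: r.key)
    return out


class _neg_str(str):
    """Reverses string comparison so max() breaks QUAL ties toward the
    lexicographically smallest sample_id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def dedup_line_mutations(
    records: Iterable[MutationRecord],
) -> list[MutationRecord]:
    """One representative per (line, chrom, pos, ref, alt).

    The representative is the highest-QUAL record; QUAL ties go to the
    lexicographically smallest sample_id.  Mutations observed in different
    lines are distinct events and all retained.
    """
    best: dict[tuple, MutationRecord] = {}
    for r in records:
        k = (r.line_id, *r.key)
        cur = best.get(k)
        if cur is None or (r.qual, _neg_str(r.sample_id)) > (cur.qual, _neg_str(cur.sample_id)):
            best[k] = r
    return sorted(best.values(), key=lambda r: (r.line_id, *r.key))


# ---------------------------------------------------------------------------
# Sample QC


@dataclass
class PloidyCall:
    """Allele-frequency-based ploidy assignment for one sample."""

    sample_id: str
    median_af: float
    call: str  # haploid | diploid | indeterminate
    n_informative_alleles: int


def infer_ploidy(
    records: Sequence[MutationRecord], min_alleles: int = 5, boundary: float = 0.75
) -> PloidyCall:
    """Classify a sample from the median allele frequency of its de-novo calls.

    Median AF above the boundary (default 0.75, midway between the haploid
    expectation 1.0 and the heterozygous-diploid expectation 0.5) calls
    haploid; at or below calls diploid.  Fewer than ``min_alleles``
    informative records -> indeterminate.
    """
    sample_id = records[0].sample_id if records else ""
    afs = [r.af for r in records if r.af is not None]
    n = len(afs)
    if n < min_alleles:
        return PloidyCall(sample_id, float("nan") if n == 0 else float(np.median(afs)),
                          "indeterminate", n)
    med = float(np.median(afs))
    return PloidyCall(sample_id, med, "haploid" if med > boundary else "diploid", n)


#: Standard one-letter stop symbol produced by Biopython translation.
_STOP = "*"


def check_genotype(consensus_codon: str, expected_residue: str) -> tuple[str, str]:
    """Translate a consensus codon and compare with the expected residue.

    Returns (verdict, note) with verdict in {"pass", "fail", "indeterminate"};
    a codon containing N is indeterminate, a stop codon fails with a note.
    """
    codon = consensus_codon.upper()
    if len(codon) != 3:
        raise ValueError(f"codon must be 3 nt, got {consensus_codon!r}")
    if "N" in codon:
        return "indeterminate", "codon contains N"
    if set(codon) - set("ACGT"):
        raise ValueError(f"codon contains non-ACGTN characters: {consensus_codon!r}")
    aa = str(Seq(codon).translate())
    if aa == _STOP:
        return "fail", f"codon {codon} is a stop codon"
    if aa == expected_residue.upper():
        return "pass", f"codon {codon} encodes {aa}"
    return "fail", f"codon {codon} encodes {aa}, expected {expected_residue.upper()}"


# ---------------------------------------------------------------------------
# Whole-cohort driver


@dataclass
class FilterOutcome:
    """Result bundle of the five-stage filter pipeline."""

    final_records: list[MutationRecord]  # per-line deduplicated
    per_sample_kept: dict[str, list[MutationRecord]]  # after prevalence stage
    report: pd.DataFrame
    stage_counts: dict[str, int]


def filter_cohort(
    records_by_sample: Mapping[str, Sequence[MutationRecord]],
    sheet: Mapping[str, SampleMeta],
    cfg: FilterConfig,
) -> FilterOutcome:
    """Run hard filters, control subtraction, prevalence filter, colony
    intersection and per-line dedup over a cohort.

    Controls are the union of variants in role=control samples; passage-0
    keys come from role=passage0 samples of the same line (after hard
    filtering).  Prevalence is counted across evolved samples only.
    """
    flag_names = ("low_dp", "low_dv", "low_qual", "low_gq", "snp_gap")
    hard: dict[str, list[MutationRecord]] = {}
    rows = []
    for sid in sorted(records_by_sample):
        if sid not in sheet:
            raise ValueError(f"sample {sid!r} absent from sample sheet")
        recs = apply_hard_filters(list(records_by_sample[sid]), cfg)
        keep = passing(recs)
        counts = Counter(f for r in recs for f in r.flags)
        rows.append(
            {"sample_id": sid, "n_input": len(recs),
             **{f"n_{f}": counts.get(f, 0) for f in flag_names},
             "n_pass_hard": len(keep)}
        )
        hard[sid] = keep

    control_keys = {
        r.key
        for sid, recs in hard.items()
        if sheet[sid].role == "control"
        for r in recs
    }
    passage0_by_line: dict[str, set] = defaultdict(set)
    for sid, recs in hard.items():
        if sheet[sid].role == "passage0":
            passage0_by_line[sheet[sid].line_id].update(r.key for r in recs)

    evolved = {sid: recs for sid, recs in hard.items() if sheet[sid].role == "evolved"}
    after_control = {
        sid: subtract_controls(recs, control_keys) for sid, recs in evolved.items()
    }
    pooled = [r for sid in sorted(after_control) for r in after_control[sid]]
    kept, removed = prevalence_quality_filter(pooled, cfg)
    kept_by_sample: dict[str, list[MutationRecord]] = defaultdict(list)
    for r in kept:
        kept_by_sample[r.sample_id].append(r)
    removed_by_sample = Counter(r.sample_id for r in removed)

    lines: dict[str, dict[str, list[MutationRecord]]] = defaultdict(dict)
    for sid, recs in kept_by_sample.items():
        lines[sheet[sid].line_id][sid] = recs
    final: list[MutationRecord] = []
    for line_id in sorted(lines):
        mode = next(iter(sheet[s].propagation for s in lines[line_id]))
        consensus = intersect_colonies(
            lines[line_id], mode, passage0_by_line.get(line_id, set())
        )
        final.extend(consensus)
    final = dedup_line_mutations(final)

    for row in rows:
        sid = row["sample_id"]
        row["n_after_control"] = len(after_control.get(sid, []))
        row["n_removed_prevalence"] = removed_by_sample.get(sid, 0)
        row["n_after_prevalence"] = len(kept_by_sample.get(sid, []))
    report = pd.DataFrame(rows)
    stage_counts = {
        "input": int(report["n_input"].sum()),
        "pass_hard": int(report["n_pass_hard"].sum()),
        "after_control": sum(len(v) for v in after_control.values()),
        "after_prevalence": len(kept),
        "final": len(final),
    }
    return FilterOutcome(final, dict(kept_by_sample), report, stage_counts)
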