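"""Domain types and file I/O for mutation-accumulation analysis.

Covers the reference genome (FASTA), per-sample variant calls (VCF),
replication-origin tables (OriDB-style TSV), COSMIC-dialect signature
probability tables, the cohort sample sheet, and the genome-wide
trinucleotide census used to normalise mutation spectra.

Coordinates are 1-based and inclusive throughout, following VCF convention.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

__all__ = [
    "Genome",
    "MutationRecord",
    "SampleMeta",
    "OriginTable",
    "SignatureMatrix",
    "TrinucFreq",
    "CLASSES6",
    "CHANNELS96",
    "revcomp",
    "complement_class",
    "pyrimidine_class",
    "channel_label",
    "read_genome",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "left_align",
    "trinucleotide_census",
    "read_origins",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_signatures",
]

# ---------------------------------------------------------------------------
# Alphabet helpers

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
VALID_BASES = frozenset("ACGTN")
PYRIMIDINES = frozenset("CT")

#: The six pyrimidine-referenced substitution classes, in COSMIC order.
CLASSES6 = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: All twelve raw substitution classes as read on the reference strand.
CLASSES12 = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_class(cls: str) -> str:
    """Complementary substitution class (e.g. ``A>C`` -> ``T>G``)."""
    r, a = cls.split(">")
    return f"{r.translate(_COMPLEMENT)}>{a.translate(_COMPLEMENT)}"


def pyrimidine_class(cls: str) -> str:
    """Map a raw class to its pyrimidine-referenced representative."""
    return cls if cls[0] in PYRIMIDINES else complement_class(cls)


def channel_label(cls: str, context: str) -> str:
    """COSMIC-style channel label, e.g. ``A[C>A]A`` from class and trinucleotide."""
    return f"{context[0]}[{cls}]{context[2]}"


def _make_channels96() -> tuple[str, ...]:
    labels = []
    for cls in CLASSES6:
        for five in "ACGT":
            for three in "ACGT":
                labels.append(f"{five}[{cls}]{three}")
    return tuple(labels)


#: The 96 pyrimidine-centred trinucleotide channels in COSMIC file order
#: (class-major, contexts lexicographic).
CHANNELS96 = _make_channels96()
CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS96)}

#: The 32 pyrimidine-centred trinucleotides (channel contexts).
TRINUCS32 = tuple(sorted({f"{f}{c}{t}" for f in "ACGT" for c in "CT" for t in "ACGT"}))
TRINUCS64 = tuple(sorted(f"{a}{b}{c}" for a in "ACGT" for b in "ACGT" for c in "ACGT"))


# ---------------------------------------------------------------------------
# Genome


class GenomeFormatError(ValueError):
    pass


@dataclass
class Genome:
    """A reference genome as uppercase A/C/G/T/N strings keyed by chromosome.

    Chromosome order is preserved (dict insertion order).
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise GenomeFormatError(f"empty sequence for record {name!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise GenomeFormatError(
                    f"record {name!r} contains illegal characters {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.sequences[chrom][pos - 1]

    def context(self, chrom: str, pos: int, flank: int = 1) -> str | None:
        """Reference context ``pos-flank .. pos+flank`` or None if truncated
        by a chromosome end."""
        seq = self.sequences[chrom]
        lo, hi = pos - 1 - flank, pos + flank
        if lo < 0 or hi > len(seq):
            return None
        return seq[lo:hi]


def read_genome(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome`, uppercasing sequences."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise GenomeFormatError(f"duplicate record name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise GenomeFormatError(f"empty sequence for record {rec.id!r}")
        sequences[rec.id] = seq
    if not sequences:
        raise GenomeFormatError(f"no FASTA records in {path}")
    return Genome(sequences)


def write_fasta(path: str | Path, genome: Genome, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Mutation records


@dataclass
class MutationRecord:
    """One called variant (one ALT allele) with quality metrics and provenance."""

    chrom: str
    pos: int  # 1-based position of REF start
    ref: str
    alt: str
    qual: float = float("nan")
    depth: int | None = None  # INFO/DP
    alt_depth: int | None = None  # FORMAT/DV
    gq: float | None = None  # FORMAT/GQ
    sample_id: str = ""
    line_id: str = ""
    kind: str = field(default="")
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if not self.kind:
            self.kind = classify_kind(self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity key used for control subtraction, prevalence and dedup."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def af(self) -> float | None:
        """Allele frequency DV/DP, or None when depth is unavailable."""
        if self.depth and self.alt_depth is not None:
            return self.alt_depth / self.depth
        return None

    @property
    def snv_class(self) -> str | None:
        """Raw substitution class as read on the reference strand (SNVs only)."""
        if self.kind == "SNV":
            return f"{self.ref}>{self.alt}"
        return None


def classify_kind(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref) and alt.startswith(ref):
        return "INS"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "DEL"
    return "OTHER"


def left_align(
    chrom: str, pos: int, ref: str, alt: str, genome: Genome
) -> tuple[int, str, str]:
    """Normalise an allele pair to its leftmost equivalent representation.

    Standard left-alignment: repeatedly trim a shared terminal base (extending
    to the left through the reference when the alleles would run out), then
    trim shared leading bases.  Idempotent; SNVs are returned unchanged.
    """
    seq = genome.sequences[chrom]
    ref, alt = ref.upper(), alt.upper()
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif ref[-1] == alt[-1] and pos > 1:
            b = seq[pos - 2]
            ref, alt = b + ref[:-1], b + alt[:-1]
            pos -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


# ---------------------------------------------------------------------------
# Sample sheet


@dataclass
class SampleMeta:
    """Metadata for one sequenced colony/sample."""

    sample_id: str
    line_id: str
    genotype: str = ""
    ploidy: str = "unknown"  # haploid | diploid | unknown
    propagation: str = "single_cell"  # single_cell | small_population
    role: str = "evolved"  # evolved | passage0 | control
    passages: int = 0

    def __post_init__(self) -> None:
        if self.role == "evolved" and self.passages <= 0:
            raise ValueError(
                f"evolved sample {self.sample_id!r} must have passages > 0"
            )


SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "line_id",
    "genotype",
    "ploidy",
    "propagation",
    "role",
    "passages",
)


def read_sample_sheet(path: str | Path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    sheet: dict[str, SampleMeta] = {}
    for row in df.itertuples(index=False):
        meta = SampleMeta(
            sample_id=row.sample_id,
            line_id=row.line_id,
            genotype=row.genotype,
            ploidy=row.ploidy or "unknown",
            propagation=row.propagation or "single_cell",
            role=row.role or "evolved",
            passages=int(row.passages or 0),
        )
        if meta.sample_id in sheet:
            raise ValueError(f"duplicate sample_id {meta.sample_id!r}")
        sheet[meta.sample_id] = meta
    return sheet


def write_sample_sheet(path: str | Path, samples: Iterable[SampleMeta]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SAMPLE_SHEET_COLUMNS)
        for s in samples:
            w.writerow(
                [s.sample_id, s.line_id, s.genotype, s.ploidy, s.propagation, s.role, s.passages]
            )


# ---------------------------------------------------------------------------
# VCF


def read_vcf(
    path: str | Path,
    sample_sheet: Mapping[str, SampleMeta] | None = None,
    genome: Genome | None = None,
) -> list[MutationRecord]:
    """Read a VCF into :class:`MutationRecord` objects.

    One record per ALT allele (multiallelic sites are split).  When a genome
    is supplied, indels are left-aligned against it.  When a sample sheet is
    supplied, each VCF sample must appear in it (line_id is filled in from
    the sheet); unknown samples raise.
    """
    records: list[MutationRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        if sample_sheet is not None:
            unknown = [s for s in vcf_samples if s not in sample_sheet]
            if unknown:
                raise ValueError(
                    f"VCF sample(s) {unknown} absent from sample sheet ({path})"
                )
        for rec in vf:
            if not rec.alts:
                continue
            try:
                dp = rec.info.get("DP")
            except (KeyError, ValueError):  # DP not declared in the header
                dp = None
            for alt in rec.alts:
                if alt is None or alt in {"<*>", "*", "."}:
                    continue
                for sname in vcf_samples or [""]:
                    dv = gq = None
                    if sname:
                        fmt = rec.samples[sname]
                        try:
                            dv = fmt.get("DV")
                            gq = fmt.get("GQ")
                        except (KeyError, ValueError):  # not declared
                            dv = gq = None
                    pos, ref_a, alt_a = rec.pos, rec.ref, alt
                    if genome is not None and (len(ref_a) != 1 or len(alt_a) != 1):
                        pos, ref_a, alt_a = left_align(
                            rec.contig, rec.pos, ref_a, alt_a, genome
                        )
                    line_id = (
                        sample_sheet[sname].line_id
                        if sample_sheet is not None and sname
                        else ""
                    )
                    records.append(
                        MutationRecord(
                            chrom=rec.contig,
                            pos=pos,
                            ref=ref_a,
                            alt=alt_a,
                            qual=rec.qual if rec.qual is not None else float("nan"),
                            depth=int(dp) if dp is not None else None,
                            alt_depth=int(dv) if dv is not None else None,
                            gq=float(gq) if gq is not None else None,
                            sample_id=sname,
                            line_id=line_id,
                        )
                    )
    return records


_VCF_META = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DV,Number=1,Type=Integer,Description="Number of high-quality non-reference bases">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def write_vcf(
    path: str | Path,
    records: Sequence[MutationRecord],
    contigs: Mapping[str, int],
    sample_id: str,
) -> None:
    """Write single-sample VCF v4.2.  Records are sorted by (chrom, pos) with
    chromosome order taken from ``contigs``."""
    order = {c: i for i, c in enumerate(contigs)}
    recs = sorted(records, key=lambda r: (order.get(r.chrom, 1 << 30), r.pos, r.ref, r.alt))
    with open(path, "w") as fh:
        fh.write(_VCF_META)
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id + "\n"
        )
        for r in recs:
            dp = f"DP={r.depth}" if r.depth is not None else "."
            dv = str(r.alt_depth) if r.alt_depth is not None else "."
            gq = str(int(r.gq)) if r.gq is not None else "."
            qual = f"{r.qual:g}" if r.qual == r.qual else "."
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{qual}\t.\t{dp}\t"
                f"GT:DV:GQ\t1/1:{dv}:{gq}\n"
            )


# ---------------------------------------------------------------------------
# Origin table


@dataclass
class OriginTable:
    """Replication-origin (ARS) intervals per chromosome, 1-based inclusive."""

    origins: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        for chrom, rows in self.origins.items():
            for start, end in rows:
                if start > end:
                    raise ValueError(
                        f"origin on {chrom} has start {start} > end {end}"
                    )
            rows.sort()

    @property
    def n_origins(self) -> int:
        return sum(len(v) for v in self.origins.values())


def read_origins(
    path: str | Path,
    chrom_col: str = "chr",
    start_col: str = "start",
    end_col: str = "end",
    status_col: str = "status",
    keep_status: str | None = "confirmed",
) -> OriginTable:
    """Read an OriDB-style tab-delimited origin table.

    Rows whose status differs from ``keep_status`` (case-insensitive) are
    dropped; pass ``keep_status=None`` to retain everything.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        log.warning("origin table %s is empty", path)
        return OriginTable({})
    if df.empty:
        log.warning("origin table %s is empty", path)
        return OriginTable({})
    for col in (chrom_col, start_col, end_col):
        if col not in df.columns:
            raise ValueError(f"origin table missing column {col!r}")
    if keep_status is not None:
        if status_col not in df.columns:
            raise ValueError(f"origin table missing column {status_col!r}")
        df = df[df[status_col].str.strip().str.lower() == keep_status.lower()]
    origins: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        chrom = getattr(row, chrom_col)
        start, end = int(getattr(row, start_col)), int(getattr(row, end_col))
        origins.setdefault(chrom, []).append((start, end))
    return OriginTable(origins)


def write_origins(path: str | Path, table: OriginTable) -> None:
    with open(path, "w") as fh:
        fh.write("chr\tstart\tend\tstatus\n")
        for chrom, rows in table.origins.items():
            for start, end in rows:
                fh.write(f"{chrom}\t{start}\t{end}\tConfirmed\n")


# ---------------------------------------------------------------------------
# Signature matrix


@dataclass
class SignatureMatrix:
    """COSMIC-style 96-channel signature probabilities (channels x signatures)."""

    channels: tuple[str, ...]
    names: tuple[str, ...]
    probs: np.ndarray  # shape (96, K)

    def __post_init__(self) -> None:
        if len(self.channels) != 96:
            raise ValueError(f"expected 96 channels, got {len(self.channels)}")
        if len(set(self.channels)) != 96:
            raise ValueError("duplicate channel labels")
        sums = self.probs.sum(axis=0)
        off = np.abs(sums - 1.0) > 1e-3
        if off.any():
            bad = [self.names[i] for i in np.flatnonzero(off)]
            raise ValueError(f"signature columns do not sum to 1: {bad}")

    def column(self, name: str) -> np.ndarray:
        return self.probs[:, self.names.index(name)]

    def reindexed(self, channel_order: Sequence[str]) -> np.ndarray:
        """Probabilities reordered to ``channel_order``; unmatched labels raise."""
        index = {c: i for i, c in enumerate(self.channels)}
        missing = [c for c in channel_order if c not in index]
        if missing:
            raise ValueError(f"channels absent from signature table: {missing[:5]}")
        rows = [index[c] for c in channel_order]
        return self.probs[rows, :]


def read_signatures(path: str | Path) -> SignatureMatrix:
    """Parse a COSMIC-dialect signature table.

    Expects 'Substitution Type' and 'Trinucleotide' columns (an optional
    'Somatic Mutation Type' column is ignored) followed by one column per
    signature; exactly 96 unique channels are required.
    """
    df = pd.read_csv(path, sep="\t")
    df = df.loc[:, ~df.columns.str.match(r"Unnamed")]
    cols = {c.strip().lower(): c for c in df.columns}
    sub_col = cols.get("substitution type")
    tri_col = cols.get("trinucleotide")
    if sub_col is None or tri_col is None:
        raise ValueError(
            "signature table needs 'Substitution Type' and 'Trinucleotide' columns"
        )
    labels = [
        channel_label(s.strip(), t.strip())
        for s, t in zip(df[sub_col], df[tri_col])
    ]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate channel(s): {dupes[:5]}")
    missing = sorted(set(CHANNELS96) - set(labels))
    if missing:
        raise ValueError(f"missing channel(s): {missing[:5]}")
    sig_cols = [
        c
        for c in df.columns
        if c not in (sub_col, tri_col) and c.strip().lower() != "somatic mutation type"
    ]
    probs = df[sig_cols].to_numpy(dtype=float)
    return SignatureMatrix(tuple(labels), tuple(str(c) for c in sig_cols), probs)


# ---------------------------------------------------------------------------
# Trinucleotide census

_BASE_LUT = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _BASE_LUT[ord(b)] = i


@dataclass
class TrinucFreq:
    """Relative genome abundance of trinucleotides.

    ``collapsed`` mode uses the 32 pyrimidine-centred representatives (each
    3-mer pooled with its reverse complement); uncollapsed mode uses all 64.
    """

    freqs: dict[str, float]
    collapsed: bool

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if self.freqs and abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, expected 1")
        if any(v < 0 for v in self.freqs.values()):
            raise ValueError("negative abundance")

    def channel_abundance(self, context: str) -> float:
        """Genome abundance of a (pyrimidine-centred) channel context.

        In uncollapsed mode the context and its reverse complement are summed
        so the value is comparable across modes.
        """
        if self.collapsed:
            return self.freqs.get(context, 0.0)
        return self.freqs.get(context, 0.0) + self.freqs.get(revcomp(context), 0.0)


def trinucleotide_census(genome: Genome, collapsed: bool = True) -> TrinucFreq:
    """Count every overlapping 3-mer on the reference strand.

    Windows containing N are excluded; chromosome ends contribute no partial
    windows.  In collapsed mode each 3-mer is pooled with its reverse
    complement under the pyrimidine-centred representative.
    """
    counts = np.zeros(64, dtype=np.int64)
    any_window = False
    for seq in genome.sequences.values():
        if len(seq) < 3:
            continue
        codes = _BASE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
        a, b, c = codes[:-2], codes[1:-1], codes[2:]
        valid = (a < 4) & (b < 4) & (c < 4)
        if valid.any():
            any_window = True
            idx = (a[valid].astype(np.int64) * 16 + b[valid] * 4 + c[valid])
            counts += np.bincount(idx, minlength=64)
    if not any_window:
        raise ValueError("no chromosome provides a full N-free 3-mer window")
    total = counts.sum()
    if collapsed:
        pooled: dict[str, float] = {t: 0.0 for t in TRINUCS32}
        for i, tri in enumerate(TRINUCS64):
            rep = tri if tri[1] in PYRIMIDINES else revcomp(tri)
            pooled[rep] += counts[i]
        freqs = {t: v / total for t, v in pooled.items()}
    else:
        freqs = {t: counts[i] / total for i, t in enumerate(TRINUCS64)}
    return TrinucFreq(freqs, collapsed=collapsed)
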