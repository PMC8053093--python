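"""Synthetic MA-cohort generator with ground truth.

Builds toy genomes with planted T-homopolymers and evenly spaced confirmed
origins, then simulates mutation-accumulation cohorts whose mutational
parameters are known exactly: a 96-channel SNV spectrum, per-class
leading/lagging asymmetry odds, homopolymer slippage indels, shared-ancestry
structure (single-cell vs small-population passaging), passage-0 background
variants, control-sample variants, and low-quality artifacts recurring across
samples.  Every emitted record carries a truth entry, so downstream filters
and statistics can be scored against what was planted.

All randomness flows from ``SimConfig.seed``; a fixed seed reproduces the
cohort bit-identically.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from .io import (
    CHANNELS96,
    Genome,
    MutationRecord,
    OriginTable,
    SampleMeta,
    complement_class,
    revcomp,
    write_fasta,
    write_origins,
    write_sample_sheet,
    write_vcf,
)
from .replicon import RepliconModel, build_model

__all__ = [
    "SimConfig",
    "SimTruth",
    "TruthEntry",
    "ToyGenome",
    "Cohort",
    "make_toy_genome",
    "SnvSimulator",
    "simulate_snvs",
    "simulate_indels",
    "simulate_cohort",
    "write_cohort",
]


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the single-cell bottleneck arm of a proofreading-mutant
    MA experiment: heterozygous diploid lines, 26 passages, two colonies per
    line, a leading-strand bias for A>C/A>T/G>T (odds 3, Cohen's w 0.5 at the
    two-cell collapse) and a weaker one for A>G/G>A, homopolymer +A/+T
    slippage, and recurrent low-quality artifacts shared by 10 samples.
    """

    seed: int = 0
    # genome geometry
    n_chromosomes: int = 2
    chromosome_length: int = 100_000
    origin_spacing: int = 15_000
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    n_homopolymers_per_chrom: int = 30
    # SNV process
    channel_probs: np.ndarray | None = None  # length 96, CHANNELS96 order
    n_snv_per_sample: float = 50.0
    asymmetry: dict[str, float] = field(
        default_factory=lambda: {"A>C": 3.0, "A>T": 3.0, "G>T": 3.0, "A>G": 1.5, "G>A": 1.5}
    )
    # indel process (per eligible homopolymer run per sample)
    ins_rate_homopolymer: float = 0.01
    del_rate: float = 0.005
    # cohort structure
    n_lines: int = 6
    colonies_per_line: int = 2
    propagation: str = "single_cell"  # single_cell | small_population
    shared_fraction: float = 0.5
    ploidy: str = "diploid"
    passages: int = 26
    genotype: str = "pol2-L439V/POL2"
    n_passage0_variants: int = 10
    n_control_variants: int = 20
    n_false_positives: int = 5  # private per colony
    # artifacts (systematic errors recurring across samples)
    artifact_count: int = 50
    artifact_prevalence: int = 10
    artifact_qual_range: tuple[float, float] = (110.0, 180.0)
    true_qual_range: tuple[float, float] = (120.0, 225.0)
    mean_depth: float = 40.0

    def __post_init__(self) -> None:
        if self.channel_probs is not None:
            self.channel_probs = np.asarray(self.channel_probs, dtype=float)
            if self.channel_probs.shape != (96,):
                raise SimConfigError("channel_probs must have length 96")
            if abs(float(self.channel_probs.sum()) - 1.0) > 1e-9:
                raise SimConfigError("channel_probs must sum to 1")
        for name in ("ins_rate_homopolymer", "del_rate", "n_snv_per_sample"):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.origin_spacing > self.chromosome_length:
            raise SimConfigError("origin_spacing exceeds chromosome_length")
        if self.chromosome_length < 3 * self.origin_spacing:
            raise SimConfigError("chromosome_length must be >= 3 x origin_spacing")
        if self.colonies_per_line < 1:
            raise SimConfigError("colonies_per_line must be >= 1")
        if self.propagation not in ("single_cell", "small_population"):
            raise SimConfigError(f"unknown propagation {self.propagation!r}")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise SimConfigError("shared_fraction must be in [0, 1]")

    def resolved_channel_probs(self) -> np.ndarray:
        if self.channel_probs is None:
            return np.full(96, 1.0 / 96.0)
        return self.channel_probs

    def class_odds(self, snv_class: str) -> float:
        """Leading:lagging odds for a reference-strand reading; the complement
        of a configured class defaults to the reciprocal odds (the same fork
        event observed on the opposite strand)."""
        if snv_class in self.asymmetry:
            return float(self.asymmetry[snv_class])
        comp = complement_class(snv_class)
        if comp in self.asymmetry:
            return 1.0 / float(self.asymmetry[comp])
        return 1.0


@dataclass
class TruthEntry:
    """Ground-truth labels for one emitted record in one sample."""

    category: str  # true_snv|true_indel|artifact|false_positive|passage0|control_background
    channel: str | None = None
    strand: str | None = None  # leading | lagging (strand class at the site)
    span: int | None = None
    is_artifact: bool = False
    is_shared_ancestry: bool = False


@dataclass
class SimTruth:
    """All truth labels for a simulated cohort, keyed per (sample, variant)."""

    config: SimConfig
    entries: dict[tuple[str, str, int, str, str], TruthEntry] = field(default_factory=dict)

    def add(self, sample_id: str, rec: MutationRecord, entry: TruthEntry) -> None:
        key = (sample_id, *rec.key)
        if key in self.entries:
            raise ValueError(f"duplicate truth entry for {key}")
        self.entries[key] = entry

    def lookup(self, sample_id: str, rec: MutationRecord) -> TruthEntry:
        return self.entries[(sample_id, *rec.key)]

    def keys_in_category(self, *categories: str) -> set[tuple[str, str, int, str, str]]:
        return {k for k, e in self.entries.items() if e.category in categories}

    def to_json(self, path: str | Path) -> None:
        cfg = asdict(self.config)
        if cfg["channel_probs"] is not None:
            cfg["channel_probs"] = list(map(float, cfg["channel_probs"]))
        payload = {
            "config": cfg,
            "entries": {
                "|".join(map(str, k)): asdict(e) for k, e in self.entries.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        cfg_d = payload["config"]
        cfg_d["base_probs"] = tuple(cfg_d["base_probs"])
        cfg_d["artifact_qual_range"] = tuple(cfg_d["artifact_qual_range"])
        cfg_d["true_qual_range"] = tuple(cfg_d["true_qual_range"])
        cfg = SimConfig(**cfg_d)
        truth = cls(cfg)
        for key_s, e in payload["entries"].items():
            s, chrom, pos, ref, alt = key_s.split("|")
            truth.entries[(s, chrom, int(pos), ref, alt)] = TruthEntry(**e)
        return truth


# ---------------------------------------------------------------------------
# Toy genome


@dataclass
class ToyGenome:
    genome: Genome
    origins: OriginTable
    #: planted T-homopolymers as (chrom, start [1-based], length)
    homopolymers: list[tuple[str, int, int]]


def _chrom_name(i: int) -> str:
    return f"chr{i + 1:02d}"


def make_toy_genome(cfg: SimConfig) -> ToyGenome:
    """Random genome with planted T-homopolymers and evenly spaced origins.

    Origins are spaced ~``origin_spacing`` apart with +/-10% jitter, each a
    200 bp 'Confirmed' ARS interval.  Planted homopolymers are 3-6 nt T runs
    whose flanks are forced non-T so the recorded run length is exact.
    """
    rng = np.random.default_rng([cfg.seed, 101])
    sequences: dict[str, str] = {}
    origins: dict[str, list[tuple[int, int]]] = {}
    homopolymers: list[tuple[str, int, int]] = []
    bases = np.array(list("ACGT"))
    for ci in range(cfg.n_chromosomes):
        chrom = _chrom_name(ci)
        L = cfg.chromosome_length
        seq = rng.choice(bases, size=L, p=cfg.base_probs)
        # plant T-homopolymers at well-separated random loci
        slots = rng.choice(
            np.arange(100, L - 100, 200), size=cfg.n_homopolymers_per_chrom, replace=False
        )
        for start0 in np.sort(slots):
            run = int(rng.integers(3, 7))
            seq[start0 : start0 + run] = "T"
            seq[start0 - 1] = rng.choice(list("ACG"))
            seq[start0 + run] = rng.choice(list("ACG"))
            homopolymers.append((chrom, int(start0) + 1, run))
        sequences[chrom] = "".join(seq)
        # origins every ~origin_spacing with jitter
        rows = []
        mid = cfg.origin_spacing // 2
        while mid < L - cfg.origin_spacing // 4:
            jitter = int(rng.integers(-cfg.origin_spacing // 10, cfg.origin_spacing // 10 + 1))
            centre = max(101, min(L - 101, mid + jitter))
            rows.append((centre - 100, centre + 100))
            mid += cfg.origin_spacing
        if len(rows) < 2:
            raise SimConfigError(f"chromosome {chrom} received <2 origins")
        origins[chrom] = rows
    return ToyGenome(Genome(sequences), OriginTable(origins), homopolymers)


# ---------------------------------------------------------------------------
# SNV simulation

_TRIS64 = np.array(["".join(t) for t in itertools.product("ACGT", repeat=3)])
_TRIS64_RC = np.array([revcomp(t) for t in _TRIS64])


class SnvSimulator:
    """Channel-first SNV sampler over a genome annotated with a replicon model.

    For each of the 96 channels the simulator indexes every genomic site
    whose reference trinucleotide matches the channel context on either
    strand, restricted to origin-bounded territory so a leading/lagging class
    is defined.  A mutation is drawn by sampling a channel from
    ``channel_probs`` and then a site with weights that realise the
    configured per-class leading:lagging odds.
    """

    def __init__(self, genome: Genome, model: RepliconModel, cfg: SimConfig):
        self.genome = genome
        self.model = model
        self.cfg = cfg
        self.channel_probs = cfg.resolved_channel_probs()
        self._build_registry()

    def _build_registry(self) -> None:
        ctx_sites: dict[str, list[tuple[str, np.ndarray, np.ndarray, np.ndarray, np.ndarray]]] = {}
        for chrom, seq in self.genome.sequences.items():
            mids = self.model.midpoints.get(chrom)
            if mids is None or len(mids) < 2:
                continue
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            lut = np.full(256, 4, dtype=np.int8)
            for i, b in enumerate(b"ACGT"):
                lut[b] = i
            codes = lut[arr]
            pos = np.arange(2, len(seq), dtype=np.int64)  # 1-based centre positions
            a, b_, c = codes[:-2], codes[1:-1], codes[2:]
            valid = (a >= 0) & (b_ >= 0) & (c >= 0)
            inside = (pos >= mids[0]) & (pos < mids[-1])
            keep = valid & inside
            pos = pos[keep]
            tri_idx = a[keep].astype(np.int64) * 16 + b_[keep] * 4 + c[keep]
            span_idx = np.searchsorted(mids, pos, side="right") - 1
            left = mids[span_idx]
            right = mids[span_idx + 1]
            rel = 100.0 * (pos - left) / (right - left)
            leading = rel < 50.0
            is_pyr = np.isin(b_[keep], (1, 3))  # C or T centre
            ctx = np.where(is_pyr, _TRIS64[tri_idx], _TRIS64_RC[tri_idx])
            for context in np.unique(ctx):
                sel = ctx == context
                ctx_sites.setdefault(context, []).append(
                    (chrom, pos[sel], leading[sel], is_pyr[sel], span_idx[sel])
                )
        # flatten per channel with asymmetry weights
        self._sites: dict[int, dict] = {}
        for k, channel in enumerate(CHANNELS96):
            context = channel[0] + channel[2] + channel[-1]
            cls = channel[2:5]  # e.g. "C>A"
            chunks = ctx_sites.get(context, [])
            if not chunks:
                if self.channel_probs[k] > 0:
                    raise SimConfigError(
                        f"channel {channel} has no matching site in the toy genome"
                    )
                continue
            chroms = np.concatenate([np.full(len(p), i) for i, (_, p, *_rest) in enumerate(chunks)])
            chrom_names = [c for c, *_ in chunks]
            posv = np.concatenate([p for _, p, *_ in chunks])
            leadv = np.concatenate([l for _, _, l, *_ in chunks])
            pyrv = np.concatenate([q for _, _, _, q, _ in chunks])
            spanv = np.concatenate([s for *_, s in chunks])
            comp = complement_class(cls)
            odds_pyr = self.cfg.class_odds(cls)
            odds_pur = self.cfg.class_odds(comp)
            site_odds = np.where(pyrv, odds_pyr, odds_pur)
            weights = np.where(leadv, site_odds, 1.0)
            cumw = np.cumsum(weights)
            self._sites[k] = {
                "chrom_names": chrom_names,
                "chrom_idx": chroms,
                "pos": posv,
                "leading": leadv,
                "is_pyr": pyrv,
                "span": spanv,
                "cumw": cumw,
                "cls": cls,
                "comp": comp,
            }

    def draw(
        self, n: int, rng: np.random.Generator, used: set[tuple[str, int]] | None = None
    ) -> list[tuple[MutationRecord, TruthEntry]]:
        """Draw ``n`` SNVs with replacement.

        When ``used`` is given, positions already in it are re-drawn (and the
        set is updated) so a sample never carries two calls at one site; the
        caller must keep ``n`` small relative to the matching-site pool, as
        heavy depletion would distort the configured site weights.
        """
        out: list[tuple[MutationRecord, TruthEntry]] = []
        channels = rng.choice(96, size=n, p=self.channel_probs)
        for k in channels:
            reg = self._sites[int(k)]
            cumw = reg["cumw"]
            for _attempt in range(100):
                i = int(np.searchsorted(cumw, rng.random() * cumw[-1], side="right"))
                i = min(i, len(cumw) - 1)
                chrom = reg["chrom_names"][int(reg["chrom_idx"][i])]
                pos = int(reg["pos"][i])
                if used is None or (chrom, pos) not in used:
                    break
            if used is not None:
                used.add((chrom, pos))
            cls = reg["cls"] if reg["is_pyr"][i] else reg["comp"]
            rec = MutationRecord(chrom=chrom, pos=pos, ref=cls[0], alt=cls[2])
            entry = TruthEntry(
                category="true_snv",
                channel=CHANNELS96[int(k)],
                strand="leading" if reg["leading"][i] else "lagging",
                span=int(reg["span"][i]),
            )
            out.append((rec, entry))
        return out


def simulate_snvs(
    genome: Genome,
    model: RepliconModel,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    n: int | None = None,
    simulator: SnvSimulator | None = None,
) -> tuple[list[MutationRecord], list[TruthEntry]]:
    """Simulate one sample's worth of SNVs (count Poisson(n_snv_per_sample)
    unless ``n`` is given).  Quality fields are not filled in here."""
    rng = rng if rng is not None else np.random.default_rng([cfg.seed, 202])
    sim = simulator if simulator is not None else SnvSimulator(genome, model, cfg)
    count = int(rng.poisson(cfg.n_snv_per_sample)) if n is None else n
    pairs = sim.draw(count, rng)
    return [p[0] for p in pairs], [p[1] for p in pairs]


# ---------------------------------------------------------------------------
# Indel simulation

_RUN_RE = re.compile(r"A{3,}|T{3,}")


def _homopolymer_runs(genome: Genome) -> list[tuple[str, int, int, str]]:
    """All reference A/T runs of length >= 3 as (chrom, start [1-based], len, base)."""
    runs = []
    for chrom, seq in genome.sequences.items():
        for mt in _RUN_RE.finditer(seq):
            runs.append((chrom, mt.start() + 1, mt.end() - mt.start(), mt.group()[0]))
    return runs


def simulate_indels(
    genome: Genome,
    model: RepliconModel,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[MutationRecord], list[TruthEntry]]:
    """Simulate homopolymer slippage indels for one sample.

    The leading-strand polymerase slipping on a T template appears in
    reference coordinates as +A/-A at reference A-runs in leading-class
    territory and as +T/-T at reference T-runs in lagging-class territory.
    Events are emitted left-aligned (anchor base just 5' of the run).
    """
    rng = rng if rng is not None else np.random.default_rng([cfg.seed, 303])
    runs = _homopolymer_runs(genome)
    if not runs:
        raise SimConfigError("genome contains no A/T homopolymer runs")
    out: list[tuple[MutationRecord, TruthEntry]] = []
    for chrom, start, length, base in runs:
        if start < 2:
            continue  # no left anchor available
        hit = model.locate_pos(chrom, start)
        if hit is None:
            continue
        span, rel = hit
        leading = rel < 50.0
        if not ((base == "A" and leading) or (base == "T" and not leading)):
            continue
        anchor = genome.base(chrom, start - 1)
        strand = "leading" if leading else "lagging"
        if rng.random() < cfg.ins_rate_homopolymer:
            rec = MutationRecord(chrom=chrom, pos=start - 1, ref=anchor, alt=anchor + base)
            out.append((rec, TruthEntry("true_indel", strand=strand, span=span)))
        if rng.random() < cfg.del_rate:
            rec = MutationRecord(chrom=chrom, pos=start - 1, ref=anchor + base, alt=anchor)
            out.append((rec, TruthEntry("true_indel", strand=strand, span=span)))
    return [p[0] for p in out], [p[1] for p in out]


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass
class Cohort:
    """An in-memory simulated cohort plus its ground truth."""

    genome: Genome
    origins: OriginTable
    model: RepliconModel
    homopolymers: list[tuple[str, int, int]]
    samples: list[SampleMeta]
    records: dict[str, list[MutationRecord]]  # sample_id -> records
    truth: SimTruth


def _fill_quality(
    rec: MutationRecord,
    rng: np.random.Generator,
    qual_range: tuple[float, float],
    cfg: SimConfig,
    ploidy: str,
) -> MutationRecord:
    rec.qual = float(rng.uniform(*qual_range))
    rec.depth = max(1, int(rng.poisson(cfg.mean_depth)))
    af = 1.0 if ploidy == "haploid" else 0.5
    rec.alt_depth = int(rng.binomial(rec.depth, af))
    rec.gq = float(rng.integers(50, 100))
    return rec


def _copy(rec: MutationRecord) -> MutationRecord:
    return MutationRecord(
        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alt, kind=rec.kind
    )


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Simulate a full MA cohort with per-sample records and truth labels.

    single_cell: each line's true mutation set is carried by all its colonies
    (plus per-colony private false positives).  small_population: colonies of
    a line share a ``shared_fraction`` ancestral subset and carry private
    draws for the rest.  Background variants present in every sample
    (including controls) model strain-vs-reference differences; passage-0
    variants are present in a line's passage-0 sample and all its colonies;
    artifacts recur at identical positions in ``artifact_prevalence`` random
    evolved samples with low quality.
    """
    toy = make_toy_genome(cfg)
    model = build_model(toy.origins)
    sim = SnvSimulator(toy.genome, model, cfg)
    rng = np.random.default_rng([cfg.seed, 404])
    truth = SimTruth(cfg)
    samples: list[SampleMeta] = []
    records: dict[str, list[MutationRecord]] = {}
    used: set[tuple[str, int]] = set()

    def add_record(sample_id: str, rec: MutationRecord, entry: TruthEntry) -> None:
        key = (sample_id, *rec.key)
        if key in truth.entries:
            return  # collision within a sample: keep first occurrence
        truth.entries[key] = entry
        records[sample_id].append(rec)

    # control sample + background variants present everywhere
    control_meta = SampleMeta("CTRL1", "CTRL", genotype="reference", ploidy=cfg.ploidy,
                              propagation=cfg.propagation, role="control", passages=0)
    samples.append(control_meta)
    records["CTRL1"] = []
    background = sim.draw(cfg.n_control_variants, rng, used)

    all_sample_meta: list[SampleMeta] = []
    evolved_ids: list[str] = []
    line_payload: dict[str, dict] = {}
    for li in range(cfg.n_lines):
        line = f"L{li + 1:02d}"
        p0_id = f"{line}P0"
        p0_meta = SampleMeta(p0_id, line, genotype=cfg.genotype, ploidy=cfg.ploidy,
                             propagation=cfg.propagation, role="passage0", passages=0)
        samples.append(p0_meta)
        records[p0_id] = []
        passage0 = sim.draw(cfg.n_passage0_variants, rng, used)

        snvs = sim.draw(int(rng.poisson(cfg.n_snv_per_sample)), rng, used)
        indel_recs, indel_truth = simulate_indels(toy.genome, model, cfg, rng)
        true_set = snvs + list(zip(indel_recs, indel_truth))
        colony_ids = []
        for c in range(cfg.colonies_per_line):
            sid = f"{line}C{c + 1}"
            colony_ids.append(sid)
            samples.append(
                SampleMeta(sid, line, genotype=cfg.genotype, ploidy=cfg.ploidy,
                           propagation=cfg.propagation, role="evolved", passages=cfg.passages)
            )
            records[sid] = []
            evolved_ids.append(sid)
        line_payload[line] = {
            "passage0": passage0,
            "true_set": true_set,
            "colonies": colony_ids,
        }

    # distribute mutations to samples
    for line, payload in line_payload.items():
        p0_id = f"{line}P0"
        colonies = payload["colonies"]
        # passage-0 variants: in the passage-0 sample and every colony
        for rec, entry in payload["passage0"]:
            e = TruthEntry("passage0", channel=entry.channel, strand=entry.strand, span=entry.span)
            add_record(p0_id, _fill_quality(_copy(rec), rng, cfg.true_qual_range, cfg, cfg.ploidy), e)
            for sid in colonies:
                add_record(sid, _fill_quality(_copy(rec), rng, cfg.true_qual_range, cfg, cfg.ploidy),
                           TruthEntry("passage0", channel=entry.channel, strand=entry.strand, span=entry.span))
        true_set = payload["true_set"]
        if cfg.propagation == "single_cell":
            shares: dict[str, list] = {sid: list(range(len(true_set))) for sid in colonies}
            shared_idx = set(range(len(true_set)))
        else:
            n_shared = int(round(cfg.shared_fraction * len(true_set)))
            shared_idx = set(rng.choice(len(true_set), size=n_shared, replace=False).tolist())
            shares = {}
            for sid in colonies:
                n_priv = len(true_set) - n_shared
                priv = sim.draw(n_priv, rng, used)
                # store colony-private draws under negative pseudo-indices
                shares[sid] = sorted(shared_idx) + [("priv", rec, ent) for rec, ent in priv]
        for sid in colonies:
            for item in shares[sid]:
                if isinstance(item, tuple):
                    _, rec, entry = item
                    e = TruthEntry("true_snv" if entry.category == "true_snv" else entry.category,
                                   channel=entry.channel, strand=entry.strand, span=entry.span,
                                   is_shared_ancestry=False)
                else:
                    rec, entry = true_set[item]
                    e = TruthEntry(entry.category, channel=entry.channel, strand=entry.strand,
                                   span=entry.span,
                                   is_shared_ancestry=(cfg.propagation == "small_population"
                                                       and item in shared_idx))
                add_record(sid, _fill_quality(_copy(rec), rng, cfg.true_qual_range, cfg, cfg.ploidy), e)
            # private false positives
            fps = sim.draw(cfg.n_false_positives, rng, used)
            for rec, entry in fps:
                add_record(sid, _fill_quality(_copy(rec), rng, cfg.true_qual_range, cfg, cfg.ploidy),
                           TruthEntry("false_positive", channel=entry.channel,
                                      strand=entry.strand, span=entry.span))

    # background variants into every sample (including control and passage0)
    for rec, entry in background:
        for meta in samples:
            add_record(meta.sample_id,
                       _fill_quality(_copy(rec), rng, cfg.true_qual_range, cfg, cfg.ploidy),
                       TruthEntry("control_background", channel=entry.channel,
                                  strand=entry.strand, span=entry.span))

    # artifacts: identical position in artifact_prevalence evolved samples
    prevalence = min(cfg.artifact_prevalence, len(evolved_ids))
    artifacts = sim.draw(cfg.artifact_count, rng, used)
    for rec, entry in artifacts:
        carriers = rng.choice(len(evolved_ids), size=prevalence, replace=False)
        for ci in carriers:
            add_record(evolved_ids[int(ci)],
                       _fill_quality(_copy(rec), rng, cfg.artifact_qual_range, cfg, cfg.ploidy),
                       TruthEntry("artifact", channel=entry.channel, strand=entry.strand,
                                  span=entry.span, is_artifact=True))

    for sid in records:
        records[sid].sort(key=lambda r: r.key)
        for r in records[sid]:
            r.sample_id = sid
    sheet = {m.sample_id: m for m in samples}
    for sid, recs in records.items():
        for r in recs:
            r.line_id = sheet[sid].line_id
    return Cohort(toy.genome, toy.origins, model, toy.homopolymers, samples, records, truth)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort to disk: FASTA, origin table, per-sample VCFs, sample
    sheet and truth JSON.  Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    write_fasta(paths["genome"], cohort.genome)
    paths["origins"] = outdir / "origins.tsv"
    write_origins(paths["origins"], cohort.origins)
    paths["sample_sheet"] = outdir / "sample_sheet.csv"
    write_sample_sheet(paths["sample_sheet"], cohort.samples)
    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    contigs = cohort.genome.lengths
    for sid, recs in cohort.records.items():
        p = vcf_dir / f"{sid}.vcf"
        write_vcf(p, recs, contigs, sid)
        paths[f"vcf:{sid}"] = p
    paths["truth"] = outdir / "truth.json"
    cohort.truth.to_json(paths["truth"])
    return paths
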