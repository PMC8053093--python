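"""End-to-end orchestration: filter -> locate -> spectra -> strand bias ->
contexts/indels -> rates, from files to a reproducible TSV/JSON report bundle.

Outputs are pure functions of the inputs plus the configuration; a manifest
records the configuration hash and per-stage record counts so reruns can be
verified byte-for-byte.
"""

from __future__ import annotations

import glob
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .contexts import build_context_matrices, classify_indel, indel_spectrum
from .filtering import FilterConfig, filter_cohort
from .io import (
    read_genome,
    read_origins,
    read_sample_sheet,
    read_signatures,
    read_vcf,
    trinucleotide_census,
)
from .rates import ma_rate
from .replicon import build_model, locate_all
from .spectra import class_frequencies, compare_to_signatures, spectrum96
from .strandbias import analyze_strand_bias

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All inputs and options of one analysis run."""

    genome_path: str
    origins_path: str
    vcf_glob: str
    sample_sheet_path: str
    out_dir: str
    signatures_path: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    normalize_spectrum: bool = True
    collapsed_census: bool = True
    restrict_thirds: bool = True
    alpha: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        for name in ("genome_path", "origins_path", "sample_sheet_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if self.signatures_path and not Path(self.signatures_path).exists():
            raise FileNotFoundError(f"signatures_path: {self.signatures_path}")
        if not glob.glob(self.vcf_glob):
            raise FileNotFoundError(f"vcf_glob matches no file: {self.vcf_glob}")

    def digest(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genome = read_genome(cfg.genome_path)
    origins = read_origins(cfg.origins_path)
    sheet = read_sample_sheet(cfg.sample_sheet_path)
    model = build_model(origins)

    records_by_sample = {}
    for vcf_path in sorted(glob.glob(cfg.vcf_glob)):
        recs = read_vcf(vcf_path, sample_sheet=sheet, genome=genome)
        for r in recs:
            records_by_sample.setdefault(r.sample_id, []).append(r)
    if not records_by_sample:
        raise ValueError("no records read from any VCF")

    outcome = filter_cohort(records_by_sample, sheet, cfg.filter)
    _write_tsv(outcome.report, out / "filter_report.tsv")
    final = outcome.final_records
    _write_tsv(
        pd.DataFrame(
            [
                {"line_id": r.line_id, "sample_id": r.sample_id, "chrom": r.chrom,
                 "pos": r.pos, "ref": r.ref, "alt": r.alt, "qual": r.qual,
                 "kind": r.kind}
                for r in final
            ]
        ),
        out / "filtered_mutations.tsv",
    )

    located, discarded = locate_all(final, model)
    _write_tsv(
        pd.DataFrame(
            [
                {"chrom": lm.chrom, "pos": lm.record.pos, "ref": lm.record.ref,
                 "alt": lm.record.alt, "span": lm.span,
                 "rel_dist": round(lm.rel_dist, 4),
                 "strand_class": lm.strand_class, "third": lm.third}
                for lm in located
            ]
        ),
        out / "located_mutations.tsv",
    )

    census = trinucleotide_census(genome, collapsed=cfg.collapsed_census)
    spec = spectrum96(final, genome, census, normalize=cfg.normalize_spectrum)
    _write_tsv(spec.to_frame(), out / "spectrum96.tsv")
    cls6 = class_frequencies(final)
    _write_tsv(
        pd.DataFrame(
            [{"class": c, "count": n, "frequency": cls6.frequencies[c]}
             for c, n in cls6.counts.items()]
        ),
        out / "class_spectrum6.tsv",
    )
    if cfg.signatures_path:
        sigs = read_signatures(cfg.signatures_path)
        _write_tsv(compare_to_signatures(spec, sigs), out / "signature_similarity.tsv")

    bias = analyze_strand_bias(located, alpha=cfg.alpha)
    _write_tsv(bias, out / "strand_bias.tsv")

    matrices = build_context_matrices(located, genome, restrict_thirds=cfg.restrict_thirds)
    ctx_rows = []
    for (cls, side), cm in sorted(matrices.items()):
        freq = cm.frequencies
        for pi, offset in enumerate((-2, -1, 0, 1, 2)):
            for bi, base in enumerate("ACGT"):
                ctx_rows.append(
                    {"class": cls, "side": side, "n": cm.n, "position": offset,
                     "base": base, "frequency": freq[pi, bi]}
                )
    _write_tsv(pd.DataFrame(ctx_rows), out / "context_matrices.tsv")

    indel_calls = [
        classify_indel(r, genome, model) for r in final if r.kind in ("INS", "DEL")
    ]
    total_passages = sum(
        {line: sheet[s].passages for s in sheet
         if sheet[s].role == "evolved" for line in [sheet[s].line_id]}.values()
    )
    _write_tsv(
        indel_spectrum(indel_calls, by_strand=True, total_passages=total_passages or None),
        out / "indel_spectrum.tsv",
    )

    by_line: dict[str, list] = {}
    for r in final:
        by_line.setdefault(r.line_id, []).append(r)
    rate_rows = []
    for line_id in sorted(by_line):
        meta = next(
            (m for m in sheet.values() if m.line_id == line_id and m.role == "evolved"),
            None,
        )
        if meta is None:
            continue
        est = ma_rate(by_line[line_id], meta)
        rate_rows.append(
            {"line_id": line_id, "genotype": meta.genotype, "n_snv": est.n_snv,
             "n_indel": est.n_indel, "passages": est.passages,
             "rate_per_passage": est.rate_per_passage,
             "indel_rate_per_passage": est.indel_rate_per_passage,
             "rate_per_gen_bp": est.rate_per_gen_bp}
        )
    _write_tsv(pd.DataFrame(rate_rows), out / "rates.tsv")

    manifest = {
        "version": __version__,
        "config_digest": cfg.digest(),
        "stage_counts": {
            **outcome.stage_counts,
            "located": len(located),
            "located_discarded": len(discarded),
            "snv_final": sum(1 for r in final if r.kind == "SNV"),
            "indel_final": len(indel_calls),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
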