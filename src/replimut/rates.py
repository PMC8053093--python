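"""Mutation-rate estimation.

Two experimental designs are covered:

* mutation-accumulation (MA) sequencing — mutations counted after filtering
  are converted to SNV (or INDEL) per haploid genome per passage and to
  per-generation per-bp rates, assuming by default the 12,071,326 bp haploid
  yeast genome and 20 generations from single cell to colony (single-cell
  bottlenecks) or ~6 doublings per growth cycle (small-population
  bottlenecks).  Genotype-level summaries use the median across lines, and
  double-mutant fold changes are compared against additive (fa + fb - 1) and
  multiplicative (fa x fb) epistasis expectations;

* fluctuation assays — mutant counts across parallel cultures follow the
  Luria-Delbrueck distribution; the expected number of mutations per culture
  m is estimated by Ma-Sandri-Sarkar maximum likelihood (with jackpot
  censoring) or the P0 method, and converted to a per-cell per-division rate
  by dividing by the final population size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import MutationRecord, SampleMeta

__all__ = [
    "GENOME_SIZE_BP",
    "GENERATIONS_PER_PASSAGE",
    "DOUBLINGS_PER_PASSAGE_SMALL_POP",
    "RateEstimate",
    "ma_rate",
    "convert_rate",
    "fold_changes",
    "epistasis_expectations",
    "FluctuationResult",
    "luria_delbruck_pmf",
    "fluctuation_mle",
    "p0_estimate",
    "simulate_fluctuation",
]

#: Haploid S. cerevisiae genome size used for unit conversion.
GENOME_SIZE_BP = 12_071_326
#: Generations from a single cell to a colony (single-cell bottlenecks).
GENERATIONS_PER_PASSAGE = 20
#: Doublings per growth cycle in 1536-format small-population passaging.
DOUBLINGS_PER_PASSAGE_SMALL_POP = 6

_PLOIDY_DIVISOR = {"haploid": 1.0, "diploid": 2.0}


@dataclass
class RateEstimate:
    """Per-sample (or per-line) mutation-rate estimate."""

    sample_id: str
    line_id: str
    n_snv: int
    n_indel: int
    passages: int
    generations_per_passage: float
    genome_size_bp: int
    ploidy_divisor: float
    rate_per_passage: float  # SNV / haploid genome / passage
    indel_rate_per_passage: float
    rate_per_gen_bp: float  # SNV / generation / bp
    ploidy_flagged: bool = False  # unknown ploidy, divisor 1 used


def convert_rate(
    rate_per_passage: float,
    generations_per_passage: float = GENERATIONS_PER_PASSAGE,
    genome_size_bp: int = GENOME_SIZE_BP,
) -> float:
    """SNV/haploid genome/passage -> SNV/generation/bp."""
    return rate_per_passage / (generations_per_passage * genome_size_bp)


def ma_rate(
    records: Iterable[MutationRecord],
    meta: SampleMeta,
    generations_per_passage: float | None = None,
    genome_size_bp: int = GENOME_SIZE_BP,
) -> RateEstimate:
    """Rate estimate from fully filtered records of one sample/line.

    The ploidy divisor (2 for diploid) expresses rates per haploid genome;
    unknown ploidy computes with divisor 1 and flags the estimate.  The
    per-passage generation count defaults by propagation mode.
    """
    if meta.passages <= 0:
        raise ValueError(f"sample {meta.sample_id!r} has passages <= 0")
    if generations_per_passage is None:
        generations_per_passage = (
            DOUBLINGS_PER_PASSAGE_SMALL_POP
            if meta.propagation == "small_population"
            else GENERATIONS_PER_PASSAGE
        )
    recs = list(records)
    n_snv = sum(1 for r in recs if r.kind == "SNV")
    n_indel = sum(1 for r in recs if r.kind in ("INS", "DEL"))
    divisor = _PLOIDY_DIVISOR.get(meta.ploidy)
    flagged = divisor is None
    if divisor is None:
        divisor = 1.0
    rpp = n_snv / meta.passages / divisor
    irpp = n_indel / meta.passages / divisor
    return RateEstimate(
        sample_id=meta.sample_id,
        line_id=meta.line_id,
        n_snv=n_snv,
        n_indel=n_indel,
        passages=meta.passages,
        generations_per_passage=generations_per_passage,
        genome_size_bp=genome_size_bp,
        ploidy_divisor=divisor,
        rate_per_passage=rpp,
        indel_rate_per_passage=irpp,
        rate_per_gen_bp=convert_rate(rpp, generations_per_passage, genome_size_bp),
        ploidy_flagged=flagged,
    )


def epistasis_expectations(fold_a: float, fold_b: float) -> tuple[float, float]:
    """(additive, multiplicative) expected fold change of a double mutant
    from its single-mutant folds."""
    return fold_a + fold_b - 1.0, fold_a * fold_b


def fold_changes(
    rates_by_genotype: Mapping[str, Sequence[float]],
    reference_genotype: str,
    double_mutants: Mapping[str, tuple[str, str]] | None = None,
    summary: str = "median",
) -> pd.DataFrame:
    """Genotype fold changes over a reference, with epistasis expectations.

    ``rates_by_genotype`` maps genotype -> per-line rates; the genotype
    summary is the median (mean via ``summary="mean"``).  For each entry of
    ``double_mutants`` (double -> (single_a, single_b)) the additive and
    multiplicative expectations and observed/expected ratios are added.
    """
    agg = np.median if summary == "median" else np.mean
    summaries = {g: float(agg(np.asarray(v, dtype=float))) for g, v in rates_by_genotype.items()}
    ref = summaries.get(reference_genotype)
    if ref is None:
        raise ValueError(f"reference genotype {reference_genotype!r} not present")
    if ref == 0:
        raise ValueError("reference genotype has zero summary rate")
    rows = []
    for g, s in summaries.items():
        row = {
            "genotype": g,
            "summary_rate": s,
            "fold": s / ref,
            "additive_expected": np.nan,
            "multiplicative_expected": np.nan,
            "obs_over_additive": np.nan,
            "obs_over_multiplicative": np.nan,
        }
        if double_mutants and g in double_mutants:
            a, b = double_mutants[g]
            fa, fb = summaries[a] / ref, summaries[b] / ref
            add, mult = epistasis_expectations(fa, fb)
            row["additive_expected"] = add
            row["multiplicative_expected"] = mult
            row["obs_over_additive"] = row["fold"] / add
            row["obs_over_multiplicative"] = row["fold"] / mult
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fluctuation assay (Luria-Delbrueck)


@dataclass
class FluctuationResult:
    """Fluctuation-assay estimate of mutations per culture and the rate."""

    m: float  # expected mutations per culture
    rate: float  # per cell per division, m / N_final
    ci_low: float
    ci_high: float
    n_cultures: int
    method: str  # "mss-mle" | "p0"


def luria_delbruck_pmf(m: float, n_max: int) -> np.ndarray:
    """P(0..n_max mutants) under the Lea-Coulson formulation.

    p0 = exp(-m); p_n = (m/n) * sum_{i=0}^{n-1} p_i / (n - i + 1).
    """
    p = np.zeros(n_max + 1)
    p[0] = np.exp(-m)
    inv = np.zeros(n_max + 2)
    inv[1:] = 1.0 / np.arange(1, n_max + 2, dtype=float)  # inv[k] = 1/k
    for n in range(1, n_max + 1):
        # sum over i of p[i] / (n - i + 1): denominators n+1, n, ..., 2
        p[n] = (m / n) * float(np.dot(p[:n], inv[n + 1 : 1 : -1]))
    return p


def _ld_loglik(m: float, obs: np.ndarray, obs_counts: np.ndarray, cap: int, n_capped: int) -> float:
    if m <= 0:
        return -np.inf
    pmf = luria_delbruck_pmf(m, cap - 1)
    tiny = 1e-300
    ll = float(np.dot(obs_counts, np.log(np.maximum(pmf[obs], tiny))))
    if n_capped:
        tail = max(1.0 - float(pmf.sum()), tiny)
        ll += n_capped * np.log(tail)
    return ll


def fluctuation_mle(
    mutant_counts: Sequence[int],
    n_final: float,
    cap: int = 512,
    m_max: float = 100.0,
) -> FluctuationResult:
    """Ma-Sandri-Sarkar maximum-likelihood estimate of m with a 95% profile
    likelihood interval.

    Counts at or above ``cap`` (jackpot cultures) contribute the tail
    probability P(X >= cap) rather than a point mass, keeping the recursion
    cheap without discarding them.
    """
    counts = np.asarray(mutant_counts, dtype=np.int64)
    if counts.size == 0:
        raise ValueError("no cultures")
    if np.any(counts < 0):
        raise ValueError("negative mutant counts")
    if n_final <= 0:
        raise ValueError("n_final must be positive")
    if np.all(counts >= n_final):
        raise ValueError("all cultures fully mutant: m unbounded")
    if np.all(counts == 0):
        # boundary MLE: likelihood exp(-m)^n maximised at m = 0
        hi = stats.chi2.ppf(0.95, 1) / 2.0 / counts.size
        return FluctuationResult(0.0, 0.0, 0.0, hi, counts.size, "mss-mle")
    capped = counts >= cap
    uncapped = counts[~capped]
    vals, val_counts = np.unique(uncapped, return_counts=True)
    n_capped = int(capped.sum())

    def nll(m: float) -> float:
        return -_ld_loglik(m, vals, val_counts, cap, n_capped)

    res = optimize.minimize_scalar(nll, bounds=(1e-8, m_max), method="bounded")
    m_hat = float(res.x)
    ll_hat = -float(res.fun)
    drop = stats.chi2.ppf(0.95, 1) / 2.0

    def profile(m: float) -> float:
        return _ld_loglik(m, vals, val_counts, cap, n_capped) - (ll_hat - drop)

    lo = 0.0
    if profile(1e-8) < 0:
        lo = float(optimize.brentq(profile, 1e-8, m_hat))
    hi = m_max
    if profile(m_max) < 0:
        hi = float(optimize.brentq(profile, m_hat, m_max))
    return FluctuationResult(m_hat, m_hat / n_final, lo, hi, counts.size, "mss-mle")


def p0_estimate(mutant_counts: Sequence[int], n_final: float) -> FluctuationResult:
    """P0 (zero-class) estimate m = -ln(fraction of cultures with no mutants),
    with a binomial-proportion 95% CI propagated through the log."""
    counts = np.asarray(mutant_counts, dtype=np.int64)
    n = counts.size
    if n == 0:
        raise ValueError("no cultures")
    n_zero = int((counts == 0).sum())
    if n_zero == 0:
        raise ValueError("no zero-mutant cultures: P0 method unusable")
    p0 = n_zero / n
    m = -np.log(p0)
    se = np.sqrt(p0 * (1 - p0) / n)
    lo_p = min(1.0, p0 + 1.96 * se)
    hi_p = max(1e-12, p0 - 1.96 * se)
    return FluctuationResult(
        float(m), float(m / n_final), float(-np.log(lo_p)), float(-np.log(hi_p)), n, "p0"
    )


def simulate_fluctuation(
    m: float, n_final: float, n_cultures: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw mutant counts from the Luria-Delbrueck process.

    Mutations per culture are Poisson(m); each mutant clone's final size j
    follows P(J >= j) = 1/j (the deterministic-growth limit), capped at the
    final population size.
    """
    counts = np.zeros(n_cultures, dtype=np.int64)
    k = rng.poisson(m, size=n_cultures)
    for i in range(n_cultures):
        if k[i] == 0:
            continue
        u = rng.random(k[i])
        sizes = np.minimum(np.floor(1.0 / u), n_final).astype(np.int64)
        counts[i] = int(sizes.sum())
    return counts
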