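"""Replication-strand asymmetry statistics per complementary mutation pair.

A mutation read as e.g. A>C on the reference strand that falls in lagging
territory is the same fork event as a T>G in leading territory, so the pair
statistic pools the two readings into a single leading/lagging count oriented
to the frame of the class the caller names.  Significance uses a one-degree
chi-square goodness-of-fit against a 50/50 split (leading and lagging
territory cover equal genome fractions under the midpoint-termination model)
and effect size is Cohen's w.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CLASSES6, complement_class
from .replicon import LocatedMutation

__all__ = [
    "StrandBiasResult",
    "strand_counts",
    "chi2_uniformity",
    "cohens_w",
    "pair_bias",
    "analyze_strand_bias",
]

#: Minimum located mutations before a significance call is made.
MIN_TOTAL_FOR_TEST = 10


def strand_counts(
    located: Sequence[LocatedMutation], pair: str | tuple[str, str]
) -> tuple[int, int]:
    """Leading/lagging counts for a complementary pair, oriented to the frame
    of the first (or only) class given.

    For a single class label only mutations read as that class are counted.
    For a pair ``(c1, c2)``: a c2 event on the lagging side counts toward the
    leading tally of c1's frame (and vice versa), since it is the identical
    fork event observed on the opposite strand.
    """
    if isinstance(pair, str):
        classes = (pair,)
    else:
        classes = tuple(pair)
    c1 = classes[0]
    n_leading = n_lagging = 0
    for lm in located:
        cls = lm.record.snv_class
        if cls is None or cls not in classes:
            continue
        is_leading = lm.strand_class == "leading"
        if cls != c1:
            is_leading = not is_leading  # complementary reading: flip frame
        if is_leading:
            n_leading += 1
        else:
            n_lagging += 1
    return n_leading, n_lagging


def chi2_uniformity(n_leading: int, n_lagging: int) -> tuple[float, float]:
    """One-df chi-square goodness-of-fit of (leading, lagging) against 50/50."""
    total = n_leading + n_lagging
    if total == 0:
        raise ValueError("no mutations to test")
    expected = total / 2.0
    chi2 = (n_leading - expected) ** 2 / expected + (n_lagging - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def cohens_w(observed: Sequence[float], expected: Sequence[float]) -> float:
    """Cohen's w effect size: sqrt(sum((p_obs - p_exp)^2 / p_exp)).

    Both arguments are proportion vectors summing to 1; expected cells must
    be strictly positive.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if np.any(exp <= 0):
        raise ValueError("expected proportions must be strictly positive")
    return float(np.sqrt(np.sum((obs - exp) ** 2 / exp)))


@dataclass
class StrandBiasResult:
    """Strand-asymmetry summary for one complementary mutation pair."""

    pair: tuple[str, str]  # (frame class, complementary class)
    n_leading: int
    n_lagging: int
    chi2_stat: float
    p_value: float
    w: float
    significant: bool
    underpowered: bool

    @property
    def total(self) -> int:
        return self.n_leading + self.n_lagging

    @property
    def odds(self) -> float:
        """Leading:lagging odds ratio (inf when no lagging events)."""
        if self.n_lagging == 0:
            return float("inf") if self.n_leading else float("nan")
        return self.n_leading / self.n_lagging


def pair_bias(
    located: Sequence[LocatedMutation],
    frame_class: str,
    alpha: float = 0.01,
    min_total: int = MIN_TOTAL_FOR_TEST,
) -> StrandBiasResult:
    """Strand-bias test for the complementary pair containing ``frame_class``,
    oriented to that class's frame."""
    comp = complement_class(frame_class)
    n_lead, n_lag = strand_counts(located, (frame_class, comp))
    total = n_lead + n_lag
    if total == 0:
        return StrandBiasResult(
            (frame_class, comp), 0, 0, float("nan"), float("nan"), float("nan"), False, True
        )
    chi2, p = chi2_uniformity(n_lead, n_lag)
    w = cohens_w([n_lead / total, n_lag / total], [0.5, 0.5])
    underpowered = total < min_total
    significant = (not underpowered) and p < alpha
    return StrandBiasResult((frame_class, comp), n_lead, n_lag, chi2, p, w, significant, underpowered)


def analyze_strand_bias(
    located: Sequence[LocatedMutation],
    alpha: float = 0.01,
    bonferroni: bool = False,
    min_total: int = MIN_TOTAL_FOR_TEST,
) -> pd.DataFrame:
    """Per-pair strand-bias table over the six complementary pairs.

    Frames are the pyrimidine classes; no multiple-testing correction by
    default (set ``bonferroni=True`` to divide alpha by six).
    """
    eff_alpha = alpha / len(CLASSES6) if bonferroni else alpha
    rows = []
    for cls in CLASSES6:
        r = pair_bias(located, cls, alpha=eff_alpha, min_total=min_total)
        rows.append(
            {
                "pair": f"{r.pair[0]}/{r.pair[1]}",
                "n_leading": r.n_leading,
                "n_lagging": r.n_lagging,
                "chi2": r.chi2_stat,
                "p_value": r.p_value,
                "cohens_w": r.w,
                "significant": r.significant,
                "underpowered": r.underpowered,
            }
        )
    return pd.DataFrame(rows)
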