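"""FISH tissue-microarray gain scoring and cohort cross-tabulation.

Each tumor's gain status comes from the ratio of mean test-probe to
mean centromere signal counts over its scored nuclei; a ratio of at
least 1.5 is a copy-number gain. Tumors with fewer than 20 or more than
60 scored nuclei are non-informative and drop out of cohort
denominators. Gain is cross-tabulated against MYCN amplification with a
Pearson chi-square test of independence.
"""

from __future__ import annotations

import decimal
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .config import AnalysisThresholds, InvalidParameterError


class InvalidCohortError(ValueError):
    """A cohort has no informative samples or degenerate margins."""


@dataclass
class FishSample:
    """One tumor's nucleus-level counts and derived gain score."""

    tumor_id: str
    nuclei: list[tuple[int, int]]          # (test_count, centromere_count)
    ratio: float = math.nan
    gain: bool = False
    informative: bool = False
    myc_amplified: Optional[bool] = None


@dataclass
class CohortCrosstab:
    n_informative: int
    counts: dict = field(default_factory=dict)   # both/gain_only/myc_only/neither
    pct_gain: int = 0
    pct_myc: int = 0
    pct_either: int = 0
    pct_both_given_gain: int = 0
    n_myc_missing: int = 0


def _round_pct(numerator: int, denominator: int) -> int:
    """Integer percent, half-up (42 for 14/33, 7 for 1/14)."""
    if denominator == 0:
        return 0
    q = decimal.Decimal(100 * numerator) / decimal.Decimal(denominator)
    return int(q.quantize(decimal.Decimal("1"), rounding=decimal.ROUND_HALF_UP))


def score_sample(tumor_id: str,
                 nuclei: Sequence[tuple[int, int]],
                 thresholds: AnalysisThresholds = AnalysisThresholds(),
                 min_nuclei: int = 20,
                 max_nuclei: int = 60,
                 myc_amplified: Optional[bool] = None) -> FishSample:
    """Score one tumor from its per-nucleus (test, centromere) counts.

    ratio = mean(test) / mean(centromere); gain when ratio >= the
    1.5-fold cutoff (inclusive). A zero centromere mean makes the sample
    non-informative rather than raising.
    """
    if not nuclei:
        raise InvalidParameterError(f"tumor {tumor_id}: empty nucleus list")
    test_mean = float(np.mean([n[0] for n in nuclei]))
    cen_mean = float(np.mean([n[1] for n in nuclei]))
    ratio = test_mean / cen_mean if cen_mean > 0 else math.nan
    informative = (min_nuclei <= len(nuclei) <= max_nuclei) and cen_mean > 0
    gain = bool(cen_mean > 0 and ratio >= thresholds.fish_gain_ratio)
    return FishSample(tumor_id=tumor_id, nuclei=list(nuclei), ratio=ratio,
                      gain=gain, informative=informative,
                      myc_amplified=myc_amplified)


def cohort_crosstab(samples: Sequence[FishSample]) -> CohortCrosstab:
    """Cross-tabulate gain vs MYCN amplification over informative samples.

    Samples with missing MYCN status are excluded from the four-cell
    counts (reported in ``n_myc_missing``); pct_gain uses all
    informative samples. Percentages are half-up integer percent.
    """
    informative = [s for s in samples if s.informative]
    if not informative:
        raise InvalidCohortError("no informative samples in cohort")
    with_myc = [s for s in informative if s.myc_amplified is not None]
    counts = {
        "both": sum(s.gain and s.myc_amplified for s in with_myc),
        "gain_only": sum(s.gain and not s.myc_amplified for s in with_myc),
        "myc_only": sum((not s.gain) and s.myc_amplified for s in with_myc),
        "neither": sum((not s.gain) and not s.myc_amplified for s in with_myc),
    }
    n_inf = len(informative)
    n_gain = sum(s.gain for s in informative)
    n_myc = counts["both"] + counts["myc_only"]
    n_either = counts["both"] + counts["gain_only"] + counts["myc_only"]
    n_gain_myc_known = counts["both"] + counts["gain_only"]
    return CohortCrosstab(
        n_informative=n_inf,
        counts=counts,
        pct_gain=_round_pct(n_gain, n_inf),
        pct_myc=_round_pct(n_myc, len(with_myc)),
        pct_either=_round_pct(n_either, len(with_myc)),
        pct_both_given_gain=_round_pct(counts["both"], n_gain_myc_known),
        n_myc_missing=n_inf - len(with_myc),
    )


def chi_square_independence(table, yates: bool = False
                            ) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Returns (statistic, degrees of freedom, upper-tail p). No continuity
    correction unless ``yates`` is set. Degenerate margins (a zero row
    or column, or fewer than two non-zero rows/columns) raise.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise InvalidCohortError("table must be a non-negative 2-D count array")
    if (obs.sum(axis=1) > 0).sum() < 2 or (obs.sum(axis=0) > 0).sum() < 2:
        raise InvalidCohortError("table needs at least two non-zero rows and columns")
    res = stats.chi2_contingency(obs, correction=yates)
    return float(res.statistic), int(res.dof), float(res.pvalue)
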