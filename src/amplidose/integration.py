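"""DNA-RNA dosage integration.

Expression probe sets are mapped to genomic positions (Ensembl gene
midpoint, with the array vendor's base-pair position as fallback), each
position receives the median log2 copy-number ratio of aCGH oligos
within 50 kb, over/underexpression is called at the symmetric 7th
percentiles of each sample's ratio distribution, and genes are binned by
copy number to expose the dosage effect as rising over-expression
frequency across bins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisThresholds, InvalidParameterError
from .cnv import CghProbe

log = logging.getLogger(__name__)

OVER = "OVER"
UNDER = "UNDER"
NONE = "NONE"

#: default copy-number bin edges (log2), aligned with calling thresholds
DEFAULT_BIN_EDGES = (-1.0, -0.5, 0.5, 1.0, 2.0, 3.5)


@dataclass
class ExpressionRecord:
    """One expression probe set with its log2 sample/reference ratio."""

    probe_set_id: str
    log2_expression_ratio: float
    gene_id: Optional[str] = None
    fallback_position: Optional[tuple[str, int]] = None


@dataclass
class IntegratedGene:
    """A probe set joined to windowed copy number and an expression call."""

    probe_set_id: str
    assigned_chromosome: str
    assigned_position_bp: int
    log2_expression_ratio: float
    copy_number_ratio: Optional[float] = None
    expression_call: str = NONE


@dataclass(frozen=True)
class CopyNumberBin:
    """One half-open (lower, upper] copy-number bin with call frequencies."""

    lower_log2: float
    upper_log2: float
    n_genes: int
    freq_over: Optional[float]
    freq_under: Optional[float]


def compute_expression_ratio(sample_value: float, reference_value: float) -> float:
    """log2 of sample over reference intensity; both must be positive."""
    if not (sample_value > 0 and reference_value > 0):
        raise InvalidParameterError(
            f"intensities must be strictly positive; got "
            f"({sample_value}, {reference_value})")
    return math.log2(sample_value / reference_value)


def assign_position(record: ExpressionRecord,
                    genes: pd.DataFrame) -> Optional[tuple[str, int]]:
    """Map a probe set to (chromosome, bp).

    Uses the matched gene's interval midpoint (rounded down); falls back
    to the vendor position; returns None (caller counts the exclusion)
    when neither is available.

    ``genes`` must be indexed by gene_id with columns chromosome,
    start_bp, end_bp.
    """
    if record.gene_id is not None and record.gene_id in genes.index:
        g = genes.loc[record.gene_id]
        return str(g["chromosome"]), int((int(g["start_bp"]) + int(g["end_bp"])) // 2)
    if record.fallback_position is not None:
        chrom, bp = record.fallback_position
        return str(chrom), int(bp)
    log.warning("probe set %s has no gene match and no fallback position; "
                "excluded", record.probe_set_id)
    return None


def windowed_copy_number(position: tuple[str, int],
                         probes: Sequence[CghProbe],
                         window_bp: int = 50_000) -> Optional[float]:
    """Median log2 ratio of same-chromosome oligos within window_bp (inclusive)."""
    chrom, bp = position
    vals = [p.log2_ratio for p in probes
            if p.chromosome == chrom and abs(p.position_bp - bp) <= window_bp]
    if not vals:
        return None
    return float(np.median(vals))


class _ProbeIndex:
    """Per-chromosome sorted position index for fast window queries."""

    def __init__(self, probes: Sequence[CghProbe]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        tmp: dict[str, list[tuple[int, float]]] = {}
        for p in probes:
            tmp.setdefault(p.chromosome, []).append((p.position_bp, p.log2_ratio))
        for chrom, items in tmp.items():
            items.sort()
            pos = np.array([i[0] for i in items], dtype=np.int64)
            val = np.array([i[1] for i in items], dtype=float)
            self._by_chrom[chrom] = (pos, val)

    def window_median(self, chrom: str, bp: int, window_bp: int) -> Optional[float]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        pos, val = entry
        lo = np.searchsorted(pos, bp - window_bp, side="left")
        hi = np.searchsorted(pos, bp + window_bp, side="right")
        if hi <= lo:
            return None
        return float(np.median(val[lo:hi]))


def call_expression_extremes(records: Sequence[ExpressionRecord],
                             extreme_percentile: float = 7.0,
                             ) -> dict[str, str]:
    """Call OVER/UNDER/NONE at the symmetric top/bottom percentiles.

    With N records and percentile p, k = floor(N*p/100) records receive
    each call. Records are ordered by (ratio, probe_set_id); the first k
    are UNDER and the last k OVER, so boundary ties resolve
    deterministically by probe-set identifier.
    """
    if not records:
        raise InvalidParameterError("no expression records to call")
    n = len(records)
    k = int(n * extreme_percentile / 100.0)
    order = sorted(records,
                   key=lambda r: (r.log2_expression_ratio, r.probe_set_id))
    calls = {r.probe_set_id: NONE for r in order}
    for r in order[:k]:
        calls[r.probe_set_id] = UNDER
    for r in order[n - k:]:
        calls[r.probe_set_id] = OVER
    return calls


def integrate(records: Sequence[ExpressionRecord],
              genes: pd.DataFrame,
              probes: Sequence[CghProbe],
              thresholds: AnalysisThresholds = AnalysisThresholds(),
              call_before_mapping: bool = True,
              ) -> tuple[list[IntegratedGene], dict]:
    """Run the full integration: call extremes, map, attach copy number.

    Expression extremes are by default called over all input records
    before position mapping, so the percentile denominators are the full
    sample. Returns the integrated genes plus a bookkeeping report with
    exclusion and no-copy-number counts.
    """
    pool = records if call_before_mapping else None
    index = _ProbeIndex(probes)
    excluded = 0
    integrated: list[IntegratedGene] = []
    mapped: list[tuple[ExpressionRecord, tuple[str, int]]] = []
    for rec in records:
        pos = assign_position(rec, genes)
        if pos is None:
            excluded += 1
            continue
        mapped.append((rec, pos))
    if pool is None:
        pool = [rec for rec, _ in mapped]
    calls = call_expression_extremes(pool, thresholds.extreme_percentile)
    no_cn = 0
    for rec, (chrom, bp) in mapped:
        cn = index.window_median(chrom, bp, thresholds.window_bp)
        if cn is None:
            no_cn += 1
        integrated.append(IntegratedGene(
            probe_set_id=rec.probe_set_id,
            assigned_chromosome=chrom,
            assigned_position_bp=bp,
            log2_expression_ratio=rec.log2_expression_ratio,
            copy_number_ratio=cn,
            expression_call=calls.get(rec.probe_set_id, NONE),
        ))
    report = {"n_input": len(records), "n_excluded": excluded,
              "n_mapped": len(mapped), "n_without_copy_number": no_cn}
    return integrated, report


def bin_frequencies(integrated: Sequence[IntegratedGene],
                    edges: Sequence[float] = DEFAULT_BIN_EDGES,
                    ) -> tuple[list[CopyNumberBin], dict]:
    """Frequency of OVER/UNDER calls per half-open (lower, upper] CN bin.

    Interior ``edges`` must be strictly increasing; outer bounds are
    +/-infinity. Genes without a copy-number ratio are excluded and
    counted in the report. Empty bins carry null frequencies.
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise InvalidParameterError("bin edges must be strictly increasing")
    bounds = [-math.inf] + edges + [math.inf]
    usable = [g for g in integrated if g.copy_number_ratio is not None]
    bins: list[CopyNumberBin] = []
    for lo, hi in zip(bounds, bounds[1:]):
        members = [g for g in usable if lo < g.copy_number_ratio <= hi]
        n = len(members)
        if n == 0:
            bins.append(CopyNumberBin(lo, hi, 0, None, None))
        else:
            n_over = sum(g.expression_call == OVER for g in members)
            n_under = sum(g.expression_call == UNDER for g in members)
            bins.append(CopyNumberBin(lo, hi, n, n_over / n, n_under / n))
    report = {"n_excluded_no_copy_number": len(integrated) - len(usable)}
    return bins, report


def amplified_overexpressed(integrated: Sequence[IntegratedGene],
                            thresholds: AnalysisThresholds = AnalysisThresholds(),
                            ) -> list[IntegratedGene]:
    """Amplified (CN > amp threshold) genes that are also called OVER."""
    hits = [g for g in integrated
            if g.copy_number_ratio is not None
            and g.copy_number_ratio > thresholds.amp_log2
            and g.expression_call == OVER]
    return sorted(hits, key=lambda g: -g.copy_number_ratio)


def integrated_to_frame(integrated: Sequence[IntegratedGene]) -> pd.DataFrame:
    return pd.DataFrame(
        [(g.probe_set_id, g.assigned_chromosome, g.assigned_position_bp,
          g.copy_number_ratio, g.expression_call, g.log2_expression_ratio)
         for g in integrated],
        columns=["probe_set_id", "chrom", "pos_bp", "copy_number_log2",
                 "expression_call", "log2_expression_ratio"])


def bins_to_frame(bins: Sequence[CopyNumberBin]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.lower_log2, b.upper_log2, b.n_genes, b.freq_over, b.freq_under)
         for b in bins],
        columns=["lower_log2", "upper_log2", "n_genes", "freq_over",
                 "freq_under"])
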