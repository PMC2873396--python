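"""aCGH locus classification and amplicon/loss segment calling.

Loci are classified by plain thresholding of the log2 copy-number ratio
(no smoothing or change-point segmentation): ratios above 2 are
amplifications, above 3.5 high-level amplifications, and below the loss
cutoff losses. Maximal runs of same-direction probes are merged into
reported segments; two probes suffice, so focal microamplifications
(e.g. a two-probe event over an oncogene) are retained.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

import math

import pandas as pd

from .config import AnalysisThresholds, InvalidParameterError

HIGH_AMP = "HIGH_AMP"
AMP = "AMP"
NEUTRAL = "NEUTRAL"
LOSS = "LOSS"


@dataclass(frozen=True)
class CghProbe:
    """One aCGH oligo: genomic position plus a log2 copy-number ratio."""

    probe_id: str
    chromosome: str
    position_bp: int
    log2_ratio: float


@dataclass(frozen=True)
class CnvSegment:
    """A called amplicon or loss region (1-based inclusive bp)."""

    chromosome: str
    start_bp: int
    end_bp: int
    locus_class: str
    n_probes: int
    median_log2: float


def classify_locus(log2_ratio: float,
                   thresholds: AnalysisThresholds = AnalysisThresholds()) -> str:
    """Classify one log2 ratio as HIGH_AMP, AMP, LOSS or NEUTRAL."""
    if not math.isfinite(log2_ratio):
        raise InvalidParameterError(f"non-finite log2 ratio: {log2_ratio}")
    if log2_ratio > thresholds.high_amp_log2:
        return HIGH_AMP
    if log2_ratio > thresholds.amp_log2:
        return AMP
    if log2_ratio < thresholds.loss_log2:
        return LOSS
    return NEUTRAL


def _direction(cls: str) -> int:
    if cls in (AMP, HIGH_AMP):
        return 1
    if cls == LOSS:
        return -1
    return 0


def call_segments(probes: Sequence[CghProbe],
                  thresholds: AnalysisThresholds = AnalysisThresholds(),
                  ) -> list[CnvSegment]:
    """Merge same-direction probe runs into amplicon/loss segments.

    Probes must be sorted by (chromosome, position). A run may bridge at
    most ``max_gap_probes`` interior non-qualifying probes; runs shorter
    than ``min_probes`` qualifying probes are discarded. A run holding
    any high-level probe is reported as HIGH_AMP. Segment boundaries are
    the first and last qualifying probe positions.
    """
    for a, b in zip(probes, probes[1:]):
        if (a.chromosome, a.position_bp) > (b.chromosome, b.position_bp):
            raise InvalidParameterError(
                "probes must be sorted by (chromosome, position_bp)")

    segments: list[CnvSegment] = []
    run: list[CghProbe] = []          # qualifying probes in the open run
    run_dir = 0
    gap = 0

    def flush() -> None:
        nonlocal run, gap
        if len(run) >= thresholds.min_probes:
            classes = {classify_locus(p.log2_ratio, thresholds) for p in run}
            if run_dir > 0:
                cls = HIGH_AMP if HIGH_AMP in classes else AMP
            else:
                cls = LOSS
            segments.append(CnvSegment(
                chromosome=run[0].chromosome,
                start_bp=run[0].position_bp,
                end_bp=run[-1].position_bp,
                locus_class=cls,
                n_probes=len(run),
                median_log2=float(median(p.log2_ratio for p in run)),
            ))
        run = []
        gap = 0

    prev_chrom = None
    for probe in probes:
        d = _direction(classify_locus(probe.log2_ratio, thresholds))
        if probe.chromosome != prev_chrom:
            flush()
            run_dir = 0
            prev_chrom = probe.chromosome
        if d == run_dir and d != 0:
            run.append(probe)
            gap = 0
        elif d == 0 and run:
            gap += 1
            if gap > thresholds.max_gap_probes:
                flush()
                run_dir = 0
        else:
            flush()
            run_dir = d
            if d != 0:
                run = [probe]
    flush()
    return segments


def format_region(segment: CnvSegment) -> str:
    """Render segment bounds as "start-end Mb" (half-up, 1 decimal)."""
    def mb(bp: int) -> str:
        q = decimal.Decimal(bp) / decimal.Decimal(1_000_000)
        return str(q.quantize(decimal.Decimal("0.1"),
                              rounding=decimal.ROUND_HALF_UP))
    return f"{mb(segment.start_bp)}-{mb(segment.end_bp)} Mb"


def probes_from_frame(df: pd.DataFrame) -> list[CghProbe]:
    """Build probe objects from a (probe_id, chrom, pos_bp, log2_ratio) frame."""
    return [CghProbe(str(r.probe_id), str(r.chrom), int(r.pos_bp),
                     float(r.log2_ratio))
            for r in df.itertuples(index=False)]


def segments_to_frame(segments: Iterable[CnvSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.chromosome, s.start_bp, s.end_bp, s.locus_class, s.n_probes,
          s.median_log2) for s in segments],
        columns=["chrom", "start_bp", "end_bp", "locus_class", "n_probes",
                 "median_log2"])


def write_seg(segments: Iterable[CnvSegment], path, sample: str = "sample") -> None:
    """Write segments in IGV-compatible SEG layout (tab-separated)."""
    df = pd.DataFrame(
        [(sample, s.chromosome, s.start_bp, s.end_bp, s.n_probes,
          s.median_log2) for s in segments],
        columns=["ID", "chrom", "loc.start", "loc.end", "num.mark",
                 "seg.mean"])
    df.to_csv(path, sep="\t", index=False)
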