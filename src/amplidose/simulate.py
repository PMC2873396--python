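"""Synthetic cohorts with planted ground truth.

Generates every input the pipeline consumes: genome-wide aCGH log2
profiles with planted focal amplicons (down to two-probe
microamplifications) and losses over a regular oligo grid; expression
ratios linearly coupled to copy number with additive Gaussian noise; a
FISH cohort with per-nucleus test/centromere counts, latent risk groups
and exponential group-structured survival with censoring; and an
expression compendium with neuroblastoma / healthy-PNS / healthy-CNS /
healthy-other classes and planted tumor-elevated genes.

All randomness flows from the single seed in :class:`SimulationConfig`,
so identical configurations give byte-identical serialized outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import InvalidParameterError, SimulationConfig
from .cnv import CghProbe
from .fish import FishSample, score_sample
from .survival import GAIN_12Q24, MYCN_AMP, NEITHER, SurvivalRecord


@dataclass(frozen=True)
class PlantedSegment:
    """Ground-truth copy-number segment (1-based inclusive bp)."""

    chromosome: str
    start_bp: int
    end_bp: int
    true_log2: float

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise InvalidParameterError("segment start must not exceed end")


@dataclass
class Genome:
    """Chromosome sizes, a gene annotation table and the oligo grid."""

    chrom_length_bp: int
    genes: pd.DataFrame            # gene_id, symbol, chromosome, start_bp, end_bp, strand
    probe_positions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.probe_positions)


def generate_genome(n_chromosomes: int, chrom_length_bp: int, n_genes: int,
                    seed: int, probe_spacing_bp: int = 10_000) -> Genome:
    """Random non-overlapping gene annotation plus a regular probe grid.

    Genes are distributed round-robin over chromosomes, placed uniformly
    in disjoint slots so they never overlap, and sorted by position.
    Deterministic for a fixed seed.
    """
    if n_chromosomes < 1 or chrom_length_bp < 1 or n_genes < 1:
        raise InvalidParameterError("sizes must be positive")
    if chrom_length_bp < n_genes:
        raise InvalidParameterError("chromosome too short for requested genes")
    rng = np.random.default_rng(seed)
    per_chrom = [n_genes // n_chromosomes + (1 if i < n_genes % n_chromosomes else 0)
                 for i in range(n_chromosomes)]
    rows = []
    idx = 0
    for ci, n_on_chrom in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        if n_on_chrom == 0:
            continue
        # disjoint equal slots; the gene occupies a random sub-interval
        slot = chrom_length_bp // n_on_chrom
        for gi in range(n_on_chrom):
            lo = gi * slot + 1
            hi = min((gi + 1) * slot, chrom_length_bp)
            length = int(rng.integers(1, max(2, (hi - lo) // 2 + 1)))
            start = int(rng.integers(lo, hi - length + 1)) if hi - length >= lo else lo
            end = min(start + length - 1, hi)
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"ENSG{idx:011d}", f"GENE{idx}", chrom, start, end,
                         strand))
            idx += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "symbol", "chromosome",
                                        "start_bp", "end_bp", "strand"])
    genes = genes.sort_values(["chromosome", "start_bp"], ignore_index=True)
    probe_positions = {
        f"chr{ci + 1}": np.arange(1, chrom_length_bp + 1, probe_spacing_bp,
                                  dtype=np.int64)
        for ci in range(n_chromosomes)}
    return Genome(chrom_length_bp=chrom_length_bp, genes=genes,
                  probe_positions=probe_positions)


def _check_segments(genome: Genome, planted: Sequence[PlantedSegment]) -> None:
    by_chrom: dict[str, list[PlantedSegment]] = {}
    for seg in planted:
        if seg.chromosome not in genome.probe_positions:
            raise InvalidParameterError(f"unknown chromosome {seg.chromosome}")
        if seg.start_bp < 1 or seg.end_bp > genome.chrom_length_bp:
            raise InvalidParameterError(
                f"segment {seg} outside genome bounds [1, "
                f"{genome.chrom_length_bp}]")
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    for segs in by_chrom.values():
        segs.sort(key=lambda s: s.start_bp)
        for a, b in zip(segs, segs[1:]):
            if b.start_bp <= a.end_bp:
                raise InvalidParameterError(
                    f"overlapping planted segments: {a} / {b}")


def true_log2_at(planted: Sequence[PlantedSegment], chrom: str, bp: int) -> float:
    """Ground-truth copy-number level at a position (0 off any segment)."""
    for seg in planted:
        if seg.chromosome == chrom and seg.start_bp <= bp <= seg.end_bp:
            return seg.true_log2
    return 0.0


def generate_cgh_profile(genome: Genome,
                         planted: Sequence[PlantedSegment],
                         config: SimulationConfig) -> list[CghProbe]:
    """aCGH probes over the grid: segment level (0 off-segment) + noise."""
    _check_segments(genome, planted)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    probes: list[CghProbe] = []
    i = 0
    for chrom in genome.chromosomes:
        positions = genome.probe_positions[chrom]
        truth = np.zeros(positions.size)
        for seg in planted:
            if seg.chromosome == chrom:
                mask = (positions >= seg.start_bp) & (positions <= seg.end_bp)
                truth[mask] = seg.true_log2
        noise = (rng.normal(0.0, config.noise_sd, positions.size)
                 if config.noise_sd > 0 else np.zeros(positions.size))
        for pos, val in zip(positions, truth + noise):
            probes.append(CghProbe(f"oligo_{i:06d}", chrom, int(pos),
                                   float(val)))
            i += 1
    return probes


def generate_expression(genome: Genome,
                        planted: Sequence[PlantedSegment],
                        config: SimulationConfig) -> pd.DataFrame:
    """Per-gene expression log2 ratios coupled to copy number.

    One probe set per gene, positioned at the gene; expression =
    dosage_slope * true_log2(gene midpoint) + N(0, expression_noise_sd).
    Returns columns probe_set_id, gene_id, chrom, pos_bp, log2_ratio.
    """
    _check_segments(genome, planted)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rows = []
    for i, g in enumerate(genome.genes.itertuples(index=False)):
        mid = (g.start_bp + g.end_bp) // 2
        base = config.dosage_slope * true_log2_at(planted, g.chromosome, mid)
        noise = (float(rng.normal(0.0, config.expression_noise_sd))
                 if config.expression_noise_sd > 0 else 0.0)
        rows.append((f"{i}_at", g.gene_id, g.chromosome, int(mid),
                     base + noise))
    return pd.DataFrame(rows, columns=["probe_set_id", "gene_id", "chrom",
                                       "pos_bp", "log2_ratio"])


_GROUPS = ("both", "gain_only", "myc_only", "neither")


def generate_fish_cohort(n_tumors: int, config: SimulationConfig
                         ) -> tuple[list[FishSample], list[SurvivalRecord], pd.DataFrame]:
    """FISH cohort with latent risk groups and group-structured survival.

    Each tumor draws a latent group from the configured prevalences,
    20-60 nuclei with Poisson centromere counts (mean 2) and Poisson
    test counts whose mean is ratio x centromere mean (ratio 2 for
    gained tumors, 1 otherwise), an exponential survival time with the
    risk-group hazard, and uniform censoring at the configured rate.
    Returns scored samples, survival records with true risk groups, and
    a truth table.
    """
    if n_tumors < 1:
        raise InvalidParameterError("n_tumors must be >= 1")
    p_both = config.both_prevalence
    p_gain_only = config.gain_prevalence - p_both
    p_myc_only = config.myc_prevalence - p_both
    p_neither = 1.0 - p_both - p_gain_only - p_myc_only
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    groups = rng.choice(len(_GROUPS), size=n_tumors,
                        p=[p_both, p_gain_only, p_myc_only, p_neither])
    lo, hi = config.nuclei_range
    samples: list[FishSample] = []
    records: list[SurvivalRecord] = []
    truth_rows = []
    for t in range(n_tumors):
        grp = _GROUPS[groups[t]]
        gained = grp in ("both", "gain_only")
        myc = grp in ("both", "myc_only")
        n_nuclei = int(rng.integers(lo, hi + 1))
        ratio = config.gained_ratio_mean if gained else 1.0
        cen = rng.poisson(config.centromere_mean, n_nuclei)
        test = rng.poisson(ratio * config.centromere_mean, n_nuclei)
        tumor_id = f"T{t:04d}"
        samples.append(score_sample(tumor_id,
                                    list(zip(test.tolist(), cen.tolist())),
                                    min_nuclei=lo, max_nuclei=hi,
                                    myc_amplified=myc))
        risk = MYCN_AMP if myc else (GAIN_12Q24 if gained else NEITHER)
        hazard = config.group_hazards[risk]
        t_event = float(rng.exponential(1.0 / hazard))
        if config.censoring_rate > 0 and rng.random() < config.censoring_rate:
            time, event = float(rng.uniform(0, t_event)), False
            time = max(time, 1e-9)
        else:
            time, event = t_event, True
        records.append(SurvivalRecord(tumor_id, time, event, risk))
        truth_rows.append((tumor_id, grp, gained, myc, risk))
    truth = pd.DataFrame(truth_rows, columns=["tumor_id", "latent_group",
                                              "gained", "myc_amplified",
                                              "risk_group"])
    return samples, records, truth


def generate_compendium(n_per_class: int,
                        gene_list: Sequence[str],
                        elevated_genes: Sequence[str],
                        config: SimulationConfig,
                        class_sizes: Optional[dict[str, int]] = None,
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Expression compendium with planted neuroblastoma-elevated genes.

    Baseline expression is N(0, compendium_baseline_sd) everywhere;
    neuroblastoma samples get +elevated_effect on the elevated genes
    only. Returns (genes x samples frame, tissue-class labels).
    """
    from .screen import TISSUE_CLASSES, NEUROBLASTOMA

    missing = set(elevated_genes) - set(gene_list)
    if missing:
        raise InvalidParameterError(
            f"elevated genes not in gene list: {sorted(missing)}")
    sizes = class_sizes or {c: n_per_class for c in TISSUE_CLASSES}
    if any(n < 1 for n in sizes.values()):
        raise InvalidParameterError("every tissue class needs >= 1 sample")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    cols, labels = [], []
    for cls in TISSUE_CLASSES:
        for i in range(sizes.get(cls, 0)):
            cols.append(f"{cls.lower()}_{i:03d}")
            labels.append(cls)
    values = rng.normal(0.0, config.compendium_baseline_sd,
                        (len(gene_list), len(cols)))
    expr = pd.DataFrame(values, index=list(gene_list), columns=cols)
    classes = pd.Series(labels, index=cols, name="tissue_class")
    nb_cols = classes[classes == NEUROBLASTOMA].index
    expr.loc[list(elevated_genes), nb_cols] += config.elevated_effect
    return expr, classes


def write_truth(path, planted: Sequence[PlantedSegment],
                elevated_genes: Sequence[str],
                truth_table: Optional[pd.DataFrame] = None) -> None:
    """Serialize ground truth (planted segments, elevated genes, groups)."""
    payload = {
        "planted_segments": [
            {"chromosome": s.chromosome, "start_bp": s.start_bp,
             "end_bp": s.end_bp, "true_log2": s.true_log2}
            for s in planted],
        "elevated_genes": list(elevated_genes),
    }
    if truth_table is not None:
        payload["groups"] = truth_table.to_dict(orient="records")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
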