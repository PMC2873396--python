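"""Synthetic-data generator: determinism, planted truth, calibration."""

import io

import numpy as np
import pandas as pd
import pytest

from amplidose.config import InvalidParameterError, SimulationConfig
from amplidose.io import write_probes_tsv
from amplidose.simulate import (PlantedSegment, generate_cgh_profile,
                                generate_compendium, generate_expression,
                                generate_fish_cohort, generate_genome,
                                true_log2_at)

from conftest import exact_binomial_interval


class TestGenerateGenome:
    def test_fixed_seed_determinism(self):
        a = generate_genome(1, 1_000_000, 10, seed=7)
        b = generate_genome(1, 1_000_000, 10, seed=7)
        pd.testing.assert_frame_equal(a.genes, b.genes)
        assert all(np.array_equal(a.probe_positions[c], b.probe_positions[c])
                   for c in a.probe_positions)

    def test_zero_genes_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_genome(1, 1_000_000, 0, seed=1)

    def test_negative_sizes_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_genome(0, 1_000_000, 5, seed=1)
        with pytest.raises(InvalidParameterError):
            generate_genome(1, -5, 5, seed=1)

    @pytest.mark.parametrize("seed", range(5))
    def test_gene_intervals_within_bounds_and_disjoint(self, seed):
        g = generate_genome(3, 2_000_000, 120, seed=seed)
        assert (g.genes.start_bp >= 1).all()
        assert (g.genes.end_bp <= 2_000_000).all()
        assert (g.genes.start_bp <= g.genes.end_bp).all()
        for _, chrom_genes in g.genes.groupby("chromosome"):
            s = chrom_genes.sort_values("start_bp")
            assert (s.start_bp.to_numpy()[1:] > s.end_bp.to_numpy()[:-1]).all()
        assert g.genes.gene_id.is_unique


class TestCghProfile:
    def make(self, noise_sd, planted, seed=1, length=1_000_000):
        cfg = SimulationConfig(seed=seed, noise_sd=noise_sd)
        genome = generate_genome(1, length, 10, seed=seed,
                                 probe_spacing_bp=cfg.probe_spacing_bp)
        return genome, generate_cgh_profile(genome, planted, cfg)

    def test_zero_noise_probes_take_exact_segment_level(self):
        seg = PlantedSegment("chr1", 200_001, 400_000, 4.0)
        _, probes = self.make(0.0, [seg])
        for p in probes:
            expected = 4.0 if seg.start_bp <= p.position_bp <= seg.end_bp \
                else 0.0
            assert p.log2_ratio == expected

    def test_zero_noise_no_segments_all_zero(self):
        _, probes = self.make(0.0, [])
        assert all(p.log2_ratio == 0.0 for p in probes)

    def test_noise_mean_within_clt_bound(self):
        cfg = SimulationConfig(seed=3, noise_sd=0.2, probe_spacing_bp=100)
        genome = generate_genome(1, 1_000_000, 10, seed=3,
                                 probe_spacing_bp=100)
        probes = generate_cgh_profile(genome, [], cfg)
        n = len(probes)
        assert n >= 10_000
        mean = np.mean([p.log2_ratio for p in probes])
        assert abs(mean) <= 4 * 0.2 / np.sqrt(n)

    def test_segment_outside_genome_rejected(self):
        with pytest.raises(InvalidParameterError):
            self.make(0.0, [PlantedSegment("chr1", 1, 2_000_000, 4.0)])
        with pytest.raises(InvalidParameterError):
            self.make(0.0, [PlantedSegment("chr9", 1, 100, 4.0)])

    def test_overlapping_planted_segments_rejected(self):
        with pytest.raises(InvalidParameterError):
            self.make(0.0, [PlantedSegment("chr1", 1, 100_000, 4.0),
                            PlantedSegment("chr1", 50_000, 150_000, 2.0)])

    def test_serialized_output_byte_identical_for_fixed_seed(self):
        seg = [PlantedSegment("chr1", 100_001, 200_000, 3.0)]
        bufs = []
        for _ in range(2):
            _, probes = self.make(0.3, seg, seed=9)
            buf = io.StringIO()
            write_probes_tsv(probes, buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]


class TestExpression:
    def test_zero_noise_unit_slope_reproduces_copy_number(self):
        cfg = SimulationConfig(seed=2, expression_noise_sd=0.0,
                               dosage_slope=1.0)
        genome = generate_genome(1, 1_000_000, 50, seed=2)
        planted = [PlantedSegment("chr1", 1, 1_000_000, 2.0)]
        expr = generate_expression(genome, planted, cfg)
        assert (expr.log2_ratio == 2.0).all()

    def test_zero_slope_decouples_expression_from_copy_number(self):
        cfg = SimulationConfig(seed=4, dosage_slope=0.0,
                               expression_noise_sd=1.0)
        genome = generate_genome(1, 10_000_000, 2000, seed=4)
        planted = [PlantedSegment("chr1", 1, 5_000_000, 4.0)]
        expr = generate_expression(genome, planted, cfg)
        cn = np.array([true_log2_at(planted, c, p)
                       for c, p in zip(expr.chrom, expr.pos_bp)])
        r = np.corrcoef(cn, expr.log2_ratio)[0, 1]
        assert abs(r) < 4 / np.sqrt(len(expr))

    def test_fixed_seed_identical_matrices(self):
        cfg = SimulationConfig(seed=6)
        genome = generate_genome(1, 1_000_000, 30, seed=6)
        planted = [PlantedSegment("chr1", 1, 500_000, 3.0)]
        a = generate_expression(genome, planted, cfg)
        b = generate_expression(genome, planted, cfg)
        pd.testing.assert_frame_equal(a, b)


class TestFishCohort:
    def test_planted_gain_prevalence_within_binomial_interval(self):
        cfg = SimulationConfig(seed=8, gain_prevalence=0.42,
                               myc_prevalence=0.2, both_prevalence=0.03)
        samples, _, truth = generate_fish_cohort(500, cfg)
        n_gained_truth = int(truth.gained.sum())
        lo, hi = exact_binomial_interval(500, 0.42)
        assert lo <= n_gained_truth <= hi

    def test_no_censoring_means_all_events(self):
        cfg = SimulationConfig(seed=9, censoring_rate=0.0)
        _, records, _ = generate_fish_cohort(100, cfg)
        assert all(r.event for r in records)

    def test_impossible_prevalences_rejected(self):
        with pytest.raises(InvalidParameterError):
            SimulationConfig(gain_prevalence=0.1, myc_prevalence=0.1,
                             both_prevalence=0.2)
        with pytest.raises(InvalidParameterError):
            SimulationConfig(gain_prevalence=0.9, myc_prevalence=0.9,
                             both_prevalence=0.1)

    def test_nuclei_counts_within_configured_range(self):
        cfg = SimulationConfig(seed=10)
        samples, _, _ = generate_fish_cohort(50, cfg)
        assert all(20 <= len(s.nuclei) <= 60 for s in samples)

    def test_truth_table_consistent_with_scores(self):
        """Gained tumors separate from non-gained by ratio on average."""
        cfg = SimulationConfig(seed=12)
        samples, _, truth = generate_fish_cohort(300, cfg)
        ratios = {s.tumor_id: s.ratio for s in samples}
        gained = [ratios[t] for t, g in zip(truth.tumor_id, truth.gained) if g]
        other = [ratios[t] for t, g in zip(truth.tumor_id, truth.gained)
                 if not g]
        assert np.mean(gained) > 1.5 > np.mean(other)

    def test_determinism(self):
        cfg = SimulationConfig(seed=13)
        a = generate_fish_cohort(40, cfg)
        b = generate_fish_cohort(40, cfg)
        assert [(s.tumor_id, s.nuclei) for s in a[0]] == \
            [(s.tumor_id, s.nuclei) for s in b[0]]
        assert [(r.patient_id, r.time, r.event) for r in a[1]] == \
            [(r.patient_id, r.time, r.event) for r in b[1]]


class TestCompendium:
    names = [f"G{i}" for i in range(20)]

    def test_elevated_genes_must_be_subset(self):
        with pytest.raises(InvalidParameterError):
            generate_compendium(10, self.names, ["NOT_A_GENE"],
                                SimulationConfig(seed=1))

    def test_empty_class_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_compendium(10, self.names, [], SimulationConfig(seed=1),
                                class_sizes={"NEUROBLASTOMA": 0,
                                             "HEALTHY_PNS": 5,
                                             "HEALTHY_CNS": 5,
                                             "HEALTHY_OTHER": 5})

    def test_fixed_seed_byte_identical_serialization(self):
        cfg = SimulationConfig(seed=21)
        outs = []
        for _ in range(2):
            expr, classes = generate_compendium(10, self.names,
                                                self.names[:2], cfg)
            buf = io.StringIO()
            expr.to_csv(buf, sep="\t")
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_shift_applied_only_to_elevated_genes_in_tumors(self):
        cfg = SimulationConfig(seed=22, elevated_effect=100.0)
        expr, classes = generate_compendium(15, self.names, ["G0"], cfg)
        nb = classes[classes == "NEUROBLASTOMA"].index
        healthy = classes[classes != "NEUROBLASTOMA"].index
        assert expr.loc["G0", nb].mean() > 50
        assert abs(expr.loc["G0", healthy].mean()) < 5
        assert abs(expr.loc["G1", nb].mean()) < 5

    def test_null_screen_false_positive_rate_bounded(self):
        """With no planted effect the all-three-significant pass rule
        fires at most about alpha per gene (union logic makes it rarer)."""
        from amplidose.screen import screen_genes
        cfg = SimulationConfig(seed=23, elevated_effect=0.0)
        names = [f"G{i}" for i in range(200)]
        expr, classes = generate_compendium(30, names, [], cfg)
        _, report = screen_genes(expr, classes, names)
        _, hi = exact_binomial_interval(200, 0.05)
        assert report["n_passing"] <= hi
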