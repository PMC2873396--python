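# amplidose

Integrative discovery of copy-number-driven genes in neuroblastoma:
aCGH amplicon calling, DNA–RNA dosage integration, FISH gain scoring
with survival stratification, and an expression-compendium screen — for
researchers analyzing tumor copy-number and expression cohorts, with a
synthetic-data generator that makes the whole pipeline testable against
planted ground truth.

## The method

**Amplicon calling.** An aCGH oligo with log2 copy-number ratio
*r* > 2 is amplified, *r* > 3.5 a high-level amplification, and
*r* < −1 (linear ratio < 0.5) a loss. Maximal runs of same-direction
probes become reported segments; two probes suffice, so focal
microamplifications are kept.

**Dosage integration.** Each expression probe set is mapped to a
genomic position (Ensembl gene midpoint, vendor position as fallback)
and assigned the median log2 ratio of aCGH oligos within 50 kb. Per
sample, the top and bottom 7% of expression ratios are called OVER and
UNDER. Binning genes by copy number exposes the dosage effect: the OVER
frequency rises monotonically with copy number. Candidate driver genes
are those both amplified (windowed CN > 2) and called OVER.

**FISH and survival.** Per tumor, ratio = mean(test signals) /
mean(centromere signals) over 20–60 scored nuclei; ratio ≥ 1.5 is a
gain. Gain is cross-tabulated against MYCN amplification (Pearson
chi-square), and patients stratify into three risk groups —
MYCN-amplified, 12q24.31-gained, neither — compared by Kaplan–Meier
curves and the log-rank test.

**Compendium screen.** For each amplicon gene, one-sided
Mann–Whitney–Wilcoxon tests compare neuroblastoma expression against
healthy nervous-system, healthy peripheral-nervous-system and all
healthy samples; a gene passes when all three p < 0.05. MYCN, MEIS1 and
ALK act as positive controls; passing genes are ranked by the tumor
−healthy median difference.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

```python
from amplidose import *

cfg = SimulationConfig(seed=7)
genome = generate_genome(1, 5_000_000, 400, seed=7,
                         probe_spacing_bp=cfg.probe_spacing_bp)
planted = [PlantedSegment("chr1", 1_000_001, 1_200_000, 4.0),
           PlantedSegment("chr1", 3_000_001, 3_020_000, 4.0)]
probes = generate_cgh_profile(genome, planted, cfg)
for s in call_segments(probes):
    print(s.locus_class, format_region(s), f"n_probes={s.n_probes}",
          f"median={s.median_log2:.2f}")

expr = generate_expression(genome, planted, cfg)
records = [ExpressionRecord(r.probe_set_id, r.log2_ratio, gene_id=r.gene_id)
           for r in expr.itertuples(index=False)]
integrated, report = integrate(records, genome.genes.set_index("gene_id"),
                               probes)
print("amplified+overexpressed genes:",
      len(amplified_overexpressed(integrated)))

samples, survival, truth = generate_fish_cohort(200, cfg)
ct = cohort_crosstab(samples)
print(f"gain: {ct.pct_gain}% of {ct.n_informative} informative tumors; "
      f"both alterations in {ct.pct_both_given_gain}% of gained")
stat, df, p = logrank_test(survival)
print(f"log-rank chi2={stat:.1f}, df={df}, p={p:.2e}")
```

prints

```
HIGH_AMP 1.0-1.2 Mb n_probes=20 median=3.94
HIGH_AMP 3.0-3.0 Mb n_probes=2 median=3.96
amplified+overexpressed genes: 16
gain: 42% of 200 informative tumors; both alterations in 8% of gained
log-rank chi2=28.0, df=2, p=8.44e-07
```

Both planted amplicons are recovered, including the two-probe
microamplification at 3.0 Mb; the genes under them are flagged as
amplified and overexpressed; the simulated FISH cohort reproduces its
configured 42% gain prevalence; and the three risk groups separate
sharply in survival.

The same pipeline is available from the shell:

```bash
amplidose simulate --outdir sim/
amplidose call-cnv --probes sim/acgh_probes.tsv --out segments.seg
amplidose fish --counts sim/fish_counts.tsv \
    --annot sim/fish_annotations.tsv --out fish/
amplidose survival --records sim/survival.tsv --out surv/
```

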