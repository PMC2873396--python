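# Methods

## Overview

`amplidose` implements an integrative framework for identifying
clinically relevant copy-number-driven genes in neuroblastoma. Four
analysis stages run over array-CGH, expression, FISH and survival data:

1. **Amplicon/loss calling** — threshold classification of aCGH log2
   copy-number ratios and merging of same-direction probe runs.
2. **Dosage integration** — joining expression probe sets to a windowed
   copy-number summary, percentile-based over/underexpression calls,
   and a copy-number-bin frequency analysis of the dosage effect.
3. **FISH gain scoring and survival stratification** — per-tumor
   test/centromere signal ratios, a gain × MYCN crosstab, three-level
   risk grouping, Kaplan–Meier curves and the log-rank test.
4. **Compendium screen** — one-sided rank-sum comparisons of
   neuroblastoma expression against three healthy tissue groupings with
   an all-three-significant pass rule.

A synthetic-data generator supplies every input with planted ground
truth, so the whole pipeline can be validated end to end without any
external download.

## Copy-number calling

Each aCGH oligo carries a log2 tumor/reference ratio. Loci are
classified by fixed cutoffs: ratio > 2 → amplification, > 3.5 →
high-level amplification, below the loss cutoff → loss, otherwise
neutral. All cutoffs are exclusive at the stated value, so a ratio of
exactly 2.0 is neutral and exactly 3.5 is an ordinary amplification.

The loss cutoff deserves a note. The natural pairing with "linear ratio
< 0.5" is log2 < −1.0, which is the package default and the standard
hemizygous-loss convention; a literal "log2 ratio < 0.5" reading is
also available via `AnalysisThresholds(loss_log2=0.5)`, but it labels
copy-neutral loci as lost and is not recommended.

Segments are maximal runs of probes sharing an alteration direction
(amplified = AMP or HIGH_AMP; lost = LOSS). A run may bridge at most
`max_gap_probes` interior non-qualifying probes (default 0 — no
bridging, since no gap tolerance is part of the published rule); runs
with fewer than `min_probes` (default 2) qualifying probes are
discarded, which keeps two-probe microamplifications while suppressing
single-probe noise. A run containing any high-level probe is reported
once as HIGH_AMP. Boundaries are the first and last qualifying probe
positions, 1-based inclusive; "Mb from the p-telomere" is
`position_bp / 1e6` rounded half-up to one decimal. No smoothing or
change-point segmentation (CBS, HMM) is applied — plain thresholding is
the method.

## Dosage integration

Expression probe sets are mapped to genomic positions: the matched
gene's interval midpoint (rounded down — the midpoint minimizes the
worst-case distance to the gene body), else the array vendor's
base-pair position, else the record is excluded and counted. Multiple
probe sets per gene are integrated independently; no collapsing.

Each position receives the **median** log2 ratio of aCGH oligos on the
same chromosome within 50 kb (closed interval: a probe at exactly
50,000 bp qualifies). If no oligo qualifies, the copy-number ratio is
absent and the gene drops out of the bin analysis (reported).

Over/underexpression is called per sample at the symmetric 7th
percentiles: with N records, exactly k = floor(N·7/100) records are
OVER and k UNDER. The rule is rank-based, not an interpolated quantile,
so call counts are reproducible set sizes; boundary ties resolve by
probe-set identifier (records ordered by (ratio, probe_set_id), first k
UNDER, last k OVER). The percentile pool is by default all records in
the sample, before mapping (`call_before_mapping=False` restricts it to
mapped records).

For the dosage-effect analysis genes are placed into half-open
(lower, upper] copy-number bins and the OVER/UNDER frequency is
computed per bin. The default interior edges (−1, −0.5, 0.5, 1, 2, 3.5)
align with the calling thresholds; they are a package choice and fully
configurable. Under a positive dosage slope the OVER frequency rises
across bins, which the tests verify on synthetic data.

`amplified_overexpressed` intersects amplification (windowed CN > 2)
with OVER calls, sorted by copy number descending — the gene-level
candidate report.

## FISH scoring and survival

Per tumor, ratio = mean(test counts) / mean(centromere counts) over the
scored nuclei; a ratio ≥ 1.5 (inclusive — the stated fold change counts
as gain) is a copy-number gain. The ratio of means is used rather than
the mean of per-nucleus ratios: it is robust to single nuclei with zero
centromere signals and matches the aggregate "mean ratio" notion.
Tumors with fewer than 20 or more than 60 scored nuclei, or a zero
centromere mean, are marked non-informative rather than rejected; they
are excluded from all cohort denominators. Samples with unknown MYCN
status are excluded from the gain × MYCN cell counts and reported
separately. Percentages are rounded half-up to integer percent.

Association between gain and MYCN amplification uses the plain Pearson
chi-square test (no Yates correction by default; configurable), with
the statistic Σ(O−E)²/E and df = (r−1)(c−1).

Risk grouping is three-level: MYCN-amplified (worst prognosis),
12q24.31-gained without MYCN amplification (intermediate), neither
(best). A tumor with both alterations goes to the MYCN-amplified group
— the worst-prognosis marker dominates clinically — with
`myc_dominates=False` available to place it with the gained group.
Kaplan–Meier curves and the k-sample log-rank test are computed with
`lifelines` (product-limit estimator; hypergeometric observed-vs-
expected statistic on k−1 degrees of freedom); deaths precede
censorings at tied times, the standard convention. Cox multivariate
regression is deliberately out of scope; clinical covariates pass
through untouched.

## Compendium screen

For each amplicon gene with compendium data, three one-sided
Mann–Whitney–Wilcoxon tests compare neuroblastoma samples against (i)
all healthy nervous-system samples (peripheral ∪ central), (ii) healthy
peripheral nervous system alone, and (iii) all healthy samples. The
one-sided alternative ("higher in tumors") is used throughout, with a
two-sided option. The p-value is exact (full enumeration of rank
assignments, via `scipy.stats.mannwhitneyu(method="exact")`) when the
samples are tie-free and |x|·|y| ≤ 400, otherwise the normal
approximation with tie-corrected variance and continuity correction.

A gene **passes** when all three raw p-values are below α = 0.05. No
multiple-testing correction is applied by default, matching a raw-p
reporting convention; a Bonferroni option (α/3 per comparison) exists
but is off by default. Genes absent from the compendium — or absent
from every sample of a comparison group, emulating mixed array
generations as per-sample missing values — are marked non-informative
and counted, giving the informative-gene fraction.

Known neuroblastoma oncogenes (MYCN, MEIS1, ALK) serve as positive
controls: their three p-values are reported and a warning is emitted if
any fails or is missing; the screen proceeds regardless.

Passing genes are ranked by a documented effect-size score — the
neuroblastoma median minus the all-healthy median, ties broken by the
smaller all-healthy p-value. "Strongest and most specific activation"
has no closed published criterion; this score is the package's own
stand-in and is labelled as such.

Human-readable output floors displayed p-values at "<1e-16"; machine
output keeps full precision.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated:

- **Genome**: configurable chromosome count and length; genes placed in
  disjoint slots (never overlapping), one expression probe set per gene
  (many-to-one mapping is exercised via hand-built fixtures instead, to
  keep truth tables unambiguous); a regular oligo grid (default
  spacing 10 kb, dense enough that every gene has probes within the
  50-kb window).
- **aCGH**: probe log2 ratio = planted segment level (0 off-segment,
  the copy-neutral baseline) + additive Gaussian noise (default
  SD 0.1). The standard two-channel array model; no GC waves, scanner
  artifacts or image-level effects are simulated.
- **Expression**: log2 ratio = dosage_slope × true copy number at the
  gene midpoint + Gaussian noise (slope 1.0, SD 0.5 by default).
- **FISH cohort**: a latent group (both / gain-only / MYCN-only /
  neither) drawn from prevalences defaulting to the observed cohort
  composition (gain 14/33, MYCN 7/33, both 1/33); 20–60 nuclei per
  tumor; centromere counts Poisson with mean 2 (diploid reference
  expectation) and test counts Poisson with mean ratio × 2, ratio 2 for
  gained tumors and 1 otherwise, so gained tumors sit clearly above the
  1.5 cutoff.
- **Survival**: exponential times with per-group hazards (default
  0.3 / 0.2 / 0.1, a 3:2:1 worst-to-best ordering that makes log-rank
  power predictable); censoring replaces the event with a uniform
  earlier time at the configured rate (default 0.2).
- **Compendium**: baseline N(0, 1) expression for all four tissue
  classes; neuroblastoma samples receive +3σ (default) on planted
  elevated genes only.

All randomness derives from the single config seed (independent
substreams per generator via seed sequences), so identical configs give
byte-identical serialized outputs. The reference pool behind real
expression ratios is modeled only implicitly through the log2 ratios.

What passing tests show — and what they do not: the synthetic data have
ideal properties (exact segment levels, Gaussian noise, regular probe
spacing, Poisson counts, exponential survival). Recovery and
calibration results demonstrate correctness of the algorithms under
those conditions, not robustness to wave artifacts, probe-response
heterogeneity, normalization errors or informative censoring in real
cohorts.

## Numerical choices and degenerate inputs

- Medians of even-sized windows are the midpoint of the two central
  values (`numpy.median`).
- Percent displays round half-up (`decimal`), matching printed cohort
  percentages; float rounding is never used for reported percent.
- Non-finite log2 ratios, non-positive intensities, empty record lists,
  unsorted probe input, unsorted bin edges, impossible prevalence
  combinations and empty comparison groups all raise typed errors;
  a zero centromere mean is a non-informative sample, not an error.
- The k-sample log-rank variance uses lifelines' generalized inverse,
  which tolerates singular covariance.

## Problem sizes used in validation

The bundled acceptance run uses a 5-Mb single-chromosome genome
(500 probes at 10-kb spacing, 400 genes) for amplicon recovery, a
500-tumor FISH cohort for prevalence recovery, 30 samples per tissue
class with 40 screened genes (500 null genes for calibration), 200
simulated 90-tumor cohorts for log-rank type-I error and a 5,000-gene
four-chromosome genome for the dosage-bin analysis — sizes chosen so
every stage has comfortable statistical resolution while the whole run
completes in seconds.

## Known limitations

- No probe-level QC gate: baseline-variation control hybridizations
  have no published numeric rule, so none is enforced.
- Thresholding-based calling has no explicit noise model; very noisy
  profiles will fragment segments (the two-probe minimum is the only
  guard).
- The windowed median ties copy number to a single position per probe
  set; genes spanning a segment boundary take whichever level dominates
  the window.
- The activation ranking score is a heuristic, not an inference.
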