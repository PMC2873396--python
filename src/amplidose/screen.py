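"""In silico compendium screen for tumor-elevated amplicon genes.

For each amplicon gene with compendium data, the neuroblastoma samples
are compared against three healthy groupings — the whole nervous system
(peripheral plus central), the peripheral nervous system alone, and all
healthy tissues — with one-sided Mann-Whitney-Wilcoxon rank-sum tests
for higher tumor expression. A gene passes when all three raw p-values
fall below alpha; known neuroblastoma oncogenes (MYCN, MEIS1, ALK by
default) serve as positive controls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisThresholds, InvalidParameterError
from .fish import InvalidCohortError

log = logging.getLogger(__name__)

NEUROBLASTOMA = "NEUROBLASTOMA"
HEALTHY_PNS = "HEALTHY_PNS"
HEALTHY_CNS = "HEALTHY_CNS"
HEALTHY_OTHER = "HEALTHY_OTHER"
TISSUE_CLASSES = (NEUROBLASTOMA, HEALTHY_PNS, HEALTHY_CNS, HEALTHY_OTHER)

DEFAULT_CONTROLS = ("MYCN", "MEIS1", "ALK")

#: exact enumeration limit on the product of the two sample sizes
EXACT_LIMIT = 400


@dataclass
class ScreenResult:
    gene: str
    informative: bool
    p_vs_nervous: Optional[float] = None
    p_vs_pns: Optional[float] = None
    p_vs_all_healthy: Optional[float] = None
    passes: bool = False


def mww_rank_sum(x: Sequence[float], y: Sequence[float],
                 alternative: str = "greater") -> tuple[float, float]:
    """One-sided Mann-Whitney-Wilcoxon rank-sum test.

    Exact p by complete enumeration of rank assignments when the
    samples are tie-free and |x|*|y| <= 400; otherwise the normal
    approximation with tie-corrected variance and continuity
    correction. Returns (U statistic for x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (no_ties and x.size * y.size <= EXACT_LIMIT) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _groupings(classes: pd.Series) -> dict[str, np.ndarray]:
    """Boolean masks for the three healthy comparison groupings."""
    return {
        "nervous": classes.isin([HEALTHY_PNS, HEALTHY_CNS]).to_numpy(),
        "pns": (classes == HEALTHY_PNS).to_numpy(),
        "all_healthy": classes.isin(
            [HEALTHY_PNS, HEALTHY_CNS, HEALTHY_OTHER]).to_numpy(),
    }


def screen_genes(expression: pd.DataFrame,
                 classes: pd.Series,
                 gene_list: Sequence[str],
                 thresholds: AnalysisThresholds = AnalysisThresholds(),
                 bonferroni: bool = False,
                 ) -> tuple[list[ScreenResult], dict]:
    """Screen amplicon genes for elevated neuroblastoma expression.

    ``expression`` is a genes x samples frame (NaN = gene missing on
    that sample's array generation); ``classes`` labels each sample
    column with a tissue class. A gene passes when all three one-sided
    p-values are below alpha (optionally Bonferroni-adjusted for the
    three comparisons). Genes absent from the compendium are marked
    non-informative; the report carries the informative fraction.
    """
    classes = classes.reindex(expression.columns)
    nb_mask = (classes == NEUROBLASTOMA).to_numpy()
    healthy = _groupings(classes)
    if nb_mask.sum() == 0 or any(m.sum() == 0 for m in healthy.values()):
        raise InvalidCohortError("every comparison group needs >= 1 sample")
    alpha = thresholds.alpha / 3 if bonferroni else thresholds.alpha
    results: list[ScreenResult] = []
    for gene in gene_list:
        if gene not in expression.index:
            results.append(ScreenResult(gene=gene, informative=False))
            continue
        row = expression.loc[gene].to_numpy(dtype=float)
        present = np.isfinite(row)
        nb = row[nb_mask & present]
        if nb.size == 0:
            results.append(ScreenResult(gene=gene, informative=False))
            continue
        ps = {}
        for name, mask in healthy.items():
            vals = row[mask & present]
            if vals.size == 0:
                ps = None
                break
            ps[name] = mww_rank_sum(nb, vals, "greater")[1]
        if ps is None:
            results.append(ScreenResult(gene=gene, informative=False))
            continue
        results.append(ScreenResult(
            gene=gene, informative=True,
            p_vs_nervous=ps["nervous"], p_vs_pns=ps["pns"],
            p_vs_all_healthy=ps["all_healthy"],
            passes=all(p < alpha for p in ps.values())))
    n_inf = sum(r.informative for r in results)
    report = {
        "n_genes": len(results),
        "n_informative": n_inf,
        "informative_pct": 100.0 * n_inf / len(results) if results else 0.0,
        "n_passing": sum(r.passes for r in results),
    }
    return results, report


def check_positive_controls(expression: pd.DataFrame,
                            classes: pd.Series,
                            control_genes: Sequence[str] = DEFAULT_CONTROLS,
                            thresholds: AnalysisThresholds = AnalysisThresholds(),
                            ) -> dict:
    """Run the screen on known oncogene controls; warn when any fails.

    Missing controls produce a warning, not a failure.
    """
    present = [g for g in control_genes if g in expression.index]
    missing = [g for g in control_genes if g not in expression.index]
    if missing:
        warnings.warn(f"positive controls missing from compendium: {missing}",
                      stacklevel=2)
    results, _ = screen_genes(expression, classes, present, thresholds) \
        if present else ([], None)
    all_pass = bool(present) and all(r.passes for r in results)
    if present and not all_pass:
        warnings.warn("one or more positive controls failed the screen",
                      stacklevel=2)
    return {"controls": {r.gene: {"p_vs_nervous": r.p_vs_nervous,
                                  "p_vs_pns": r.p_vs_pns,
                                  "p_vs_all_healthy": r.p_vs_all_healthy,
                                  "passes": r.passes} for r in results},
            "missing": missing, "all_pass": all_pass}


def rank_activation(results: Sequence[ScreenResult],
                    expression: pd.DataFrame,
                    classes: pd.Series) -> pd.DataFrame:
    """Order passing genes by effect size.

    Score = neuroblastoma median minus all-healthy median (per gene,
    over samples with data); ties broken by smaller p vs all healthy.
    Returns an empty frame when nothing passes.
    """
    classes = classes.reindex(expression.columns)
    nb_mask = (classes == NEUROBLASTOMA).to_numpy()
    healthy_mask = _groupings(classes)["all_healthy"]
    rows = []
    for r in results:
        if not r.passes:
            continue
        vals = expression.loc[r.gene].to_numpy(dtype=float)
        present = np.isfinite(vals)
        score = (np.median(vals[nb_mask & present])
                 - np.median(vals[healthy_mask & present]))
        rows.append((r.gene, float(score), r.p_vs_all_healthy))
    out = pd.DataFrame(rows, columns=["gene", "activation_score",
                                      "p_vs_all_healthy"])
    return out.sort_values(["activation_score", "p_vs_all_healthy"],
                           ascending=[False, True], ignore_index=True)


def format_p(p: float) -> str:
    """Human-readable p-value with a display floor of 1e-16."""
    return "<1e-16" if p < 1e-16 else f"{p:.3g}"
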