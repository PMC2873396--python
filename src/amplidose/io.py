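"""Plain-text (TSV/JSON) readers and writers for pipeline inputs/outputs."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .cnv import CghProbe
from .fish import FishSample
from .integration import ExpressionRecord

PROBE_COLUMNS = ["probe_id", "chrom", "pos_bp", "log2_ratio"]
EXPR_COLUMNS = ["probe_set_id", "gene_id", "pos_bp", "log2_ratio"]
FISH_COLUMNS = ["tumor_id", "nucleus_id", "test_count", "centromere_count"]


def write_probes_tsv(probes: Sequence[CghProbe], path) -> None:
    pd.DataFrame(
        [(p.probe_id, p.chromosome, p.position_bp, p.log2_ratio)
         for p in probes],
        columns=PROBE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_probes_tsv(path) -> list[CghProbe]:
    df = pd.read_csv(path, sep="\t")
    return [CghProbe(str(r.probe_id), str(r.chrom), int(r.pos_bp),
                     float(r.log2_ratio)) for r in df.itertuples(index=False)]


def read_expression_tsv(path, mapping_path=None) -> list[ExpressionRecord]:
    """Read expression records; optional mapping TSV supplies gene ids
    and fallback positions (probe_set_id, gene_id, fallback_chrom,
    fallback_bp)."""
    df = pd.read_csv(path, sep="\t")
    mapping = None
    if mapping_path is not None:
        mapping = pd.read_csv(mapping_path, sep="\t").set_index("probe_set_id")
    out = []
    for r in df.itertuples(index=False):
        gene_id = getattr(r, "gene_id", None)
        fallback = None
        if mapping is not None and r.probe_set_id in mapping.index:
            m = mapping.loc[r.probe_set_id]
            gene_id = m.get("gene_id", gene_id)
            if pd.notna(m.get("fallback_chrom")) and pd.notna(m.get("fallback_bp")):
                fallback = (str(m["fallback_chrom"]), int(m["fallback_bp"]))
        elif {"chrom", "pos_bp"} <= set(df.columns):
            fallback = (str(r.chrom), int(r.pos_bp))
        out.append(ExpressionRecord(
            probe_set_id=str(r.probe_set_id),
            log2_expression_ratio=float(r.log2_ratio),
            gene_id=None if pd.isna(gene_id) else str(gene_id),
            fallback_position=fallback))
    return out


def write_fish_tsv(samples: Sequence[FishSample], path, annot_path=None) -> None:
    rows = [(s.tumor_id, i, t, c)
            for s in samples for i, (t, c) in enumerate(s.nuclei)]
    pd.DataFrame(rows, columns=FISH_COLUMNS).to_csv(path, sep="\t", index=False)
    if annot_path is not None:
        pd.DataFrame(
            [(s.tumor_id, s.myc_amplified) for s in samples],
            columns=["tumor_id", "myc_status"]).to_csv(annot_path, sep="\t",
                                                       index=False)


def read_fish_tsv(path, annot_path=None) -> list[tuple[str, list, object]]:
    """Group nucleus-level counts by tumor; returns
    (tumor_id, [(test, cen), ...], myc_status or None) tuples."""
    df = pd.read_csv(path, sep="\t")
    myc = {}
    if annot_path is not None:
        a = pd.read_csv(annot_path, sep="\t")
        myc = {str(r.tumor_id): (None if pd.isna(r.myc_status)
                                 else bool(r.myc_status))
               for r in a.itertuples(index=False)}
    out = []
    for tumor_id, grp in df.groupby("tumor_id", sort=True):
        nuclei = list(zip(grp["test_count"].astype(int),
                          grp["centromere_count"].astype(int)))
        out.append((str(tumor_id), nuclei, myc.get(str(tumor_id))))
    return out


def write_survival_tsv(records, path) -> None:
    pd.DataFrame(
        [(r.patient_id, r.time, int(r.event), r.risk_group) for r in records],
        columns=["patient_id", "time", "event", "risk_group"]
    ).to_csv(path, sep="\t", index=False)


def read_survival_tsv(path):
    from .survival import records_from_frame
    return records_from_frame(pd.read_csv(path, sep="\t"))


def write_compendium_tsv(expression: pd.DataFrame, classes: pd.Series,
                         expr_path, annot_path) -> None:
    expression.to_csv(expr_path, sep="\t", index_label="gene")
    classes.rename_axis("sample_id").to_frame().to_csv(annot_path, sep="\t")


def read_compendium_tsv(expr_path, annot_path) -> tuple[pd.DataFrame, pd.Series]:
    expr = pd.read_csv(expr_path, sep="\t", index_col="gene")
    annot = pd.read_csv(annot_path, sep="\t", index_col="sample_id")
    return expr, annot["tissue_class"]
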