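"""Per-class summary report and class-comparison statistics.

``assemble_gene_table`` joins every upstream per-gene result into one
DataFrame; ``build_report`` condenses it to the per-class summary (rows of
counts/percentages and means, columns All / Type I / Type II / Previously
Known) and runs the class-comparison tests (each New class against the
Previously Known class: chi-square for frequencies, KS + Welch for means).
All percentages are printed with one decimal; reruns on the same inputs
produce byte-identical files.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .models import ClassLabel, GeneModel, KNOWN, TYPE_I, TYPE_II
from .evidence import EvidenceMatrix
from .stats import chisq_prop, mean_comparison

CLASS_COLUMNS = ["All", TYPE_I, TYPE_II, KNOWN]

BOOLEAN_FEATURES = [
    ("single_exon", "Single coding-exon genes"),
    ("multi_exon", "Multi coding-exon genes"),
    ("peptide", "Genes with a peptide match"),
    ("homolog", "Genes overlapping a protein-homolog alignment"),
    ("dmel_homolog", "Genes overlapping a Dipteran-reference protein alignment"),
    ("transcript_any", "Genes with any transcript overlap"),
    ("spliced_any", "Genes with spliced transcript overlap"),
    ("no_spliced", "Genes without spliced transcript overlap"),
    ("broad", "Broadly expressed genes (all designated tissues)"),
    ("narrow", "Narrowly expressed genes (single tissue)"),
    ("biological_gene_evidence", "Genes with biological gene evidence"),
    ("any_support", "Genes with any support incl. conservation"),
]
MEAN_FEATURES = [
    ("cds_length", "Average CDS length (nt)"),
    ("n_coding_exons", "Average number of coding exons"),
    ("weighted_gc_pct", "Average GC of compositional domain (%)"),
    ("enc", "Average effective number of codons"),
]


def assemble_gene_table(genes: Sequence[GeneModel],
                        labels: Sequence[ClassLabel],
                        evidence: EvidenceMatrix,
                        breadth: pd.Series,
                        weighted_gc: Mapping[str, Optional[float]],
                        enc_values: Mapping[str, Optional[float]]) -> pd.DataFrame:
    idx = pd.Index([g.id for g in genes], name="gene_id")
    df = pd.DataFrame(index=idx)
    class_of = {l.gene_id: l.gene_class for l in labels}
    df["gene_class"] = [class_of[gid] for gid in idx]
    df["cds_length"] = [g.cds_length for g in genes]
    df["n_coding_exons"] = [g.n_coding_exons for g in genes]
    df["single_exon"] = df["n_coding_exons"] == 1
    df["multi_exon"] = ~df["single_exon"]
    ev = evidence.table.reindex(idx)
    for col in ("peptide", "homolog", "dmel_homolog", "transcript_any",
                "spliced_any", "unspliced_any", "biological_gene_evidence", "any_support"):
        df[col] = ev[col].fillna(False)
    for col in ev.columns:
        if col.startswith("conservation:"):
            df[col] = ev[col].fillna(False)
    df["no_spliced"] = ~df["spliced_any"]
    br = breadth.reindex(idx)
    df["breadth"] = br
    df["broad"] = br == "broad"
    df["narrow"] = br == "narrow"
    df["weighted_gc_pct"] = [
        None if weighted_gc.get(gid) is None else 100.0 * weighted_gc[gid] for gid in idx
    ]
    df["enc"] = [enc_values.get(gid) for gid in idx]
    return df


def _per_class(df: pd.DataFrame):
    yield "All", df
    for cls in (TYPE_I, TYPE_II, KNOWN):
        yield cls, df[df["gene_class"] == cls]


def build_report(gene_table: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
    """Per-class report rows plus New-vs-Known comparison statistics."""
    rows = []
    n_all = len(gene_table)
    counts_row = {"feature": "Number of genes"}
    for cls, sub in _per_class(gene_table):
        counts_row[cls] = f"{len(sub)} ({100.0 * len(sub) / n_all:.1f}%)" if n_all else "0"
    rows.append(counts_row)
    bool_feats = [f for f in BOOLEAN_FEATURES if f[0] in gene_table.columns]
    bool_feats += [(c, f"Genes aligning to informant {c.split(':', 1)[1]}")
                   for c in gene_table.columns if c.startswith("conservation:")]
    for col, label in bool_feats:
        row = {"feature": label}
        for cls, sub in _per_class(gene_table):
            n = len(sub)
            k = int(sub[col].sum())
            row[cls] = f"{k} ({100.0 * k / n:.1f}%)" if n else "0"
        rows.append(row)
    for col, label in MEAN_FEATURES:
        if col not in gene_table.columns:
            continue
        row = {"feature": label}
        for cls, sub in _per_class(gene_table):
            vals = pd.to_numeric(sub[col], errors="coerce").dropna()
            row[cls] = f"{vals.mean():.2f}" if len(vals) else "NA"
        rows.append(row)
    report = pd.DataFrame(rows, columns=["feature"] + CLASS_COLUMNS)

    comparisons: list[dict] = []
    known = gene_table[gene_table["gene_class"] == KNOWN]
    for cls in (TYPE_I, TYPE_II):
        sub = gene_table[gene_table["gene_class"] == cls]
        if len(sub) == 0 or len(known) == 0:
            continue
        for col, label in bool_feats:
            res = chisq_prop(int(sub[col].sum()), len(sub), int(known[col].sum()), len(known))
            comparisons.append({
                "feature": col, "classes": f"{cls} vs {KNOWN}", "test": "proportion_chisq",
                "statistic": res.statistic, "p_reported": res.p_value, "reason": res.reason,
            })
        for col, label in MEAN_FEATURES:
            if col not in gene_table.columns:
                continue
            a = pd.to_numeric(sub[col], errors="coerce").dropna()
            b = pd.to_numeric(known[col], errors="coerce").dropna()
            if len(a) < 2 or len(b) < 2:
                continue
            mc = mean_comparison(a, b)
            comparisons.append({
                "feature": col, "classes": f"{cls} vs {KNOWN}", "test": "mean_ks_welch",
                "statistic": [mc.ks_statistic, mc.welch_statistic],
                "p_reported": mc.p_reported,
                "direction": "lower" if a.mean() < b.mean() else "higher",
            })
    return report, comparisons


def write_report(report: pd.DataFrame, path: str) -> None:
    report.to_csv(path, sep="\t", index=False)
    with open(path, "a") as fh:
        fh.write("# percentages are per gene class; raw P-values, "
                 "no multiple-testing correction\n")


def check_report_partition(report: pd.DataFrame) -> bool:
    """Row-sum sanity check: Type I + Type II + Known counts equal All."""
    def count_of(cell: str) -> int:
        return int(str(cell).split(" ")[0])
    for _, row in report.iterrows():
        cells = [row[c] for c in CLASS_COLUMNS]
        if any("(" not in str(c) for c in cells):
            continue  # mean rows
        if count_of(cells[0]) != sum(count_of(c) for c in cells[1:]):
            return False
    return True
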