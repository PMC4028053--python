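"""Per-gene evidence tallies and the aggregate evidence matrix.

Strand rules follow the annotation-evidence conventions: a spliced
transcript alignment carries orientation (from its splice signals) and is
discarded when on the opposite strand from the gene; an unspliced alignment
has unknown orientation and may support a gene on either strand.  Support
always requires at least one base pair of overlap with a coding exon.

"Biological gene evidence" is transcript OR peptide OR protein-homolog OR
protein-domain support; cross-genome conservation is kept separate and only
enters the broader ``any_support`` flag.
"""

from __future__ import annotations

import re
import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .models import GeneModel, SplicedAlignment
from .sequtils import extract_cds, translate

MIN_PEPTIDE_LEN = 6
HOMOLOG_MIN_IDENTITY = 0.60
HOMOLOG_MIN_COVERAGE = 0.60
_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


def _coding_trees(genes: Sequence[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        for s, e in g.coding_exons:
            trees[g.scaffold].addi(s, e, (g.id, g.strand))
    return trees


def _overlapping_genes(trees: Mapping[str, IntervalTree],
                       aln: SplicedAlignment) -> set[tuple[str, str]]:
    """(gene_id, gene_strand) pairs whose coding exons the blocks touch."""
    hits: set[tuple[str, str]] = set()
    tree = trees.get(aln.target)
    if tree is None:
        return hits
    for s, e in aln.blocks:
        for iv in tree.overlap(s, e):
            hits.add(iv.data)
    return hits


def transcript_overlap(genes: Sequence[GeneModel],
                       libraries: Mapping[str, Iterable[SplicedAlignment]]
                       ) -> pd.DataFrame:
    """Per-gene, per-library spliced and unspliced transcript support.

    Spliced alignments support only same-strand genes; unspliced alignments
    (unknown orientation) support genes on either strand.  One coding base
    pair of overlap suffices.  Returns a boolean DataFrame indexed by
    gene_id with columns ``spliced:<lib>`` and ``unspliced:<lib>``.
    """
    trees = _coding_trees(genes)
    cols: dict[str, set[str]] = {}
    for lib, alns in libraries.items():
        spliced_hit: set[str] = set()
        unspliced_hit: set[str] = set()
        for a in alns:
            if a.spliced and a.strand in "+-":
                for gid, strand in _overlapping_genes(trees, a):
                    if strand == a.strand:
                        spliced_hit.add(gid)
            else:
                for gid, _strand in _overlapping_genes(trees, a):
                    unspliced_hit.add(gid)
        cols[f"spliced:{lib}"] = spliced_hit
        cols[f"unspliced:{lib}"] = unspliced_hit
    idx = [g.id for g in genes]
    return pd.DataFrame({c: [gid in hits for gid in idx] for c, hits in cols.items()},
                        index=pd.Index(idx, name="gene_id"))


def expression_breadth(support: pd.DataFrame,
                       tissue_libraries: Sequence[str]) -> pd.Series:
    """narrow / broad / neither / none from spliced support in the
    designated single-tissue libraries (narrow = exactly one, broad = all).
    """
    if len(tissue_libraries) < 2:
        raise ValueError("need at least two designated tissue libraries")
    cols = [f"spliced:{t}" for t in tissue_libraries]
    missing = [c for c in cols if c not in support.columns]
    if missing:
        raise ValueError(f"support table lacks columns {missing}")
    n = support[cols].sum(axis=1)
    out = pd.Series("neither", index=support.index, name="breadth")
    out[n == 0] = "none"
    out[n == 1] = "narrow"
    out[n == len(cols)] = "broad"
    return out


def peptide_support(peptides: Iterable[str], genes: Sequence[GeneModel],
                    assembly: Mapping[str, str]
                    ) -> tuple[pd.Series, list[tuple[str, str]]]:
    """Exact-substring peptide matching against translated CDSs.

    A gene is supported iff at least one peptide of length >= 6 occurs
    verbatim in its protein (equivalent to a 100%-identity full-length
    peptide alignment).  Returns (per-gene boolean Series, match list).
    """
    clean: list[str] = []
    for pep in peptides:
        pep = pep.strip().upper()
        if not pep:
            continue
        if not _AA_RE.match(pep):
            warnings.warn(f"peptide {pep!r} contains non-amino-acid symbols; skipped")
            continue
        if len(pep) >= MIN_PEPTIDE_LEN:
            clean.append(pep)
    matches: list[tuple[str, str]] = []
    flags = {}
    for g in genes:
        protein = translate(extract_cds(g, assembly[g.scaffold]))
        hit = False
        for pep in clean:
            if pep in protein:
                matches.append((pep, g.id))
                hit = True
        flags[g.id] = hit
    return pd.Series(flags, name="peptide").rename_axis("gene_id"), matches


def homolog_overlap(genes: Sequence[GeneModel],
                    alignments_by_source: Mapping[str, Iterable[SplicedAlignment]],
                    dmel_source: Optional[str] = "dmel") -> pd.DataFrame:
    """Same-strand >= 1 coding-bp overlap with protein-homolog alignments.

    Alignments carrying identity/coverage are admitted at the
    protein-to-genome defaults (>= 60% identity, >= 60% coverage);
    alignments without those fields are taken as given.  Returns booleans
    per source plus ``homolog`` (any source) and ``dmel_homolog``.
    """
    trees = _coding_trees(genes)
    idx = [g.id for g in genes]
    df = pd.DataFrame(index=pd.Index(idx, name="gene_id"))
    for source, alns in alignments_by_source.items():
        hit: set[str] = set()
        for a in alns:
            if a.identity is not None and a.identity < HOMOLOG_MIN_IDENTITY:
                continue
            if a.query_coverage is not None and a.query_coverage < HOMOLOG_MIN_COVERAGE:
                continue
            if a.strand not in "+-":
                continue
            for gid, strand in _overlapping_genes(trees, a):
                if strand == a.strand:
                    hit.add(gid)
        df[f"homolog:{source}"] = [gid in hit for gid in idx]
    source_cols = [c for c in df.columns if c.startswith("homolog:")]
    df["homolog"] = df[source_cols].any(axis=1) if source_cols else False
    dmel_col = f"homolog:{dmel_source}"
    df["dmel_homolog"] = df[dmel_col] if dmel_col in df.columns else False
    return df


def conservation_table(rows: Iterable[tuple[str, str, bool]],
                       genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Pivot (gene, informant, supported) rows to per-gene booleans."""
    idx = [g.id for g in genes]
    known = set(idx)
    per: dict[str, dict[str, bool]] = defaultdict(dict)
    for gid, informant, ok in rows:
        if gid not in known:
            warnings.warn(f"conservation row for unknown gene {gid}; dropped")
            continue
        per[informant][gid] = per[informant].get(gid, False) or bool(ok)
    df = pd.DataFrame(index=pd.Index(idx, name="gene_id"))
    for informant in sorted(per):
        df[f"conservation:{informant}"] = [per[informant].get(gid, False) for gid in idx]
    return df


@dataclass
class EvidenceMatrix:
    table: pd.DataFrame  # one row per gene, boolean evidence columns

    def __post_init__(self) -> None:
        t = self.table
        if not (t["biological_gene_evidence"] <= t["any_support"]).all():
            raise AssertionError("biological gene evidence must imply any_support")


def build_evidence_matrix(genes: Sequence[GeneModel],
                          transcript_support: pd.DataFrame,
                          peptide: pd.Series,
                          homolog: pd.DataFrame,
                          conservation: pd.DataFrame,
                          domain_rows: Iterable[tuple[str, str]]) -> EvidenceMatrix:
    """Join all support tables into the per-gene evidence matrix.

    ``biological_gene_evidence`` = any transcript OR peptide OR homolog OR
    domain-table support; ``any_support`` additionally ORs the cross-genome
    conservation flags (conservation alone is support but not *gene*
    evidence).
    """
    idx = pd.Index([g.id for g in genes], name="gene_id")
    df = pd.DataFrame(index=idx)
    spliced_cols = [c for c in transcript_support.columns if c.startswith("spliced:")]
    unspliced_cols = [c for c in transcript_support.columns if c.startswith("unspliced:")]
    ts = transcript_support.reindex(idx).fillna(False)
    df[spliced_cols + unspliced_cols] = ts[spliced_cols + unspliced_cols]
    df["spliced_any"] = ts[spliced_cols].any(axis=1) if spliced_cols else False
    df["unspliced_any"] = ts[unspliced_cols].any(axis=1) if unspliced_cols else False
    df["transcript_any"] = df["spliced_any"] | df["unspliced_any"]
    df["peptide"] = peptide.reindex(idx).fillna(False)
    hm = homolog.reindex(idx).fillna(False)
    for c in hm.columns:
        df[c] = hm[c]
    known = set(idx)
    domain_hit: set[str] = set()
    for gid, _dom in domain_rows:
        if gid not in known:
            warnings.warn(f"domain row for unknown gene {gid}; dropped")
            continue
        domain_hit.add(gid)
    df["domain_table"] = [gid in domain_hit for gid in idx]
    cons_cols = [c for c in conservation.columns if c.startswith("conservation:")]
    cv = conservation.reindex(idx).fillna(False)
    for c in cons_cols:
        df[c] = cv[c]
    df["conservation_any"] = cv[cons_cols].any(axis=1) if cons_cols else False
    df["biological_gene_evidence"] = (
        df["transcript_any"] | df["peptide"] | df["homolog"] | df["domain_table"]
    )
    df["any_support"] = df["biological_gene_evidence"] | df["conservation_any"]
    return EvidenceMatrix(df.astype(bool))


def per_class_counts(matrix: EvidenceMatrix, classes: Mapping[str, str],
                     columns: Sequence[str]) -> pd.DataFrame:
    """Counts and percentages of flagged genes per class for chosen columns."""
    df = matrix.table.copy()
    df["gene_class"] = [classes.get(gid, "unclassified") for gid in df.index]
    rows = []
    for col in columns:
        grp = df.groupby("gene_class")[col].agg(["sum", "count"])
        for cls, (n_true, n_total) in grp.iterrows():
            rows.append((col, cls, int(n_true), int(n_total),
                         round(100.0 * n_true / n_total, 1) if n_total else float("nan")))
    return pd.DataFrame(rows, columns=["feature", "gene_class", "count", "total", "percent"])
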