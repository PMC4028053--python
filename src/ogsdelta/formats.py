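"""Readers and writers for the standard formats the pipeline touches.

Gene sets travel as GFF3 (gene -> mRNA -> CDS), parsed with :mod:`gffutils`;
block alignments travel as BED12, PSL, or flat GFF3 ``match``/``match_part``
rows.  All files are 1-based inclusive where the format says so; everything
in memory is 0-based half-open (:mod:`ogsdelta.models`).  No reader mutates
its input and writers are byte-deterministic for a given object list.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, Interval, SplicedAlignment


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence id {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: dict[str, str], path: str, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3 gene sets
# ---------------------------------------------------------------------------

def _prescan_gff3(path: str) -> None:
    """Cheap validation pass that can still name line numbers."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 1 or end < start:
                raise FormatError(f"{path}:{lineno}: out-of-range coordinates {start}..{end}")
            if cols[2] in ("gene", "mRNA", "CDS") and cols[6] not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {cols[6]!r}")
            if cols[2] == "CDS" and "Parent=" not in cols[8]:
                raise FormatError(f"{path}:{lineno}: CDS without Parent attribute")


def read_gene_set(path: str) -> list[GeneModel]:
    """Read a gene -> mRNA -> CDS GFF3 file into :class:`GeneModel` objects.

    1-based inclusive file coordinates become 0-based half-open.  A CDS whose
    parent chain does not reach a gene, or a gene whose CDS features disagree
    on strand or scaffold, is a hard error.
    """
    _prescan_gff3(path)
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True,
    )
    genes: list[GeneModel] = []
    claimed_cds = 0
    for gene in db.features_of_type("gene", order_by="start"):
        cds = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not cds:
            raise FormatError(f"{path}: gene {gene.id} has no CDS features")
        claimed_cds += len(cds)
        strands = {c.strand for c in cds} | {gene.strand}
        if len(strands) != 1:
            raise FormatError(f"{path}: gene {gene.id} mixes strands {sorted(strands)}")
        seqids = {c.seqid for c in cds} | {gene.seqid}
        if len(seqids) != 1:
            raise FormatError(f"{path}: gene {gene.id} spans scaffolds {sorted(seqids)}")
        exons: list[Interval] = [(c.start - 1, c.end) for c in cds]
        utr = [
            (u.start - 1, u.end)
            for u in db.children(gene, order_by="start")
            if u.featuretype in ("five_prime_UTR", "three_prime_UTR")
        ]
        attrs = gene.attributes
        partial = attrs.get("partial", ["false"])[0].lower() == "true"
        try:
            genes.append(GeneModel(gene.id, gene.seqid, gene.strand, exons,
                                   utr_exons=utr, partial=partial))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    total_cds = sum(1 for _ in db.features_of_type("CDS"))
    if total_cds != claimed_cds:
        raise FormatError(f"{path}: {total_cds - claimed_cds} CDS feature(s) not reachable from any gene")
    genes.sort(key=lambda g: (g.scaffold, g.span, g.id))
    return genes


def _cds_phases(gene: GeneModel) -> list[int]:
    """GFF3 phase column for each coding exon, in ascending genomic order."""
    phases = []
    cum = 0
    for s, e in gene.exons_5to3():
        phases.append((3 - cum % 3) % 3)
        cum += e - s
    if gene.strand == "-":
        phases.reverse()
    return phases


def write_gene_set(genes: Iterable[GeneModel], path: str, source: str = "ogsdelta") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.scaffold, g.span, g.id)):
            start, end = g.span
            extra = ";partial=true" if g.partial else ""
            fh.write(f"{g.scaffold}\t{source}\tgene\t{start + 1}\t{end}\t.\t{g.strand}\t.\tID={g.id}{extra}\n")
            mrna = f"{g.id}.t1"
            fh.write(f"{g.scaffold}\t{source}\tmRNA\t{start + 1}\t{end}\t.\t{g.strand}\t.\tID={mrna};Parent={g.id}\n")
            for (s, e), ph in zip(g.coding_exons, _cds_phases(g)):
                fh.write(f"{g.scaffold}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{ph}\tID={mrna}.cds;Parent={mrna}\n")
            for s, e in g.utr_exons:
                fh.write(f"{g.scaffold}\t{source}\tUTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={mrna}\n")


# ---------------------------------------------------------------------------
# Block alignments: BED12 / PSL / flat GFF3 match rows
# ---------------------------------------------------------------------------

def _read_bed12(path: str) -> list[SplicedAlignment]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}:{lineno}: BED12 needs 12 columns, got {len(cols)}")
            chrom, start, name, strand = cols[0], int(cols[1]), cols[3], cols[5]
            n_blocks = int(cols[9])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path}:{lineno}: blockCount disagrees with block lists")
            blocks = [(start + o, start + o + sz) for o, sz in zip(starts, sizes)]
            try:
                out.append(SplicedAlignment(name, chrom, strand, blocks))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def _write_bed12(alignments: Iterable[SplicedAlignment], path: str) -> None:
    with open(path, "w") as fh:
        for a in alignments:
            start, end = a.target_span
            sizes = ",".join(str(e - s) for s, e in a.blocks)
            starts = ",".join(str(s - start) for s, e in a.blocks)
            fh.write(
                f"{a.target}\t{start}\t{end}\t{a.query_id}\t0\t{a.strand}\t"
                f"{start}\t{end}\t0\t{len(a.blocks)}\t{sizes}\t{starts}\n"
            )


def _read_psl(path: str) -> list[SplicedAlignment]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("psLayout", "match", "-", " ")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 21:
                raise FormatError(f"{path}:{lineno}: PSL needs 21 columns, got {len(cols)}")
            matches, mismatches = int(cols[0]), int(cols[1])
            strand = cols[8][-1] if cols[8] else "."
            qname, qsize = cols[9], int(cols[10])
            tname = cols[13]
            sizes = [int(x) for x in cols[18].rstrip(",").split(",")]
            tstarts = [int(x) for x in cols[20].rstrip(",").split(",")]
            blocks = [(t, t + sz) for t, sz in zip(tstarts, sizes)]
            aligned = matches + mismatches
            identity = matches / aligned if aligned else None
            coverage = aligned / qsize if qsize else None
            try:
                out.append(SplicedAlignment(qname, tname, strand, blocks,
                                            identity=identity, query_coverage=coverage,
                                            query_length=qsize))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def _write_psl(alignments: Iterable[SplicedAlignment], path: str,
               target_sizes: Optional[dict[str, int]] = None) -> None:
    """Write alignments as PSL rows.

    ``matches``/``misMatches`` are reconstructed from identity over the
    aligned block bases, so identity and coverage round-trip exactly when
    ``query_length`` equals the aligned bases divided by the coverage.
    """
    with open(path, "w") as fh:
        for a in alignments:
            aligned = a.aligned_target_bases()
            ident = 1.0 if a.identity is None else a.identity
            matches = round(ident * aligned)
            mismatches = aligned - matches
            qsize = a.query_length if a.query_length else aligned
            start, end = a.target_span
            tsize = target_sizes.get(a.target, end) if target_sizes else end
            sizes = ",".join(str(e - s) for s, e in a.blocks) + ","
            qstarts = ",".join(str(q) for q in _cumulative_query_starts(a.blocks)) + ","
            tstarts = ",".join(str(s) for s, _ in a.blocks) + ","
            strand = a.strand if a.strand in "+-" else "+"
            fh.write(
                f"{matches}\t{mismatches}\t0\t0\t0\t0\t{len(a.blocks) - 1}\t"
                f"{sum(s2 - e1 for (_, e1), (s2, _) in zip(a.blocks, a.blocks[1:]))}\t"
                f"{strand}\t{a.query_id}\t{qsize}\t0\t{aligned}\t"
                f"{a.target}\t{tsize}\t{start}\t{end}\t{len(a.blocks)}\t"
                f"{sizes}\t{qstarts}\t{tstarts}\n"
            )


def _cumulative_query_starts(blocks: list[Interval]) -> list[int]:
    qs, cum = [], 0
    for s, e in blocks:
        qs.append(cum)
        cum += e - s
    return qs


def _read_gff3_alignments(path: str) -> list[SplicedAlignment]:
    """Flat GFF3 alignment rows: discontinuous features sharing one ID."""
    rows: dict[str, dict] = {}  # insertion-ordered
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            if cols[2] not in ("match", "cDNA_match", "protein_match", "EST_match", "match_part"):
                continue
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            key = attrs.get("ID") or attrs.get("Parent")
            if key is None:
                raise FormatError(f"{path}:{lineno}: alignment row without ID/Parent")
            target_attr = attrs.get("Target", "")
            qid = target_attr.split(" ")[0] if target_attr else key
            rec = rows.setdefault(key, {"target": cols[0], "strand": cols[6],
                                        "source": cols[1], "qid": qid, "blocks": []})
            rec["blocks"].append((int(cols[3]) - 1, int(cols[4])))
    out = []
    for key, rec in rows.items():
        try:
            out.append(SplicedAlignment(rec["qid"], rec["target"], rec["strand"],
                                        sorted(rec["blocks"]), source=rec["source"]))
        except ValueError as exc:
            raise FormatError(f"{path}: alignment {key}: {exc}") from exc
    return out


_DIALECTS = {".bed": "bed12", ".bed12": "bed12", ".psl": "psl", ".gff": "gff3", ".gff3": "gff3"}


def read_alignments(path: str, fmt: Optional[str] = None) -> list[SplicedAlignment]:
    """Read block alignments, auto-detecting the dialect from the extension."""
    if fmt is None:
        fmt = _DIALECTS.get(os.path.splitext(path)[1].lower())
        if fmt is None:
            raise FormatError(f"{path}: cannot infer alignment format; pass fmt=")
    if fmt == "bed12":
        return _read_bed12(path)
    if fmt == "psl":
        return _read_psl(path)
    if fmt == "gff3":
        return _read_gff3_alignments(path)
    raise FormatError(f"unknown alignment format {fmt!r}")


def write_alignments(alignments: Iterable[SplicedAlignment], path: str,
                     fmt: Optional[str] = None, **kw) -> None:
    if fmt is None:
        fmt = _DIALECTS.get(os.path.splitext(path)[1].lower())
        if fmt is None:
            raise FormatError(f"{path}: cannot infer alignment format; pass fmt=")
    if fmt == "bed12":
        _write_bed12(alignments, path)
    elif fmt == "psl":
        _write_psl(alignments, path, **kw)
    else:
        raise FormatError(f"no writer for alignment format {fmt!r}")
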