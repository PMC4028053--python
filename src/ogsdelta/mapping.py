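"""Map new-set coding sequences onto the old assembly and classify genes.

Every gene of the new annotation gets exactly one class per mapping mode:

* ``TypeI`` — the CDS has no retained alignment to the old assembly at the
  mode's identity/coverage thresholds (the gene was un-findable because the
  old assembly lacked the sequence);
* ``TypeII`` — the CDS aligns, but no retained alignment shares a single
  coding base pair, on the same strand, with any old-annotation gene (the
  sequence was there but the gene was not annotated);
* ``PreviouslyKnown`` — the CDS aligns and overlaps an old gene's coding
  sequence.

Thresholds default to 95% identity with 80% (stringent) or 50% (relaxed)
query coverage.  The built-in mapper is a deterministic exact-k-mer
anchor-and-chain aligner (k = 15): it is intended for the simulator's
old-is-a-subsequence-of-new setting; for real genomes, supply splice-aware
alignments (PSL/GFF3) via :func:`ogsdelta.formats.read_alignments` —
both paths share :func:`filter_alignments` and :func:`classify_genes`.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from intervaltree import IntervalTree

from .models import (CLASSES, GeneModel, Interval, KNOWN, SplicedAlignment,
                     TYPE_I, TYPE_II, ClassLabel)
from .sequtils import revcomp


@dataclass
class MappingParams:
    min_identity: float = 0.95
    min_coverage: float = 0.80          # stringent; 0.50 for relaxed
    prefilter_evalue: float = 1e-20     # documented; the k-mer anchor requirement
                                        # stands in for it in the built-in mapper
    mode: str = "stringent"

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.mode not in ("stringent", "relaxed"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def stringent(cls) -> "MappingParams":
        return cls(mode="stringent", min_coverage=0.80)

    @classmethod
    def relaxed(cls) -> "MappingParams":
        return cls(mode="relaxed", min_coverage=0.50)


# ---------------------------------------------------------------------------
# Built-in k-mer anchor mapper
# ---------------------------------------------------------------------------

K = 15
MAX_KMER_HITS = 20      # k-mers seen more often are treated as repetitive
MAX_INTRON = 20_000     # largest target gap a chain may bridge
# Shorter exact segments are indistinguishable from low-complexity chance
# hits and are never reported; this is also the smallest retained fragment
# the mapping contract regards as alignable (the simulator's ground-truth
# retained fractions count fragments of at least this size).
MIN_SEGMENT = K + 8
JUNCTION_PENALTY = 12   # chain-score cost per junction, against spurious weaving


class KmerIndex:
    """Exact k-mer index of a sequence set; build once, query many CDSs."""

    def __init__(self, assembly: dict[str, str], k: int = K):
        self.k = k
        self.scaffolds = list(assembly)
        self.lengths = {name: len(s) for name, s in assembly.items()}
        self.index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for si, (name, seq) in enumerate(assembly.items()):
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                hits = self.index[kmer]
                if len(hits) <= MAX_KMER_HITS:
                    hits.append((si, i))

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        hits = self.index.get(kmer, ())
        return hits if len(hits) <= MAX_KMER_HITS else ()


@dataclass
class _Segment:
    qs: int
    qe: int
    ts: int
    te: int


def _exact_segments(query: str, idx: KmerIndex) -> dict[int, list[_Segment]]:
    """Merge co-diagonal k-mer anchors into maximal exact-match segments."""
    k = idx.k
    by_diag: dict[tuple[int, int], list[int]] = defaultdict(list)
    for i in range(len(query) - k + 1):
        for si, t in idx.lookup(query[i:i + k]):
            by_diag[(si, t - i)].append(i)
    segments: dict[int, list[_Segment]] = defaultdict(list)
    def emit(si: int, diag: int, start: int, prev: int) -> None:
        if prev + k - start >= MIN_SEGMENT:
            segments[si].append(_Segment(start, prev + k, start + diag, prev + k + diag))

    for (si, diag), qpos in by_diag.items():
        qpos.sort()
        start = prev = qpos[0]
        for q in qpos[1:]:
            if q <= prev + k:       # anchors overlap or touch: same segment
                prev = q
            else:
                emit(si, diag, start, prev)
                start = prev = q
        emit(si, diag, start, prev)
    return segments


def _chain(segments: list[_Segment]) -> tuple[list[_Segment], int, int]:
    """Best colinear chain by dynamic programming.

    Returns (chain, matched_bases, mismatch_columns): matched bases are the
    exact-segment query bases (trimmed at query overlaps); mismatch columns
    approximate substitution runs between consecutive segments as
    min(query_gap, target_gap).
    """
    segs = sorted(segments, key=lambda s: (s.qs, s.ts))
    n = len(segs)
    if not segs:
        return [], 0, 0
    # per segment: (score, matched, mismatch, prev); score = matched minus a
    # per-junction cost so chance hits far away cannot inflate the chain
    best: list[tuple[int, int, int, int]] = [(0, 0, 0, -1)] * n
    for j in range(n):
        mj = segs[j].qe - segs[j].qs
        best[j] = (mj, mj, 0, -1)
        for i in range(j):
            si, sj = segs[i], segs[j]
            if sj.qe <= si.qe or sj.te <= si.te:
                continue
            overlap = max(0, si.qe - sj.qs)
            tgap = sj.ts - si.te
            qgap = sj.qs - si.qe
            # chance single-base extensions at segment ends can make target
            # intervals overlap by up to ~k even when query intervals do not
            if tgap < -(overlap + 2 * K) or tgap > MAX_INTRON:
                continue
            add = (sj.qe - sj.qs) - overlap
            if add <= 0:
                continue
            # comparable small gaps on both sides are substitution runs
            # (mismatch columns); a target gap of intron size is an intron,
            # and an unmatched large query gap is unaligned query (it lowers
            # coverage, not identity)
            if 0 < tgap < SplicedAlignment.MIN_INTRON and 0 <= qgap < SplicedAlignment.MIN_INTRON:
                mism = min(qgap, tgap)
            else:
                mism = 0
            cand = (best[i][0] + add - JUNCTION_PENALTY,
                    best[i][1] + add, best[i][2] + mism, i)
            if (cand[0], -cand[2]) > (best[j][0], -best[j][2]):
                best[j] = cand
    end = max(range(n), key=lambda j: (best[j][0], -best[j][2]))
    chain = []
    j = end
    while j != -1:
        chain.append(segs[j])
        j = best[j][3]
    chain.reverse()
    return chain, best[end][1], best[end][2]


def map_cds(cds_sequences: dict[str, str], old_assembly: dict[str, str],
            params: MappingParams | None = None, k: int = K) -> list[SplicedAlignment]:
    """Align each CDS to the old assembly; both orientations are searched.

    For every (scaffold, orientation) with anchors, the best chain is
    reported as a splice-modeled block alignment with overall identity and
    query coverage.  Deterministic: ties broken by scaffold order.
    """
    if not old_assembly:
        raise ValueError("old assembly is empty")
    if not cds_sequences:
        raise ValueError("no CDS sequences supplied")
    idx = KmerIndex(old_assembly, k=k)
    out: list[SplicedAlignment] = []
    for qid in cds_sequences:
        query = cds_sequences[qid].upper()
        for strand, q in (("+", query), ("-", revcomp(query))):
            for si, segs in sorted(_exact_segments(q, idx).items()):
                chain, matched, mism = _chain(segs)
                if not chain:
                    continue
                blocks = _blocks_from_chain(chain)
                aligned = matched + mism
                identity = matched / aligned if aligned else 0.0
                coverage = aligned / len(query)
                out.append(SplicedAlignment(qid, idx.scaffolds[si], strand, blocks,
                                            identity=identity,
                                            query_coverage=min(coverage, 1.0),
                                            query_length=len(query)))
    out.sort(key=lambda a: (a.query_id, -(a.query_coverage or 0), a.target))
    return out


def _blocks_from_chain(chain: list[_Segment]) -> list[Interval]:
    blocks: list[Interval] = []
    for seg in chain:
        if blocks and seg.ts <= blocks[-1][1] + 1:
            blocks[-1] = (blocks[-1][0], max(blocks[-1][1], seg.te))
        else:
            blocks.append((seg.ts, seg.te))
    return blocks


# ---------------------------------------------------------------------------
# Filtering and classification
# ---------------------------------------------------------------------------

def filter_alignments(alignments: list[SplicedAlignment],
                      params: MappingParams) -> list[SplicedAlignment]:
    """Retain alignments with identity and query coverage at/above threshold."""
    out = []
    for a in alignments:
        if a.query_coverage is None:
            raise ValueError(
                f"alignment {a.query_id}: query coverage unknown; supply query "
                "lengths (e.g. use PSL input) so coverage can be computed"
            )
        ident = 1.0 if a.identity is None else a.identity
        if ident >= params.min_identity and a.query_coverage >= params.min_coverage:
            out.append(a)
    return out


def classify_genes(new_genes: list[GeneModel],
                   retained_alignments: list[SplicedAlignment],
                   old_genes: list[GeneModel],
                   mode: str,
                   old_scaffolds: set[str] | None = None) -> list[ClassLabel]:
    """Assign one class per gene from its retained alignments.

    Type I: no retained alignment.  Type II: retained alignments exist but
    zero alignment-block bases intersect any old-gene coding exon on the
    same strand.  Previously Known otherwise; ``overlap_bp`` records the
    summed coding overlap and ``multi_overlap`` flags genes whose alignments
    hit more than one old gene (split/merge candidates, left as Previously
    Known).
    """
    if old_scaffolds is not None:
        for a in retained_alignments:
            if a.target not in old_scaffolds:
                raise ValueError(f"alignment {a.query_id} targets unknown old scaffold {a.target}")
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    merged_exons: dict[tuple[str, str], list[Interval]] = {}
    for og in old_genes:
        for s, e in og.coding_exons:
            trees[(og.scaffold, og.strand)].addi(s, e, og.id)
    for key, tree in trees.items():
        tree_copy = IntervalTree(tree)
        tree_copy.merge_overlaps()
        merged_exons[key] = sorted((iv.begin, iv.end) for iv in tree_copy)
    by_gene: dict[str, list[SplicedAlignment]] = defaultdict(list)
    for a in retained_alignments:
        by_gene[a.query_id].append(a)

    labels: list[ClassLabel] = []
    for gene in new_genes:
        alns = by_gene.get(gene.id, [])
        if not alns:
            labels.append(ClassLabel(gene.id, TYPE_I, mode))
            continue
        hit_old: set[str] = set()
        best = max(alns, key=lambda a: (a.query_coverage or 0, a.identity or 0))
        # per-base union of alignment-block positions covered by same-strand
        # old coding exons: merge blocks per (target, strand), then intersect
        block_union: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        for a in alns:
            for s, e in a.blocks:
                block_union[(a.target, a.strand)].addi(s, e)
            tree = trees.get((a.target, a.strand))
            if tree is not None:
                for s, e in a.blocks:
                    for iv in tree.overlap(s, e):
                        hit_old.add(iv.data)
        overlap_bp = 0
        for key, btree in block_union.items():
            exons = merged_exons.get(key)
            if not exons:
                continue
            btree.merge_overlaps()
            blocks = sorted((iv.begin, iv.end) for iv in btree)
            overlap_bp += _interval_intersection_size(blocks, exons)
        cls = KNOWN if overlap_bp >= 1 else TYPE_II
        labels.append(ClassLabel(gene.id, cls, mode, best_alignment=best,
                                 overlap_bp=overlap_bp, multi_overlap=len(hit_old) > 1))
    assert len(labels) == len(new_genes)
    return labels


def _interval_intersection_size(a: list[Interval], b: list[Interval]) -> int:
    """Total overlap of two sorted, internally disjoint interval lists."""
    total = i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def class_counts(labels: list[ClassLabel]) -> dict[str, int]:
    counts = {c: 0 for c in CLASSES}
    for lab in labels:
        counts[lab.gene_class] += 1
    return counts
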