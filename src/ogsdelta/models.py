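"""Core in-memory containers shared by every pipeline stage.

Coordinate convention: everything in memory is 0-based, half-open
``[start, end)`` on the forward strand of the named scaffold.  GFF3 I/O
converts to and from 1-based inclusive at the file boundary (see
:mod:`ogsdelta.formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

Interval = tuple[int, int]


def _check_intervals(ivs: list[Interval], what: str) -> None:
    for s, e in ivs:
        if not (0 <= s < e):
            raise ValueError(f"{what}: bad interval [{s}, {e})")
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ValueError(f"{what}: intervals overlap or are unsorted")


@dataclass
class GeneModel:
    """One protein-coding gene: ordered coding exons plus optional UTR.

    ``coding_exons`` are stored in ascending genomic order regardless of
    strand; 5'->3' order is derived from ``strand`` where needed.
    """

    id: str
    scaffold: str
    strand: str
    coding_exons: list[Interval]
    utr_exons: list[Interval] = field(default_factory=list)
    partial: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: unknown strand {self.strand!r}")
        if not self.coding_exons:
            raise ValueError(f"gene {self.id}: no coding exons")
        self.coding_exons = sorted(tuple(iv) for iv in self.coding_exons)
        _check_intervals(self.coding_exons, f"gene {self.id}")
        if self.cds_length % 3 != 0 and not self.partial:
            raise ValueError(
                f"gene {self.id}: CDS length {self.cds_length} not a multiple "
                "of 3 (flag partial=True for incomplete models)"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.coding_exons)

    @property
    def span(self) -> Interval:
        """Full genomic extent of the coding exons (first start, last end)."""
        return self.coding_exons[0][0], self.coding_exons[-1][1]

    @property
    def n_coding_exons(self) -> int:
        return len(self.coding_exons)

    def introns(self) -> list[Interval]:
        """Genomic gaps between consecutive coding exons, ascending order."""
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.coding_exons, self.coding_exons[1:])
        ]

    def exons_5to3(self) -> list[Interval]:
        if self.strand == "+":
            return list(self.coding_exons)
        return list(reversed(self.coding_exons))


@dataclass
class SplicedAlignment:
    """A query->target alignment as ordered blocks on the target.

    ``identity`` and ``query_coverage`` are fractions in [0, 1]; either may
    be ``None`` when the source format does not carry them (e.g. BED12).
    ``strand`` may be '.' for alignments whose orientation is unknown
    (unspliced transcript reads).
    """

    query_id: str
    target: str
    strand: str
    blocks: list[Interval]
    identity: Optional[float] = None
    query_coverage: Optional[float] = None
    query_length: Optional[int] = None
    source: Optional[str] = None

    MIN_INTRON: int = 30  # gap size from which a block gap counts as an intron

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"alignment {self.query_id}: bad strand {self.strand!r}")
        if not self.blocks:
            raise ValueError(f"alignment {self.query_id}: no blocks")
        self.blocks = [tuple(iv) for iv in self.blocks]
        _check_intervals(self.blocks, f"alignment {self.query_id}")
        for name, val in (("identity", self.identity), ("query_coverage", self.query_coverage)):
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"alignment {self.query_id}: {name}={val} outside [0, 1]")

    @property
    def spliced(self) -> bool:
        return any(s2 - e1 >= self.MIN_INTRON for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:]))

    @property
    def target_span(self) -> Interval:
        return self.blocks[0][0], self.blocks[-1][1]

    def block_gaps(self) -> list[Interval]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:])]

    def aligned_target_bases(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass
class CompositionalDomain:
    """A contiguous scaffold segment homogeneous in GC content.

    ``gc_all`` is the GC fraction over all non-ambiguous positions;
    ``gc_noncoding`` over positions not covered by any coding exon on
    either strand (``None`` when no such position exists).  ``gap`` marks
    runs of assembly Ns that were excluded from segmentation; ``segmented``
    is False for scaffolds below the segmentation length floor, which are
    returned whole.
    """

    scaffold: str
    start: int
    end: int
    gc_all: Optional[float]
    gc_noncoding: Optional[float] = None
    n_noncoding: int = 0
    segmented: bool = True
    gap: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"domain on {self.scaffold}: bad interval [{self.start}, {self.end})")
        for name, val in (("gc_all", self.gc_all), ("gc_noncoding", self.gc_noncoding)):
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValueError(f"domain on {self.scaffold}: {name}={val} outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


# Gene classes
TYPE_I = "TypeI"
TYPE_II = "TypeII"
KNOWN = "PreviouslyKnown"
CLASSES = (TYPE_I, TYPE_II, KNOWN)


@dataclass
class ClassLabel:
    """The class assigned to one new-set gene under one mapping mode."""

    gene_id: str
    gene_class: str
    mode: str
    best_alignment: Optional[SplicedAlignment] = None
    overlap_bp: int = 0
    multi_overlap: bool = False

    def __post_init__(self) -> None:
        if self.gene_class not in CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        if self.mode not in ("stringent", "relaxed"):
            raise ValueError(f"unknown mode {self.mode!r}")
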