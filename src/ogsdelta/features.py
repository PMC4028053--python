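"""Per-gene structural and codon-usage characterisation.

Covers coding-sequence length statistics, exon multiplicity, splice-site
canonicality restricted to transcript-supported introns, Wright's effective
number of codons (Nc), and the N50 assembly summary.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .models import GeneModel, Interval, SplicedAlignment
from .sequtils import revcomp

# ---------------------------------------------------------------------------
# CDS metrics
# ---------------------------------------------------------------------------

CDS_HIST_BIN = 20  # nt per histogram bin


@dataclass
class CdsMetrics:
    per_gene: pd.DataFrame       # gene_id, cds_length, n_coding_exons, single_exon
    mean_length: float
    min_length: int
    max_length: int
    total_coding_nt: int
    histogram: pd.Series         # index = bin left edge, value = gene count


def cds_metrics(genes: Sequence[GeneModel]) -> CdsMetrics:
    """Exact integer CDS totals plus a 20-nt length histogram.

    Totals are invariant under gene reordering.
    """
    rows = [(g.id, g.cds_length, g.n_coding_exons, g.n_coding_exons == 1) for g in genes]
    df = pd.DataFrame(rows, columns=["gene_id", "cds_length", "n_coding_exons", "single_exon"])
    df = df.sort_values("gene_id").reset_index(drop=True)
    lengths = df["cds_length"].to_numpy()
    bins = lengths // CDS_HIST_BIN * CDS_HIST_BIN
    hist = pd.Series(Counter(bins)).sort_index()
    return CdsMetrics(
        per_gene=df,
        mean_length=float(lengths.mean()),
        min_length=int(lengths.min()),
        max_length=int(lengths.max()),
        total_coding_nt=int(lengths.sum()),
        histogram=hist,
    )


# ---------------------------------------------------------------------------
# Splice-site survey
# ---------------------------------------------------------------------------

@dataclass
class SpliceSiteRecord:
    gene_id: str
    intron: Interval
    donor: str
    acceptor: str
    canonical: bool
    transcript_supported: bool
    valid: bool = True


def splice_site_survey(genes: Sequence[GeneModel], assembly: dict[str, str],
                       spliced_alignments: Iterable[SplicedAlignment]
                       ) -> tuple[list[SpliceSiteRecord], dict[str, int]]:
    """Donor/acceptor dinucleotides per intron, canonical = GT/AG.

    An intron counts as transcript supported iff some same-strand spliced
    alignment has a block gap with identical start and end coordinates.
    The returned counts consider only supported, valid introns, so the
    survey is invariant under alignment file order.
    """
    supported: dict[tuple[str, str], set[Interval]] = defaultdict(set)
    for a in spliced_alignments:
        if not a.spliced or a.strand not in "+-":
            continue
        for gap in a.block_gaps():
            if gap[1] - gap[0] >= SplicedAlignment.MIN_INTRON:
                supported[(a.target, a.strand)].add(gap)

    records: list[SpliceSiteRecord] = []
    counts = {"canonical": 0, "noncanonical": 0, "unsupported": 0, "invalid": 0}
    for gene in genes:
        seq = assembly[gene.scaffold]
        for intron in gene.introns():
            s, e = intron
            if e - s < 4:
                records.append(SpliceSiteRecord(gene.id, intron, "", "", False, False, valid=False))
                counts["invalid"] += 1
                continue
            if gene.strand == "+":
                donor, acceptor = seq[s:s + 2], seq[e - 2:e]
            else:
                donor, acceptor = revcomp(seq[e - 2:e]), revcomp(seq[s:s + 2])
            donor, acceptor = donor.upper(), acceptor.upper()
            is_supported = intron in supported.get((gene.scaffold, gene.strand), ())
            canonical = donor == "GT" and acceptor == "AG"
            records.append(SpliceSiteRecord(gene.id, intron, donor, acceptor,
                                            canonical, is_supported))
            if not is_supported:
                counts["unsupported"] += 1
            elif canonical:
                counts["canonical"] += 1
            else:
                counts["noncanonical"] += 1
    return records, counts


# ---------------------------------------------------------------------------
# Effective number of codons (Wright)
# ---------------------------------------------------------------------------

_TABLE = unambiguous_dna_by_id[1].forward_table  # codon -> amino acid, stops excluded
_AA_CODONS: dict[str, list[str]] = defaultdict(list)
for _codon, _aa in _TABLE.items():
    _AA_CODONS[_aa].append(_codon)
# degeneracy class -> amino acids (9 two-fold, Ile alone three-fold,
# 5 four-fold, 3 six-fold; Met and Trp are invariant and contribute the
# constant 2 in Wright's formula)
_DEGENERACY: dict[int, list[str]] = defaultdict(list)
for _aa, _codons in _AA_CODONS.items():
    _DEGENERACY[len(_codons)].append(_aa)
_CLASS_SIZES = {2: len(_DEGENERACY[2]), 3: len(_DEGENERACY[3]),
                4: len(_DEGENERACY[4]), 6: len(_DEGENERACY[6])}
NC_MIN, NC_MAX = 20.0, 61.0


@dataclass
class CodonUsageSummary:
    codon_counts: dict[str, Counter]          # amino acid -> codon counts
    f_hat: dict[int, Optional[float]] = field(default_factory=dict)
    nc: Optional[float] = None
    reason: Optional[str] = None              # why Nc is undefined, if it is


def _codon_homozygosity(counts: Counter) -> Optional[float]:
    """Wright's F-hat for one amino acid: (n * sum p_i^2 - 1) / (n - 1)."""
    n = sum(counts.values())
    if n < 2:
        return None
    p = np.array([c / n for c in counts.values()])
    return float((n * np.sum(p ** 2) - 1) / (n - 1))


def enc(cds: str) -> CodonUsageSummary:
    """Wright's effective number of codons for one coding sequence.

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, with per-degeneracy-class averages
    of the codon homozygosity F-hat over the amino acids observed at least
    twice.  If the three-fold class (Ile) is undefined, the mean of F2 and
    F4 is substituted.  Nc is truncated at 61, the no-bias maximum;
    Nc = 20 corresponds to exactly one codon per amino acid.  A trailing
    partial codon is dropped with a warning; stop codons are excluded.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        warnings.warn(f"CDS length {len(cds)} not divisible by 3; trailing bases dropped")
        cds = cds[: len(cds) - len(cds) % 3]
    per_aa: dict[str, Counter] = defaultdict(Counter)
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        aa = _TABLE.get(codon)
        if aa is not None:  # stops and ambiguous codons excluded
            per_aa[aa][codon] += 1
    summary = CodonUsageSummary(codon_counts=dict(per_aa))

    class_f: dict[int, Optional[float]] = {}
    for k in (2, 3, 4, 6):
        vals = [f for aa in _DEGENERACY[k]
                if (f := _codon_homozygosity(per_aa.get(aa, Counter()))) is not None]
        class_f[k] = float(np.mean(vals)) if vals else None
    if class_f[3] is None and class_f[2] is not None and class_f[4] is not None:
        class_f[3] = (class_f[2] + class_f[4]) / 2.0
    summary.f_hat = class_f

    missing = [k for k in (2, 3, 4, 6) if class_f[k] is None]
    if missing:
        summary.reason = f"no usable amino acids in degeneracy class(es) {missing}"
        return summary
    if any(class_f[k] == 0.0 for k in (2, 3, 4, 6)):
        summary.reason = "a degeneracy-class homozygosity is zero"
        return summary
    nc = 2.0
    for k in (2, 3, 4, 6):
        nc += _CLASS_SIZES[k] / class_f[k]
    summary.nc = min(nc, NC_MAX)
    return summary


# ---------------------------------------------------------------------------
# N50
# ---------------------------------------------------------------------------

def scaffold_n50(lengths: Sequence[int]) -> int:
    """Smallest L such that sequences of length >= L hold half the bases."""
    if len(lengths) == 0:
        raise ValueError("empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if 2 * acc >= total:
            return l
    raise AssertionError("unreachable")
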