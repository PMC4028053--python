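"""Synthetic genomes, gene sets, degraded old assemblies and evidence.

The generator emulates the situation the pipeline is built for: a genome
with strongly heterogeneous, bimodal GC content organised in piecewise-
homogeneous compositional domains; protein-coding genes placed
preferentially in the AT-rich domains; an "old" assembly derived from the
new one by deleting sequence with a bias toward low-GC segments and by
fragmenting scaffolds; and multi-tissue transcript, peptide, homolog and
cross-genome conservation evidence.  Every draw comes from a seeded
generator, so identical specs produce byte-identical fixture files, and
ground-truth class labels are recorded so the downstream classification can
be checked exactly.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import formats
from .mapping import MIN_SEGMENT as ALIGNABLE_MIN
from .models import GeneModel, Interval, SplicedAlignment, TYPE_I, TYPE_II, KNOWN
from .sequtils import extract_cds, revcomp, translate

STOPS = ("TAA", "TAG", "TGA")
CANONICAL_INTRON = ("GT", "AG")
NONCANONICAL_INTRONS = (("GC", "AG"), ("AT", "AC"))

# Default coding-exon-count distribution for 1..10 exons.  Mass at one exon
# is ~0.15, in the range observed for compact insect gene sets.
DEFAULT_EXON_COUNT_WEIGHTS = (0.15, 0.20, 0.16, 0.13, 0.10, 0.08, 0.07, 0.05, 0.035, 0.025)


@dataclass
class GenomeSimSpec:
    """Parameters of the simulated "new" genome."""

    seed: int = 0
    n_scaffolds: int = 5
    scaffold_length: int = 100_000
    domain_length_mean: int = 20_000
    gc_levels: tuple[float, ...] = (0.20, 0.45)
    gene_density_per_mb: float = 100.0
    low_gc_gene_bias: float = 0.75
    exon_count_weights: tuple[float, ...] = DEFAULT_EXON_COUNT_WEIGHTS
    noncanonical_intron_rate: float = 0.02
    min_domain_length: int = 4000

    def __post_init__(self) -> None:
        if self.n_scaffolds <= 0 or self.scaffold_length <= 0 or self.domain_length_mean <= 0:
            raise ValueError("scaffold counts and lengths must be positive")
        if not self.gc_levels or any(not (0.0 <= g <= 1.0) for g in self.gc_levels):
            raise ValueError("gc_levels must be fractions in [0, 1]")
        if not (0.0 <= self.low_gc_gene_bias <= 1.0):
            raise ValueError("low_gc_gene_bias must be in [0, 1]")
        if not (0.0 <= self.noncanonical_intron_rate <= 1.0):
            raise ValueError("noncanonical_intron_rate must be in [0, 1]")
        w = np.asarray(self.exon_count_weights, float)
        if w.ndim != 1 or len(w) < 1 or (w < 0).any() or w.sum() <= 0:
            raise ValueError("exon_count_weights must be non-negative with positive sum")


@dataclass
class DegradationSpec:
    """How the old assembly is carved out of the new one."""

    seed: int = 0
    deletion_rate_low_gc: float = 0.12
    deletion_rate_high_gc: float = 0.02
    deletion_length_mean: int = 2_000
    scaffold_break_rate: float = 2e-5
    annotated_fraction: float = 0.85
    short_gene_annotation_penalty: float = 0.35
    short_cds_threshold: int = 600

    def __post_init__(self) -> None:
        for name in ("deletion_rate_low_gc", "deletion_rate_high_gc",
                     "annotated_fraction", "short_gene_annotation_penalty"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.deletion_rate_low_gc < self.deletion_rate_high_gc:
            raise ValueError("deletion_rate_low_gc must be >= deletion_rate_high_gc")
        if self.deletion_length_mean <= 0:
            raise ValueError("deletion_length_mean must be positive")
        if self.scaffold_break_rate < 0:
            raise ValueError("scaffold_break_rate must be non-negative")


@dataclass
class EvidenceSimSpec:
    """Multi-tissue transcript, homolog, peptide and conservation evidence."""

    seed: int = 0
    tissue_names: tuple[str, ...] = ("brain", "antennae", "ovary", "testes")
    expression_prob: float = 0.55
    spliced_fraction: float = 0.9
    unspliced_fraction: float = 0.7
    antisense_noise_rate: float = 0.0
    homolog_coverage_prob: dict = field(default_factory=lambda: {"metazoa": 0.45, "dmel": 0.08})
    peptide_per_gene_rate: float = 0.4
    conservation_prob: dict = field(default_factory=lambda: {"aflo": 0.85, "bter": 0.78})
    domain_match_prob: float = 0.5

    def __post_init__(self) -> None:
        probs = [self.expression_prob, self.spliced_fraction, self.unspliced_fraction,
                 self.antisense_noise_rate, self.domain_match_prob,
                 *self.homolog_coverage_prob.values(), *self.conservation_prob.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must be in [0, 1]")
        if self.peptide_per_gene_rate < 0:
            raise ValueError("peptide_per_gene_rate must be non-negative")


@dataclass
class TruthDomain:
    scaffold: str
    start: int
    end: int
    gc_level: float


@dataclass
class GeneTruth:
    gene_id: str
    class_stringent: str
    class_relaxed: str
    retained_fraction: float        # max retained CDS fraction on any one old scaffold
    retained_fraction_total: float  # retained CDS fraction pooled over old scaffolds
    breadth: Optional[str] = None   # narrow | broad | neither | none


@dataclass
class TruthTable:
    genes: dict[str, GeneTruth]

    def __post_init__(self) -> None:
        for gid, t in self.genes.items():
            if gid != t.gene_id:
                raise ValueError("truth table keys must equal gene ids")

    def classes(self, mode: str) -> dict[str, str]:
        attr = "class_stringent" if mode == "stringent" else "class_relaxed"
        return {gid: getattr(t, attr) for gid, t in self.genes.items()}


@dataclass
class LiftSegment:
    """One surviving block: new coords [new_start, new_end) -> old coords."""
    new_scaffold: str
    new_start: int
    new_end: int
    old_scaffold: str
    old_start: int

    @property
    def length(self) -> int:
        return self.new_end - self.new_start


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

_BASES_GC = np.frombuffer(b"GC", dtype="S1")
_BASES_AT = np.frombuffer(b"AT", dtype="S1")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    is_gc = rng.random(n) < gc
    which = rng.integers(0, 2, n)
    arr = np.where(is_gc, _BASES_GC[which], _BASES_AT[which])
    return arr.tobytes().decode()


def simulate_genome(spec: GenomeSimSpec) -> tuple[dict[str, str], list[TruthDomain]]:
    """Generate scaffolds as concatenations of GC-homogeneous domains.

    Within a domain every base is G or C with that domain's GC fraction,
    i.i.d.; the returned truth domains partition each scaffold.
    """
    rng = np.random.default_rng(spec.seed)
    assembly: dict[str, str] = {}
    domains: list[TruthDomain] = []
    for i in range(spec.n_scaffolds):
        name = f"scf{i + 1:03d}"
        parts: list[str] = []
        pos = 0
        prev_gc = None
        while pos < spec.scaffold_length:
            dlen = int(max(spec.min_domain_length, rng.exponential(spec.domain_length_mean)))
            if spec.scaffold_length - pos - dlen < spec.min_domain_length:
                dlen = spec.scaffold_length - pos
            choices = [g for g in spec.gc_levels if g != prev_gc] or list(spec.gc_levels)
            gc = float(rng.choice(choices))
            parts.append(_random_seq(rng, dlen, gc))
            domains.append(TruthDomain(name, pos, pos + dlen, gc))
            pos += dlen
            prev_gc = gc
        assembly[name] = "".join(parts)
    return assembly, domains


# ---------------------------------------------------------------------------
# Gene placement
# ---------------------------------------------------------------------------

def _random_codons(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    """Sense codons with per-base GC propensity ``gc``; stops are resampled."""
    out: list[str] = []
    while len(out) < n:
        batch = max(16, n - len(out))
        seq = _random_seq(rng, 3 * batch, gc)
        for j in range(batch):
            codon = seq[3 * j: 3 * j + 3]
            if codon not in STOPS:
                out.append(codon)
            if len(out) == n:
                break
    return out


def _gene_structure(rng: np.random.Generator, spec: GenomeSimSpec) -> tuple[list[int], list[int]]:
    """Draw (exon_lengths, intron_lengths) for one gene; CDS length % 3 == 0, >= 75."""
    w = np.asarray(spec.exon_count_weights, float)
    n_exons = int(rng.choice(np.arange(1, len(w) + 1), p=w / w.sum()))
    n_codons = int(np.clip(np.round(rng.lognormal(np.log(280.0), 0.6)), 27, 1500))
    cds_nt = 3 * n_codons  # includes the stop codon
    min_exon = 30
    n_exons = min(n_exons, max(1, cds_nt // (2 * min_exon)))
    if n_exons == 1:
        exon_lens = [cds_nt]
    else:
        free = cds_nt - min_exon * n_exons
        cuts = np.floor(rng.dirichlet(np.ones(n_exons)) * free).astype(int)
        cuts[0] += free - cuts.sum()
        exon_lens = [min_exon + int(c) for c in cuts]
    intron_lens = [int(x) for x in rng.integers(60, 400, n_exons - 1)]
    return exon_lens, intron_lens


def place_genes(assembly: dict[str, str], domain_truth: list[TruthDomain],
                spec: GenomeSimSpec) -> tuple[dict[str, str], list[GeneModel]]:
    """Place non-overlapping genes with real ORFs, biased to low-GC domains.

    The sequence under each gene is overwritten so that the spliced CDS
    starts with ATG, ends with a stop, contains no internal stop, and all
    introns carry GT/AG dinucleotides except a configurable minority.
    Returns a new assembly (inputs are not mutated) plus the gene models.
    """
    rng = np.random.default_rng([spec.seed, 1])
    seqs = {name: bytearray(s, "ascii") for name, s in assembly.items()}
    total = sum(len(s) for s in assembly.values())
    n_genes = max(1, round(spec.gene_density_per_mb * total / 1e6))

    lowest = min(spec.gc_levels)
    low_domains = [d for d in domain_truth if d.gc_level == lowest]
    all_domains = list(domain_truth)

    def pick_domain() -> TruthDomain:
        pool = low_domains if (low_domains and rng.random() < spec.low_gc_gene_bias) else all_domains
        weights = np.array([d.end - d.start for d in pool], float)
        return pool[int(rng.choice(len(pool), p=weights / weights.sum()))]

    occupied: dict[str, list[Interval]] = {name: [] for name in assembly}
    genes: list[GeneModel] = []
    margin = 50
    for gi in range(n_genes):
        placed = False
        for _attempt in range(300):
            dom = pick_domain()
            exon_lens, intron_lens = _gene_structure(rng, spec)
            span = sum(exon_lens) + sum(intron_lens)
            scaf_len = len(seqs[dom.scaffold])
            if span + 2 * margin >= scaf_len:
                continue
            mid = int(rng.integers(dom.start, dom.end))
            start = int(np.clip(mid - span // 2, margin, scaf_len - span - margin))
            end = start + span
            if start + span // 2 < dom.start or start + span // 2 >= dom.end:
                # keep the midpoint inside the chosen domain so the placement
                # bias is exact
                continue
            if any(s < end + 20 and start < e + 20 for s, e in occupied[dom.scaffold]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            gene = _write_gene(rng, seqs[dom.scaffold], dom, start, exon_lens,
                               intron_lens, strand, spec, f"g{gi + 1:05d}")
            occupied[dom.scaffold].append((start, end))
            genes.append(gene)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place gene {gi + 1}/{n_genes}: gene density too high "
                "for non-overlapping placement"
            )
    genes.sort(key=lambda g: (g.scaffold, g.span))
    return {name: bytes(b).decode() for name, b in seqs.items()}, genes


def _write_gene(rng: np.random.Generator, seq: bytearray, dom: TruthDomain, start: int,
                exon_lens: list[int], intron_lens: list[int], strand: str,
                spec: GenomeSimSpec, gene_id: str) -> GeneModel:
    cds_nt = sum(exon_lens)
    n_codons = cds_nt // 3
    codons = ["ATG"] + _random_codons(rng, n_codons - 2, dom.gc_level) + [STOPS[int(rng.integers(0, 3))]]
    cds = "".join(codons)
    genomic_cds = revcomp(cds) if strand == "-" else cds

    # ascending genomic exon intervals; the concatenation of ascending exon
    # sequence must equal genomic_cds
    exons: list[Interval] = []
    pos = start
    for k, elen in enumerate(exon_lens):
        exons.append((pos, pos + elen))
        pos += elen
        if k < len(intron_lens):
            pos += intron_lens[k]
    off = 0
    for (s, e) in exons:
        seq[s:e] = genomic_cds[off:off + (e - s)].encode()
        off += e - s

    # introns: transcribed-sense donor..acceptor, reverse-complemented onto
    # the forward strand for minus-strand genes
    for (s1, e1), (s2, _e2) in zip(exons, exons[1:]):
        ilen = s2 - e1
        if rng.random() < spec.noncanonical_intron_rate:
            donor, acceptor = NONCANONICAL_INTRONS[int(rng.integers(0, len(NONCANONICAL_INTRONS)))]
        else:
            donor, acceptor = CANONICAL_INTRON
        interior = _random_seq(rng, ilen - 4, dom.gc_level)
        transcribed = donor + interior + acceptor
        forward = revcomp(transcribed) if strand == "-" else transcribed
        seq[e1:s2] = forward.encode()
    return GeneModel(gene_id, dom.scaffold, strand, exons)


# ---------------------------------------------------------------------------
# Assembly degradation
# ---------------------------------------------------------------------------

@dataclass
class DegradationResult:
    old_assembly: dict[str, str]
    lift_table: list[LiftSegment]
    truth: TruthTable
    old_genes: list[GeneModel]


def _merge_intervals(ivs: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def degrade_assembly(assembly: dict[str, str], genes: list[GeneModel],
                     spec: DegradationSpec, domain_truth: list[TruthDomain]) -> DegradationResult:
    """Derive the old assembly by biased deletion plus scaffold breaks.

    Deletions are drawn per compositional domain with an expected deleted
    fraction of ``deletion_rate_low_gc`` in the lowest-GC domain class and
    ``deletion_rate_high_gc`` elsewhere.  The lift table maps every
    surviving new-assembly base to its old-assembly coordinate.  Class truth
    per gene: Type I when the best per-old-scaffold retained CDS fraction is
    below 0.80 (stringent; 0.50 for the relaxed column); retained genes are
    Previously Known when also emitted into the simulated old gene set,
    otherwise Type II.
    """
    rng = np.random.default_rng(spec.seed)
    gc_min = min(d.gc_level for d in domain_truth) if domain_truth else 0.0
    by_scaffold: dict[str, list[TruthDomain]] = {}
    for d in domain_truth:
        by_scaffold.setdefault(d.scaffold, []).append(d)

    old_assembly: dict[str, str] = {}
    lift: list[LiftSegment] = []
    for name in assembly:
        seq = assembly[name]
        n = len(seq)
        deletions: list[Interval] = []
        for d in by_scaffold.get(name, [TruthDomain(name, 0, n, 0.5)]):
            rate = spec.deletion_rate_low_gc if d.gc_level == gc_min else spec.deletion_rate_high_gc
            if rate <= 0:
                continue
            n_del = rng.poisson((d.end - d.start) * rate / spec.deletion_length_mean)
            for _ in range(n_del):
                dlen = max(100, int(rng.exponential(spec.deletion_length_mean)))
                s = int(rng.integers(d.start, d.end))
                deletions.append((s, min(s + dlen, n)))
        deletions = _merge_intervals(deletions)

        n_breaks = rng.binomial(n, spec.scaffold_break_rate) if spec.scaffold_break_rate > 0 else 0
        breaks = sorted(int(b) for b in rng.integers(1, n, n_breaks)) if n_breaks else []

        # surviving segments = complement of deletions, then split at breaks
        survivors: list[Interval] = []
        pos = 0
        for s, e in deletions + [(n, n)]:
            if s > pos:
                survivors.append((pos, s))
            pos = max(pos, e)
        pieces: list[list[Interval]] = [[]]
        bi = 0
        for s, e in survivors:
            cur = s
            while bi < len(breaks) and breaks[bi] <= e:
                b = breaks[bi]
                if b > cur:
                    pieces[-1].append((cur, b))
                pieces.append([])
                cur = b
                bi += 1
            if e > cur:
                pieces[-1].append((cur, e))
        while bi < len(breaks):  # breaks inside trailing deletions
            pieces.append([])
            bi += 1
        pieces = [p for p in pieces if p]
        for j, segs in enumerate(pieces):
            old_name = f"{name}_p{j + 1}"
            old_pos = 0
            chunks = []
            for s, e in segs:
                lift.append(LiftSegment(name, s, e, old_name, old_pos))
                chunks.append(assembly[name][s:e])
                old_pos += e - s
            old_assembly[old_name] = "".join(chunks)

    truth, old_genes = _gene_truth(rng, genes, lift, spec)
    return DegradationResult(old_assembly, lift, truth, old_genes)


def _gene_truth(rng: np.random.Generator, genes: list[GeneModel],
                lift: list[LiftSegment], spec: DegradationSpec) -> tuple[TruthTable, list[GeneModel]]:
    lift_by_scaffold: dict[str, list[LiftSegment]] = {}
    for seg in lift:
        lift_by_scaffold.setdefault(seg.new_scaffold, []).append(seg)

    truth: dict[str, GeneTruth] = {}
    old_genes: list[GeneModel] = []
    for gene in genes:
        segs = lift_by_scaffold.get(gene.scaffold, [])
        retained: dict[str, int] = {}
        pieces: dict[str, list[Interval]] = {}
        for es, ee in gene.coding_exons:
            for seg in segs:
                s, e = max(es, seg.new_start), min(ee, seg.new_end)
                # fragments below the alignable minimum cannot be recovered
                # by any seeded local alignment and do not count as retained
                if e - s >= ALIGNABLE_MIN:
                    retained[seg.old_scaffold] = retained.get(seg.old_scaffold, 0) + (e - s)
                    old_s = seg.old_start + (s - seg.new_start)
                    pieces.setdefault(seg.old_scaffold, []).append((old_s, old_s + (e - s)))
        cds_len = gene.cds_length
        total_frac = sum(retained.values()) / cds_len
        if retained:
            best_old = max(retained, key=lambda k: (retained[k], k))
            best_frac = retained[best_old] / cds_len
        else:
            best_old, best_frac = None, 0.0

        annotated = False
        if best_frac >= 0.80:
            p = spec.annotated_fraction
            if cds_len < spec.short_cds_threshold:
                p *= spec.short_gene_annotation_penalty
            annotated = rng.random() < p
        cls_str = TYPE_I if best_frac < 0.80 else (KNOWN if annotated else TYPE_II)
        cls_rel = TYPE_I if best_frac < 0.50 else (KNOWN if annotated else TYPE_II)
        truth[gene.id] = GeneTruth(gene.id, cls_str, cls_rel, best_frac, total_frac)
        if annotated:
            exons = _merge_intervals(pieces[best_old])
            old_len = sum(e - s for s, e in exons)
            old_genes.append(GeneModel(f"old_{gene.id}", best_old, gene.strand, exons,
                                       partial=(old_len % 3 != 0 or old_len != cds_len)))
    old_genes.sort(key=lambda g: (g.scaffold, g.span))
    return TruthTable(truth), old_genes


# ---------------------------------------------------------------------------
# Evidence simulation
# ---------------------------------------------------------------------------

@dataclass
class EvidenceBundle:
    transcripts: dict[str, list[SplicedAlignment]]   # library -> alignments
    homologs: dict[str, list[SplicedAlignment]]      # source proteome -> alignments
    peptides: list[str]
    conservation: list[tuple[str, str, bool]]        # gene, informant, supported
    domain_table: list[tuple[str, str]]              # gene, domain id
    breadth_truth: dict[str, str]


def _tryptic_fragments(protein: str, min_len: int = 6) -> list[str]:
    frags, cur = [], []
    for aa in protein:
        cur.append(aa)
        if aa in "KR":
            frags.append("".join(cur))
            cur = []
    if cur:
        frags.append("".join(cur))
    return [f for f in frags if len(f) >= min_len]


def simulate_evidence(genes: list[GeneModel], assembly: dict[str, str],
                      spec: EvidenceSimSpec) -> EvidenceBundle:
    """Emit per-library transcript alignments, homologs, peptides and tables.

    Spliced alignments reproduce the gene's exact exon/intron coordinates on
    the gene's strand; unspliced alignments are single blocks with unknown
    strand; antisense noise (if any) is spliced evidence on the opposite
    strand.  Peptides are tryptic fragments (>= 6 aa) of the translated CDS.
    Expression-breadth truth is recorded from the actual spliced emissions.
    """
    rng = np.random.default_rng(spec.seed)
    transcripts: dict[str, list[SplicedAlignment]] = {t: [] for t in spec.tissue_names}
    breadth_truth: dict[str, str] = {}
    homologs: dict[str, list[SplicedAlignment]] = {s: [] for s in spec.homolog_coverage_prob}
    peptides: list[str] = []
    conservation: list[tuple[str, str, bool]] = []
    domain_table: list[tuple[str, str]] = []

    n_tissues = len(spec.tissue_names)
    for gene in genes:
        spliced_in = 0
        for tissue in spec.tissue_names:
            if rng.random() < spec.expression_prob:
                if rng.random() < spec.spliced_fraction:
                    aln = SplicedAlignment(f"{tissue}_rna_{gene.id}", gene.scaffold,
                                           gene.strand, list(gene.coding_exons))
                    transcripts[tissue].append(aln)
                    # single-exon genes yield single-block (unspliced)
                    # alignments; only genuinely spliced evidence counts
                    # toward expression-breadth truth
                    if aln.spliced:
                        spliced_in += 1
                if rng.random() < spec.unspliced_fraction:
                    es, ee = gene.coding_exons[int(rng.integers(0, gene.n_coding_exons))]
                    blen = min(ee - es, int(rng.integers(50, 200)))
                    bs = int(rng.integers(es, ee - blen + 1))
                    transcripts[tissue].append(SplicedAlignment(
                        f"{tissue}_est_{gene.id}", gene.scaffold, ".",
                        [(bs, bs + blen)]))
            if rng.random() < spec.antisense_noise_rate:
                flipped = "-" if gene.strand == "+" else "+"
                transcripts[tissue].append(SplicedAlignment(
                    f"{tissue}_anti_{gene.id}", gene.scaffold, flipped,
                    list(gene.coding_exons)))
        if spliced_in == 0:
            breadth_truth[gene.id] = "none"
        elif spliced_in == 1:
            breadth_truth[gene.id] = "narrow"
        elif spliced_in == n_tissues:
            breadth_truth[gene.id] = "broad"
        else:
            breadth_truth[gene.id] = "neither"

        for source, prob in spec.homolog_coverage_prob.items():
            if rng.random() < prob:
                cov = rng.uniform(0.62, 1.0)
                target_bases = max(30, int(round(cov * gene.cds_length)))
                blocks: list[Interval] = []
                remaining = target_bases
                for es, ee in gene.exons_5to3():
                    take = min(ee - es, remaining)
                    if take <= 0:
                        break
                    if gene.strand == "+":
                        blocks.append((es, es + take))
                    else:
                        blocks.append((ee - take, ee))
                    remaining -= take
                blocks.sort()
                aligned = sum(e - s for s, e in blocks)
                homologs[source].append(SplicedAlignment(
                    f"{source}_prot_{gene.id}", gene.scaffold, gene.strand, blocks,
                    identity=float(rng.uniform(0.65, 0.95)),
                    query_coverage=aligned / gene.cds_length,
                    query_length=gene.cds_length))

        n_pep = rng.poisson(spec.peptide_per_gene_rate)
        if n_pep > 0:
            frags = _tryptic_fragments(translate(extract_cds(gene, assembly[gene.scaffold])))
            if frags:
                idx = rng.choice(len(frags), size=min(n_pep, len(frags)), replace=False)
                peptides.extend(frags[i] for i in sorted(idx))

        for informant, prob in spec.conservation_prob.items():
            conservation.append((gene.id, informant, bool(rng.random() < prob)))
        if rng.random() < spec.domain_match_prob:
            domain_table.append((gene.id, f"IPR{int(rng.integers(1, 20000)):06d}"))

    return EvidenceBundle(transcripts, homologs, peptides, conservation,
                          domain_table, breadth_truth)


# ---------------------------------------------------------------------------
# Full fixture bundle
# ---------------------------------------------------------------------------

def simulate_bundle(genome_spec: GenomeSimSpec, degradation_spec: DegradationSpec,
                    evidence_spec: EvidenceSimSpec, outdir: str) -> dict:
    """Run the whole generator and write every fixture file under ``outdir``.

    Returns a dict with both the in-memory objects and the file paths.
    """
    os.makedirs(outdir, exist_ok=True)
    assembly0, domains = simulate_genome(genome_spec)
    assembly, genes = place_genes(assembly0, domains, genome_spec)
    degr = degrade_assembly(assembly, genes, degradation_spec, domains)
    evidence = simulate_evidence(genes, assembly, evidence_spec)
    for gid, breadth in evidence.breadth_truth.items():
        degr.truth.genes[gid].breadth = breadth

    paths = {
        "new_assembly": os.path.join(outdir, "new_assembly.fasta"),
        "new_genes": os.path.join(outdir, "new_genes.gff3"),
        "old_assembly": os.path.join(outdir, "old_assembly.fasta"),
        "old_genes": os.path.join(outdir, "old_genes.gff3"),
        "lift_table": os.path.join(outdir, "lift_table.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "domains_truth": os.path.join(outdir, "domains_truth.tsv"),
        "peptides": os.path.join(outdir, "peptides.txt"),
        "conservation": os.path.join(outdir, "conservation.tsv"),
        "domain_table": os.path.join(outdir, "domain_table.tsv"),
        "meta": os.path.join(outdir, "meta.json"),
    }
    formats.write_fasta(assembly, paths["new_assembly"])
    formats.write_gene_set(genes, paths["new_genes"])
    formats.write_fasta(degr.old_assembly, paths["old_assembly"])
    formats.write_gene_set(degr.old_genes, paths["old_genes"])
    with open(paths["lift_table"], "w") as fh:
        fh.write("new_scaffold\tnew_start\tnew_end\told_scaffold\told_start\n")
        for seg in degr.lift_table:
            fh.write(f"{seg.new_scaffold}\t{seg.new_start}\t{seg.new_end}\t"
                     f"{seg.old_scaffold}\t{seg.old_start}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("gene_id\tclass_stringent\tclass_relaxed\tretained_fraction\t"
                 "retained_fraction_total\tbreadth\n")
        for gid in sorted(degr.truth.genes):
            t = degr.truth.genes[gid]
            fh.write(f"{gid}\t{t.class_stringent}\t{t.class_relaxed}\t"
                     f"{t.retained_fraction:.6f}\t{t.retained_fraction_total:.6f}\t"
                     f"{t.breadth}\n")
    with open(paths["domains_truth"], "w") as fh:
        fh.write("scaffold\tstart\tend\tgc_level\n")
        for d in domains:
            fh.write(f"{d.scaffold}\t{d.start}\t{d.end}\t{d.gc_level:.4f}\n")
    with open(paths["peptides"], "w") as fh:
        for pep in evidence.peptides:
            fh.write(pep + "\n")
    with open(paths["conservation"], "w") as fh:
        fh.write("gene_id\tinformant\tsupported\n")
        for gid, informant, ok in evidence.conservation:
            fh.write(f"{gid}\t{informant}\t{int(ok)}\n")
    with open(paths["domain_table"], "w") as fh:
        fh.write("gene_id\tdomain_id\n")
        for gid, dom in evidence.domain_table:
            fh.write(f"{gid}\t{dom}\n")

    transcript_paths: dict[str, str] = {}
    for tissue, alns in evidence.transcripts.items():
        p = os.path.join(outdir, f"transcripts_{tissue}.bed")
        formats.write_alignments(alns, p, fmt="bed12")
        transcript_paths[tissue] = p
    homolog_paths: dict[str, str] = {}
    for source, alns in evidence.homologs.items():
        p = os.path.join(outdir, f"homologs_{source}.psl")
        formats.write_alignments(alns, p, fmt="psl",
                                 target_sizes={k: len(v) for k, v in assembly.items()})
        homolog_paths[source] = p
    paths["transcripts"] = transcript_paths
    paths["homologs"] = homolog_paths

    meta = {
        "genome_spec": dataclasses.asdict(genome_spec),
        "degradation_spec": dataclasses.asdict(degradation_spec),
        "evidence_spec": dataclasses.asdict(evidence_spec),
    }
    with open(paths["meta"], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")

    return {
        "paths": paths,
        "assembly": assembly,
        "domains": domains,
        "genes": genes,
        "old_assembly": degr.old_assembly,
        "old_genes": degr.old_genes,
        "lift_table": degr.lift_table,
        "truth": degr.truth,
        "evidence": evidence,
    }
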