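"""GC compositional domains by recursive Jensen-Shannon segmentation.

A scaffold is viewed as a binary sequence (G/C = 1, A/T = 0).  At each
recursion step the split point maximising the Jensen-Shannon divergence
between the two halves is proposed and accepted when the divergence exceeds
an empirical null threshold, calibrated by simulating homogeneous Bernoulli
sequences of the same length and composition and taking the 1 - alpha
quantile of their maximal divergences.  Recursion stops on rejection or at
the minimum domain length.  Scaffolds below a length floor (default 10 kb)
cannot be segmented meaningfully and are returned whole, flagged.

Ambiguous bases: positions that are not A/C/G/T are excluded from both the
numerator and denominator of every GC computation, and runs of >= 10 Ns
split candidate domains outright (assembly gaps must not masquerade as
compositional boundaries).

Each gene is then assigned the mean non-coding GC of the domains it spans,
weighted by the fraction of the gene's genomic extent falling in each
domain; non-coding GC is used so codon bias does not leak into the
domain's compositional signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import CompositionalDomain, GeneModel, Interval

N_RUN_SPLIT = 10  # runs of >= this many ambiguous bases split candidate domains


@dataclass
class SegmentationParams:
    min_scaffold_length: int = 10_000
    min_domain_length: int = 3_000
    significance_alpha: float = 0.01
    null_replicates: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.significance_alpha < 1.0):
            raise ValueError("significance_alpha must be in (0, 1)")
        if self.min_domain_length <= 0 or self.min_scaffold_length <= 0:
            raise ValueError("length parameters must be positive")
        if self.null_replicates < 20:
            raise ValueError("null_replicates too small to estimate the threshold")


def _entropy(p: np.ndarray | float) -> np.ndarray | float:
    """Bernoulli entropy in bits, with H(0) = H(1) = 0."""
    p = np.asarray(p, float)
    out = np.zeros_like(p)
    mask = (p > 0) & (p < 1)
    pm = p[mask]
    out[mask] = -(pm * np.log2(pm) + (1 - pm) * np.log2(1 - pm))
    return out


def _max_jsd(gc: np.ndarray, valid: np.ndarray, min_len: int) -> tuple[float, int]:
    """Best split of a binary segment by weighted Jensen-Shannon divergence.

    Returns (divergence, split_index); (0, -1) when no admissible split.
    Ambiguous positions carry zero weight.
    """
    n = len(gc)
    if n < 2 * min_len:
        return 0.0, -1
    cg = np.cumsum(gc)
    cv = np.cumsum(valid)
    tot_g, tot_v = cg[-1], cv[-1]
    if tot_v == 0:
        return 0.0, -1
    ks = np.arange(min_len, n - min_len + 1)
    vl = cv[ks - 1]
    vr = tot_v - vl
    ok = (vl > 0) & (vr > 0)
    if not ok.any():
        return 0.0, -1
    ks, vl, vr = ks[ok], vl[ok], vr[ok]
    gl = cg[ks - 1]
    pl = gl / vl
    pr = (tot_g - gl) / vr
    h_tot = float(_entropy(tot_g / tot_v))
    d = h_tot - (vl / tot_v) * _entropy(pl) - (vr / tot_v) * _entropy(pr)
    j = int(np.argmax(d))
    return float(d[j]), int(ks[j])


def _null_threshold(rng: np.random.Generator, n: int, p: float, min_len: int,
                    reps: int, alpha: float) -> float:
    """1 - alpha quantile of max-JSD over homogeneous Bernoulli(p) sequences."""
    if p <= 0.0 or p >= 1.0:
        return np.inf
    maxima = np.empty(reps)
    valid = np.ones(n, dtype=np.int64)
    for r in range(reps):
        seq = (rng.random(n) < p).astype(np.int64)
        maxima[r], _ = _max_jsd(seq, valid, min_len)
    return float(np.quantile(maxima, 1.0 - alpha))


def segment_scaffold(sequence: str, params: SegmentationParams | None = None,
                     scaffold: str = "scaffold") -> list[CompositionalDomain]:
    """Partition one scaffold into GC-homogeneous compositional domains.

    Deterministic for a given ``params.seed``.  Scaffolds shorter than
    ``min_scaffold_length`` are returned as a single domain with
    ``segmented=False``.
    """
    params = params or SegmentationParams()
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype="S1")
    gc = np.isin(arr, np.array([b"G", b"C"])).astype(np.int64)
    valid = np.isin(arr, np.array([b"A", b"C", b"G", b"T"])).astype(np.int64)

    def gc_of(a: int, b: int) -> float | None:
        v = int(valid[a:b].sum())
        return float(gc[a:b].sum() / v) if v else None

    n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")
    if n < params.min_scaffold_length:
        return [CompositionalDomain(scaffold, 0, n, gc_of(0, n), segmented=False)]

    # split on long ambiguity runs first
    chunks: list[tuple[int, int, bool]] = []  # (start, end, is_gap)
    invalid = valid == 0
    pos = 0
    i = 0
    while i < n:
        if invalid[i]:
            j = i
            while j < n and invalid[j]:
                j += 1
            if j - i >= N_RUN_SPLIT:
                if i > pos:
                    chunks.append((pos, i, False))
                chunks.append((i, j, True))
                pos = j
            i = j
        else:
            i += 1
    if pos < n:
        chunks.append((pos, n, False))

    rng = np.random.default_rng(params.seed)
    domains: list[CompositionalDomain] = []
    for cs, ce, is_gap in chunks:
        if is_gap:
            domains.append(CompositionalDomain(scaffold, cs, ce, gc_of(cs, ce), gap=True))
            continue
        stack = [(cs, ce)]
        while stack:
            a, b = stack.pop()
            seg_gc, seg_valid = gc[a:b], valid[a:b]
            d, k = _max_jsd(seg_gc, seg_valid, params.min_domain_length)
            accepted = False
            if k > 0:
                nv = int(seg_valid.sum())
                p = float(seg_gc.sum() / nv) if nv else 0.0
                thr = _null_threshold(rng, b - a, p, params.min_domain_length,
                                      params.null_replicates, params.significance_alpha)
                accepted = d > thr
            if accepted:
                # recurse left-then-right for a deterministic emission order
                stack.append((a + k, b))
                stack.append((a, a + k))
            else:
                domains.append(CompositionalDomain(scaffold, a, b, gc_of(a, b)))
    domains.sort(key=lambda d: d.start)
    return domains


def segment_assembly(assembly: dict[str, str],
                     params: SegmentationParams | None = None) -> list[CompositionalDomain]:
    out: list[CompositionalDomain] = []
    for name in assembly:
        out.extend(segment_scaffold(assembly[name], params, scaffold=name))
    return out


# ---------------------------------------------------------------------------
# Non-coding GC and gene-weighted GC
# ---------------------------------------------------------------------------

def domain_noncoding_gc(domains: list[CompositionalDomain], genes: list[GeneModel],
                        assembly: dict[str, str]) -> list[CompositionalDomain]:
    """Fill ``gc_noncoding``: GC over domain positions outside all coding exons.

    Coding cover is taken over both strands.  Returns new domain objects;
    inputs are untouched.  A fully coding domain gets ``gc_noncoding=None``.
    """
    coding_by_scaffold: dict[str, list[Interval]] = {}
    for g in genes:
        coding_by_scaffold.setdefault(g.scaffold, []).extend(g.coding_exons)
    masks: dict[str, np.ndarray] = {}
    gcs: dict[str, np.ndarray] = {}
    valids: dict[str, np.ndarray] = {}
    for name, seq in assembly.items():
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype="S1")
        gcs[name] = np.isin(arr, np.array([b"G", b"C"]))
        valids[name] = np.isin(arr, np.array([b"A", b"C", b"G", b"T"]))
        mask = np.zeros(len(seq), dtype=bool)
        for s, e in coding_by_scaffold.get(name, []):
            mask[s:e] = True
        masks[name] = mask

    out: list[CompositionalDomain] = []
    for d in domains:
        nonc = ~masks[d.scaffold][d.start:d.end] & valids[d.scaffold][d.start:d.end]
        n_nonc = int(nonc.sum())
        gc_nc = float(gcs[d.scaffold][d.start:d.end][nonc].sum() / n_nonc) if n_nonc else None
        out.append(CompositionalDomain(d.scaffold, d.start, d.end, d.gc_all,
                                       gc_noncoding=gc_nc, n_noncoding=n_nonc,
                                       segmented=d.segmented, gap=d.gap))
    return out


def gene_weighted_gc(gene: GeneModel, domains: list[CompositionalDomain]) -> float | None:
    """Non-coding GC of the domains a gene spans, weighted by span overlap.

    The weight of a domain is the fraction of the gene's genomic extent
    (first to last coding base) overlapping it; domains with undefined
    non-coding GC are skipped with renormalisation.  Returns ``None`` for
    genes on unsegmented (too-short) scaffolds — such genes are excluded
    from GC analyses — or when no overlapping domain has a defined value.
    """
    gs, ge = gene.span
    weighted = 0.0
    weight = 0.0
    for d in domains:
        if d.scaffold != gene.scaffold:
            continue
        if not d.segmented:
            if max(gs, d.start) < min(ge, d.end):
                return None
            continue
        ov = min(ge, d.end) - max(gs, d.start)
        if ov <= 0 or d.gc_noncoding is None:
            continue
        weighted += ov * d.gc_noncoding
        weight += ov
    return weighted / weight if weight > 0 else None
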