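"""CDS metrics, splice-site survey, Wright's ENC and N50."""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ogsdelta import features as ft
from ogsdelta.features import _AA_CODONS, enc, scaffold_n50
from ogsdelta.models import GeneModel, SplicedAlignment
from ogsdelta.sequtils import revcomp

AA_ORDER = sorted(_AA_CODONS)  # all 20 amino acids


def one_codon_per_aa_cds(repeats: int = 100) -> str:
    cassette = "".join(sorted(_AA_CODONS[aa])[0] for aa in AA_ORDER)
    return cassette * repeats


def equal_usage_cds(copies: int = 60) -> str:
    parts = []
    for aa in AA_ORDER:
        if len(_AA_CODONS[aa]) >= 2:
            parts.extend(sorted(_AA_CODONS[aa]) * copies)
    return "".join(parts)


class TestEnc:
    def test_single_codon_per_amino_acid_gives_exactly_20(self):
        assert enc(one_codon_per_aa_cds()).nc == pytest.approx(20.0, abs=1e-12)

    def test_equal_synonymous_usage_truncates_to_61(self):
        assert enc(equal_usage_cds()).nc == pytest.approx(61.0, abs=1e-12)

    def test_no_degenerate_amino_acid_is_undefined_with_reason(self):
        summary = enc("ATGTGG" * 30)  # Met and Trp only
        assert summary.nc is None and summary.reason

    def test_partial_codon_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="divisible"):
            s = enc(one_codon_per_aa_cds() + "AT")
        assert s.nc == pytest.approx(20.0, abs=1e-12)

    def test_matches_literal_formula_transcription(self, rng):
        """Random 200-codon CDSs vs a step-by-step oracle, to 1e-9."""
        sense = [c for c in _AA_CODONS_FLAT if c not in ("TAA", "TAG", "TGA")]
        for _ in range(100):
            codons = [sense[i] for i in rng.integers(0, len(sense), 200)]
            cds = "".join(codons)
            expected = _wright_oracle(codons)
            got = enc(cds).nc
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.sampled_from(sorted({c for v in _AA_CODONS.values() for c in v})),
                    min_size=50, max_size=300))
    def test_nc_bounds_whenever_defined(self, codons):
        nc = enc("".join(codons)).nc
        if nc is not None:
            assert 20.0 - 1e-9 <= nc <= 61.0 + 1e-9


_AA_CODONS_FLAT = sorted({c for v in _AA_CODONS.values() for c in v})


def _wright_oracle(codons: list[str]) -> float | None:
    """Literal transcription of Wright's estimator, computed step by step."""
    by_aa: dict[str, Counter] = defaultdict(Counter)
    for c in codons:
        for aa, cs in _AA_CODONS.items():
            if c in cs:
                by_aa[aa][c] += 1
    class_of = {aa: len(cs) for aa, cs in _AA_CODONS.items()}
    f_by_class: dict[int, list[float]] = defaultdict(list)
    for aa, counts in by_aa.items():
        k = class_of[aa]
        if k == 1:
            continue
        n = sum(counts.values())
        if n < 2:
            continue
        s = sum((cnt / n) ** 2 for cnt in counts.values())
        f_by_class[k].append((n * s - 1) / (n - 1))
    avg = {k: (sum(v) / len(v) if v else None) for k, v in
           ((k, f_by_class.get(k, [])) for k in (2, 3, 4, 6))}
    if avg[3] is None and avg[2] is not None and avg[4] is not None:
        avg[3] = (avg[2] + avg[4]) / 2
    sizes = {2: 9, 3: 1, 4: 5, 6: 3}
    if any(avg[k] is None for k in sizes):
        return None
    if any(avg[k] == 0 for k in sizes):
        return None
    nc = 2 + sum(sizes[k] / avg[k] for k in sizes)
    return min(nc, 61.0)


class TestCdsMetrics:
    def test_mean_and_total(self):
        genes = [GeneModel("a", "s", "+", [(0, 300)]),
                 GeneModel("b", "s", "+", [(500, 1400)])]
        m = ft.cds_metrics(genes)
        assert m.mean_length == 600 and m.total_coding_nt == 1200
        assert m.min_length == 300 and m.max_length == 900

    def test_single_exon_flag_and_reordering_invariance(self, small_bundle):
        genes = small_bundle["genes"]
        m1 = ft.cds_metrics(genes)
        m2 = ft.cds_metrics(list(reversed(genes)))
        assert m1.total_coding_nt == m2.total_coding_nt
        assert m1.histogram.equals(m2.histogram)
        flags = dict(zip(m1.per_gene["gene_id"], m1.per_gene["single_exon"]))
        for g in genes:
            assert flags[g.id] == (g.n_coding_exons == 1)

    def test_totals_equal_per_exon_summation_oracle(self, small_bundle):
        expected = sum(e - s for g in small_bundle["genes"] for s, e in g.coding_exons)
        assert ft.cds_metrics(small_bundle["genes"]).total_coding_nt == expected

    def test_histogram_bins_are_20nt(self):
        genes = [GeneModel("a", "s", "+", [(0, 81)], partial=True),
                 GeneModel("b", "s", "+", [(0, 99)], partial=True)]
        hist = ft.cds_metrics(genes).histogram
        assert hist.loc[80] == 2  # both in [80, 100)


class TestSpliceSurvey:
    def _setup(self):
        #          0         1         2
        #          0123456789012345678901234567890123456789
        seq_plus = "AAAATGAAAA" + "GT" + "C" * 30 + "AG" + "AAAAAAAAAA" * 3
        gene = GeneModel("g", "s", "+", [(0, 10), (44, 74)], partial=True)
        return {"s": seq_plus}, gene

    def test_plus_strand_canonical(self):
        asm, gene = self._setup()
        aln = SplicedAlignment("t", "s", "+", [(0, 10), (44, 74)])
        records, counts = ft.splice_site_survey([gene], asm, [aln])
        (rec,) = records
        assert rec.donor == "GT" and rec.acceptor == "AG"
        assert rec.canonical and rec.transcript_supported
        assert counts["canonical"] == 1

    def test_minus_strand_reverse_complemented(self):
        asm, gene = self._setup()
        seq_rc = revcomp(asm["s"])
        n = len(seq_rc)
        exons = sorted((n - e, n - s) for s, e in gene.coding_exons)
        gene_rc = GeneModel("g", "s2", "-", exons, partial=True)
        aln = SplicedAlignment("t", "s2", "-", exons)
        records, counts = ft.splice_site_survey([gene_rc], {"s2": seq_rc}, [aln])
        (rec,) = records
        assert rec.canonical  # forward strand reads CT..AC
        assert counts["canonical"] == 1

    def test_unsupported_intron_excluded_from_counts(self):
        asm, gene = self._setup()
        records, counts = ft.splice_site_survey([gene], asm, [])
        assert counts["canonical"] == 0 and counts["unsupported"] == 1
        assert records[0].canonical and not records[0].transcript_supported

    def test_alignment_order_invariance(self, small_bundle):
        alns = [a for lib in small_bundle["evidence"].transcripts.values()
                for a in lib if a.spliced]
        genes = small_bundle["genes"]
        asm = small_bundle["assembly"]
        _, c1 = ft.splice_site_survey(genes, asm, alns)
        _, c2 = ft.splice_site_survey(genes, asm, list(reversed(alns)))
        assert c1 == c2

    def test_fixture_noncanonical_rate_reflects_generator(self, small_bundle):
        alns = [a for lib in small_bundle["evidence"].transcripts.values()
                for a in lib if a.spliced]
        _, counts = ft.splice_site_survey(small_bundle["genes"],
                                          small_bundle["assembly"], alns)
        total = counts["canonical"] + counts["noncanonical"]
        assert total > 50
        assert counts["noncanonical"] / total < 0.10  # generator minority rate


class TestN50:
    def test_single_and_walkthrough(self):
        assert scaffold_n50([100]) == 100
        assert scaffold_n50([8, 5, 3, 2]) == 5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            scaffold_n50([])

    def test_against_sort_and_scan_oracle(self, rng):
        for _ in range(25):
            lengths = rng.integers(1, 10_000, size=int(rng.integers(1, 1_000))).tolist()
            # oracle: scan sorted-descending cumulative sum
            total = sum(lengths)
            acc, expected = 0, None
            for l in sorted(lengths, reverse=True):
                acc += l
                if acc * 2 >= total:
                    expected = l
                    break
            assert scaffold_n50(lengths) == expected
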