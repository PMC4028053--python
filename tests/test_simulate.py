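"""Generator contracts: composition, real ORFs, determinism, truth bookkeeping."""

from __future__ import annotations

import filecmp

import numpy as np
import pytest

from ogsdelta import simulate as sim
from ogsdelta.mapping import MIN_SEGMENT
from ogsdelta.sequtils import extract_cds, translate


def gc_fraction(s: str) -> float:
    return (s.count("G") + s.count("C")) / len(s)


class TestSimulateGenome:
    def test_single_level_gc_converges(self):
        asm, _ = sim.simulate_genome(sim.GenomeSimSpec(seed=1, n_scaffolds=1,
                                                       scaffold_length=100_000,
                                                       gc_levels=(0.5,)))
        assert abs(gc_fraction(next(iter(asm.values()))) - 0.5) < 0.01

    def test_per_domain_gc_matches_truth(self):
        spec = sim.GenomeSimSpec(seed=2, n_scaffolds=10, scaffold_length=100_000,
                                 gc_levels=(0.2, 0.45))
        asm, domains = sim.simulate_genome(spec)
        # direct counting per emitted truth interval
        for d in domains:
            observed = gc_fraction(asm[d.scaffold][d.start:d.end])
            assert abs(observed - d.gc_level) < 0.02

    def test_domains_partition_each_scaffold(self):
        spec = sim.GenomeSimSpec(seed=3, n_scaffolds=3, scaffold_length=60_000)
        asm, domains = sim.simulate_genome(spec)
        for name, seq in asm.items():
            ivs = sorted((d.start, d.end) for d in domains if d.scaffold == name)
            assert ivs[0][0] == 0 and ivs[-1][1] == len(seq)
            assert all(a[1] == b[0] for a, b in zip(ivs, ivs[1:]))

    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        spec = sim.GenomeSimSpec(seed=9, n_scaffolds=2, scaffold_length=30_000)
        for sub in ("a", "b"):
            d = tmp_path / sub
            sim.simulate_bundle(spec, sim.DegradationSpec(seed=1),
                                sim.EvidenceSimSpec(seed=2), str(d))
        for fname in ("new_assembly.fasta", "new_genes.gff3", "old_assembly.fasta",
                      "truth.tsv", "transcripts_brain.bed", "homologs_dmel.psl"):
            assert filecmp.cmp(tmp_path / "a" / fname, tmp_path / "b" / fname,
                               shallow=False), fname

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            sim.GenomeSimSpec(scaffold_length=-5)
        with pytest.raises(ValueError):
            sim.GenomeSimSpec(gc_levels=(1.5,))
        with pytest.raises(ValueError):
            sim.DegradationSpec(deletion_rate_low_gc=0.01, deletion_rate_high_gc=0.5)


class TestPlaceGenes:
    def test_full_bias_places_all_midpoints_in_lowest_gc_domains(self):
        spec = sim.GenomeSimSpec(seed=4, n_scaffolds=3, scaffold_length=80_000,
                                 gene_density_per_mb=80, low_gc_gene_bias=1.0)
        asm0, domains = sim.simulate_genome(spec)
        _, genes = sim.place_genes(asm0, domains, spec)
        lowest = min(spec.gc_levels)
        low = [(d.scaffold, d.start, d.end) for d in domains if d.gc_level == lowest]
        for g in genes:
            mid = sum(g.span) // 2
            assert any(sc == g.scaffold and s <= mid < e for sc, s, e in low), g.id

    def test_every_cds_is_a_clean_orf(self, small_bundle):
        for g in small_bundle["genes"]:
            cds = extract_cds(g, small_bundle["assembly"][g.scaffold])
            assert len(cds) >= 75 and len(cds) % 3 == 0
            assert cds.startswith("ATG")
            assert cds[-3:] in ("TAA", "TAG", "TGA")
            assert "*" not in translate(cds)

    def test_genes_do_not_overlap(self, small_bundle):
        by_scaffold: dict[str, list] = {}
        for g in small_bundle["genes"]:
            by_scaffold.setdefault(g.scaffold, []).append(g.span)
        for spans in by_scaffold.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_single_exon_fraction_within_binomial_interval(self):
        # weights put 0.15 mass on one exon; with n = 500 placements the
        # exact 99.9% binomial interval for the count is [50, 102]
        spec = sim.GenomeSimSpec(seed=8, n_scaffolds=10, scaffold_length=250_000,
                                 gene_density_per_mb=200)
        asm0, domains = sim.simulate_genome(spec)
        _, genes = sim.place_genes(asm0, domains, spec)
        assert len(genes) == 500
        n_single = sum(1 for g in genes if g.n_coding_exons == 1)
        assert 50 <= n_single <= 102

    def test_density_too_high_fails_explicitly(self):
        spec = sim.GenomeSimSpec(seed=1, n_scaffolds=1, scaffold_length=12_000,
                                 gene_density_per_mb=3000)
        asm0, domains = sim.simulate_genome(spec)
        with pytest.raises(RuntimeError, match="density"):
            sim.place_genes(asm0, domains, spec)


class TestDegradeAssembly:
    def test_zero_deletion_rates_identity(self, small_bundle):
        spec = sim.DegradationSpec(seed=3, deletion_rate_low_gc=0.0,
                                   deletion_rate_high_gc=0.0, scaffold_break_rate=0.0)
        res = sim.degrade_assembly(small_bundle["assembly"], small_bundle["genes"],
                                   spec, small_bundle["domains"])
        assert list(res.old_assembly.values()) == list(small_bundle["assembly"].values())
        assert all(t.retained_fraction == 1.0 for t in res.truth.genes.values())
        assert not any(t.class_stringent == "TypeI" for t in res.truth.genes.values())

    def test_fully_deleted_gene_is_type_i_truth(self, small_bundle):
        # force near-total deletion of the low-GC class where genes live
        spec = sim.DegradationSpec(seed=4, deletion_rate_low_gc=1.0,
                                   deletion_rate_high_gc=0.0,
                                   deletion_length_mean=200_000)
        res = sim.degrade_assembly(small_bundle["assembly"], small_bundle["genes"],
                                   spec, small_bundle["domains"])
        wiped = [t for t in res.truth.genes.values() if t.retained_fraction == 0.0]
        assert wiped, "expected at least one fully deleted gene"
        assert all(t.class_stringent == "TypeI" and t.class_relaxed == "TypeI"
                   for t in wiped)

    def test_retained_fraction_matches_base_by_base_lift(self, small_bundle):
        """Brute-force oracle: lift every CDS base through the lift table."""
        lift = small_bundle["lift_table"]
        by_scaffold: dict[str, list] = {}
        for seg in lift:
            by_scaffold.setdefault(seg.new_scaffold, []).append(seg)
        for g in small_bundle["genes"]:
            per_old: dict[str, int] = {}
            for es, ee in g.coding_exons:
                for seg in by_scaffold.get(g.scaffold, []):
                    s, e = max(es, seg.new_start), min(ee, seg.new_end)
                    run = sum(1 for pos in range(s, e)
                              if seg.new_start <= pos < seg.new_end)
                    if run >= MIN_SEGMENT:  # the alignable-fragment floor
                        per_old[seg.old_scaffold] = per_old.get(seg.old_scaffold, 0) + run
            expected = max(per_old.values(), default=0) / g.cds_length
            assert small_bundle["truth"].genes[g.id].retained_fraction == pytest.approx(expected)

    def test_lift_table_maps_sequence_verbatim(self, small_bundle):
        new = small_bundle["assembly"]
        old = small_bundle["old_assembly"]
        for seg in small_bundle["lift_table"][::7]:
            assert (new[seg.new_scaffold][seg.new_start:seg.new_end]
                    == old[seg.old_scaffold][seg.old_start:seg.old_start + seg.length])

    def test_truth_covers_every_gene_once(self, small_bundle):
        truth = small_bundle["truth"]
        assert set(truth.genes) == {g.id for g in small_bundle["genes"]}


class TestSimulateEvidence:
    def test_expression_prob_one_forces_broad_breadth(self, small_bundle):
        # breadth is defined on spliced support, which single-exon genes can
        # never have: full expression forces broad for every multi-exon gene
        spec = sim.EvidenceSimSpec(seed=1, expression_prob=1.0, spliced_fraction=1.0)
        ev = sim.simulate_evidence(small_bundle["genes"], small_bundle["assembly"], spec)
        for g in small_bundle["genes"]:
            expected = "broad" if g.n_coding_exons > 1 else "none"
            assert ev.breadth_truth[g.id] == expected

    def test_zero_antisense_noise_means_no_opposite_strand_spliced(self, small_bundle):
        ev = small_bundle["evidence"]
        strand_of = {g.id: g.strand for g in small_bundle["genes"]}
        for alns in ev.transcripts.values():
            for a in alns:
                if a.spliced and a.strand in "+-":
                    gid = a.query_id.split("_rna_")[-1]
                    assert a.strand == strand_of[gid]

    def test_peptides_are_verbatim_substrings_of_their_proteome(self, small_bundle):
        proteins = [translate(extract_cds(g, small_bundle["assembly"][g.scaffold]))
                    for g in small_bundle["genes"]]
        for pep in small_bundle["evidence"].peptides:
            assert len(pep) >= 6
            assert any(pep in p for p in proteins), pep  # naive substring oracle

    def test_spliced_alignments_reproduce_gene_introns(self, small_bundle):
        introns_of = {g.id: set(g.introns()) for g in small_bundle["genes"]}
        checked = 0
        for alns in small_bundle["evidence"].transcripts.values():
            for a in alns:
                if "_rna_" in a.query_id and a.spliced:
                    gid = a.query_id.split("_rna_")[-1]
                    gaps = {g for g in a.block_gaps()}
                    assert gaps == introns_of[gid]
                    checked += 1
        assert checked > 10
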