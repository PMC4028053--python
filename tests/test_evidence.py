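"""Evidence strand rules, breadth, peptides, homologs and the matrix."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ogsdelta import evidence as ev
from ogsdelta.models import GeneModel, SplicedAlignment
from ogsdelta.sequtils import extract_cds, translate


def spliced_aln(qid, scaffold, strand, blocks):
    return SplicedAlignment(qid, scaffold, strand, blocks)


@pytest.fixture()
def one_gene():
    # exons (100,200) and (400,520); intron (200,400)
    return GeneModel("g1", "s", "+", [(100, 200), (400, 520)], partial=True)


class TestTranscriptOverlap:
    def test_spliced_opposite_strand_discarded(self, one_gene):
        aln = spliced_aln("t", "s", "-", [(100, 200), (400, 520)])
        sup = ev.transcript_overlap([one_gene], {"lib": [aln]})
        assert not sup.loc["g1", "spliced:lib"]

    def test_unspliced_any_strand_one_bp_suffices(self, one_gene):
        aln = SplicedAlignment("t", "s", "-", [(199, 260)])  # 1 bp coding overlap
        sup = ev.transcript_overlap([one_gene], {"lib": [aln]})
        assert sup.loc["g1", "unspliced:lib"]

    def test_spliced_same_strand_intron_only_no_support(self, one_gene):
        aln = spliced_aln("t", "s", "+", [(210, 260), (300, 390)])
        sup = ev.transcript_overlap([one_gene], {"lib": [aln]})
        assert not sup.loc["g1", "spliced:lib"]

    def test_monotone_under_added_alignments(self, one_gene, rng):
        alns = []
        prev = np.zeros(2, dtype=bool)
        for _ in range(20):
            s = int(rng.integers(0, 600))
            alns.append(SplicedAlignment("t", "s", "+", [(s, s + 40)]))
            sup = ev.transcript_overlap([one_gene], {"lib": list(alns)})
            cur = sup.loc["g1", ["spliced:lib", "unspliced:lib"]].to_numpy(bool)
            assert (cur | prev == cur).all()  # support never lost
            prev = cur


class TestExpressionBreadth:
    @pytest.mark.parametrize("pattern,expected", [
        ((1, 0, 0, 0), "narrow"),
        ((1, 1, 1, 1), "broad"),
        ((1, 1, 0, 0), "neither"),
        ((0, 0, 0, 0), "none"),
    ])
    def test_patterns(self, pattern, expected):
        tissues = ["t1", "t2", "t3", "t4"]
        sup = pd.DataFrame({f"spliced:{t}": [bool(v)] for t, v in zip(tissues, pattern)},
                           index=pd.Index(["g"], name="gene_id"))
        assert ev.expression_breadth(sup, tissues).loc["g"] == expected

    def test_too_few_tissues_rejected(self):
        sup = pd.DataFrame({"spliced:t1": [True]}, index=["g"])
        with pytest.raises(ValueError):
            ev.expression_breadth(sup, ["t1"])

    def test_fixture_breadth_equals_generator_truth(self, noise_free_bundle):
        b = noise_free_bundle
        sup = ev.transcript_overlap(b["genes"], b["evidence"].transcripts)
        tissues = sorted(b["evidence"].transcripts)
        breadth = ev.expression_breadth(sup, tissues)
        for gid, expected in b["evidence"].breadth_truth.items():
            assert breadth.loc[gid] == expected, gid


class TestPeptideSupport:
    def _gene_and_assembly(self):
        # protein: MKTAYIAKQR...
        cds = ("ATG" "AAA" "ACC" "GCT" "TAC" "ATT" "GCA" "AAA" "CAG" "CGT"
               "GGT" "GGT" "TAA")
        gene = GeneModel("g", "s", "+", [(0, len(cds))])
        return [gene], {"s": cds}

    def test_six_mer_exact_substring_supported(self):
        genes, asm = self._gene_and_assembly()
        protein = translate(extract_cds(genes[0], asm["s"]))
        flags, matches = ev.peptide_support([protein[2:8]], genes, asm)
        assert flags["g"] and matches == [(protein[2:8], "g")]

    def test_five_mer_not_counted(self):
        genes, asm = self._gene_and_assembly()
        protein = translate(extract_cds(genes[0], asm["s"]))
        flags, _ = ev.peptide_support([protein[:5]], genes, asm)
        assert not flags["g"]

    def test_one_substitution_breaks_match(self):
        genes, asm = self._gene_and_assembly()
        protein = translate(extract_cds(genes[0], asm["s"]))
        pep = "W" + protein[3:8]
        flags, _ = ev.peptide_support([pep], genes, asm)
        assert not flags["g"]

    def test_bad_symbols_rejected_with_warning(self):
        genes, asm = self._gene_and_assembly()
        with pytest.warns(UserWarning, match="symbols"):
            flags, _ = ev.peptide_support(["MKTA*Y"], genes, asm)
        assert not flags["g"]


class TestHomologOverlap:
    def test_same_strand_one_bp_supported_opposite_not(self, one_gene):
        hit = SplicedAlignment("p1", "s", "+", [(199, 230)],
                               identity=0.8, query_coverage=0.9)
        miss = SplicedAlignment("p2", "s", "-", [(100, 520)],
                                identity=0.8, query_coverage=0.9)
        df = ev.homolog_overlap([one_gene], {"src": [hit]})
        assert df.loc["g1", "homolog"]
        df = ev.homolog_overlap([one_gene], {"src": [miss]})
        assert not df.loc["g1", "homolog"]

    def test_admission_thresholds_applied_when_fields_present(self, one_gene):
        weak = SplicedAlignment("p", "s", "+", [(100, 200)],
                                identity=0.5, query_coverage=0.9)
        unknown = SplicedAlignment("p", "s", "+", [(100, 200)])
        assert not ev.homolog_overlap([one_gene], {"src": [weak]}).loc["g1", "homolog"]
        assert ev.homolog_overlap([one_gene], {"src": [unknown]}).loc["g1", "homolog"]

    def test_fixture_matches_brute_force_intersection_oracle(self, small_bundle):
        b = small_bundle
        df = ev.homolog_overlap(b["genes"], b["evidence"].homologs)
        for g in b["genes"]:
            expected = False
            for src, alns in b["evidence"].homologs.items():
                for a in alns:
                    if a.target != g.scaffold or a.strand != g.strand:
                        continue
                    if a.identity is not None and a.identity < 0.6:
                        continue
                    if a.query_coverage is not None and a.query_coverage < 0.6:
                        continue
                    for bs, be in a.blocks:
                        if any(max(bs, es) < min(be, ee) for es, ee in g.coding_exons):
                            expected = True
            assert df.loc[g.id, "homolog"] == expected, g.id


class TestEvidenceMatrix:
    def _matrix(self, genes, **overrides):
        idx = pd.Index([g.id for g in genes], name="gene_id")
        sup = pd.DataFrame({"spliced:lib": overrides.get("spliced", [False] * len(idx)),
                            "unspliced:lib": overrides.get("unspliced", [False] * len(idx))},
                           index=idx)
        pep = pd.Series(overrides.get("peptide", [False] * len(idx)), index=idx)
        hom = pd.DataFrame({"homolog:src": overrides.get("homolog", [False] * len(idx))},
                           index=idx)
        hom["homolog"] = hom["homolog:src"]
        hom["dmel_homolog"] = False
        cons = pd.DataFrame({"conservation:aflo": overrides.get("aflo", [False] * len(idx))},
                            index=idx)
        return ev.build_evidence_matrix(genes, sup, pep, hom, cons,
                                        overrides.get("domains", []))

    def test_conservation_only_is_support_but_not_gene_evidence(self, one_gene):
        m = self._matrix([one_gene], aflo=[True])
        row = m.table.loc["g1"]
        assert not row["biological_gene_evidence"] and row["any_support"]

    def test_all_false_gives_nothing(self, one_gene):
        row = self._matrix([one_gene]).table.loc["g1"]
        assert not row["biological_gene_evidence"] and not row["any_support"]

    def test_unknown_gene_in_domain_table_warned_and_dropped(self, one_gene):
        with pytest.warns(UserWarning, match="unknown gene"):
            m = self._matrix([one_gene], domains=[("ghost", "IPR000001")])
        assert not m.table.loc["g1", "domain_table"]

    def test_per_class_percentages_match_hand_tally(self):
        genes = [GeneModel(f"g{i}", "s", "+", [(i * 1000, i * 1000 + 300)])
                 for i in range(20)]
        m = self._matrix(genes, peptide=[i < 8 for i in range(20)])
        classes = {f"g{i}": ("TypeI" if i < 5 else "PreviouslyKnown") for i in range(20)}
        out = ev.per_class_counts(m, classes, ["peptide"])
        known = out[(out.gene_class == "PreviouslyKnown")].iloc[0]
        typei = out[(out.gene_class == "TypeI")].iloc[0]
        # hand tally: genes 0..7 have peptides; 0..4 are TypeI
        assert typei["count"] == 5 and typei["total"] == 5 and typei["percent"] == 100.0
        assert known["count"] == 3 and known["total"] == 15 and known["percent"] == 20.0
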