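#!/usr/bin/env python
"""Per-gene evidence tallies: transcript overlap with strand rules,
expression breadth, peptide substring matches, protein-homolog overlap and
cross-genome conservation — aggregated per gene class."""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import RESULTS, study_bundle  # noqa: E402

from ogsdelta import evidence as ev


def main() -> None:
    bundle = study_bundle()
    genes, truth = bundle["genes"], bundle["truth"]
    evid = bundle["evidence"]
    support = ev.transcript_overlap(genes, evid.transcripts)
    breadth = ev.expression_breadth(support, sorted(evid.transcripts))
    pep, matches = ev.peptide_support(evid.peptides, genes, bundle["assembly"])
    hom = ev.homolog_overlap(genes, evid.homologs)
    cons = ev.conservation_table(evid.conservation, genes)
    matrix = ev.build_evidence_matrix(genes, support, pep, hom, cons, evid.domain_table)

    t = matrix.table
    print(f"{len(genes)} genes: {int(t['biological_gene_evidence'].sum())} with "
          f"biological gene evidence, {int(t['any_support'].sum())} with any support "
          f"(incl. conservation); {len(matches)} peptide matches")
    classes = truth.classes("stringent")
    out = ev.per_class_counts(matrix, classes,
                              ["spliced_any", "unspliced_any", "transcript_any",
                               "peptide", "homolog", "dmel_homolog", "domain_table",
                               "conservation:aflo", "conservation:bter",
                               "biological_gene_evidence", "any_support"])
    for feature in ("biological_gene_evidence", "any_support"):
        sub = out[out.feature == feature]
        print(f"  {feature}: " + ", ".join(
            f"{r.gene_class} {r.percent}%" for r in sub.itertuples()))
    out.to_csv(os.path.join(RESULTS, "05_evidence_by_class.tsv"), sep="\t", index=False)
    print(f"wrote {RESULTS}/05_evidence_by_class.tsv")


if __name__ == "__main__":
    main()
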