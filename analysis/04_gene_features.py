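#!/usr/bin/env python
"""Structural and codon-usage features per gene class: CDS length, exon
multiplicity, transcript-supported splice-site canonicality, and Wright's
effective number of codons."""

import os
import sys
from collections import defaultdict

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from common import RESULTS, study_bundle  # noqa: E402

from ogsdelta import features as ft
from ogsdelta.sequtils import extract_cds


def main() -> None:
    bundle = study_bundle()
    genes, truth = bundle["genes"], bundle["truth"]
    classes = truth.classes("stringent")
    metrics = ft.cds_metrics(genes)
    print(f"{len(genes)} genes, total coding {metrics.total_coding_nt:,} nt, "
          f"mean CDS {metrics.mean_length:.0f} nt "
          f"(range {metrics.min_length}-{metrics.max_length})")

    enc_of = {g.id: ft.enc(extract_cds(g, bundle["assembly"][g.scaffold])).nc
              for g in genes}
    spliced = [a for lib in bundle["evidence"].transcripts.values()
               for a in lib if a.spliced]
    _, splice_counts = ft.splice_site_survey(genes, bundle["assembly"], spliced)
    supported = splice_counts["canonical"] + splice_counts["noncanonical"]
    print(f"splice sites: {splice_counts['canonical']}/{supported} canonical "
          f"among transcript-supported introns "
          f"({splice_counts['unsupported']} unsupported excluded)")

    by_class = defaultdict(lambda: defaultdict(list))
    for g in genes:
        cls = classes[g.id]
        by_class[cls]["cds"].append(g.cds_length)
        by_class[cls]["exons"].append(g.n_coding_exons)
        if enc_of[g.id] is not None:
            by_class[cls]["enc"].append(enc_of[g.id])
    rows = []
    for cls, d in sorted(by_class.items()):
        row = {"class": cls, "n_genes": len(d["cds"]),
               "mean_cds_nt": round(float(np.mean(d["cds"])), 1),
               "mean_coding_exons": round(float(np.mean(d["exons"])), 2),
               "pct_single_exon": round(100 * np.mean([e == 1 for e in d["exons"]]), 1),
               "mean_enc": round(float(np.mean(d["enc"])), 2)}
        rows.append(row)
        print(f"  {cls}: CDS {row['mean_cds_nt']} nt, "
              f"{row['mean_coding_exons']} exons, ENC {row['mean_enc']}")
    pd.DataFrame(rows).to_csv(os.path.join(RESULTS, "04_features_by_class.tsv"),
                              sep="\t", index=False)
    n50 = ft.scaffold_n50([len(s) for s in bundle["assembly"].values()])
    print(f"assembly N50: {n50:,} bp")
    print(f"wrote {RESULTS}/04_features_by_class.tsv")


if __name__ == "__main__":
    main()
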