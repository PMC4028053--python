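"""End-to-end pipeline: config in, report bundle out.

The config (YAML or dict) names every input file and the parameters of each
stage; ``run_pipeline`` executes mapping/classification, GC-domain
segmentation, gene features, evidence support and the statistical report in
order, writing every intermediate to the output directory.  Any stage
failure aborts with the stage name; reruns on identical inputs produce
identical bytes.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Any, Optional

import pandas as pd
import yaml

from . import evidence as ev
from . import features as ft
from . import formats, gcdomains, mapping, report as rp
from .models import ClassLabel, GeneModel
from .sequtils import extract_cds

log = logging.getLogger("ogsdelta")


class PipelineError(RuntimeError):
    pass


def _require(path: str, what: str) -> str:
    if not os.path.exists(path):
        raise PipelineError(f"missing {what} file: {path}")
    return path


def load_config(path: str) -> dict:
    with open(_require(path, "config")) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict | str, outdir: Optional[str] = None) -> dict[str, Any]:
    """Run every stage; returns a dict of in-memory results and file paths."""
    if isinstance(config, str):
        config = load_config(config)
    inputs = config["inputs"]
    params = config.get("params", {})
    outdir = outdir or config.get("output_dir") or "ogsdelta_out"
    os.makedirs(outdir, exist_ok=True)
    log.info("pipeline start: outdir=%s", outdir)
    log.info("parameters: %s", json.dumps(params, sort_keys=True, default=str))

    results: dict[str, Any] = {"outdir": outdir}
    stage = "read inputs"
    try:
        new_assembly = formats.read_fasta(_require(inputs["new_assembly"], "new assembly"))
        new_genes = formats.read_gene_set(_require(inputs["new_genes"], "new gene set"))
        old_assembly = formats.read_fasta(_require(inputs["old_assembly"], "old assembly"))
        old_genes = formats.read_gene_set(_require(inputs["old_genes"], "old gene set"))
        transcripts = {
            lib: formats.read_alignments(_require(p, f"transcript library {lib}"))
            for lib, p in sorted(inputs.get("transcripts", {}).items())
        }
        homologs = {
            src: formats.read_alignments(_require(p, f"homolog alignments {src}"))
            for src, p in sorted(inputs.get("homologs", {}).items())
        }
        with open(_require(inputs["peptides"], "peptide list")) as fh:
            peptides = [line.strip() for line in fh if line.strip()]
        cons = pd.read_csv(_require(inputs["conservation"], "conservation table"), sep="\t")
        cons_rows = [(r.gene_id, r.informant, bool(r.supported)) for r in cons.itertuples()]
        dom = pd.read_csv(_require(inputs["domain_table"], "domain table"), sep="\t")
        dom_rows = [(r.gene_id, r.domain_id) for r in dom.itertuples()]

        stage = "mapping and classification"
        mp = params.get("mapping", {})
        cds_seqs = {g.id: extract_cds(g, new_assembly[g.scaffold]) for g in new_genes}
        alignments = mapping.map_cds(cds_seqs, old_assembly)
        labels: dict[str, list[ClassLabel]] = {}
        old_scaffold_set = set(old_assembly)
        for mode, cov_key, default in (("stringent", "stringent_coverage", 0.80),
                                       ("relaxed", "relaxed_coverage", 0.50)):
            p = mapping.MappingParams(min_identity=mp.get("min_identity", 0.95),
                                      min_coverage=mp.get(cov_key, default), mode=mode)
            retained = mapping.filter_alignments(alignments, p)
            labels[mode] = mapping.classify_genes(new_genes, retained, old_genes,
                                                  mode, old_scaffolds=old_scaffold_set)
            _write_labels(labels[mode], os.path.join(outdir, f"class_labels_{mode}.tsv"))

        stage = "GC-domain segmentation"
        sp = params.get("segmentation", {})
        seg_params = gcdomains.SegmentationParams(
            min_scaffold_length=sp.get("min_scaffold_length", 10_000),
            min_domain_length=sp.get("min_domain_length", 3_000),
            significance_alpha=sp.get("alpha", 0.01),
            null_replicates=sp.get("null_replicates", 200),
            seed=sp.get("seed", 0),
        )
        domains = gcdomains.segment_assembly(new_assembly, seg_params)
        domains = gcdomains.domain_noncoding_gc(domains, new_genes, new_assembly)
        weighted_gc = {g.id: gcdomains.gene_weighted_gc(g, domains) for g in new_genes}
        _write_domains(domains, os.path.join(outdir, "domains.bed"))
        _write_gene_gc(weighted_gc, os.path.join(outdir, "gene_gc.tsv"))

        stage = "gene features"
        metrics = ft.cds_metrics(new_genes)
        enc_values = {g.id: ft.enc(cds_seqs[g.id]).nc for g in new_genes}
        all_spliced = [a for alns in transcripts.values() for a in alns if a.spliced]
        splice_records, splice_counts = ft.splice_site_survey(new_genes, new_assembly, all_spliced)
        metrics.per_gene.assign(enc=[enc_values[g] for g in metrics.per_gene["gene_id"]]) \
            .to_csv(os.path.join(outdir, "gene_features.tsv"), sep="\t", index=False)

        stage = "evidence support"
        support = ev.transcript_overlap(new_genes, transcripts)
        tissue_libs = inputs.get("tissue_libraries", sorted(transcripts))
        breadth = ev.expression_breadth(support, tissue_libs)
        pep_flags, pep_matches = ev.peptide_support(peptides, new_genes, new_assembly)
        hom = ev.homolog_overlap(new_genes, homologs,
                                 dmel_source=inputs.get("dmel_source", "dmel"))
        cons_df = ev.conservation_table(cons_rows, new_genes)
        matrix = ev.build_evidence_matrix(new_genes, support, pep_flags, hom,
                                          cons_df, dom_rows)
        matrix.table.to_csv(os.path.join(outdir, "evidence_matrix.tsv"), sep="\t")

        stage = "report"
        gene_table = rp.assemble_gene_table(new_genes, labels["stringent"], matrix,
                                            breadth, weighted_gc, enc_values)
        report_df, comparisons = rp.build_report(gene_table)
        rp.write_report(report_df, os.path.join(outdir, "report.tsv"))
        gene_table.to_csv(os.path.join(outdir, "gene_table.tsv"), sep="\t")
        stats_out = {
            "comparisons": comparisons,
            "splice_site_counts": splice_counts,
            "totals": {
                "n_genes": len(new_genes),
                "total_coding_nt": metrics.total_coding_nt,
                "mean_cds_length": metrics.mean_length,
                "scaffold_n50": ft.scaffold_n50([len(s) for s in new_assembly.values()]),
            },
        }
        with open(os.path.join(outdir, "stats.json"), "w") as fh:
            json.dump(stats_out, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    results.update(
        new_genes=new_genes, old_genes=old_genes, labels=labels,
        alignments=alignments, domains=domains, weighted_gc=weighted_gc,
        metrics=metrics, enc=enc_values, splice_records=splice_records,
        splice_counts=splice_counts, evidence=matrix, breadth=breadth,
        gene_table=gene_table, report=report_df, comparisons=comparisons,
        stats=stats_out,
    )
    log.info("pipeline done: %d genes classified", len(new_genes))
    return results


def _write_labels(labels: list[ClassLabel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tclass\tmode\toverlap_bp\tmulti_overlap\tbest_target\t"
                 "best_identity\tbest_coverage\n")
        for l in sorted(labels, key=lambda l: l.gene_id):
            b = l.best_alignment
            fh.write(f"{l.gene_id}\t{l.gene_class}\t{l.mode}\t{l.overlap_bp}\t"
                     f"{int(l.multi_overlap)}\t{b.target if b else '.'}\t"
                     f"{f'{b.identity:.4f}' if b and b.identity is not None else '.'}\t"
                     f"{f'{b.query_coverage:.4f}' if b and b.query_coverage is not None else '.'}\n")


def _write_domains(domains, path: str) -> None:
    with open(path, "w") as fh:
        for d in domains:
            gc_all = f"{d.gc_all:.4f}" if d.gc_all is not None else "NA"
            gc_nc = f"{d.gc_noncoding:.4f}" if d.gc_noncoding is not None else "NA"
            flags = "gap" if d.gap else ("unsegmented" if not d.segmented else "domain")
            fh.write(f"{d.scaffold}\t{d.start}\t{d.end}\t{flags}\t{gc_all}\t{gc_nc}\t"
                     f"{d.n_noncoding}\n")


def _write_gene_gc(weighted_gc: dict[str, float | None], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tweighted_noncoding_gc\n")
        for gid in sorted(weighted_gc):
            v = weighted_gc[gid]
            fh.write(f"{gid}\t{f'{v:.6f}' if v is not None else 'NA'}\n")


def bundle_config(bundle_paths: dict, outdir: str, seed: int = 0) -> dict:
    """Pipeline config pointing at a simulator bundle's files."""
    return {
        "inputs": {
            "new_assembly": bundle_paths["new_assembly"],
            "new_genes": bundle_paths["new_genes"],
            "old_assembly": bundle_paths["old_assembly"],
            "old_genes": bundle_paths["old_genes"],
            "transcripts": dict(bundle_paths["transcripts"]),
            "tissue_libraries": sorted(bundle_paths["transcripts"]),
            "homologs": dict(bundle_paths["homologs"]),
            "dmel_source": "dmel",
            "peptides": bundle_paths["peptides"],
            "conservation": bundle_paths["conservation"],
            "domain_table": bundle_paths["domain_table"],
        },
        "params": {"segmentation": {"seed": seed}},
        "output_dir": outdir,
    }


def write_config(config: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
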