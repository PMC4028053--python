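"""Shared study conditions for the analysis scripts.

One seeded megabase fixture (10 scaffolds x 100 kb, ~100 genes, bimodal
20%/45% GC, deletions biased 12% vs 2% toward the low-GC domain class)
stands in for the real new/old assembly pair.  Large fixture files go under
scratch/ (regenerated on demand); the scripts write their small result
tables under results/.
"""

from __future__ import annotations

import os

from ogsdelta import simulate as sim
from ogsdelta import pipeline

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
SCRATCH = os.path.join(ROOT, "scratch", "fixture")
RESULTS = os.path.join(ROOT, "results")

GENOME_SPEC = sim.GenomeSimSpec(seed=42, n_scaffolds=10, scaffold_length=100_000,
                                gene_density_per_mb=100)
DEGRADATION_SPEC = sim.DegradationSpec(seed=43)
EVIDENCE_SPEC = sim.EvidenceSimSpec(seed=44)


def study_bundle() -> dict:
    """Generate (or regenerate — it is deterministic) the study fixture."""
    os.makedirs(RESULTS, exist_ok=True)
    return sim.simulate_bundle(GENOME_SPEC, DEGRADATION_SPEC, EVIDENCE_SPEC, SCRATCH)


def study_config(bundle: dict) -> dict:
    return pipeline.bundle_config(bundle["paths"], os.path.join(SCRATCH, "pipeline_out"),
                                  seed=42)
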