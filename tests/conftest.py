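"""Shared fixtures: small seeded synthetic bundles and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from ogsdelta import simulate as sim


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """~50-gene bundle with evidence, written to disk once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    genome_spec = sim.GenomeSimSpec(seed=5, n_scaffolds=5, scaffold_length=80_000,
                                    gene_density_per_mb=130)
    degr_spec = sim.DegradationSpec(seed=6)
    ev_spec = sim.EvidenceSimSpec(seed=7)
    return sim.simulate_bundle(genome_spec, degr_spec, ev_spec, str(outdir))


@pytest.fixture(scope="session")
def noise_free_bundle(tmp_path_factory):
    """Bundle with no antisense noise, used for exact truth-recovery checks."""
    outdir = tmp_path_factory.mktemp("bundle_clean")
    genome_spec = sim.GenomeSimSpec(seed=13, n_scaffolds=4, scaffold_length=75_000,
                                    gene_density_per_mb=120)
    degr_spec = sim.DegradationSpec(seed=14)
    ev_spec = sim.EvidenceSimSpec(seed=15, antisense_noise_rate=0.0)
    return sim.simulate_bundle(genome_spec, degr_spec, ev_spec, str(outdir))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
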