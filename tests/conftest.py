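"""Shared fixtures: one default simulated dataset per session."""

from __future__ import annotations

import json
from pathlib import Path

import pytest

from gcfkit.genome_model import read_genbank
from gcfkit.similarity_gcf import gcf_families
from gcfkit.synthetic_data import (
    default_config,
    export_reference_bundles,
    family_reference_sequences,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """Default study conditions (16 strains, seed 42) simulated once."""
    out = tmp_path_factory.mktemp("sim_default")
    config = default_config(seed=42)
    truth = simulate_dataset(config, out)
    return {"dir": out, "config": config, "truth": truth}


@pytest.fixture(scope="session")
def genomes(sim):
    return [read_genbank(p) for p in sorted(Path(sim["dir"]).glob("*.gbk"))]


@pytest.fixture(scope="session")
def regions(genomes):
    return {r.region_id: r for g in genomes for r in g.regions}


@pytest.fixture(scope="session")
def gcfs(regions):
    return gcf_families(list(regions.values()))


@pytest.fixture(scope="session")
def family_refs(sim):
    return family_reference_sequences(sim["config"])


@pytest.fixture(scope="session")
def reference_bundles(sim, tmp_path_factory):
    out = tmp_path_factory.mktemp("refs")
    return export_reference_bundles(sim["config"], out)
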