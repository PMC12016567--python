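"""Shared fixtures: the default planted scenario is simulated once per
session and reused by the TAD, classifier and acceptance tests."""

from __future__ import annotations

import pytest

from tadrewire.pipeline import PipelineParams, run_pipeline
from tadrewire.simulate import ScenarioSpec, simulate_condition_pair, simulate_regulome


@pytest.fixture(scope="session")
def default_scenario():
    """(spec, cmap1, cmap2, manifest) for the default seeded scenario."""
    spec = ScenarioSpec()
    cmap1, cmap2, manifest = simulate_condition_pair(spec)
    return spec, cmap1, cmap2, manifest


@pytest.fixture(scope="session")
def default_regulome(default_scenario):
    """(ctcf1, ctcf2, atac1, atac2, genes, counts) for the default scenario."""
    spec, _cm1, _cm2, manifest = default_scenario
    return simulate_regulome(spec, manifest)


@pytest.fixture(scope="session")
def default_pipeline_result(default_scenario, default_regulome):
    spec, cmap1, cmap2, _manifest = default_scenario
    return run_pipeline(cmap1, cmap2, *default_regulome, params=PipelineParams())


@pytest.fixture()
def tiny_fasta(tmp_path):
    """Indexed two-record FASTA for GC-content tests."""
    import pyfaidx

    path = tmp_path / "tiny.fa"
    path.write_text(">chrA\nGGCCATGCANGC\n>chrB\nNNNN\n")
    return pyfaidx.Fasta(str(path))
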