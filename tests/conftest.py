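"""Shared fixtures: one small simulated dataset reused across module tests."""

from __future__ import annotations

import pytest

from ieskit import genome_io, simulate


@pytest.fixture(scope="session")
def small_config() -> simulate.SimulationConfig:
    return simulate.SimulationConfig(
        seed=42,
        n_scaffolds=2,
        scaffold_len=25000,
        n_ies=80,
        n_identical_pairs=4,
        coverage=25,
        retention=simulate.RetentionModel(kind="uniform"),
        srna=simulate.SrnaModel(n_scn=8000, n_ies_reads=4000),
    )


@pytest.fixture(scope="session")
def small_sim(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    return simulate.simulate_to_dir(small_config, out)


@pytest.fixture(scope="session")
def small_mic_alignments(small_sim):
    records, _report = genome_io.filter_unique_pairs(
        genome_io.read_sam(small_sim["paths"]["dna_mic_sam"])
    )
    return records
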