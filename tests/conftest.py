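"""Shared fixtures: the worked-example toy and synthetic studies.

Everything is generated programmatically at test time; session scope keeps
the larger simulations to one run each.
"""

from __future__ import annotations

import io

import pytest

from splicecons import read_maf
from splicecons.simulate import SimulationConfig, figure1_fixture, simulate_study


@pytest.fixture(scope="session")
def fig1():
    return figure1_fixture()


@pytest.fixture(scope="session")
def fig1_map(fig1):
    return read_maf(io.StringIO(fig1.maf_text), "hg")


@pytest.fixture(scope="session")
def small_cfg():
    """A tiny study: 6 genomes, 12 genes; fast enough for oracle tests."""
    return SimulationConfig(
        seed=42,
        m=6,
        n_genes=12,
        exons_per_gene=4,
        exon_len=(40, 80),
        intron_len=(120, 200),
        n_random_transcripts=40,
        random_exon_len=(10, 20),
        random_intron_len=(50, 100),
        intergenic_len=120,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_study")
    return simulate_study(small_cfg, out)


@pytest.fixture(scope="session")
def small_map(small_study, small_cfg):
    return read_maf(small_study.maf_path, small_cfg.reference_id)


@pytest.fixture(scope="session")
def std_cfg():
    """The standard study conditions (defaults of the generator)."""
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def std_study(std_cfg, tmp_path_factory):
    out = tmp_path_factory.mktemp("std_study")
    return simulate_study(std_cfg, out)


@pytest.fixture(scope="session")
def std_map(std_study, std_cfg):
    return read_maf(std_study.maf_path, std_cfg.reference_id)


@pytest.fixture(scope="session")
def std_realign(std_study, std_map):
    """Full realignment pass over the standard study (merged map w')."""
    from splicecons.catalogs import unique_exons
    from splicecons.realign import realign_missing_exons

    exons = unique_exons([std_study.mane, std_study.extra, std_study.random])
    return realign_missing_exons(exons, std_map, std_study.genomes)
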