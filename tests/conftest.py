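"""Shared fixtures: a small genome for unit tests and the standard-scale
simulations (built once per session) used by the end-to-end checks."""

from __future__ import annotations

import dataclasses

import pandas as pd
import pytest
from hypothesis import settings

from nanotiming.rt_profile import RTProfile, compute_profile
from nanotiming.simulate import SimConfig, build_genome, simulate_population_reads

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

# fixed, arbitrary seeds for the standard-condition session simulations
GENOME_SEED = 11
SIM_SEED = 12
REPLICATE_SEED = 13


@pytest.fixture(scope="session")
def small_genome():
    """2 x 300 kb toy genome: fast, with all subtelomere features present."""
    cfg = SimConfig(n_chrom=2, chrom_length=300_000, n_reads=800, seed=5)
    return build_genome(cfg, 5)


@pytest.fixture(scope="session")
def small_sim(small_genome):
    return simulate_population_reads(
        small_genome, 7, keep_records=True, with_sequence=True, store_site_truth=True
    )


@pytest.fixture(scope="session")
def default_genome():
    """The standard study conditions: 12 Mb over 4 chromosomes, B = 5 uM."""
    return build_genome(SimConfig(seed=GENOME_SEED), GENOME_SEED)


@pytest.fixture(scope="session")
def default_sim(default_genome):
    return simulate_population_reads(default_genome, SIM_SEED)


@pytest.fixture(scope="session")
def replicate_sim(default_genome):
    return simulate_population_reads(default_genome, REPLICATE_SEED)


@pytest.fixture(scope="session")
def high_dose_sim(default_genome):
    """Same genome and ground truth, labelled at 1 mM instead of 5 uM."""
    cfg = dataclasses.replace(default_genome.config, brdu_dose=1000.0)
    genome = dataclasses.replace(default_genome, config=cfg)
    return simulate_population_reads(genome, SIM_SEED)


@pytest.fixture(scope="session")
def default_profile(default_genome, default_sim) -> RTProfile:
    return compute_profile(default_sim.tracks, default_genome.annotation.chrom_lengths)


def profile_truth_table(profile: RTProfile, genome) -> pd.DataFrame:
    """Join a profile with the simulator's per-bin replication-time truth."""
    truth = genome.truth_bins.set_index(["chrom", "start"])
    return profile.data.set_index(["chrom", "start"]).join(truth, how="inner").reset_index()
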