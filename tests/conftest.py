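import numpy as np
import pandas as pd
import pytest

from dnamod.config import (ChipConfig, DipConfig, KineticsConfig,
                           RnaseqConfig, SimConfig, TandemRepeatConfig,
                           TEFamilyConfig)
from dnamod.core import AnnotatedGenome, ReadSet
from dnamod.sim import plant_methylome, simulate_genome


def small_config(seed: int = 7) -> SimConfig:
    """A fast desk-top configuration used across the unit tests."""
    return SimConfig(
        seed=seed,
        genome_length=60000,
        n_contigs=2,
        n_genes=8,
        te_families=[TEFamilyConfig("Gypsy", 2000, 2, 2, 4)],
        tandem_repeats=TandemRepeatConfig(n_arrays=2),
        kinetics=KineticsConfig(n_background_sites=2000),
        dip=DipConfig(library_size=8000),
        chip=ChipConfig(library_size=8000),
        rnaseq=RnaseqConfig(library_size=20000),
    )


@pytest.fixture(scope="session")
def config():
    return small_config()


@pytest.fixture(scope="session")
def genome(config):
    return simulate_genome(config)


@pytest.fixture(scope="session")
def methylome(genome, config):
    return plant_methylome(genome, config)


@pytest.fixture
def toy_genome():
    """A tiny fixed two-contig genome for hand-checkable oracles."""
    return AnnotatedGenome(
        contigs={"c1": "ACGTACGTCGCGATTAGGCAATCGGA" * 10,
                 "c2": "TTTTACGCGCATGCAGGAACCGTAGA" * 10},
        genes=[], te_copies=[], tandem_repeats=[])


def make_reads(rows, assay="test") -> ReadSet:
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "strand"])
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return ReadSet(assay, df)
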