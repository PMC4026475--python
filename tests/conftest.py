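from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from numtscan import SimulationConfig, simulate_dataset
from numtscan.known_structures import KNOWN_ROWS
from numtscan.motifs import reconstruct_from_structure


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated dataset in the study regime, shared across tests."""
    return simulate_dataset(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def table_reconstructions():
    """Sequences reconstructed from every published size-class structure."""
    return {(r.individual, r.size_class): reconstruct_from_structure(r.structure) for r in KNOWN_ROWS}


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture()
def random_dna_factory(rng):
    return lambda n: random_dna(rng, n)
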