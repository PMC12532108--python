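import numpy as np
import pytest

import chromarch as ca
from chromarch import simulate as sim


@pytest.fixture(scope="session")
def genome():
    return sim.default_genome()


@pytest.fixture(scope="session")
def bins(genome):
    return ca.make_bins(genome)


@pytest.fixture(scope="session")
def truth(bins):
    return sim.plant_states(bins, seed=1)


def simulate_normalized(genome, bins, truth, params):
    mat = sim.simulate_contact_map(genome, bins, truth, params)
    ca.normalize(mat)
    return mat


@pytest.fixture(scope="session")
def null_matrix(genome, bins, truth):
    """All-structure-off simulation at 1e7 contacts, normalized."""
    return simulate_normalized(genome, bins, truth, sim.preset("null", seed=1))


@pytest.fixture(scope="session")
def compartment_matrix(genome, bins, truth):
    """Planted 5-state map (epsilon=0.8, no spatial architecture)."""
    from dataclasses import replace
    p = replace(sim.preset("null", seed=1), epsilon=0.8)
    return simulate_normalized(genome, bins, truth, p)


@pytest.fixture(scope="session")
def tracks(bins, truth):
    return sim.simulate_tracks(bins, truth, snr=3.0, seed=11)


@pytest.fixture()
def small_genome():
    """Single metacentric chromosome of 8 bins (arms of 4)."""
    return ca.GenomeSpec(
        chrom_names=("chrA",),
        chrom_lengths=(800_000,),
        centromeres=((350_000, 450_000),),
        bin_size=100_000,
    )
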