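from types import SimpleNamespace

import pytest

from pirnakit import (
    ConsensusSet,
    SimulatorConfig,
    build_index,
    map_library,
    random_consensus,
    simulate_primary,
    simulate_secondary,
)


@pytest.fixture(scope="session")
def consensus5k():
    """5-kb random transposon consensus at 50% GC."""
    return random_consensus(5000, 0.5, seed=101)


@pytest.fixture(scope="session")
def sim(consensus5k):
    """A moderately sized simulated ping-pong pair, mapped, shared across tests."""
    primary_cfg = SimulatorConfig(n_reads=2000, seed=102, p_1U=0.8)
    primary, primary_truth = simulate_primary(consensus5k, primary_cfg)
    secondary_cfg = SimulatorConfig(n_reads=2000, seed=103, p_1U=0.8)
    secondary, secondary_truth = simulate_secondary(primary_truth, consensus5k, secondary_cfg)
    cset = ConsensusSet(entries=(consensus5k,))
    index = build_index(cset, k=16)
    return SimpleNamespace(
        consensus=consensus5k,
        consensus_set=cset,
        index=index,
        primary=primary,
        primary_truth=primary_truth,
        primary_cfg=primary_cfg,
        secondary=secondary,
        secondary_truth=secondary_truth,
        mapped_primary=map_library(index, primary),
        mapped_secondary=map_library(index, secondary),
    )
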