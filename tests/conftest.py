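import numpy as np
import pytest
from hypothesis import settings

from horscan.monomers import ConsensusMonomer, default_consensus
from horscan.seqio import GenomeSequence
from horscan.synth import random_dna

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def consensus() -> ConsensusMonomer:
    return default_consensus()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(171)


def mutate(seq: str, positions, rng=None, offset=1) -> str:
    """Substitute bases at the given 0-based positions (deterministic shift)."""
    order = "ACGT"
    out = list(seq)
    for p in positions:
        out[p] = order[(order.index(out[p]) + offset) % 4]
    return "".join(out)


@pytest.fixture()
def tandem_sequence(consensus):
    """Builder: flank + n exact/mutated consensus copies + flank."""

    def build(n_copies=10, flank=500, mutated_positions=None, seed=5, name="synthetic"):
        r = np.random.default_rng(seed)
        copies = []
        for i in range(n_copies):
            s = consensus.sequence
            if mutated_positions and i in mutated_positions:
                s = mutate(s, mutated_positions[i])
            copies.append(s)
        return GenomeSequence(
            name=name,
            bases=random_dna(flank, r) + "".join(copies) + random_dna(flank, r),
        )

    return build
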