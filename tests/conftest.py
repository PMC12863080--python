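import pytest

from synbreak.synthetic_data import SynthParams, make_species


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic species with random rearrangements (fixed seed)."""
    return make_species(
        SynthParams(seed=11, n_genomes=6, C=60, genome_length_bp=200_000,
                    with_sequences=False)
    )


@pytest.fixture(scope="session")
def quiet_bundle():
    """A species with no rearrangements at all."""
    return make_species(
        SynthParams(seed=5, n_genomes=5, C=40, rearr_per_branch=0.0,
                    genome_length_bp=150_000, with_sequences=False)
    )
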