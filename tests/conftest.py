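import pytest

from dmgfinder.config import BadgeConfig
from dmgfinder.synthgen import SynthSpec, generate_dataset


def small_spec(seed: int = 42, **overrides) -> SynthSpec:
    """A compact fixture spec: every decoy class planted, genomes small
    enough that the exact DP oracle can align ORFs against whole contigs."""
    kwargs = dict(
        n_core=6,
        genome_len=14_000,
        plasmid_len=10_000,
        gene_len=(500, 800),
        seed=seed,
    )
    kwargs.update(overrides)
    return SynthSpec(**kwargs)


@pytest.fixture(scope="session")
def small_fixture():
    spec = small_spec()
    group_a, group_b, truth = generate_dataset(spec)
    return spec, group_a, group_b, truth


@pytest.fixture()
def default_cfg():
    return BadgeConfig()
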