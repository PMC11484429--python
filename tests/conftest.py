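import numpy as np
import pytest

from hapasm import simforge as sf


def plain_repeats() -> sf.RepeatConfig:
    """Repeat-free backbone configuration."""
    return sf.RepeatConfig(
        n_homopolymers=0, n_tandem=0, n_dispersed_copies=0, segdup_len=0
    )


@pytest.fixture(scope="session")
def plain_guide() -> sf.GuideHaplotype:
    """A 20 kb repeat-free guide haplotype."""
    guides, _ = sf.make_guide_set(
        7, 20_000, [sf.ClassSpec("SHORT")], repeat_config=plain_repeats()
    )
    return guides[0]


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
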