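import numpy as np
import pytest

from rindvirome.synthetic import CommunityDesign, GuildSpec, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One full simulated study shared by the read-only tests."""
    return simulate_study(seed=7)


@pytest.fixture(scope="session")
def small_design():
    """A reduced community for fast sequence-level tests."""
    return CommunityDesign(
        guilds=[
            GuildSpec("stable", 6, "stable", 0.5, host_genus="Lactococcus", phage_group="936"),
            GuildSpec("declining", 4, "declining", 0.3, rate=0.5,
                      host_genus="Lactococcus", phage_group="P335"),
            GuildSpec("rising", 4, "rising", 0.15, rate=16.0,
                      host_genus="Glutamicibacter", phage_group="Montesquieu"),
        ],
        length_range=(2_000, 12_000),
        n_outgroups=3,
        n_chimeras=2,
        n_fragments=2,
        n_nonviral=3,
        seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
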