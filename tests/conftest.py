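import numpy as np
import pytest

from crowdsim.conformity import ConformityConfig
from crowdsim.contagion import ContagionConfig
from crowdsim.networks import ScoreFieldConfig, SmallWorldConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_conformity_config():
    """A fast configuration for dynamics tests: 60 agents, short horizon."""

    def make(rewiring_prob=0.1, seed=0, **kw):
        return ConformityConfig(
            network_config=SmallWorldConfig(
                n_nodes=60, degree=6, rewiring_prob=rewiring_prob
            ),
            score_field_config=ScoreFieldConfig(n_nodes=60, smoothness=6, **kw.pop("score_kw", {})),
            periods_per_agent=200,
            stall_periods_per_agent=50,
            seed=seed,
            **kw,
        )

    return make


@pytest.fixture
def small_contagion_config():
    """A fast contagion configuration: 100 individuals, short horizon."""

    def make(seed=0, **kw):
        kw.setdefault("periods_per_capita", 60)
        return ContagionConfig(
            n_population=100,
            n_susceptible=20,
            n_infected_initial=4,
            seed=seed,
            **kw,
        )

    return make
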