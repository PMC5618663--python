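import numpy as np
import pytest

import rsfpkit as rk


@pytest.fixture
def noiseless_truth():
    """Default ground truth with all noise sources disabled."""

    def make(seed: int = 0, **popdyn_overrides) -> rk.GroundTruth:
        base = rk.default_truth(seed, noise=rk.NoiseModel.noiseless())
        if popdyn_overrides:
            pop = rk.PopulationDynamicsParams(**{**base.popdyn.to_dict(), **popdyn_overrides})
            base = rk.GroundTruth(kinetics=base.kinetics, popdyn=pop, noise=base.noise, seed=seed)
        return base

    return make


@pytest.fixture
def short_protocol():
    return rk.SwitchingProtocol.hela_default(n_cycles=20)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
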