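import numpy as np
import pytest

import flowvasc as fv


def circ_diff(a, b):
    """Smallest signed angular difference a - b."""
    return np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b))))


@pytest.fixture(scope="session")
def monolayer_clean():
    """A noiseless monolayer with known ratio and moderate alignment."""
    params = fv.MonolayerParams(n_cells=150, kappa=2.0, noise_sd=0.0,
                                markers={"psmad159": 2.5}, seed=11)
    return fv.gen_monolayer(params)


@pytest.fixture(scope="session")
def vessel_fixture():
    params = fv.VesselFixtureParams(stages=("final", "final", "final",
                                            "intermediate"), seed=5)
    return fv.gen_vessel_fixture(params)


@pytest.fixture(scope="session")
def retina_beta25():
    params = fv.RetinaParams(
        n_cells=2000,
        components=(fv.RetinaComponent(1.0, phi_beta=(2.0, 5.0)),),
        seed=3)
    return fv.gen_retina(params)
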