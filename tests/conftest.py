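import numpy as np
import pytest

from jawdx.phantoms import PhantomSpec, render_phantom


@pytest.fixture(scope="session")
def tiny_spec():
    return PhantomSpec.tiny(seed=0)


@pytest.fixture(scope="session")
def lesion_sample(tiny_spec):
    return render_phantom("DC", np.random.default_rng(7), tiny_spec, "DC_fix")


@pytest.fixture(scope="session")
def healthy_sample(tiny_spec):
    return render_phantom("healthy", np.random.default_rng(8), tiny_spec,
                          "healthy_fix")
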