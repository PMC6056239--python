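import numpy as np
import pytest

from formincg import enm, pipeline, synth


@pytest.fixture(scope="session")
def bent_rod():
    return synth.make_bent_rod_template(20)


@pytest.fixture(scope="session")
def ideal_seven_mer(bent_rod):
    geom = synth.HelixGeometry(twist_deg=167.0)
    return synth.build_ideal_filament(bent_rod, 7, geom)


@pytest.fixture(scope="session")
def demo_complex():
    return pipeline.build_demo_complex()


@pytest.fixture(scope="session")
def lattice_network():
    """30-site connected heterogeneous network with known spring constants."""
    coords = synth.make_lattice_sites(dims=(3, 2, 5), spacing=8.0, jitter=1.0, seed=0)
    net = enm.build_network(coords, 12.0)
    rng = np.random.default_rng(1)
    net.k = rng.uniform(1.0, 10.0, net.n_bonds)
    return net
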