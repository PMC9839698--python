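import numpy as np
import pytest

from statemap.synthetic_data import BundleSpec, make_two_state_bundle


@pytest.fixture
def two_helix_bundle():
    """Two-helix bundle with helix 2 shifted 3 Å along the inter-axis line
    in the inactive state: plants several active-unique pairs."""
    spec = BundleSpec(
        n_helices=2, residues_per_helix=8,
        axis_positions=[(0.0, 0.0), (7.5, 0.0)],
        state_shift=[(0.0, 0.0, 0.0), (3.0, 0.0, 0.0)],
        seed=7,
    )
    return make_two_state_bundle(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
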