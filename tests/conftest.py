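import numpy as np
import pytest

from cervimetry.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def straight_phantom():
    """Straight 35 mm tube, no cysts/bladder: the fully analytic base case."""
    spec = PhantomSpec(
        canal_length=35.0,
        bend_angle=0.0,
        inlet_diameter=8.0,
        outlet_diameter=8.0,
        n_cysts=0,
        include_bladder=False,
        seed=1,
    )
    return spec, *generate_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom():
    """Full-featured phantom: bend, taper, cysts, bladder."""
    spec = PhantomSpec(seed=3)
    return spec, *generate_phantom(spec)


@pytest.fixture(scope="session")
def bent_phantom():
    spec = PhantomSpec(
        canal_length=35.0,
        bend_angle=30.0,
        n_cysts=0,
        include_bladder=False,
        seed=7,
    )
    return spec, *generate_phantom(spec)
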