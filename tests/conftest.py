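import numpy as np
import pytest

import doseforge as df


@pytest.fixture(scope="session")
def gyn_case():
    """One deterministic GYN-like phantom: single 4500 cGy target, four OARs."""
    return df.make_phantom(df.gyn_spec(seed=7))


@pytest.fixture(scope="session")
def hn_case():
    """One deterministic HN-like phantom: three nested targets, eight OARs."""
    return df.make_phantom(df.hn_spec(seed=7))


@pytest.fixture(scope="session")
def cohort20():
    """The standard 20-phantom experiment cohort (fixed seed)."""
    return df.default_cohort(n=20, seed=11)


@pytest.fixture
def two_sphere():
    """A tiny two-sphere geometry: target at centre, OAR offset in +x."""
    spec = df.PhantomSpec(
        grid_shape=(24, 40, 40),
        spacing=(2.5, 2.0, 2.0),
        body_semi_axes_mm=(27.0, 36.0, 36.0),
        targets=[df.TargetSpec("ptv", (0.0, 0.0, 0.0), 10.0, 4500.0)],
        oars=[df.OarSpec("oar", (0.0, 0.0, 22.0), (6.0, 6.0, 6.0))],
        noise_sd=0.0,
        seed=1,
    )
    return df.make_phantom(spec)
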