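import pytest

from kkpolar import Conditions, LayerGeometry, get_preset, random_instance


@pytest.fixture(scope="session")
def glucose():
    return get_preset("nephrophan-glucose")


@pytest.fixture(scope="session")
def ethanol():
    return get_preset("nephrophan-ethanol")


@pytest.fixture(scope="session")
def geometry():
    """Symmetric mid-range boundary layers."""
    return LayerGeometry(5e-4, 5e-4)


@pytest.fixture(scope="session")
def osmotic_conditions():
    """Strong osmotic gradient, no hydrostatic force."""
    return Conditions(C_l=1.0, C_h=50.0, dP=0.0, T=295.0)


@pytest.fixture(scope="session")
def mixed_conditions():
    """Osmotic and hydrostatic forces together."""
    return Conditions(C_l=5.0, C_h=40.0, dP=800.0, T=295.0)


def instances(n, start=0):
    """Seeded random parameter bundles around the presets."""
    return [random_instance(seed) for seed in range(start, start + n)]
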