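import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ironrelax as ir

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def magnet() -> ir.MagneticParams:
    return ir.MagneticParams()


@pytest.fixture(scope="session")
def dilute_iron_map() -> ir.IronMap3D:
    """Dilute sphere phantom with many perturbers and fixed concentration."""
    spec = ir.PhantomSpec(
        grid_shape=(96, 96, 96),
        zeta_nm=0.02,
        sphere_radius_range=(3.0, 6.0),
        c_nm_mean=387.0,
        c_nm_sd=0.0,
        c_ft=56.0,
        seed=2,
    )
    return ir.generate_neuron_phantom(spec)


@pytest.fixture(scope="session")
def dilute_field(dilute_iron_map, magnet) -> ir.FrequencyMap:
    chi = ir.susceptibility_from_iron(dilute_iron_map, magnet)
    return ir.larmor_shift_map(chi, magnet, padding=2)


@pytest.fixture(scope="session")
def nigrosome_field(magnet) -> ir.FrequencyMap:
    """Sample-1-like phantom field at a test-friendly 64^3 size."""
    spec = ir.PhantomSpec(
        grid_shape=(64, 64, 64),
        zeta_nm=0.02,
        sphere_radius_range=(4.0, 8.0),
        c_nm_mean=387.0,
        c_nm_sd=150.0,
        c_ft=56.0,
        seed=5,
    )
    iron = ir.generate_neuron_phantom(spec)
    chi = ir.susceptibility_from_iron(iron, magnet)
    return ir.larmor_shift_map(chi, magnet, padding=2)


@pytest.fixture(scope="session")
def ge_echoes() -> np.ndarray:
    return np.asarray(ir.GE_ECHO_TIMES_S)
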