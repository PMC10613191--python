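import numpy as np
import pytest

from osteoadapt import defaults
from osteoadapt.constitutive import ModuliSet
from osteoadapt.fem import build_mesh


@pytest.fixture(scope="session")
def reference_moduli() -> ModuliSet:
    """The printed trabecular-bone parameter set (moduli in Pa, 1.5 N
    second-gradient stiffnesses)."""
    return ModuliSet.from_gpa(
        defaults.REFERENCE_MODULI_GPA, defaults.SECOND_GRADIENT_STIFFNESS_N
    )


@pytest.fixture(scope="session")
def isotropic_moduli() -> ModuliSet:
    return ModuliSet(
        K=10e9, mu=5e9, alpha1=0.0, alpha2=0.0, mu1=0.0, mu2=0.0,
        beta1=0.0, beta2=0.0, beta3=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def coarse_mesh():
    """Small specimen-shaped mesh shared by cheap assembly tests."""
    return build_mesh(0.075, 0.025, 6, 2)


def random_strain(rng: np.random.Generator, scale: float = 1e-3, shape=()) -> np.ndarray:
    a = rng.normal(scale=scale, size=shape + (2, 2))
    return 0.5 * (a + np.swapaxes(a, -1, -2))


def random_hessian(rng: np.random.Generator, scale: float = 1e2, shape=()) -> np.ndarray:
    h = rng.normal(scale=scale, size=shape + (2, 2, 2))
    return 0.5 * (h + np.swapaxes(h, -1, -2))
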