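import numpy as np
import pytest

from defocim import ImagingSystem

# Study conditions used throughout: green illumination, NA 0.05, 100 mm
# object distance, unit magnification.
LAMBDA = 500e-9
NA0 = 0.05
O_DIST = 100e-3


@pytest.fixture(scope="session")
def reference() -> ImagingSystem:
    """Reference Gaussian-apodized system (lambda=500 nm, NA0=0.05, o=100 mm)."""
    return ImagingSystem.from_na(LAMBDA, NA0, O_DIST, 1.0)


@pytest.fixture(scope="session")
def scaled_reference() -> ImagingSystem:
    """Same NA and wavelength, ten-fold geometry: deep sigma_l >> sigma0 regime."""
    return ImagingSystem.from_na(LAMBDA, NA0, 10 * O_DIST, 1.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(987654321)


def rel_l2(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (non-scale-fitted) relative L2 distance between arrays."""
    return float(np.linalg.norm(np.asarray(a) - np.asarray(b)) / np.linalg.norm(a))


def random_real_object(rng: np.random.Generator, nu: float, order: int):
    """Random Hermitian-coefficient (real-valued) periodic transmittance."""
    from defocim import FourierObject

    coeffs = {0: complex(rng.uniform(0.4, 0.6))}
    for n in range(1, order + 1):
        c = complex(rng.normal(0, 0.1), rng.normal(0, 0.1))
        coeffs[n] = c
        coeffs[-n] = c.conjugate()
    budget = 1.0 - coeffs[0].real
    total = sum(abs(c) for n, c in coeffs.items() if n != 0)
    if total > budget:  # keep |A| <= 1 (passive transmittance)
        scale = 0.95 * budget / total
        coeffs = {n: (c * scale if n != 0 else c) for n, c in coeffs.items()}
    return FourierObject(nu, coeffs)
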