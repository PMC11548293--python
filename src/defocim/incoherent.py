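"""Closed-form incoherent (intensity) imaging of periodic objects.

Incoherent image formation is linear in the sample intensity: each harmonic
of ``|A|^2`` is attenuated by the modulation transfer function (MTF), a
Gaussian low-pass filter whose width grows with defocus through the circle
of confusion.  Image coordinates scale with the defocused magnification
``M(delta)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .objects import FourierObject
from .optics import DefocusState, ImagingSystem, incoherent_transfer
from .oracle import ImageProfile

__all__ = [
    "MtfValue",
    "DofResult",
    "UnresolvableError",
    "mtf",
    "cutoff",
    "image_periodic",
    "image_sinusoid",
    "dof",
    "mtf_table",
    "write_mtf_csv",
    "write_profile_csv",
]


class UnresolvableError(ValueError):
    """The requested frequency is beyond the focused system's capability."""


@dataclass(frozen=True)
class MtfValue:
    """One MTF sample: attenuation of frequency ``nu`` at defocus ``delta``."""

    nu: float
    delta: float
    value: float


@dataclass(frozen=True)
class DofResult:
    """Symmetric depth-of-field interval ``[-delta_max, +delta_max]``.

    ``tolerance`` is the accepted harmonic distortion ``c`` in (0, 1);
    ``modality`` records which imaging mode the bound describes.
    """

    nu: float
    tolerance: float
    delta_max: float
    modality: str

    @property
    def interval(self) -> tuple[float, float]:
        return (-self.delta_max, self.delta_max)


def mtf(state: DefocusState, nu: float) -> float:
    """Gaussian incoherent MTF ``exp(-2 pi^2 sigma_inc(delta)^2 nu^2)``.

    Uses the conventional Airy-plus-CoC width ``sigma_inc``; unity at zero
    frequency, strictly decreasing in ``nu``.
    """
    if nu < 0:
        raise ValueError("nu must be non-negative")
    return math.exp(-2.0 * math.pi**2 * state.sigma_inc**2 * nu**2)


def cutoff(state: DefocusState) -> float:
    """1/e^2 cut-off frequency ``1 / (pi sigma_inc(delta))`` in cycles/m.

    At focus this is ``2 NA0 / (sqrt(pi) lambda)``; for defocus-dominated
    states it falls off as ``1 / (NA delta)`` -- halving the aperture
    doubles the defocused cut-off.
    """
    return 1.0 / (math.pi * state.sigma_inc)


def image_periodic(
    state: DefocusState,
    obj_intensity: FourierObject,
    grid,
    transfer: str = "green",
) -> ImageProfile:
    """Incoherent image of a periodic intensity pattern.

    ``obj_intensity`` is the Fourier series of the sample *intensity*
    ``|A|^2`` (real, non-negative mean); the image keeps the same harmonic
    content with each coefficient multiplied by the transfer function at
    ``n nu`` and coordinates magnified by ``M(delta)``.

    ``transfer="green"`` uses the exact Fourier transform of the
    Green's-function PSF; ``"model"`` uses the conventional
    ``exp(-2 pi^2 sigma_inc^2 nu^2)`` parameterization (identical at focus).
    """
    if not obj_intensity.is_real:
        raise ValueError("intensity series must be real (Hermitian coefficients)")
    dc = obj_intensity.coeffs.get(0, 0j)
    if dc.real < 0:
        raise ValueError("intensity series has negative mean")
    x = np.asarray(grid, dtype=float)
    M = state.magnification
    out = np.zeros(x.shape, dtype=complex)
    for n, c in obj_intensity.coeffs.items():
        t = incoherent_transfer(state, abs(n) * obj_intensity.nu, kind=transfer)
        out += c * t * np.exp(2j * np.pi * n * obj_intensity.nu * x / M)
    return ImageProfile(
        x, np.maximum(out.real, 0.0), M,
        {"delta": state.delta, "nu": obj_intensity.nu, "mode": "incoherent"},
    )


def image_sinusoid(state: DefocusState, nu: float, grid) -> ImageProfile:
    """Closed-form incoherent sinusoid image, exactly as conventionally printed:

    ``I(x) = (1/2) [1 - exp(-2 pi^2 (sigma0(delta)^2 + sigma_coc^2) nu^2)
    cos(4 pi nu x / M(delta))]``

    Note the attenuation argument is ``nu`` while the spatial modulation is
    at ``2 nu``; for arbitrary objects :func:`image_periodic` applied to the
    ``|A|^2`` series is the self-consistent reference.
    """
    if nu <= 0:
        raise ValueError("nu must be positive")
    x = np.asarray(grid, dtype=float)
    M = state.magnification
    I = 0.5 * (1.0 - mtf(state, nu) * np.cos(4.0 * np.pi * nu * x / M))
    return ImageProfile(x, I, M, {"delta": state.delta, "nu": nu,
                                  "mode": "incoherent-sinusoid"})


def dof(
    system: ImagingSystem,
    nu: float,
    c: float,
    include_airy: bool = True,
) -> DofResult:
    """Incoherent depth of field at attenuation tolerance ``c``.

    Largest ``delta`` with ``MTF(delta, nu) >= 1 - c``, solved by bracketing
    bisection with the aperture ``NA(delta)`` treated self-consistently.
    With ``include_airy=False`` only the circle-of-confusion term is kept --
    the defocus-dominated asymptotic law ``delta_max ~ 1/(NA nu)``.

    Raises
    ------
    UnresolvableError
        when the frequency is already attenuated beyond tolerance at focus
        (only possible with the Airy term included).
    """
    if not 0.0 < c < 1.0:
        raise ValueError("tolerance c must lie in (0, 1)")
    if nu <= 0:
        raise ValueError("nu must be positive")
    target = 1.0 - c

    def attenuation(delta: float) -> float:
        st = DefocusState(system, delta)
        s2 = st.sigma_inc**2 if include_airy else st.sigma_coc**2
        return math.exp(-2.0 * math.pi**2 * s2 * nu**2)

    if include_airy and attenuation(0.0) < target:
        raise UnresolvableError(
            f"nu = {nu:.4g} cycles/m unresolvable at focus for c = {c}"
        )
    hi = 10.0 * system.object_distance
    if attenuation(hi) >= target:
        return DofResult(nu, c, math.inf, "incoherent")
    delta_max = brentq(lambda d: attenuation(d) - target, 0.0, hi, xtol=1e-9)
    return DofResult(nu, c, float(delta_max), "incoherent")


# ---------------------------------------------------------------------------
# tables / CSV writers (boundary units: mm, cycles/mm)


def mtf_table(
    system: ImagingSystem,
    nus: Sequence[float],
    deltas: Sequence[float],
) -> pd.DataFrame:
    """MTF samples as a tidy table (SI inputs, mm-based columns)."""
    rows = [
        {
            "nu_cycles_per_mm": nu * 1e-3,
            "delta_mm": d * 1e3,
            "mtf": mtf(DefocusState(system, d), nu),
        }
        for d in deltas
        for nu in nus
    ]
    return pd.DataFrame(rows)


def write_mtf_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_profile_csv(profile: ImageProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"x_mm": profile.x * 1e3, "intensity": profile.intensity}
    ).to_csv(path, index=False)
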