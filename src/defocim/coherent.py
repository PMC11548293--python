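"""Coherent imaging of periodic objects under defocus.

Under spatially coherent plane-wave illumination the image is the squared
modulus of the field amplitude

    U(x) = sum_n a_n phi0(n nu) exp(-i pi lambda delta n^2 nu^2)
                 exp(i 2 pi n nu x / M0),

so defocus multiplies each field harmonic by a *pure phase* quadratic in the
harmonic order (the Fresnel chirp over the defocus distance) while the
attenuation ``phi0`` is that of the *focused* system only: the circle of
confusion never enters.  Squaring doubles the harmonic content (an order-N
field yields intensity harmonics up to 2N), and the chirp phase makes the
intensity pattern periodic in ``delta`` with the self-imaging (Talbot-like)
period ``2 / (lambda nu^2)``:

* ``delta = 2m / (lambda nu^2)``          -- perfect imaging (revival),
* ``delta = (2m+1) / (lambda nu^2)``      -- image shifted by half a period,
* ``delta = (m + 1/2) / (lambda nu^2)``   -- fundamental suppressed entirely.

None of these positions depend on the numerical aperture, which is the root
of the NA-independent square-root depth-of-field law implemented in
:func:`dof_coherent`.

Coordinates of coherent closed forms are referred to the *native*
magnification ``M0`` (the focused conjugate plane), not ``M(delta)``.
Global intensity scales are non-physical throughout; compare profiles with
:func:`defocim.oracle.compare_normalized`.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .incoherent import DofResult
from .objects import FourierObject, make_sinusoid
from .optics import DefocusState, ImagingSystem
from .oracle import ImageProfile

__all__ = [
    "PupilSpectrum",
    "CoherentCoeffs",
    "GaussianCoherentParams",
    "gaussian_pupil_spectrum",
    "coherent_coeffs",
    "harmonic_response",
    "coherent_image",
    "image_sinusoid_ideal",
    "image_sinusoid_generic",
    "image_sinusoid_gaussian",
    "image_sinusoid_central",
    "mtf_proxies",
    "MtfTriple",
    "SpecialPlane",
    "special_planes",
    "dof_coherent",
]


@dataclass(frozen=True)
class PupilSpectrum:
    """Coherent transfer function ``phi0(nu)`` of the focused system.

    ``phi0`` is the Fourier transform of the focused Green's function with
    its weak image-coordinate dependence dropped.  For a real point response
    ``phi0(-nu) = conj(phi0(nu))``.
    """

    phi0: Callable[[float], complex]

    def __call__(self, nu: float) -> complex:
        return complex(self.phi0(nu))

    def phase(self, nu: float) -> float:
        """``arg phi0(nu)``."""
        return cmath.phase(self(nu))

    def normalized(self, nu: float) -> complex:
        """``phi0(nu) / phi0(0)``; unit value at zero frequency."""
        return self(nu) / self(0.0)

    @classmethod
    def ideal(cls) -> "PupilSpectrum":
        """Infinite-aperture limit: ``phi0(nu) = 1`` for every frequency."""
        return cls(lambda nu: 1.0 + 0j)


def gaussian_pupil_spectrum(system: ImagingSystem) -> PupilSpectrum:
    """Analytic ``phi0`` of the Gaussian-apodized focused system.

    With the on-axis kernel ``exp(-(p - i a) x0^2)`` (``p = 1/(4 sigma0^2)``,
    ``a = k/(2 o)``) the transform is

        phi0(nu) = sqrt(pi / (p - i a)) exp(-pi^2 nu^2 / (p - i a)),

    whose normalized modulus is ``exp(-4 pi^2 sigma0^2 nu^2)`` up to the tiny
    ``(a/p)^2`` quadratic-phase correction.
    """
    c = complex(system._p, -system._a)

    def phi0(nu: float) -> complex:
        return cmath.sqrt(math.pi / c) * cmath.exp(-(math.pi * nu) ** 2 / c)

    return PupilSpectrum(phi0)


# ---------------------------------------------------------------------------
# Fourier-coefficient transform (the defocus chirp)


@dataclass(frozen=True)
class CoherentCoeffs:
    """Intensity Fourier series of a coherent image at one defocus.

    Coefficients ``a'_n(delta)`` for ``|n| <= 2N``; Hermitian, so the
    reconstructed intensity is real.
    """

    delta: float
    nu: float
    coeffs: Mapping[int, complex]
    magnification: float = 1.0

    def evaluate(self, grid) -> np.ndarray:
        """Reconstruct the (real) intensity on a detector grid (m)."""
        x = np.asarray(grid, dtype=float)
        out = np.zeros(x.shape, dtype=complex)
        for n, c in self.coeffs.items():
            out += c * np.exp(2j * np.pi * n * self.nu * x / self.magnification)
        return out.real


def _field_harmonics(
    obj: FourierObject, state: DefocusState, pupil: PupilSpectrum
) -> dict[int, complex]:
    """Amplitude harmonics ``a_m phi0(m nu) exp(-i pi lambda delta m^2 nu^2)``."""
    lam = state.system.wavelength
    chirp = math.pi * lam * state.delta * obj.nu**2
    return {
        m: a * pupil.normalized(m * obj.nu) * cmath.exp(-1j * chirp * m**2)
        for m, a in obj.coeffs.items()
    }


def coherent_coeffs(
    obj: FourierObject, state: DefocusState, pupil: PupilSpectrum
) -> CoherentCoeffs:
    """Defocus-transformed intensity coefficients of a coherent image.

    Expands ``|U(x)|^2`` of the chirped field series: the output coefficient
    is the autocorrelation of the chirped amplitude harmonics,

        a'_n = sum_m c_m conj(c_{m-n}),
        c_m  = a_m phi0(m nu)/phi0(0) exp(-i pi lambda delta m^2 nu^2).

    At focus with the ideal pupil this is exactly the Fourier series of
    ``|A|^2``.  The moduli of the extreme coefficients ``|a'_{+-2N}|`` are
    independent of defocus, and every attenuation factor involves only the
    focused pupil.
    """
    c = _field_harmonics(obj, state, pupil)
    out: dict[int, complex] = {}
    for m1, v1 in c.items():
        for m2, v2 in c.items():
            n = m1 - m2
            out[n] = out.get(n, 0j) + v1 * v2.conjugate()
    return CoherentCoeffs(state.delta, obj.nu, out, state.system.magnification)


# ---------------------------------------------------------------------------
# exact Gaussian closed forms


def harmonic_response(state: DefocusState, nu_signed: float, x) -> np.ndarray:
    """Closed-form response ``G(x)`` to the field harmonic ``e^{i 2 pi nu x_s}``.

    The Gaussian integral of the plane wave against the defocused kernel:

        G(x) = prefactor * exp(env2 X^2 - (g X + i kappa)^2 / (4 A)),
        X = x / M0,  kappa = 2 pi nu.

    Exact for the Gaussian-apodized system at any defocus (focused branch
    included); the full image-coordinate dependence of the pupil -- envelope,
    frequency pulling and cosh/sinh edge modulation -- is retained.
    """
    kc = state._kernel
    kappa = 2.0 * math.pi * nu_signed
    X = np.asarray(x, dtype=float) / state.system.magnification
    B = kc.g * X + 1j * kappa
    return kc.prefactor * np.exp(kc.env2 * X**2 - B**2 / (4.0 * kc.A))


def coherent_image(obj: FourierObject, state: DefocusState, grid) -> ImageProfile:
    """Exact coherent image of a periodic object through the Gaussian system.

    ``I(x) = | sum_n a_n G_{n nu}(x) |^2`` with :func:`harmonic_response`;
    no central-field-of-view or infinite-aperture approximation.  The global
    scale carries the (non-physical) propagator prefactor.
    """
    x = np.asarray(grid, dtype=float)
    U = np.zeros(x.shape, dtype=complex)
    for n, a in obj.coeffs.items():
        U += a * harmonic_response(state, n * obj.nu, x)
    return ImageProfile(
        x, np.abs(U) ** 2, state.system.magnification,
        {"delta": state.delta, "nu": obj.nu, "mode": "coherent"},
    )


def image_sinusoid_gaussian(state: DefocusState, nu: float, grid) -> ImageProfile:
    """Full Gaussian-system coherent image of the sinusoid ``sin^2(pi nu x)``.

    The image is no longer periodic: it sits under the finite field-of-view
    envelope set by the lens, with slightly pulled fringe frequency and
    hyperbolic edge modulation (see :class:`GaussianCoherentParams`).
    """
    return coherent_image(make_sinusoid(nu), state, grid)


@dataclass(frozen=True)
class GaussianCoherentParams:
    """Central-field-of-view parameters of the Gaussian coherent image.

    Extracted from the exact harmonic response: near the middle of the FoV
    the fundamental intensity harmonic behaves as

        -2 c1 cos(pi lambda nu^2 (delta + delta0)) cos(2 pi nu' x / M0)

    modulated by ``cosh/sinh(2 pi nu'' x / M0)`` edge terms, and the second
    harmonic carries the defocus-independent weight ``c0^2 / 2``.

    In imaging conditions (``sigma_l >> sigma0``): ``nu' -> nu``,
    ``delta0 -> 0``, ``nu'' << nu`` and ``c0 -> exp(-4 pi^2 sigma0^2 nu^2)``.
    """

    c0: float
    c1: float
    nu_prime: float
    nu_second: float
    delta0: float

    @classmethod
    def from_state(cls, state: DefocusState, nu: float) -> "GaussianCoherentParams":
        kc = state._kernel
        kappa = 2.0 * math.pi * nu
        lam = state.system.wavelength
        atten = cmath.exp(kappa**2 / (4.0 * kc.A))
        c0 = c1 = abs(atten)
        # fringe factor exp(w X) with w = -i g kappa / (2 A)
        w = -1j * kc.g * kappa / (2.0 * kc.A)
        nu_prime = abs(w.imag) / (2.0 * math.pi)
        nu_second = abs(w.real) / (2.0 * math.pi)
        phase = cmath.phase(atten)
        delta0 = -phase / (math.pi * lam * nu**2) - state.delta
        return cls(c0, c1, nu_prime, nu_second, delta0)


# ---------------------------------------------------------------------------
# sinusoid closed forms in the ideal / generic-pupil / central approximations


def image_sinusoid_ideal(delta: float, nu: float, wavelength: float, grid) -> ImageProfile:
    """Infinite-aperture coherent image of the sinusoid.

    ``I(x) = 3/2 - 2 cos(pi lambda delta nu^2) cos(2 pi nu x)
    + (1/2) cos(4 pi nu x)``; at focus this is ``4 sin^4(pi nu x)``.
    Coordinates are object-referred (detector coordinate divided by M0).
    """
    x = np.asarray(grid, dtype=float)
    theta = math.pi * wavelength * delta * nu**2
    I = (
        1.5
        - 2.0 * math.cos(theta) * np.cos(2.0 * np.pi * nu * x)
        + 0.5 * np.cos(4.0 * np.pi * nu * x)
    )
    return ImageProfile(x, np.maximum(I, 0.0), 1.0,
                        {"delta": delta, "nu": nu, "mode": "coherent-ideal"})


def image_sinusoid_generic(
    pupil: PupilSpectrum, delta: float, nu: float, wavelength: float, grid
) -> ImageProfile:
    """Coherent sinusoid image for an arbitrary focused pupil ``phi0``.

    Derived by expanding the chirped field series of the sinusoid:

        I = 1 + t^2/2 + (t^2/2) cos(4 pi nu x + 2 phi_nu)
              - 2 t cos(pi lambda delta nu^2 + phi_0) cos(2 pi nu x + phi_nu)

    with ``t = |phi0(nu)/phi0(0)|``, ``phi_nu = arg phi0(nu) - arg phi0(0)``
    and ``phi_0 = 0`` entering through the pupil's zero-frequency phase.
    Reduces exactly to :func:`image_sinusoid_ideal` for the ideal pupil.
    """
    x = np.asarray(grid, dtype=float)
    t = abs(pupil.normalized(nu))
    phi_nu = cmath.phase(pupil.normalized(nu))
    theta = math.pi * wavelength * delta * nu**2
    I = (
        1.0
        + 0.5 * t**2
        + 0.5 * t**2 * np.cos(4.0 * np.pi * nu * x + 2.0 * phi_nu)
        - 2.0 * t * math.cos(theta) * np.cos(2.0 * np.pi * nu * x + phi_nu)
    )
    return ImageProfile(x, np.maximum(I, 0.0), 1.0,
                        {"delta": delta, "nu": nu, "mode": "coherent-generic"})


def image_sinusoid_central(state: DefocusState, nu: float, grid) -> ImageProfile:
    """Central-FoV approximation of the Gaussian coherent sinusoid image.

    ``I(x) = 1 + (1/2) e^{-8 pi^2 sigma0^2 nu^2} (1 + cos(4 pi nu x / M0))
    - 2 e^{-4 pi^2 sigma0^2 nu^2} cos(pi lambda nu^2 delta)
    cos(2 pi nu x / M0)``

    Valid near the middle of the field of view with ``sigma_l >> sigma0``;
    as ``sigma0 -> 0`` it reproduces the infinite-aperture expression.
    Coordinates scale with the native magnification ``M0``, not ``M(delta)``.
    """
    sys_ = state.system
    x = np.asarray(grid, dtype=float) / sys_.magnification
    u = 4.0 * math.pi**2 * sys_.sigma0**2 * nu**2
    theta = math.pi * sys_.wavelength * nu**2 * state.delta
    I = (
        1.0
        + 0.5 * math.exp(-2.0 * u) * (1.0 + np.cos(4.0 * np.pi * nu * x))
        - 2.0 * math.exp(-u) * math.cos(theta) * np.cos(2.0 * np.pi * nu * x)
    )
    return ImageProfile(np.asarray(grid, dtype=float), np.maximum(I, 0.0),
                        sys_.magnification,
                        {"delta": state.delta, "nu": nu, "mode": "coherent-central"})


# ---------------------------------------------------------------------------
# MTF proxies, self-imaging planes, depth of field


class MtfTriple(tuple):
    """(incoherent MTF, coherent fundamental proxy, coherent second-harmonic proxy)."""

    __slots__ = ()

    def __new__(cls, incoherent, fundamental, second):
        return super().__new__(cls, (incoherent, fundamental, second))

    incoherent = property(lambda self: self[0])
    fundamental = property(lambda self: self[1])
    second = property(lambda self: self[2])


def mtf_proxies(state: DefocusState, nu: float) -> MtfTriple:
    """The incoherent MTF and the two coherent MTF proxies at ``(delta, nu)``.

    * ``MTF_inc = exp(-2 pi^2 (sigma0(delta)^2 + sigma_coc^2) nu^2)``
    * ``MTF_coh1 = -MTF_inc(0, nu)^2 cos(pi lambda nu^2 delta)`` -- the
      fundamental-frequency coefficient; oscillates in defocus and can be
      negative, with zeros independent of NA.
    * ``MTF_coh2 = MTF_inc(0, nu)^4`` -- the second-harmonic coefficient;
      independent of defocus altogether.
    """
    sys_ = state.system
    inc = math.exp(-2.0 * math.pi**2 * state.sigma_inc**2 * nu**2)
    env = math.exp(-4.0 * math.pi**2 * sys_.sigma0**2 * nu**2)
    theta = math.pi * sys_.wavelength * nu**2 * state.delta
    return MtfTriple(inc, -env * math.cos(theta), env**2)


@dataclass(frozen=True)
class SpecialPlane:
    delta: float
    kind: str  # perfect | shifted | suppressed


def special_planes(
    nu: float, wavelength: float, delta_range: tuple[float, float]
) -> list[SpecialPlane]:
    """Enumerate the self-imaging planes inside ``delta_range`` (m).

    With the axial unit ``L = 1 / (lambda nu^2)``: perfect imaging at even
    multiples of ``L``, half-period-shifted copies at odd multiples, and
    fundamental-suppressed planes at half-integer multiples.
    """
    if nu <= 0:
        raise ValueError("nu must be positive")
    lo, hi = delta_range
    if hi < lo:
        raise ValueError("empty delta range")
    L = 1.0 / (wavelength * nu**2)
    out: list[SpecialPlane] = []
    for kind, offset, step in (
        ("perfect", 0.0, 2.0 * L),
        ("shifted", L, 2.0 * L),
        ("suppressed", 0.5 * L, L),
    ):
        m_lo = math.ceil((lo - offset) / step - 1e-12)
        m_hi = math.floor((hi - offset) / step + 1e-12)
        for m in range(m_lo, m_hi + 1):
            out.append(SpecialPlane(offset + m * step, kind))
    out.sort(key=lambda sp: (sp.delta, sp.kind))
    return out


def dof_coherent(nu: float, wavelength: float, c: float) -> DofResult:
    """NA-independent coherent depth of field at harmonic-distortion tolerance ``c``.

    The only defocus dependence of the central coherent image is the factor
    ``cos(pi lambda nu^2 delta)``; requiring it within ``c`` of its focused
    value gives ``delta_max = arccos(1 - c) / (pi lambda nu^2)``, i.e. a
    tolerable defocus scaling as ``nu^-2`` (resolution ``1/sqrt(lambda
    delta)``) with no aperture dependence at all.
    """
    if not 0.0 < c < 1.0:
        raise ValueError("tolerance c must lie in (0, 1)")
    if nu <= 0:
        raise ValueError("nu must be positive")
    delta_max = math.acos(1.0 - c) / (math.pi * wavelength * nu**2)
    return DofResult(nu=nu, tolerance=c, delta_max=delta_max, modality="coherent")
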