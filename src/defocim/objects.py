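"""Periodic field-transmittance objects as truncated Fourier series.

A sample is described by its complex field transmittance
``A(x_s) = sum_n a_n exp(i 2 pi n nu x_s)`` with fundamental frequency
``nu`` (cycles/m) and sparse integer-indexed coefficients.  Coherent imaging
responds to ``A`` itself; incoherent imaging responds to ``|A|^2``, whose
Fourier series (:func:`square_series`) is the coefficient autocorrelation
and extends to twice the harmonic order of the field.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "FourierObject",
    "make_sinusoid",
    "square_series",
    "evaluate_field",
    "object_to_json",
    "object_from_json",
]

_HERMITIAN_TOL = 1e-12


@dataclass(frozen=True)
class FourierObject:
    """Periodic complex transmittance with fundamental ``nu`` (cycles/m).

    ``coeffs`` maps the harmonic index ``n`` to the complex coefficient
    ``a_n``; missing indices are zero.  Transmittances are dimensionless and
    no absorption bound is enforced (a peak modulus above one only triggers
    a warning, since the imaging math is linear in the field).
    """

    nu: float
    coeffs: Mapping[int, complex] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValueError("fundamental frequency nu must be positive")
        clean = {int(n): complex(c) for n, c in self.coeffs.items() if c != 0}
        object.__setattr__(self, "coeffs", clean)
        peak = np.abs(self.evaluate(np.arange(256) / (256 * self.nu))).max() if clean else 0.0
        if peak > 1.0 + 1e-9:
            warnings.warn(
                f"peak |A| = {peak:.3g} > 1: not a passive transmittance",
                stacklevel=2,
            )

    @property
    def order(self) -> int:
        """Highest harmonic order ``N`` present."""
        return max((abs(n) for n in self.coeffs), default=0)

    @property
    def is_real(self) -> bool:
        """True when the coefficients are Hermitian (real-valued field)."""
        return all(
            abs(c - self.coeffs.get(-n, 0j).conjugate()) <= _HERMITIAN_TOL * max(1.0, abs(c))
            for n, c in self.coeffs.items()
        )

    def evaluate(self, grid) -> np.ndarray:
        """Evaluate ``A(x)`` on a grid of positions (m); complex output."""
        x = np.asarray(grid, dtype=float)
        out = np.zeros(x.shape, dtype=complex)
        for n, c in self.coeffs.items():
            out += c * np.exp(2j * np.pi * n * self.nu * x)
        return out

    def squared(self) -> "FourierObject":
        """Fourier series of the intensity ``|A|^2`` (order doubles)."""
        out: dict[int, complex] = {}
        items = list(self.coeffs.items())
        for n1, c1 in items:
            for n2, c2 in items:
                n = n1 - n2
                out[n] = out.get(n, 0j) + c1 * c2.conjugate()
        return FourierObject(self.nu, out)


def make_sinusoid(nu: float) -> FourierObject:
    """The simplest non-phase periodic sample: ``S(x) = sin^2(pi nu x)``.

    Equivalently ``(1 - cos(2 pi nu x)) / 2``, i.e. coefficients
    ``a0 = 1/2``, ``a(+-1) = -1/4``.
    """
    return FourierObject(nu, {0: 0.5, 1: -0.25, -1: -0.25})


def square_series(obj: FourierObject) -> FourierObject:
    """Functional alias for :meth:`FourierObject.squared`."""
    return obj.squared()


def evaluate_field(obj: FourierObject, grid) -> np.ndarray:
    """Functional alias for :meth:`FourierObject.evaluate`."""
    return obj.evaluate(grid)


# ---------------------------------------------------------------------------
# JSON interchange (boundary units: cycles/mm)


def object_to_json(obj: FourierObject, path: str | Path | None = None) -> str:
    """Serialize to ``{"nu_cycles_per_mm": ..., "coeffs": [[n, re, im], ...]}``."""
    doc = {
        "nu_cycles_per_mm": obj.nu * 1e-3,
        "coeffs": [[n, c.real, c.imag] for n, c in sorted(obj.coeffs.items())],
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def object_from_json(source: str | Path) -> FourierObject:
    """Load an object spec written by :func:`object_to_json`."""
    p = Path(source)
    text = p.read_text() if p.exists() else str(source)
    doc = json.loads(text)
    coeffs = {int(n): complex(re, im) for n, re, im in doc["coeffs"]}
    return FourierObject(doc["nu_cycles_per_mm"] * 1e3, coeffs)
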