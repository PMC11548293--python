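"""Coherent defocus transform: chirped coefficients, self-imaging, DOF."""

import cmath
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from defocim import (
    GaussianCoherentParams,
    ImagingSystem,
    PupilSpectrum,
    coherent_coeffs,
    coherent_image,
    compare_normalized,
    dof,
    dof_coherent,
    extract_harmonics,
    gaussian_pupil_spectrum,
    harmonic_response,
    image_sinusoid_central,
    image_sinusoid_gaussian,
    image_sinusoid_generic,
    image_sinusoid_ideal,
    make_sinusoid,
    mtf_proxies,
    special_planes,
)
from defocim.oracle import ImageProfile

from conftest import LAMBDA, NA0, O_DIST, random_real_object

NU = 20e3
TALBOT = 2.0 / (LAMBDA * NU**2)  # 10 mm at 20 cycles/mm, 500 nm


class TestPupilSpectrum:
    def test_ideal_is_unity(self):
        pupil = PupilSpectrum.ideal()
        for nu in (0.0, 1e4, -3e5):
            assert pupil(nu) == 1.0
            assert pupil.phase(nu) == 0.0

    def test_gaussian_matches_numerical_transform(self, reference):
        from defocim import focused_green

        pupil = gaussian_pupil_spectrum(reference)
        t, w = np.polynomial.legendre.leggauss(600)
        half = 12 * reference.sigma0
        x0 = half * t
        kernel = focused_green(reference, x0, 0.0)
        for nu in (0.0, 20e3, 80e3, -50e3):
            quad = half * (w * kernel * np.exp(-2j * np.pi * nu * x0)).sum()
            assert abs(pupil(nu) - quad) / abs(quad) <= 1e-8

    def test_even_bounded_and_near_real(self, reference):
        """phi0 depends on nu only through nu^2; its phase is the tiny
        focused-system quadratic-phase residue, so Hermitian symmetry
        phi0(-nu) = conj(phi0(nu)) holds to the size of that residue."""
        pupil = gaussian_pupil_spectrum(reference)
        for nu in (5e3, 40e3, 111e3):
            assert pupil(-nu) == pupil(nu)
            ratio = pupil.normalized(nu)
            assert abs(ratio) <= 1.0
            assert abs(cmath.phase(ratio)) <= 1e-2
        assert pupil.normalized(0.0) == 1.0


class TestCoherentCoeffs:
    def test_focus_ideal_equals_intensity_series(self):
        obj = make_sinusoid(NU)
        system = ImagingSystem.from_na(LAMBDA, NA0, O_DIST)
        cc = coherent_coeffs(obj, system.at(0.0), PupilSpectrum.ideal())
        expected = obj.squared().coeffs
        assert set(cc.coeffs) == set(expected)
        for n, v in expected.items():
            assert cc.coeffs[n] == pytest.approx(v, abs=1e-15)

    def test_extreme_coefficient_defocus_invariant(self, reference):
        obj = make_sinusoid(NU)
        mags = [
            abs(coherent_coeffs(obj, reference.at(d), PupilSpectrum.ideal()).coeffs[2])
            for d in (0.0, 0.7e-3, 2.5e-3, -4e-3)
        ]
        assert np.ptp(mags) <= 1e-15

    def test_attenuation_uses_focused_pupil_only(self, reference, rng):
        """|a'_n| must not change with defocus when the pupil is held fixed."""
        obj = random_real_object(rng, NU, 2)
        pupil = gaussian_pupil_spectrum(reference)
        mags = {}
        for d in (0.0, 1e-3, 3.3e-3):
            cc = coherent_coeffs(obj, reference.at(d), pupil)
            mags[d] = abs(cc.coeffs[2 * obj.order])
        vals = list(mags.values())
        assert np.ptp(vals) <= 1e-12 * max(vals)

    def test_reconstruction_identity(self, reference, rng):
        """The 2N-order series reproduces |chirped field series|^2 pointwise."""
        obj = random_real_object(rng, NU, 3)
        state = reference.at(1.7e-3)
        pupil = gaussian_pupil_spectrum(reference)
        cc = coherent_coeffs(obj, state, pupil)
        x = np.linspace(-2e-4, 2e-4, 257)
        lhs = cc.evaluate(x)
        chirp = math.pi * LAMBDA * state.delta * NU**2
        U = np.zeros(x.size, dtype=complex)
        for m, a in obj.coeffs.items():
            U += (
                a
                * pupil.normalized(m * NU)
                * cmath.exp(-1j * chirp * m**2)
                * np.exp(2j * np.pi * m * NU * x)
            )
        assert np.allclose(lhs, np.abs(U) ** 2, atol=1e-12)

    @settings(deadline=None, max_examples=12)
    @given(order=st.integers(1, 4), seed=st.integers(0, 2**31 - 1))
    def test_harmonic_content_doubles_exactly(self, order, seed):
        rng = np.random.default_rng(seed)
        obj = random_real_object(rng, NU, order)
        system = ImagingSystem.from_na(LAMBDA, NA0, O_DIST)
        cc = coherent_coeffs(obj, system.at(1.3e-3), PupilSpectrum.ideal())
        assert max(abs(n) for n in cc.coeffs) == 2 * order
        assert abs(cc.coeffs[2 * order]) > 1e-12


class TestIdealImage:
    def test_focus_is_sin4(self):
        x = np.linspace(0, 2 / NU, 101)
        img = image_sinusoid_ideal(0.0, NU, LAMBDA, x)
        assert np.allclose(img.intensity, 4 * np.sin(np.pi * NU * x) ** 4, atol=1e-12)
        assert img.intensity[0] == pytest.approx(0.0, abs=1e-14)
        at_half = image_sinusoid_ideal(0.0, NU, LAMBDA, [1 / (2 * NU)]).intensity[0]
        assert at_half == pytest.approx(4.0)

    def test_suppressed_plane(self):
        """At delta = 1/(2 lambda nu^2) the fundamental vanishes entirely."""
        x = np.linspace(-2 / NU, 2 / NU, 400)
        img = image_sinusoid_ideal(2.5e-3, NU, LAMBDA, x)
        expected = 1.5 + 0.5 * np.cos(4 * np.pi * NU * x)
        assert np.allclose(img.intensity, expected, atol=1e-12)
        coeffs = extract_harmonics(img, NU, 1.0, n_max=2)
        assert abs(coeffs[1]) <= 1e-10

    def test_talbot_revival(self):
        x = np.linspace(-1e-4, 1e-4, 211)
        a = image_sinusoid_ideal(0.0, NU, LAMBDA, x)
        b = image_sinusoid_ideal(TALBOT, NU, LAMBDA, x)
        assert np.allclose(a.intensity, b.intensity, atol=1e-12)

    def test_half_period_shift_plane(self):
        x = np.linspace(-1e-4, 1e-4, 211)
        shifted = image_sinusoid_ideal(TALBOT / 2, NU, LAMBDA, x)
        moved = image_sinusoid_ideal(0.0, NU, LAMBDA, x + 1 / (2 * NU))
        assert np.allclose(shifted.intensity, moved.intensity, atol=1e-12)

    @pytest.mark.parametrize("delta", [0.4e-3, -1.9e-3])
    def test_axial_periodicity(self, delta):
        x = np.linspace(-1e-4, 1e-4, 151)
        a = image_sinusoid_ideal(delta, NU, LAMBDA, x)
        b = image_sinusoid_ideal(delta + TALBOT, NU, LAMBDA, x)
        assert np.allclose(a.intensity, b.intensity, atol=1e-12)


class TestGenericImage:
    def test_ideal_pupil_reduction(self):
        x = np.linspace(-1e-4, 1e-4, 101)
        for delta in (0.0, 1.2e-3):
            a = image_sinusoid_generic(PupilSpectrum.ideal(), delta, NU, LAMBDA, x)
            b = image_sinusoid_ideal(delta, NU, LAMBDA, x)
            assert np.allclose(a.intensity, b.intensity, atol=1e-12)

    def test_gaussian_pupil_low_frequency_focus(self, reference):
        nu = 1e3
        pupil = gaussian_pupil_spectrum(reference)
        x = np.linspace(-1.5 / nu, 1.5 / nu, 400)
        img = image_sinusoid_generic(pupil, 0.0, nu, LAMBDA, x)
        target = ImageProfile(x, 4 * np.sin(np.pi * nu * x) ** 4, 1.0)
        assert compare_normalized(img, target) <= 1e-3

    def test_second_harmonic_weight(self, reference):
        """Second harmonic carries |phi0(nu)|^2/|phi0(0)|^2 / 4, at any defocus."""
        pupil = gaussian_pupil_spectrum(reference)
        t2 = abs(pupil.normalized(NU)) ** 2
        x = np.linspace(-3 / NU, 3 / NU, 1200)
        for delta in (0.0, 0.9e-3, 2.5e-3):
            img = image_sinusoid_generic(pupil, delta, NU, LAMBDA, x)
            coeffs = extract_harmonics(img, NU, 1.0, n_max=2)
            assert abs(coeffs[2]) == pytest.approx(t2 / 4, rel=1e-9)


class TestGaussianImage:
    def test_matches_central_form_in_wide_pupil_regime(self, scaled_reference):
        for d in (0.0, 1e-3, 3e-3):
            state = scaled_reference.at(d)
            x = np.linspace(-1.5 / NU, 1.5 / NU, 301)
            assert compare_normalized(
                image_sinusoid_gaussian(state, NU, x),
                image_sinusoid_central(state, NU, x),
            ) <= 1e-3

    def test_envelope_tracks_lens_width(self, reference):
        """The FoV envelope of the exact image is set by the pupil geometry."""
        state = reference.at(0.0)
        env = np.abs(harmonic_response(state, 0.0, np.linspace(0, 6e-3, 40))) ** 2
        # exact envelope: intensity sigma = sigma_l / sqrt(2 pi) for p >> a
        sig_env = reference.pupil_width / math.sqrt(2 * math.pi)
        x = np.linspace(0, 6e-3, 40)
        assert np.allclose(env / env[0], np.exp(-(x**2) / sig_env**2), rtol=1e-3)

    def test_general_object_matches_oracle(self, reference, rng):
        from defocim import sample_object, simulate

        obj = random_real_object(rng, NU, 2)
        state = reference.at(1e-3)
        x = np.linspace(-1.5 / NU, 1.5 / NU, 201)
        closed = coherent_image(obj, state, x)
        oracle = simulate(state, sample_object(obj, state, x, "coherent"),
                          "coherent", x)
        assert compare_normalized(oracle, closed) <= 1e-4


class TestCentralImage:
    def test_reference_fundamental_weight(self, reference):
        """-2 e^{-4 pi^2 sigma0^2 nu^2} cos(pi lambda nu^2 delta) at 1 mm, 20/mm."""
        state = reference.at(1e-3)
        x = -3 / NU + np.arange(1200) * (6 / NU / 1200)  # integer periods
        img = image_sinusoid_central(state, NU, x)
        coeffs = extract_harmonics(img, NU, 1.0, n_max=2)
        # -2 exp(-0.125664) cos(0.2 pi) = -1.42696
        assert 2 * coeffs[1].real == pytest.approx(-1.426963, rel=1e-5)

    def test_native_magnification_convention(self):
        """Central coherent fringes scale with M0, not M(delta)."""
        system = ImagingSystem.from_na(LAMBDA, NA0, O_DIST, magnification=2.0)
        state = system.at(2e-3)
        dx = 2.5e-7
        x = np.arange(1200) * dx
        img = image_sinusoid_central(state, NU, x)
        idx = int(round(2.0 / NU / dx))  # one full period M0/nu = 100 um
        assert np.allclose(img.intensity[idx:], img.intensity[:-idx], atol=1e-9)
        bad = int(round(state.magnification / NU / dx))  # M(delta)-referred period
        assert not np.allclose(img.intensity[bad:], img.intensity[:-bad], atol=1e-3)

    def test_infinite_aperture_limit(self):
        """sigma0 -> 0 reproduces the ideal-pupil expression pointwise."""
        nu = 1e3
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # enormous NA, deliberately
            tiny_sigma = ImagingSystem.from_na(
                LAMBDA, LAMBDA / (2 * math.sqrt(math.pi) * 1e-9), O_DIST
            )
        assert tiny_sigma.sigma0 == pytest.approx(1e-9)
        x = np.linspace(-2 / nu, 2 / nu, 500)
        for delta in (0.0, 1e-3):
            a = image_sinusoid_central(tiny_sigma.at(delta), nu, x)
            b = image_sinusoid_ideal(delta, nu, LAMBDA, x)
            assert np.max(np.abs(a.intensity - b.intensity)) <= 1e-9


class TestGaussianCoherentParams:
    def test_wide_pupil_limits(self, scaled_reference):
        p = GaussianCoherentParams.from_state(scaled_reference.at(1e-3), NU)
        assert p.nu_prime == pytest.approx(NU, rel=1e-6)
        assert p.nu_second / NU <= 1e-3
        assert abs(p.delta0) <= 1e-6
        assert p.c0 == pytest.approx(
            math.exp(-4 * math.pi**2 * scaled_reference.sigma0**2 * NU**2), rel=1e-6
        )

    def test_attenuation_defocus_invariant(self, reference):
        c0s = [GaussianCoherentParams.from_state(reference.at(d), NU).c0
               for d in (0.5e-3, 1e-3, 3e-3)]
        assert np.ptp(c0s) <= 1e-6 * c0s[0]


class TestMtfProxies:
    def test_zero_frequency(self, reference):
        trip = mtf_proxies(reference.at(1e-3), 0.0)
        assert trip == (1.0, -1.0, 1.0)

    def test_reference_values(self, reference):
        trip = mtf_proxies(reference.at(0.0), 10e3)
        assert trip.fundamental == pytest.approx(-0.969072, rel=1e-5)
        assert trip.second == pytest.approx(0.939101, rel=1e-5)

    def test_second_proxy_defocus_independent(self, reference):
        vals = [mtf_proxies(reference.at(d), 15e3).second for d in (0, 1e-3, 5e-3)]
        assert np.ptp(vals) == 0.0

    def test_fundamental_zeros_na_independent(self):
        """Zeros in defocus sit at (m+1/2)/(lambda nu^2) for any aperture."""
        nu = 15e3
        for na in (0.05, 0.025):
            system = ImagingSystem.from_na(LAMBDA, na, O_DIST)

            def f(d):
                return mtf_proxies(system.at(d), nu).fundamental

            zero = brentq(f, 0.1e-3, 8e-3, xtol=1e-15)
            assert zero == pytest.approx(0.5 / (LAMBDA * nu**2), rel=1e-12)


class TestSpecialPlanes:
    def test_reference_enumeration(self):
        planes = special_planes(NU, LAMBDA, (-7e-3, 7e-3))
        by_kind = {k: sorted(p.delta for p in planes if p.kind == k)
                   for k in ("perfect", "shifted", "suppressed")}
        assert by_kind["perfect"] == pytest.approx([0.0])
        assert by_kind["shifted"] == pytest.approx([-5e-3, 5e-3])
        assert by_kind["suppressed"] == pytest.approx([-2.5e-3, 2.5e-3])

    def test_zero_always_perfect(self):
        for nu in (1e3, 7e3, 42e3):
            planes = special_planes(nu, LAMBDA, (-1e-6, 1e-6))
            assert [p.kind for p in planes] == ["perfect"]

    def test_spacing_scales_inverse_nu_squared(self):
        a = special_planes(NU, LAMBDA, (0.0, 50e-3))
        b = special_planes(NU / math.sqrt(2), LAMBDA, (0.0, 100e-3))
        da = sorted(p.delta for p in a if p.kind == "shifted")[0]
        db = sorted(p.delta for p in b if p.kind == "shifted")[0]
        assert db == pytest.approx(2 * da, rel=1e-12)


class TestCoherentDof:
    def test_reference_value(self):
        res = dof_coherent(10e3, LAMBDA, 0.2)
        assert res.delta_max == pytest.approx(4.0967e-3, rel=1e-4)
        assert res.modality == "coherent"

    def test_inverse_square_scaling(self):
        assert dof_coherent(2 * NU, LAMBDA, 0.2).delta_max == pytest.approx(
            dof_coherent(NU, LAMBDA, 0.2).delta_max / 4, rel=1e-12
        )

    def test_advantage_over_diffraction_limited_incoherent(self, reference):
        """Coherent DOF beats the full incoherent DOF at every frequency the
        incoherent system can resolve, and the advantage diverges as nu
        approaches the focused incoherent resolution limit."""
        ratios = []
        for nu in (5e3, 10e3, 20e3, 30e3, 34e3, 36e3, 37e3):
            coh = dof_coherent(nu, LAMBDA, 0.2).delta_max
            inc = dof(reference, nu, 0.2).delta_max
            ratios.append(coh / inc)
        assert min(ratios) > 1.0
        assert np.all(np.diff(ratios[-4:]) > 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dof_coherent(10e3, LAMBDA, 1.5)
        with pytest.raises(ValueError):
            dof_coherent(-1.0, LAMBDA, 0.2)
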