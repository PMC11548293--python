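# Methods

This note records the model implemented by `defocim`, its conventions, the
numerical choices, and the design decisions taken where the underlying
physics admits more than one self-consistent reading.

## 1. Model and assumptions

One transverse dimension; monochromatic scalar field; paraxial propagation.
The imaging system is specified by the wavelength λ, the object distance o
of the focused plane, the Gaussian half-width σ_l of the apodized limiting
iris, and the native magnification M₀. Derived quantities: Gaussian
equivalent numerical aperture NA₀ = σ_l/o, wavenumber k = 2π/λ, focused
Airy width σ₀ = λ/(2√π·NA₀). A sample sits at axial offset δ from the
focused plane, positive away from the lens; the effective quantities are
NA(δ) = σ_l/(o+δ), M(δ) = M₀/(1+δ/o), σ₀(δ) = λ/(2√π·NA(δ)).

Image formation is built from two kernels:

* vacuum Fresnel propagator over δ (a pure quadratic-phase chirp),
  `D_δ(u) = e^{ikδ}/(i·2πδ/k) · exp(ik u²/2δ)`;
* focused Gaussian-apodized coherent Green's function,
  `P₀(x_s, x) = exp(−(x_s−x/M₀)²/4σ₀²) · exp(iπ/(λo)·(x_s²−x²/M₀²))`.

Their convolution over the plane in focus, P_δ = D_δ * P₀, is a Gaussian
integral with complex quadratic exponent, evaluated in closed form
(`optics.defocused_green`). A second analytic Gaussian integral against a
plane wave gives the harmonic response G_ν(x) (`coherent.harmonic_response`)
from which every coherent closed form follows. Coherent images are
`I = |∫A·P_δ dx_s|²`; incoherent images are `I = ∫|A|²·|P_δ|² dx_s`.

**Normalization.** The literal 1/(i·2πδ/k) propagator prefactor is kept,
which makes the global intensity scale of defocused images non-physical
(it diverges as δ→0; the focused branch uses the identity kernel directly).
All profile comparisons are therefore defined up to one positive scale
factor, implemented by `oracle.compare_normalized` (least-squares scale
fit, relative L2).

**Units.** SI throughout the library (m, cycles/m). The CLI converts once
at its boundary: nm for λ, mm for o and δ, cycles/mm for ν. All Gaussian
attenuations are written in cycles-based form, `exp(−2π²σ²ν²)`; the
1/e² incoherent cut-off is ν_inc = 1/(π·σ_inc), i.e. 2NA₀/(√π·λ) ≈ 112.8
cycles/mm at focus for the reference configuration (λ = 500 nm, NA₀ = 0.05),
consistent with the nominal ≈105 cycles/mm usually quoted for it at the
~7 % level inherent in the choice of O(1) constants.

## 2. Incoherent path

The incoherent PSF is `|P_δ|²`, an exact Gaussian. Two parameterizations of
its width coexist in the package, and both are exposed:

* **conventional ("model")**: σ_inc² = σ₀(δ)² + σ_CoC², with
  σ_CoC = δ·NA(δ)/(2√π) — the textbook Airy-plus-circle-of-confusion sum.
  This drives the public `mtf`, `cutoff`, `sigma_components` and `dof`.
* **exact ("green")**: carrying out the Gaussian integrals gives
  σ²(δ) = σ₀(δ)² + (δ·NA₀)²/(4π) — the CoC term holds the *native* NA₀.
  The two differ at O(δ/o) (≈2 % in the attenuation coefficients at
  δ = 1 mm, o = 100 mm).

`image_periodic` (the general harmonic-filter image, coordinates scaled by
M(δ)) defaults to the exact transfer so that it matches the quadrature
oracle to ~1e-14; `transfer="model"` reproduces the conventional form
exactly. `image_sinusoid` keeps the traditional printed closed form for the
sinusoid verbatim (attenuation argument at ν, spatial modulation at 2ν);
its internal tension with the general harmonic filter is deliberate — the
`image_periodic` route applied to the sin⁴ intensity series is the
self-consistent reference for arbitrary objects.

**Incoherent DOF.** `dof` solves MTF(δ, ν) = 1−c by bracketed root finding
(`brentq` on [0, 10·o], 1e-9 m tolerance) with NA(δ) self-consistent; the
reported interval is the symmetric ±δ_max (the NA(δ) asymmetry between ±δ
is O(δ/o) and ignored in the report). A frequency whose focused MTF is
already below 1−c raises `UnresolvableError` (at c = 0.2 and the reference
system this happens above ≈37.7 cycles/mm). `include_airy=False` keeps only
the CoC term — the defocus-dominated asymptotic branch with
δ_max ∝ 1/(NA·ν) exactly; this is the branch whose log-log slope is −1
(the full solution has no solution at all over part of any wide frequency
range, so a slope is only well defined asymptotically).

## 3. Coherent path

The coherent amplitude of a periodic object is
`U(x) = Σ a_n φ₀(nν) e^{−iπλδn²ν²} e^{i2πnνx/M₀}`: attenuation by the
*focused* coherent transfer function φ₀ only, plus the defocus chirp phase
quadratic in the harmonic order. Consequences implemented and tested:

* `coherent_coeffs` expands |U|² into the intensity series a′_n(δ),
  |n| ≤ 2N (harmonic doubling); the extreme coefficients |a′_±2N| are
  δ-independent, and every attenuation involves only focused-pupil values.
* Self-imaging: with the ideal pupil the image is exactly periodic in δ
  with period 2/(λν²); `special_planes` enumerates perfect (δ = 2m/λν²),
  half-period-shifted (odd multiples) and fundamental-suppressed
  (half-integer multiples) planes.
* MTF proxies (`mtf_proxies`): MTF_coh1 = −e^{−4π²σ₀²ν²}·cos(πλν²δ) for
  the fundamental (oscillating, sign-indefinite, zeros independent of NA)
  and MTF_coh2 = e^{−8π²σ₀²ν²} for the second harmonic (δ-independent).
* Coherent DOF: δ_max = arccos(1−c)/(πλν²), independent of every system
  parameter but λ. Against the CoC-only incoherent law the advantage ratio
  behaves as NA/(λν) (largest at low ν); against the full
  diffraction-limited incoherent DOF the ratio is U-shaped in ν and
  diverges as ν approaches the focused incoherent limit — both behaviors
  are exercised in the tests.

**Closed-form hierarchy for the sinusoid.** Three levels, from exact to
most approximate:

1. `image_sinusoid_gaussian` / `coherent_image`: the full Gaussian closed
   form `|Σ a_n G_{nν}(x)|²` with no approximation. This is the form
   validated against the oracle at ~1e-11 (scale-fitted relative L2). The
   image is not periodic: it sits under a field-of-view envelope whose
   intensity width is σ_l/√(2π) (≈2 mm at the reference geometry), with
   slightly pulled fringe frequency ν′ and hyperbolic (cosh/sinh) edge
   modulation at the slow rate ν″ ≈ νλo/σ_l². `GaussianCoherentParams`
   extracts (c₀, c₁, ν′, ν″, δ₀) from the exact kernel algebra rather than
   from any printed reparameterization, whose rendering is unreliable; the
   wide-pupil limits ν′→ν, δ₀→0, ν″≪ν, c₀→e^{−4π²σ₀²ν²} are tested.
2. `image_sinusoid_central`: the central-FoV approximation
   `1 + ½e^{−8π²σ₀²ν²}(1+cos4πνx/M₀) − 2e^{−4π²σ₀²ν²}cos(πλν²δ)cos2πνx/M₀`.
   Its intrinsic error against the exact form is set by the neglected
   envelope and cosh/sinh terms: at the reference geometry it is a few
   ×10⁻³ over windows holding 1.5 periods, and it reaches the 1e-3 level
   only in the wide-pupil regime (σ_l ≫ σ₀ with ν″·window ≪ 1), where the
   acceptance suite tests it. It cannot hold at all when the object period
   is comparable to the FoV (e.g. 1 cycle/mm at the reference geometry).
3. `image_sinusoid_ideal` / `image_sinusoid_generic`: the infinite-aperture
   limit (exactly 4·sin⁴ at focus) and its arbitrary-pupil generalization.
   The generic form uses the derived second-harmonic phase 2·arg φ₀(ν)
   (the two coincide for any real-spectrum pupil). Coordinates of all
   coherent forms are referred to M₀, never M(δ).

`gaussian_pupil_spectrum` evaluates φ₀ analytically from the on-axis
focused kernel (the weak image-coordinate dependence of φ₀ is dropped, as
is standard; the full x-dependence survives only in level 1 and in the
oracle). Because the focused kernel carries the quadratic phase
iπx²/(λo), φ₀ is even in ν but only approximately Hermitian — exactly
Hermitian in the a → 0 (long-o) limit.

## 4. Numerical oracle

`oracle.simulate` integrates the raw imaging integrals by composite
trapezoid quadrature of the sampled transmittance against the closed-form
kernel (only the inner plane-in-focus integral is analytic). Sampling
rules (validated, violations raise `SamplingError` naming the constraint):

* Nyquist: step ≤ 1/(16·ν_max) of the finest retained field frequency;
* chirp: at most π/4 of kernel phase per step anywhere in the window,
  with the phase gradient bounded by 2|Im A|·W + |Im g|·|X|_max + 2πν_max
  from the kernel's quadratic-exponent coefficients;
* kernel: step ≤ √2σ(δ)/8 and window covering the back-projected detector
  span plus eight kernel widths.

With a Gaussian-enveloped smooth integrand the trapezoid rule converges
superalgebraically; halving the step changes images at the 1e-13 level
(tested at 1e-6). Default detector grids in the tests are 201–301 points
over ±1.5 object periods; the CLI map scan uses 512 points over a
configurable span. The heaviest validated configuration
(1 cycle/mm at the reference geometry) uses ~2·10⁵ field samples.

`extract_harmonics` fits cos/sin pairs up to n_max by linear least squares
over the largest whole number of periods centered in the window (≥3
required; rank-deficiency raises). `compare_normalized` resamples by
linear interpolation when grids differ and minimizes over a positive scale.

## 5. Degenerate inputs, ties, tolerances

* δ = 0 is always handled by the identity-kernel branch, never by a chirp
  limit (`vacuum_green` refuses δ = 0 explicitly).
* o+δ ≤ 0 (sample at or behind the lens) is rejected at state construction.
* NA₀ ≥ 0.2 triggers a paraxial-regime warning, as does a transmittance
  with peak |A| > 1 (non-passive; the math stays linear in A).
* Fourier coefficients are stored sparsely; exact zeros are dropped.
  `square_series` is the exact coefficient autocorrelation, so "no content
  beyond 2N" is structural, and the tests additionally refit harmonics
  from reconstructed profiles to confirm it numerically (≤1e-12).
* DOF bisection tolerance 1e-9 m; `dof` returns ∞ when even δ = 10·o
  passes the tolerance (CLI reports such entries as unbounded).

## 6. What the synthetic inputs do and do not cover

All inputs are generated: the built-in sinusoid sin²(πνx) (the standard
MTF-style probe), random Hermitian-coefficient transmittances of order
≤4 scaled to |A| ≤ 1, and the reference optical configuration λ = 500 nm,
NA₀ = 0.05, o = 100 mm, M₀ = 1 with defocus up to a few mm and frequencies
1–50 cycles/mm. These match the regime the model targets. Not represented:
phase gratings (representable in `FourierObject` but unvalidated against
any reference), two-dimensional pupils and fields, hard-edged (non-Gaussian)
apertures, partial coherence, polychromatic illumination, aberrations, and
detector noise. Passing tests therefore demonstrate the internal
consistency of the Gaussian-apodized paraxial model and its closed forms —
not the behavior of a real microscope outside the paraxial, thin,
absorption-only, quasi-monochromatic regime.

## 7. Known limitations

* The conventional σ_inc (NA(δ) in the CoC term) and the exact
  Green's-function PSF width (NA₀ in the CoC term) differ at O(δ/o);
  both are exposed and the default of each function is documented above.
* The coherent ±δ symmetry of the proxies is exact, but the exact Gaussian
  image is only symmetric up to O(δ/o) envelope effects.
* `image_sinusoid` reproduces the traditional sinusoid closed form
  verbatim, including its frequency-labelling quirk; prefer
  `image_periodic` for quantitative work.
* The oracle is one-dimensional quadrature, adequate at desk scale; no
  FFT/angular-spectrum path is provided.
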