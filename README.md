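# defocim

Analytic image formation for **defocused periodic objects** in a
Gaussian-apodized paraxial imaging system, under **spatially coherent**
plane-wave illumination and under conventional **incoherent** (brightfield /
Köhler-style) illumination — with a brute-force diffraction-integral oracle
that validates every closed form.

## Who this is for

Microscopists and optical-system modelers weighing coherent (LED / laser)
illumination against incoherent illumination for brightfield and light-field
imaging of thick samples, where the trade-off between lateral resolution and
depth of field (DOF) is the limiting factor.

## The model

A one-dimensional periodic sample with complex field transmittance
`A(x_s) = Σ_n a_n exp(i 2π n ν x_s)` is observed through a paraxial system of
native magnification `M₀`, object distance `o` and Gaussian-apodized pupil of
width `σ_l` (Gaussian-equivalent numerical aperture `NA₀ = σ_l/o`), displaced
axially by a defocus `δ`.

* **Incoherent imaging** is linear in the intensity `|A|²`: each intensity
  harmonic is attenuated by the Gaussian MTF
  `exp(−2π² σ_inc²(δ) ν²)` with `σ_inc² = σ₀²(δ) + σ_CoC²(δ)`, the quadrature
  sum of the Airy width `σ₀ = λ/(2√π·NA)` and the circle of confusion
  `σ_CoC = δ·NA/(2√π)`. Defocus blurs: contrast is lost at a rate set by the
  NA, giving `DOF ∝ 1/(NA·ν)`.
* **Coherent imaging** is nonlinear (`I = |∫A·P_δ|²`) and has no true MTF.
  Free-space diffraction to the plane in focus multiplies each *field*
  harmonic by the pure phase `exp(−iπλδ n²ν²)` — a chirp in the harmonic
  order — while attenuation involves only the *focused* pupil. Squaring
  doubles the harmonic content (order N fields → order 2N intensities) and
  makes the image periodic in defocus with the self-imaging (Talbot-like)
  period `2/(λν²)`: perfect revivals, half-period-shifted copies, and planes
  where the fundamental vanishes entirely. The resulting
  `DOF = arccos(1−c)/(πλν²)` is **independent of the numerical aperture**,
  an `ν ∝ 1/√(λδ)` square-root resolution law.

Everything is cross-checked against composite-quadrature evaluation of the
raw imaging integrals (`defocim.oracle`), which shares only the Green's
function with the closed forms.

## Worked example

Depth of field at a 20 % harmonic-distortion tolerance for green light
(λ = 500 nm), NA₀ = 0.05, o = 100 mm:

```sh
$ defocim dof --nu 1 --nu 10 --nu 20 --c 0.2 --out demo
$ cat demo/dof_table.csv
nu_cycles_per_mm,dof_coherent_mm,dof_incoherent_mm,ratio_coh_over_inc
1.0,409.66552939826676,8.149031636781599,50.27168228789221
10.0,4.096655293982668,0.7317052222790198,5.598778263769857
20.0,1.024163823495667,0.32008426653247884,3.1996693701648886
```

At 10 cycles/mm the coherent system tolerates ±4.10 mm of defocus where the
incoherent one tolerates ±0.73 mm; the coherent bound would be identical at
any aperture. The self-imaging ladder for the 20 cycles/mm sinusoid:

```sh
$ defocim planes --nu 20 --range-mm 7 --out demo
$ cat demo/planes.csv
nu_cycles_per_mm,delta_mm,kind
20.0,-4.999999999999999,shifted
20.0,-2.4999999999999996,suppressed
20.0,0.0,perfect
20.0,2.4999999999999996,suppressed
20.0,4.999999999999999,shifted
```

i.e. at δ = ±5 mm the coherent image is an exact half-period-shifted copy of
the focused one, and at δ = ±2.5 mm the fundamental frequency disappears
from the image. `defocim map` renders the full x–δ intensity maps (TIFF +
CSV), `defocim mtf` tabulates the incoherent MTF and the two coherent MTF
proxies (which oscillate and go negative instead of monotonically decaying),
and `defocim validate` reruns the closed-form-vs-oracle comparison:

```sh
$ defocim validate --nu 20 --delta-mm 0 --delta-mm 1 --out demo
nu=20/mm delta=0 mm: coherent 2.73e-14, incoherent 5.71e-16
nu=20/mm delta=1 mm: coherent 2.28e-14, incoherent 2.21e-14
max deviation: coherent 2.73e-14, incoherent 2.21e-14
```

The same functionality is available as a library (`ImagingSystem`,
`DefocusState`, `FourierObject`, `coherent_coeffs`, `image_sinusoid_*`,
`dof`, `dof_coherent`, `simulate`, ...); see `docs/methods.md` for the
mathematical details and conventions.

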