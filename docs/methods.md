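# Methods

This note documents the models behind optisect, the parameters that matter,
the synthetic study conditions, and the numerical choices. It states no
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Normalized optical coordinates

All frequency-domain models are dimensionless. Lateral frequency `s` is
normalized so the incoherent cutoff of the objective is 2 (physical
frequency × λ/NA); axial defocus uses the high-aperture convention

    u = (8π n z / λ) · sin²(α/2),   sin α = NA / n,

which is odd in the physical defocus z and keeps every integral's limits
fixed at s ∈ [0, 2]. Illumination-arm quantities use the excitation
wavelength, detection-arm the emission wavelength; two-photon excitation
uses twice its excitation wavelength. The reference system is a 20×/NA 1.0
water-immersion objective (n = 1.33) at 488/520 nm.

## Defocused OTF

The OTF is the normalized autocorrelation of the defocused pupil
`P(ρ) = circ(ρ)·exp(i u ρ²/2)`. For a pure defocus phase the 2-D overlap
integral reduces to a single integral (Hopkins):

    T(s, u) = (4/π) ∫₀^{1−s/2} √(1 − (x + s/2)²) cos(u s x) dx,

evaluated with a 600-node Gauss–Legendre rule (phase resolved to |u| ≈ 500).
At u = 0 this equals the chord-area closed form, which the tests use as a
regression anchor; a brute-force 2-D pupil-overlap sum is the independent
oracle. T(0, u) = 1 exactly and T is even in u. The default comparison
lattice is 513 s-samples × 401 u-samples on [−40, 40], which resolves every
response FWHM to well under 1% (a refinement test asserts < 0.5% drift).

## Axial responses and the sectioning ranking

Per-method sheet responses are the integrals listed in
`optisect/axial.py`'s module docstring, with jinc(x) = 2J₁(x)/x and
sinc(x) = sin x/x so every apodization factor is 1 at the origin. Choices
worth noting:

* **Two-photon** has two forms: the intra-focal model `∫ jinc(2bs) T²(s,u/2)
  s ds` (the `response_two_photon` default) and the comparison form
  `∫ T(s/2, u/2) T(s, u) s ds` — excitation at the doubled wavelength,
  detection unconstrained at the native emission wavelength. The ranking
  uses the comparison form: with both OTF factors at the doubled wavelength
  the method would implausibly rank behind the plain line confocal, because
  that model ignores the full-resolution detection path entirely. An
  optional detection pinhole multiplies the integrand by T(s,u)·jinc(βs)
  (the constrained detection path, not the bare aperture factor — the bare
  jinc alone slightly *broadens* the response).
* **Hybrid illumination** is the root of the band integral
  `√(∫ T² T₀ ds)` over [s_min, s_max]. With s_max pinned at the cutoff the
  bandwidth tunes the sectioning strength, but not monotonically: bands
  squeezed against the cutoff lose strength again because near-cutoff
  frequencies decay slowly with defocus. The strongest single frequency is
  s₀ = 1, half the cutoff, which is also the structured-illumination
  default.
* **Light sheet** is Gaussian, `exp(−u²/2c²)`; the default thickness
  parameter maps the illumination Rayleigh range z_R = nλ/(π NA_ill²) into
  detection-arm defocus units (c ≈ 2.26 for the reference system).
* **Reference parameters** for the ranking: ideal illumination (b = 0),
  pinhole/slit β = 0.5 (about one back-projected camera pixel half-width),
  s₀ = 1, HiLo band [1, 2]. FWHM is extracted by linear interpolation of
  the half-maximum crossings.

Under these parameters the FWHM order is light sheet < LiMo < confocal <
{SIM, HiLo} < two-photon < line confocal.

## Deep-background tails

Tail integrals B(u₁) = ∫ I(u) du use the paraxial kernel [2J₁(us)/us]² and
reduce, via ξ = us, to cumulative Bessel moments tabulated once on a fine ξ
grid. The structured branch uses the *first* power |2J₁(us₀)/us₀| — the
demodulated single-frequency response is |T(s₀,u)|, and only the first
power produces the O(1/√u₁) tail; the squared kernel would give O(1/u₁²).
"Infinity" is truncated at u = 10⁴ with a convergence check for convergent
branches; the divergent line-confocal branch is only ever reported as a
growth profile over truncation bounds (its increments per decade of the
bound approach G₁(∞)·ln 10 = ½·ln 10). A fixed hybrid grid (geometric below
u = 50, π/12-step linear above, to resolve the Bessel oscillation) and an
adaptive quadrature route must agree to 0.5%.

## PSF engine and the scan simulator

The point amplitude is the scalar Debye integral over the circular pupil;
node count grows with defocus phase. The line-illumination profile is the
y-integral of the intensity PSF, L(x, z) = ∫ h_eff dy (energy per z-plane is
conserved, which the tests assert). Sub-detector PSFs convolve h_eff with a
rect pixel aperture at offsets n·p; the rect convolution is evaluated as a
difference of cumulative integrals on a fine symmetric grid, so
mirror-image lines agree to machine precision and the sum over a tiling
subarray equals the full-aperture detection PSF (checked against a direct
convolution to 1%).

Image formation: at focal plane z₀, each volume slice is convolved with the
product kernel K_n(x, y; z) = L(x, z−z₀)·H_det(x + n p, y, z−z₀) and summed
over z (zero-padded FFT convolution; the volume is implicitly zero outside
its bounds). Line indexing is 1…6 with lines 3 and 4 straddling the
illumination line. Shot noise is Poisson on the expected photon counts,
plus additive Gaussian read noise, applied last with the run seed.

A duality check mirrors the scanned-system equivalence of patterned
illumination and detection-side masking: the same pattern applied as a
weighted sum of sub-line images (detection side) or as a shifted-sum
excitation profile with unconstrained detection (illumination side) must
produce the same image in the interior of a y-invariant phantom to 1%
(image edges differ by the zero-padding roll-off, which is a boundary
artifact, not a physics difference).

The simulator is validated end to end against the analytic theory: sweeping
a thin sheet through focus with a centred detector line reproduces the
line-confocal axial response (slit half-width β = 2π NA w/2 / λ for pixel
width w) to within 2% of peak.

## Phantom and study conditions

The phantom is a set of smoothed 3-D random-walk trajectories rasterized as
tubes (default radius 0.5 μm) with a lognormal intensity law varying
smoothly along z, in a 256×256×128 volume at 0.325/0.5 μm sampling — a
desk-scale stand-in for a 1024³ block (the full size is a config, not a
test requirement). Defaults that define the synthetic experiment:

* **12 paths** per volume: a dense filament tangle, so the focal plane's
  surroundings genuinely contain out-of-focus structure. With only a few
  paths the background annulus is nearly photon-free and the comparison
  degenerates.
* **Noise: Poisson + 2 e⁻ read noise at 3000 photons per intensity unit**
  (≈ 450 photons at a fibre peak) — a realistic line-scan fluorescence
  budget. Noise is not a nuisance here but part of the physics being
  compared: the absolute-difference decoding (DSIM) rectifies noise into a
  background floor ∝ √5·E|n₃−n₁|, the HiLo fusion averages noise in its
  low-pass arm, and the LiMo linear combination has the smallest clipped
  floor. A noiseless run inverts the DSIM/DHiLo pair — that regime rewards
  exact background cancellation, which no real detector achieves.
* **SBR protocol**: signal = structure voxels within ±1 μm of the focal
  plane, background = the 1–4 μm annulus around them — the fibre-adjacent
  background a practitioner would box, not the empty far field.
* **DHiLo** is scored with the contrast-weighted fusion
  HP{I₃} + η·LP{C_s·I₃}, C_s = smoothed (I₃−I₁)/(I₃+I₁), η = 1, Gaussian
  low-pass with frequency-domain σ = 1/(4·pixel). The subtraction form
  I₃ − γ·LP(I₃) (γ = 0.9 default) is implemented and is the
  `recon_dhilo` default for algebraic checks, but as a scoring algorithm
  it is fragile: its residual background, a fixed (1−γ) fraction of the
  low-pass, sits within a few percent of DSIM's residual and the pair's
  order then flips from phantom to phantom.

Under these conditions the SBR order LiMo > DHiLo > DSIM > LC is stable
across every seed tested (margins ≥ 25%). What passing shows: the decoding
algebra, the off-axis encoding physics and the noise propagation rank
exactly as the models predict on filament-like samples. What it does not
show: performance on real tissue (scattering, aberrations, motion,
vignetting are all outside the forward model), absolute SBR values, or
robustness to mis-registration of the line images.

## Performance calculators

The timing laws are closed forms: mosaic T_m = (t_m + √(4M/a))·L²/M² −
√(4M/a) and strip T_s = L²t_s/(pM) + (L/M − 1)√(4M/a), with the reference
field M = 0.67 mm and stage acceleration a = 200 mm/s²; per-field exposures
come from the stated camera/mirror rates (e.g. point scanning:
2048²px at 512² px per 1/30 s → 533 ms). Small samples are scan-limited:
T = (t_m/M²)·L². Quadratic coefficients are reported to the printed
precision. SNR branches follow the per-method formulas with a declared
reference modulation profile m = (0.3, 0.6, 1, 1, 0.6, 0.3) (centre-dominated,
symmetric — the in-focus character of the six lines), pinhole/spot area
ratio 0.098 for point confocal and 1-D width ratio 0.31 for the slit, and
SIM normalization k = 2 (two lines per phase). Penetration depth and light
dose are the stated exponential and P·t/S laws.

The resolution ranking uses the two PSF classes (focused h², wide h), the
mean of the two for line-scanning methods (focused across the line, wide
along it), the doubled excitation wavelength for two-photon, and two
documented reconstruction penalties: SIM's usable band shrinks to
(cutoff − s₀), widening its PSF by 2/(2−s₀); HiLo's fusion costs a small
broadening (factor 1.1). The 1.41 confocal-vs-widefield ratio is the
Gaussian-approximation value (√2); the Airy-model ratio is ≈ 1.39.

## Known limitations

* Scalar, aberration-free pupil model; no vectorial or polarization
  effects, no tissue scattering, no stage jitter or bleaching.
* The u ↔ μm mapping of published response curves cannot be recovered from
  shapes alone, so sectioning claims are made in normalized units and as
  orderings, never as absolute micrometre FWHMs.
* The √5 constant in the simplified DSIM form and the exact three-phase
  mask values are not derivable from first principles here; the general
  and simplified forms agree in shape (correlation > 0.85 on a point
  source) but not pointwise, and both cancel modulation-free input exactly.
* The wide-field mosaic coefficient computes to 0.2763 s/mm², which rounds
  to 0.28 at two decimals.
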