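# optisect

A quantitative framework for comparing optical-sectioning fluorescence
microscopy methods — point/line confocal, two-photon, structured and hybrid
illumination (SIM/HiLo), light sheet, and off-axis line-illumination
modulation (LiMo) — for microscopists and instrument builders choosing a
sectioning strategy for thick samples.

Everything runs on synthetic inputs: analytic optical models plus a
phantom-based image-formation simulator. No experimental data is required.

## What it computes

**Sectioning strength.** The axial response of each method to a thin
fluorescent sheet, expressed through the defocused optical transfer function
T(s, u) of a circular pupil (normalized lateral frequency s, cutoff 2;
normalized defocus u). For example, the confocal pinhole response is

    I(u) = ∫₀² jinc(b s) T²(s, u) jinc(β s) s ds,

with illumination spot radius b and pinhole radius β, and the sectioning
figure of merit is the FWHM of I(u). Analogous integrals cover slits,
two-photon excitation, single-frequency and band-filtered modulation, a
Gaussian light sheet, and the LiMo decoding weight (1 − cos 2βs).

**Deep-background suppression.** Tail integrals B(u₁) = ∫ᵤ₁^∞ I(u) du with
paraxial Bessel kernels, their empirical decay orders (confocal ~ 1/u₁,
structured ~ 1/√u₁, LiMo ~ ln u₁/u₁², light sheet ~ exp(−u₁²/2)), and the
logarithmic divergence of the plain line-confocal tail.

**Off-axis line-scan simulation.** A line focus scanned across a 3-D
phantom, recorded by a multi-line detector subarray; the per-off-axis-line
images I₁…I₆ are decoded four ways:

    LC    = I₃                          (virtual slit)
    DSIM  = √5 |I₃ − I₁|                (digital SIM)
    DHiLo = HP{I₃} + η·LP{C_s·I₃}       (digital HiLo fusion)
    LiMo  = 2(I₃+I₄) − (I₁+I₂+I₅+I₆)    (linear decoding)

and scored by signal-to-background ratio (SBR) against the phantom's
structure mask.

**Performance calculators.** Mosaic/strip imaging-time laws, per-method SNR
branches, penetration depth, and light dose, with the cross-method rankings
they imply.

## Worked example

```python
from optisect import OpticalConfig, sectioning_ranking, make_otf_grid

cfg = OpticalConfig()            # NA 1.0 water immersion, 488/520 nm
otf = make_otf_grid()
for method, fwhm in sectioning_ranking(cfg, otf=otf):
    print(f"{method:>14s}  FWHM = {fwhm:6.2f}")
```

prints the axial-response FWHM (normalized defocus units) of each method
under the reference parameters — smaller is stronger sectioning:

```
   light_sheet  FWHM =   5.33
          limo  FWHM =   7.71
      confocal  FWHM =   8.53
    structured  FWHM =   9.13
        hybrid  FWHM =   9.61
    two_photon  FWHM =  10.60
 line_confocal  FWHM =  12.17
```

The light sheet sections most strongly, LiMo beats point confocal, modulated
illumination follows, and the plain virtual-slit line confocal is weakest.

The full synthetic experiment (phantom → scan → four decodings → SBR table):

```bash
optisect run --seed 1 --out results_run
```

which ends with a summary like

```
method       sbr
  limo 61.663544
 dhilo 48.912562
  dsim 24.359456
    lc 15.978758
```

— the LiMo decoding suppresses the out-of-focus background best, followed by
DHiLo, DSIM, and the raw line-confocal image. Other subcommands: `optisect
curves`, `tails`, `simulate`, `reconstruct`, `metrics` (see `--help`).

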