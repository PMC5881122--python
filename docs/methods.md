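# Methods

## The model

`parvocone` models the retinal stage of the primate parvocellular
channel in the foveola and asks which pair of M- and L-cone peak
spectral sensitivities (λmaxM, λmaxL) best supports the discrimination
of chromatic patterns — concretely, sinusoidal gratings whose bright
bars carry a fruit spectrum and whose dark bars carry a leaf spectrum.

The processing chain for one candidate pair j and one spectral image
P_i(x, y, λ) is:

1. **Sensitivity mosaic.** Cone labels a_xy ∈ {M, L} are drawn i.i.d.
   with P(L) = 0.5 on a square grid (one cone = one pixel = 1/120°).
   Each pixel receives the spectral sensitivity
   C_j(x, y, λ) = 10^(−Δ(λ)) · ψ(λ, λmax of its type),
   where Δ(λ) is the combined lens + macular optical density and ψ is a
   peak-shifted visual-pigment absorbance template converted to
   absorptance (1 − 10^(−D·ψ), D = 0.5).
2. **Quantal catch.** Q(x, y) = Σ_λ P_i(x, y, λ) C_j(x, y, λ). The
   catch is deterministic (no photon noise).
3. **Opponent processing.** Midget ganglion cells are
   difference-of-Gaussians receptive fields on a 9×9-cone window,
   W_ON = N(0, σc) − ω N(0, σs) with unnormalised Gaussians,
   σc = 0.25, σs = 1.66 cones, ω = 0.55, and W_OFF = −W_ON. G_ON =
   Q ∗ W_ON with 'valid' boundary handling, which removes the
   (Nw − 1)/2 = 4 border pixels on every side.
4. **Channel integration.** With binary cone-identity masks L, M
   (m_xy = 1 − l_xy), the red-green cortical input is
   O = L∘G_ON + M∘G_OFF (equivalently (L − M)∘G_ON) and the luminance
   input is O′ = G_ON.
5. **Scoring.** O is min-max normalised to [0, 1] and compared with the
   border-trimmed reference grating by PSNR = 10·log10(1/MSE)
   (peak value 1; a zero-MSE match is capped at 120 dB). The score z_j
   of a pair is the mean PSNR over all images in the database, and an
   exhaustive search evaluates every pair on a grid subject to
   λmaxL ≥ λmaxM, repeated over independently seeded mosaics.

## Stimuli

Each spectral image is built from exactly two spectra: a target and a
background, both multiplied by the illuminant, mixed per pixel with the
grating weight p̄(x) = (1 − cos 2πx/T)/2 (two full cycles per image,
T ∈ {30, 60, 110, 222} cones per cycle for 4, 2, 1, 0.5 cycles/degree;
column 0 is pure background). Optionally every pixel's spectrum is then
scaled by a luminance coefficient, and finally every wavelength plane
is blurred with a diffraction-limited Airy kernel for a 5 mm pupil
(first dark ring at 1.22 λ/d — about 1.17 pixels at 700 nm, 0.67 at
400 nm), truncated at 9 pixels and convolved with wrap-around
boundaries (the grating is periodic in x, so wrap-around introduces no
artificial edges ahead of the border trim).

## Synthetic spectra

The package generates its own spectral libraries; they emulate the
structure of measured natural-spectra collections without reproducing
any measured curve.

* **Fruit** (targets): 65% logistic long-pass edges with inflection
  uniform on 500–640 nm, widths 8–20 nm, plateau reflectance
  0.15–0.55 over a 0.02–0.08 pedestal; 25% green-peaked (unripe or
  cryptic) fruits; 10% dark fruits. The moderate plateaus keep fruit
  and foliage broadly comparable in overall intensity, a documented
  property of measured foraging spectra.
* **Leaf** (background): a low pedestal (0.03–0.05) plus a chlorophyll
  green peak near 550 nm (amplitude 0.08–0.15) and the onset of the
  far-red reflectance rise near 700 nm; between-leaf variance is small.
  The image background is always the pointwise mean of the leaf
  library.
* **Munsell-like** (diverse-hue control): logistic-squashed random
  mixtures of six broad Gaussian basis functions, spanning reflectances
  0.04–0.95 across the whole hue circle. Images in this mode draw two
  spectra per image at random without replacement.
* **Illuminant**: a broad smooth curve with a green bias emulating
  canopy-filtered forest light, normalised to unit mean. Results are
  insensitive to reasonable illuminant choices; a flat illuminant is
  used wherever tests need exact algebraic identities.

**Luminance fields.** Natural-scene luminance variation is emulated by
a random-phase field synthesised in the frequency domain with amplitude
∝ 1/f, inverse-transformed, scaled to RMS contrast 0.45 about its
mean, clipped at a 2% deep-shadow floor, and renormalised to exact unit
mean. The bounded, light-tailed form mirrors greyscale pixel values of
photographs (which is what such coefficients represent physically);
RMS contrast 0.45 is typical of natural greyscale scenes. The fitted
log-log slope of the radially averaged amplitude spectrum is −1 ± 0.3.
A fresh field is drawn per image from the experiment's seed stream.

## Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| wavelength grid | 400–700 step 4 | nm | primate visual range; 76 samples |
| L:M ratio | 0.5 | — | average in non-human catarrhines |
| σc, σs | 0.25, 1.66 | cones | single-cone centre; centre/surround ratio 0.15 |
| ω | 0.55 | — | mean relative surround sensitivity |
| Nw | 9 | cones | covers ~±3 surround SD with a single-cone centre |
| D (peak optical density) | 0.5 | — | typical cone axial density for absorptance |
| pupil diameter | 5 | mm | sets the Airy kernel scale |
| luminance RMS contrast | 0.45 | — | natural greyscale-scene contrast |
| PSNR cap | 120 | dB | keeps zero-MSE matches finite |

All are configurable; the ocular-media table can be replaced by any
two-column CSV on the grid, and a zero-density mode exists.

## Numerical choices

* Convolution is implemented as correlation; the kernels are
  even-symmetric so the two coincide.
* A spatially constant channel output normalises to 0.5 everywhere, so
  degenerate pairs score finitely rather than aborting a search.
* Argmax ties in a search go to the shortest wavelengths and are
  flagged in the output records.
* Confidence intervals use the normal approximation mean ± 1.96·sd/√n;
  the spatial-frequency comparison uses Welch's t-test by default
  (pooled available). Two identical zero-variance samples return
  t = 0, p = 1.
* Seeding: one master seed spawns disjoint named streams for spectra,
  and per (frequency, replicate) for the mosaic and the per-image
  luminance fields, so ablations change one factor at a time and every
  run is bit-reproducible.
* Resampling of measured spectra is linear interpolation (monotone
  preserving; source data are already near the grid resolution);
  negative measured values are clipped to 0.

## Problem sizes

The named experiments default to a reduced profile — 10 replicates and
100 synthetic targets — which preserves every qualitative contrast of
the full-scale profiles (50–100 replicates, >1000 spectra) at
desk-scale runtimes; `full_scale=True` (CLI `--full-scale`) restores
the published search parameters. The acceptance script uses 3–8
replicates and 80–150 spectra per question.

## What passing tests do and do not show

The synthetic families reproduce the *structure* of the study
conditions (long-pass fruit edges against a uniform green background,
diverse-hue controls, 1/f luminance noise, chromatic blur) but not the
measured spectra themselves. Behaviours that depend only on that
structure are reproduced and tested: performance on diverse-hue images
grows with peak separation and is maximal at the grid corner; with
long-pass fruit targets a free L peak always runs to the longest
wavelength available; all algebraic identities of the pipeline hold to
numerical precision.

One behaviour is *not* reproduced at desk scale: the interior optimum
of the M peak (~525 nm) under luminance variation, and with it the
shift of the optimum toward shorter wavelengths when luminance
variation is removed. With the literal unnormalised
difference-of-Gaussians (kernel sum ≈ −8.4), channel outputs are
dominated by mosaic sign noise whose normalised variance falls as the
M peak moves short, giving a monotone preference for the shortest
available M peak on the synthetic libraries; luminance variation
flattens this gradient about three-fold — acting in the expected
direction — but does not move the argmax. The corresponding acceptance
test is left failing rather than weakened. Reproducing the interior
optimum appears to require the measured fruit/leaf reflectances, whose
much lower and more variable chromatic contrast lets the
luminance-noise term dominate; with an external directory of measured
spectra (`--dataset <dir>` with `fruits.csv`/`leaves.csv`) the
full-scale experiments run unchanged.

## Known limitations

* S cones, rods, photon (Poisson) noise, cone coupling, non-1:1 L:M
  ratios, hexagonal mosaics, and cortical spatial integration are out
  of scope by design.
* The ocular-media table is an approximate digitisation of standard
  human values, not a measured dataset.
* The pigment template is an A1 (Govardovskii-type) absorbance
  template; the beta band matters little above 440 nm.
* Whether the original optics used the wavelength in the ocular medium
  is unknown; the Airy kernel uses the vacuum wavelength with the
  stated pupil diameter (refractive index and focal length are kept as
  metadata).
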