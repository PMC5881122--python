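"""Spectral-image construction: gratings, luminance fields, chromatic blur.

A stimulus is a hyperspectral stack built from exactly two radiance
spectra arranged as a horizontal sinusoidal grating, optionally modulated
by a 1/f ("pink") luminance-coefficient field emulating the shadow
structure of natural scenes, and finally blurred wavelength-by-wavelength
with a diffraction-limited Airy point-spread function to capture the
chromatic aberration of the eye's optics.

Axis convention: axis 0 is x (horizontal, the grating axis), axis 1 is y.
One pixel equals one cone equals 1/120 degree of visual arc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import special

from .spectra import Spectrum, WavelengthGrid, DEFAULT_GRID

__all__ = [
    "ReferencePattern",
    "LuminanceField",
    "OpticsModel",
    "SpectralImage",
    "SceneConfig",
    "make_grating",
    "synth_luminance_field",
    "airy_psf",
    "assemble_image",
    "make_otfs",
    "amplitude_spectrum_slope",
]

#: cones (pixels) per grating cycle at the standard spatial frequencies.
#: 120 cones per degree in the foveola; the 1 cpd entry is 110, not 120.
CONES_PER_CYCLE = {4.0: 30, 2.0: 60, 1.0: 110, 0.5: 222}

PIXEL_PITCH_DEG = 1.0 / 120.0


@dataclass
class ReferencePattern:
    """The noiseless spatial pattern the channel outputs are scored against.

    ``values`` lie in [0, 1]: 1 marks target (fruit) positions, 0 marks
    background (leaf) positions, intermediate values are mixtures.
    """

    values: np.ndarray
    spatial_frequency: float
    cones_per_cycle: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("reference pattern must be 2-D")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("reference pattern values must lie in [0, 1]")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class LuminanceField:
    """Strictly positive per-pixel luminance coefficients, mean 1."""

    coefficients: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if c.min() <= 0:
            raise ValueError("luminance coefficients must be strictly positive")
        self.coefficients = c


@dataclass(frozen=True)
class OpticsModel:
    """Optical parameters of the model eye.

    The diffraction-limited Airy pattern depends only on wavelength and
    pupil diameter; refractive index and focal length are retained as
    descriptive metadata of the modelled (human) eye.
    """

    refractive_index: float = 1.406
    focal_length_mm: float = 21.3
    pupil_diameter_mm: float = 5.0
    pixel_pitch_deg: float = PIXEL_PITCH_DEG
    kernel_truncation: int = 9   # pixels; covers >= 3 Airy rings at 700 nm

    def __post_init__(self) -> None:
        for name in ("refractive_index", "focal_length_mm",
                     "pupil_diameter_mm", "pixel_pitch_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SpectralImage:
    """An Nx x Ny x Nlambda radiance stack built from two spectra."""

    values: np.ndarray
    grid: WavelengthGrid
    pattern_ref: ReferencePattern
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[2] != self.grid.n:
            raise ValueError("spectral image must be Nx x Ny x Nlambda")
        if v.shape[:2] != self.pattern_ref.shape:
            raise ValueError("spatial dims must match the reference pattern")
        if v.min() < -1e-9:
            raise ValueError("spectral image must be nonnegative")
        self.values = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class SceneConfig:
    """How to build one simulation's image database.

    ``pairing`` selects the target/background policy: the default
    ``target_background`` presents each library target against the fixed
    library background; ``draw_pairs`` draws two spectra per image at
    random without replacement (used with diverse surface-colour
    libraries that have no natural background); ``per_pixel_background``
    draws an independent random background spectrum in every pixel
    (off by default — retained as an ablation).
    """

    spatial_frequency: float = 4.0
    ny: int = 30
    luminance_variation: bool = True
    lum_contrast: float = 0.45
    optics: OpticsModel | None = field(default_factory=OpticsModel)
    pairing: str = "target_background"
    n_images: int | None = None   # draw_pairs mode: images per library

    def __post_init__(self) -> None:
        if self.pairing not in ("target_background", "draw_pairs",
                                "per_pixel_background"):
            raise ValueError(f"unknown pairing policy {self.pairing!r}")


def make_grating(spatial_frequency: float, ny: int = 30) -> ReferencePattern:
    """Two full cycles of a horizontal sinusoidal grating.

    The profile is p(x) = (1 - cos(2*pi*x/T))/2 with T cones per cycle,
    so column 0 is pure background and the pattern spans [0, 1] exactly.
    Standard frequencies use the tabulated cones-per-cycle values;
    other frequencies use round(120 / sf).
    """
    T = CONES_PER_CYCLE.get(float(spatial_frequency))
    if T is None:
        T = int(round(120.0 / spatial_frequency))
    nx = 2 * T
    x = np.arange(nx)
    profile = 0.5 * (1.0 - np.cos(2.0 * np.pi * x / T))
    values = np.repeat(profile[:, None], ny, axis=1)
    return ReferencePattern(values, float(spatial_frequency), T)


#: deep-shadow floor for luminance coefficients, as a fraction of the mean
LUM_FLOOR = 0.02


def synth_luminance_field(nx: int, ny: int, seed: int,
                          contrast: float = 0.45) -> LuminanceField:
    """Random-phase 1/f field rescaled to positive, mean-1 coefficients.

    White Gaussian noise is shaped in the frequency domain with an
    amplitude envelope proportional to 1/f and inverse-transformed.
    The spatial field is then treated like the greyscale pixel values of
    a natural leafy scene: fluctuations are scaled to ``contrast``
    (RMS contrast, i.e. standard deviation over mean), clipped at a
    small deep-shadow floor, and divided by the mean so the field
    neither brightens nor darkens the image on average. The resulting
    coefficients are bounded and light-tailed, like photographic pixel
    values.
    """
    if nx < 8 or ny < 8:
        raise ValueError("field dimensions must be >= 8")
    rng = np.random.default_rng(seed)
    fx = np.fft.fftfreq(nx)[:, None]
    fy = np.fft.fftfreq(ny)[None, :]
    f = np.hypot(fx, fy)
    envelope = np.zeros_like(f)
    nonzero = f > 0
    envelope[nonzero] = 1.0 / f[nonzero]
    white = rng.standard_normal((nx, ny))
    shaped = np.fft.ifft2(np.fft.fft2(white) * envelope).real
    shaped /= shaped.std()
    coeff = np.clip(1.0 + contrast * shaped, LUM_FLOOR, None)
    coeff /= coeff.mean()
    return LuminanceField(coeff, seed)


def amplitude_spectrum_slope(values: np.ndarray,
                             f_lo: float = 0.05, f_hi: float = 0.4) -> float:
    """Log-log slope of the radially averaged 2-D amplitude spectrum.

    Frequencies are in cycles/pixel; the fit window [f_lo, f_hi] excludes
    the DC bin and the corner frequencies beyond the Nyquist circle.
    """
    nx, ny = values.shape
    amp = np.abs(np.fft.fft2(values - values.mean()))
    fx = np.fft.fftfreq(nx)[:, None]
    fy = np.fft.fftfreq(ny)[None, :]
    f = np.hypot(fx, fy).ravel()
    a = amp.ravel()
    keep = (f >= f_lo) & (f <= f_hi) & (a > 0)
    # average amplitude in logarithmic frequency bins before fitting
    bins = np.geomspace(f_lo, f_hi, 12)
    idx = np.digitize(f[keep], bins)
    fs, amps = [], []
    for b in range(1, len(bins)):
        sel = idx == b
        if sel.sum() >= 2:
            fs.append(np.exp(np.log(f[keep][sel]).mean()))
            amps.append(a[keep][sel].mean())
    slope = np.polyfit(np.log(fs), np.log(amps), 1)[0]
    return float(slope)


def airy_psf(lam_nm: float, optics: OpticsModel) -> np.ndarray:
    """Diffraction-limited Airy intensity kernel at one wavelength.

    Sampled at pixel centres on the angular grid, truncated at
    ``kernel_truncation`` pixels from the centre, and normalised to unit
    sum. The kernel's first zero lies at an angular radius of
    1.22 * lambda / d, so long wavelengths are blurred more.
    """
    if lam_nm <= 0:
        raise ValueError("wavelength must be positive")
    if not (300.0 <= lam_nm <= 800.0):
        raise ValueError("wavelength outside supported range [300, 800] nm")
    k = optics.kernel_truncation
    pitch_rad = np.deg2rad(optics.pixel_pitch_deg)
    offsets = np.arange(-k, k + 1)
    theta = pitch_rad * np.hypot(offsets[:, None], offsets[None, :])
    d = optics.pupil_diameter_mm * 1e-3
    lam = lam_nm * 1e-9
    x = np.pi * d * theta / lam
    kernel = np.ones_like(x)
    nz = x > 0
    kernel[nz] = (2.0 * special.j1(x[nz]) / x[nz]) ** 2
    return kernel / kernel.sum()


def make_otfs(grid: WavelengthGrid, shape: tuple[int, int],
              optics: OpticsModel) -> np.ndarray:
    """Per-wavelength optical transfer functions for circular convolution.

    Each Airy kernel is embedded in an image-sized array centred at the
    origin (wrap-around), then transformed; multiplying a plane's FFT by
    the OTF implements periodic-boundary blurring. The stimulus is
    periodic along x, so wrap-around introduces no artificial edges ahead
    of the downstream border trim.
    """
    nx, ny = shape
    k = optics.kernel_truncation
    if 2 * k + 1 > min(nx, ny):
        raise ValueError("PSF kernel larger than the image")
    otfs = np.empty((grid.n, nx, ny), dtype=complex)
    for j, lam in enumerate(grid.values):
        kern = airy_psf(lam, optics)
        padded = np.zeros((nx, ny))
        padded[: 2 * k + 1, : 2 * k + 1] = kern
        padded = np.roll(padded, (-k, -k), axis=(0, 1))
        otfs[j] = np.fft.fft2(padded)
    return otfs


def _blur_planes(values: np.ndarray, otfs: np.ndarray) -> np.ndarray:
    """Circularly convolve each wavelength plane with its OTF."""
    planes = np.moveaxis(values, 2, 0)
    blurred = np.fft.ifft2(np.fft.fft2(planes, axes=(1, 2)) * otfs,
                           axes=(1, 2)).real
    return np.moveaxis(blurred, 0, 2)


def assemble_image(pattern: ReferencePattern, target: Spectrum,
                   background: Spectrum | np.ndarray, illuminant: Spectrum,
                   lum: LuminanceField | None = None,
                   optics: OpticsModel | None = None,
                   otfs: np.ndarray | None = None,
                   metadata: dict | None = None) -> SpectralImage:
    """Build one spectral image from a pattern and two spectra.

    Pipeline order: (1) apply the illuminant to the target and background
    reflectances; (2) mix the two radiances pixel-wise with the pattern
    weight; (3) scale every pixel's spectrum by its luminance
    coefficient; (4) blur each wavelength plane with its Airy kernel.
    ``lum=None`` means coefficients of 1 everywhere; ``optics=None``
    skips blurring. ``background`` may also be a per-pixel reflectance
    stack (Nx, Ny, Nlambda) for the random-background ablation.
    """
    grid = target.grid
    if illuminant.grid != grid:
        raise ValueError("illuminant grid differs from spectrum grid")
    nx, ny = pattern.shape
    rt = target.values * illuminant.values
    if isinstance(background, Spectrum):
        if background.grid != grid:
            raise ValueError("background grid differs from target grid")
        rb = background.values * illuminant.values
        rb_stack = rb[None, None, :]
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (nx, ny, grid.n):
            raise ValueError("per-pixel background stack has wrong shape")
        rb_stack = bg * illuminant.values[None, None, :]
    w = pattern.values[:, :, None]
    values = w * rt[None, None, :] + (1.0 - w) * rb_stack
    if lum is not None:
        if lum.coefficients.shape != (nx, ny):
            raise ValueError("luminance field dims do not match the pattern")
        values = values * lum.coefficients[:, :, None]
    if optics is not None:
        if otfs is None:
            otfs = make_otfs(grid, (nx, ny), optics)
        values = np.clip(_blur_planes(values, otfs), 0.0, None)
    meta = dict(metadata or {})
    meta.setdefault("target", target.label)
    if lum is not None:
        meta.setdefault("lum_seed", lum.seed)
    return SpectralImage(values, grid, pattern, meta)
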