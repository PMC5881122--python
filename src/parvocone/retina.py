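"""The biological model: cone mosaic, spectral sensitivities, opponency.

The modelled retina is the central primate foveola: a square grid of M
and L cones in a locally random 1:1 arrangement, each cone one pixel.
Cone spectral sensitivities are generated from a peak-shifted visual
pigment template, converted from absorbance to absorptance, and filtered
by the ocular media (lens + macular pigment). Midget retinal ganglion
cells are modelled as difference-of-Gaussians receptive fields with a
single-cone centre and a non-selective surround; ON and OFF responses
are combined with cone-type identifier masks into a red-green opponent
signal and a luminance signal, the two inputs to the cortex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .scene import SpectralImage
from .spectra import DEFAULT_GRID, Spectrum, WavelengthGrid

__all__ = [
    "Mosaic",
    "OcularMedia",
    "PigmentTemplate",
    "SensitivityMosaic",
    "ReceptiveField",
    "ConeIdentifierMasks",
    "RGCResponseMaps",
    "ChannelOutput",
    "make_mosaic",
    "cone_fundamental",
    "build_sensitivity_mosaic",
    "quantal_catch",
    "make_receptive_fields",
    "rgc_responses",
    "identifier_masks",
    "integrate_channels",
    "trim_border",
    "save_mosaic",
    "load_mosaic",
]

#: peak-sensitivity range over which the pigment template is applied
LAMBDA_MAX_RANGE = (440.0, 620.0)


@dataclass
class Mosaic:
    """Spatial arrangement of M and L cone labels on a square grid."""

    labels: np.ndarray          # dtype '<U1', entries 'M' or 'L'
    ratio: float                # probability of L
    seed: int

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("mosaic labels must be 2-D")
        if not np.isin(lab, ("M", "L")).all():
            raise ValueError("mosaic labels must be 'M' or 'L'")
        self.labels = lab

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def is_l(self) -> np.ndarray:
        return self.labels == "L"


def make_mosaic(nx: int, ny: int, ratio: float = 0.5, seed: int = 0) -> Mosaic:
    """I.i.d. random cone labels; each pixel is L with probability ``ratio``."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must be a probability")
    rng = np.random.default_rng(seed)
    is_l = rng.random((nx, ny)) < ratio
    return Mosaic(np.where(is_l, "L", "M"), ratio, seed)


def save_mosaic(mosaic: Mosaic, path: str | Path) -> None:
    """Write the label grid as lines of M/L characters plus JSON metadata."""
    path = Path(path)
    rows = ["".join(row) for row in mosaic.labels.T]  # one line per y row
    path.write_text("\n".join(rows) + "\n")
    meta = {"ratio": mosaic.ratio, "seed": mosaic.seed,
            "shape": list(mosaic.shape)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_mosaic(path: str | Path) -> Mosaic:
    path = Path(path)
    rows = [list(line) for line in path.read_text().splitlines() if line]
    labels = np.array(rows).T
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Mosaic(labels, meta.get("ratio", 0.5), meta.get("seed", -1))


@dataclass
class OcularMedia:
    """Combined lens + macular optical density on the wavelength grid."""

    densities: np.ndarray
    grid: WavelengthGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, dtype=float)
        if d.size != self.grid.n:
            raise ValueError("density vector length must match the grid")
        if d.min() < 0:
            raise ValueError("optical densities must be nonnegative")
        self.densities = d

    @property
    def transmission(self) -> np.ndarray:
        return 10.0 ** (-self.densities)

    @classmethod
    def human(cls, grid: WavelengthGrid = DEFAULT_GRID) -> "OcularMedia":
        """Built-in approximate human lens + macular density table."""
        with resources.files("parvocone.data").joinpath(
                "ocular_media.csv").open() as fh:
            table = pd.read_csv(fh, comment="#")
        dens = np.interp(grid.values, table["wavelength"], table["density"])
        return cls(dens, grid)

    @classmethod
    def transparent(cls, grid: WavelengthGrid = DEFAULT_GRID) -> "OcularMedia":
        """Zero density everywhere; useful for tests."""
        return cls(np.zeros(grid.n), grid)


@dataclass(frozen=True)
class PigmentTemplate:
    """A1 visual-pigment absorbance template, peak-shifted on wavelength.

    The alpha band follows the standard A1 template of Govardovskii and
    colleagues, with the small beta band included; this approximates the
    shape-invariant-in-log-wavelength mean cone fundamental used in
    human colorimetry. ``peak_optical_density`` converts absorbance to
    absorptance via 1 - 10^(-D * absorbance).
    """

    peak_optical_density: float = 0.5

    def absorbance(self, lam_nm: np.ndarray, lmax: float) -> np.ndarray:
        """Normalised (peak-1) absorbance at wavelengths ``lam_nm``."""
        lam = np.asarray(lam_nm, dtype=float)
        x = lmax / lam
        a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
        alpha = 1.0 / (np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
                       + np.exp(-14.9 * (1.104 - x)) + 0.674)
        lam_beta = 189.0 + 0.315 * lmax
        b_beta = -40.5 + 0.195 * lmax
        beta = 0.26 * np.exp(-(((lam - lam_beta) / b_beta) ** 2))
        s = alpha + beta
        return s / s.max()


def cone_fundamental(lmax: float, template: PigmentTemplate,
                     media: OcularMedia,
                     grid: WavelengthGrid = DEFAULT_GRID,
                     normalize_peak: bool = False) -> Spectrum:
    """Spectral sensitivity of a cone with peak absorbance at ``lmax``.

    sensitivity(lambda) = 10^(-Delta(lambda)) * (1 - 10^(-D * psi)),
    where psi is the peak-1 absorbance template and Delta the ocular
    media density. By default the result is left on the absorptance
    scale (not re-normalised to unit peak); ``normalize_peak=True``
    rescales to peak 1.
    """
    lo, hi = LAMBDA_MAX_RANGE
    if not lo <= lmax <= hi:
        raise ValueError(
            f"lambda_max {lmax:g} nm outside template validity [{lo:g}, {hi:g}]")
    if media.grid != grid:
        raise ValueError("ocular media grid differs from requested grid")
    psi = template.absorbance(grid.values, lmax)
    absorptance = 1.0 - 10.0 ** (-template.peak_optical_density * psi)
    sens = media.transmission * absorptance
    if normalize_peak:
        sens = sens / sens.max()
    return Spectrum(grid, sens, role="sensitivity", label=f"cone_{lmax:g}nm")


@dataclass
class SensitivityMosaic:
    """Per-pixel cone spectral sensitivities for one (M, L) peak pair.

    Every pixel holds one of exactly two prototype curves, selected by
    the mosaic label at that pixel.
    """

    pair: tuple[float, float]         # (lambda_max_M, lambda_max_L)
    mosaic: Mosaic
    prototype_m: np.ndarray
    prototype_l: np.ndarray
    grid: WavelengthGrid = DEFAULT_GRID

    @property
    def values(self) -> np.ndarray:
        """Materialised Nx x Ny x Nlambda sensitivity stack."""
        sel = self.mosaic.is_l[:, :, None]
        return np.where(sel, self.prototype_l[None, None, :],
                        self.prototype_m[None, None, :])


def build_sensitivity_mosaic(pair: tuple[float, float], mosaic: Mosaic,
                             template: PigmentTemplate, media: OcularMedia,
                             grid: WavelengthGrid = DEFAULT_GRID
                             ) -> SensitivityMosaic:
    lmax_m, lmax_l = pair
    cm = cone_fundamental(lmax_m, template, media, grid)
    cl = cone_fundamental(lmax_l, template, media, grid)
    return SensitivityMosaic((lmax_m, lmax_l), mosaic, cm.values, cl.values,
                             grid)


def quantal_catch(image: SpectralImage, C: SensitivityMosaic) -> np.ndarray:
    """Per-cone photon catch: sum over wavelength of radiance x sensitivity."""
    if image.shape[:2] != C.mosaic.shape:
        raise ValueError("image and sensitivity mosaic dims differ")
    if image.grid != C.grid:
        raise ValueError("image and sensitivity grids differ")
    qm = image.values @ C.prototype_m
    ql = image.values @ C.prototype_l
    return np.where(C.mosaic.is_l, ql, qm)


@dataclass
class ReceptiveField:
    """Difference-of-Gaussians centre-surround kernels on an Nw x Nw window."""

    sigma_c: float
    sigma_s: float
    omega: float
    nw: int
    w_on: np.ndarray
    w_off: np.ndarray


def make_receptive_fields(sigma_c: float = 0.25, sigma_s: float = 1.66,
                          omega: float = 0.55, nw: int = 9) -> ReceptiveField:
    """Build the ON-centre kernel and its exact negation.

    The centre Gaussian (sigma 0.25 cones) confines ~95% of its volume
    to the single central cone; the surround (sigma 1.66 cones) pools
    many cones non-selectively at relative weight omega. Gaussians are
    unnormalised, sampled at integer cone offsets centred on the window.
    """
    if nw % 2 != 1:
        raise ValueError("receptive-field window must have odd size")
    off = np.arange(nw) - (nw - 1) // 2
    r2 = off[:, None] ** 2 + off[None, :] ** 2
    w_on = (np.exp(-r2 / (2.0 * sigma_c ** 2))
            - omega * np.exp(-r2 / (2.0 * sigma_s ** 2)))
    return ReceptiveField(sigma_c, sigma_s, omega, nw, w_on, -w_on)


@dataclass
class RGCResponseMaps:
    """Border-trimmed ON- and OFF-centre ganglion cell response maps."""

    g_on: np.ndarray
    g_off: np.ndarray


def rgc_responses(Q: np.ndarray, rf: ReceptiveField) -> RGCResponseMaps:
    """Valid-region convolution of the catch matrix with the DoG kernels.

    The convolution window produces Nw - 1 border pixels with edge
    artefacts; using 'valid' mode removes them, leaving
    (Nx - Nw + 1) x (Ny - Nw + 1) responses. The kernels are
    even-symmetric, so convolution and correlation coincide.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape[0] < rf.nw or Q.shape[1] < rf.nw:
        raise ValueError("catch matrix smaller than the receptive-field window")
    g_on = signal.convolve(Q, rf.w_on, mode="valid")
    return RGCResponseMaps(g_on, -g_on)


@dataclass
class ConeIdentifierMasks:
    """Binary pointer matrices to L and M cones (complementary)."""

    l: np.ndarray
    m: np.ndarray


def identifier_masks(mosaic: Mosaic) -> ConeIdentifierMasks:
    l = mosaic.is_l.astype(float)
    return ConeIdentifierMasks(l, 1.0 - l)


def trim_border(arr: np.ndarray, nw: int = 9) -> np.ndarray:
    """Remove the (Nw-1)/2-pixel margin lost to the valid convolution."""
    k = (nw - 1) // 2
    return arr[k:-k, k:-k]


@dataclass
class ChannelOutput:
    """A cortical-input matrix: red-green opponent or luminance."""

    values: np.ndarray
    channel: str   # "red_green" or "luminance"


def integrate_channels(G: RGCResponseMaps, masks: ConeIdentifierMasks
                       ) -> tuple[ChannelOutput, ChannelOutput]:
    """Mask-weighted combination of ON/OFF responses into the two channels.

    Red-green: L-ON-centre plus M-OFF-centre responses (both excited by
    reddish stimuli, jointly covering the scene). Luminance: all
    ON-centre responses, which equals G_ON identically.
    """
    kx = masks.l.shape[0] - G.g_on.shape[0]
    ky = masks.l.shape[1] - G.g_on.shape[1]
    if kx != ky or kx % 2 != 0 or kx < 0:
        raise ValueError("mask and response dims are inconsistent")
    k = kx // 2
    l = masks.l[k:-k, k:-k] if k else masks.l
    m = masks.m[k:-k, k:-k] if k else masks.m
    red_green = l * G.g_on + m * G.g_off
    return (ChannelOutput(red_green, "red_green"),
            ChannelOutput(G.g_on.copy(), "luminance"))
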