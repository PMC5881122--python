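"""Scoring channel outputs and searching the space of cone peak pairs.

A candidate pair of peak sensitivities (lambda_max_M, lambda_max_L) is
scored by how faithfully the retina's channel output reproduces the
known grating reference pattern, measured as the mean peak
signal-to-noise ratio (PSNR, dB) over a database of spectral images.
An exhaustive search evaluates every pair on a grid (subject to the
constraint lambda_max_L >= lambda_max_M), repeated over independently
seeded cone mosaics, and replicate statistics summarise the optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

from .retina import (Mosaic, OcularMedia, PigmentTemplate, cone_fundamental,
                     identifier_masks, make_mosaic, make_receptive_fields,
                     trim_border)
from .scene import (LuminanceField, ReferencePattern, SceneConfig,
                    SpectralImage, assemble_image, make_grating, make_otfs,
                    synth_luminance_field)
from .spectra import DEFAULT_GRID, SpectralLibrary, Spectrum, WavelengthGrid

__all__ = [
    "SearchGrid",
    "PerformanceSurface",
    "PairScorer",
    "normalize_output",
    "psnr",
    "build_image_library",
    "score_pair",
    "exhaustive_search",
    "aggregate_optima",
    "compare_frequencies",
]

PSNR_CEILING_DB = 120.0


def normalize_output(O: np.ndarray) -> np.ndarray:
    """Min-max normalise a channel output to [0, 1].

    A spatially constant output carries no pattern information; it maps
    to 0.5 everywhere so its PSNR stays finite rather than undefined.
    """
    O = np.asarray(O, dtype=float)
    lo, hi = O.min(), O.max()
    span = hi - lo
    if span <= 1e-12 * max(1.0, abs(hi)):
        return np.full_like(O, 0.5)
    return (O - lo) / span


def psnr(o_norm: np.ndarray, reference: np.ndarray,
         ceiling: float = PSNR_CEILING_DB) -> float:
    """Peak signal-to-noise ratio in dB with peak value 1.

    PSNR = 10 log10(1 / MSE); a zero-MSE (perfect) match is capped at
    ``ceiling`` dB.
    """
    o = np.asarray(o_norm, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if o.shape != ref.shape:
        raise ValueError(f"shape mismatch: {o.shape} vs {ref.shape}")
    mse = float(np.mean((o - ref) ** 2))
    if mse <= 10.0 ** (-ceiling / 10.0):
        return ceiling
    return min(10.0 * np.log10(1.0 / mse), ceiling)


@dataclass(frozen=True)
class SearchGrid:
    """Enumerated (lambda_max_M, lambda_max_L) candidate pairs.

    ``l_values`` may be a scalar to fix the L peak. With the default
    constraint, only pairs with lambda_max_L >= lambda_max_M are kept.
    """

    m_values: tuple[float, ...]
    l_values: tuple[float, ...]
    constraint: bool = True

    @classmethod
    def from_ranges(cls, m_start, m_stop, m_step,
                    l_start=None, l_stop=None, l_step=None,
                    l_fixed=None, constraint=True) -> "SearchGrid":
        m = tuple(np.arange(m_start, m_stop + 1e-9, m_step).tolist())
        if l_fixed is not None:
            l = (float(l_fixed),)
        else:
            if l_start is None:
                l_start, l_stop, l_step = m_start, m_stop, m_step
            l = tuple(np.arange(l_start, l_stop + 1e-9, l_step).tolist())
        return cls(m, l, constraint)

    @property
    def pairs(self) -> list[tuple[float, float]]:
        out = [(m, l) for m in self.m_values for l in self.l_values
               if not self.constraint or l >= m]
        if not out:
            raise ValueError("search grid is empty after applying the constraint")
        return sorted(out)

    def __len__(self) -> int:
        return len(self.pairs)


class PairScorer:
    """Scores peak-sensitivity pairs on a fixed image database and mosaic.

    Quantal catches are cached per unique peak wavelength: for one
    mosaic, the catch at every pixel is one of two prototype inner
    products, so the full image set's catches for a pair are assembled
    from two cached stacks.
    """

    def __init__(self, images: list[SpectralImage], pattern: ReferencePattern,
                 mosaic: Mosaic, template: PigmentTemplate,
                 media: OcularMedia, psnr_ceiling: float = PSNR_CEILING_DB):
        if not images:
            raise ValueError("need at least one image")
        self.grid = images[0].grid
        self.mosaic = mosaic
        self.template = template
        self.media = media
        self.psnr_ceiling = psnr_ceiling
        self.rf = make_receptive_fields()
        self._stack = np.stack([im.values for im in images])  # (Nf,Nx,Ny,Nl)
        if self._stack.shape[1:3] != mosaic.shape:
            raise ValueError("image dims do not match the mosaic")
        self.reference = trim_border(pattern.values, self.rf.nw)
        masks = identifier_masks(mosaic)
        self._sign = trim_border(masks.l - masks.m, self.rf.nw)
        self._is_l = mosaic.is_l
        self._catch_cache: dict[float, np.ndarray] = {}

    @property
    def n_images(self) -> int:
        return self._stack.shape[0]

    def _proto_catches(self, lmax: float) -> np.ndarray:
        """(Nf, Nx, Ny) catches if every cone had peak ``lmax``."""
        key = round(float(lmax), 6)
        if key not in self._catch_cache:
            c = cone_fundamental(lmax, self.template, self.media, self.grid)
            self._catch_cache[key] = self._stack @ c.values
        return self._catch_cache[key]

    def catches(self, pair: tuple[float, float]) -> np.ndarray:
        """(Nf, Nx, Ny) mosaic quantal catches for one pair."""
        qm = self._proto_catches(pair[0])
        ql = self._proto_catches(pair[1])
        return np.where(self._is_l[None, :, :], ql, qm)

    def score(self, pair: tuple[float, float],
              channel: str = "red_green") -> float:
        """Mean PSNR (dB) of the channel output over all images."""
        if channel not in ("red_green", "luminance"):
            raise ValueError(f"unknown channel {channel!r}")
        q = self.catches(pair)
        total = 0.0
        for i in range(q.shape[0]):
            g_on = signal.convolve(q[i], self.rf.w_on, mode="valid")
            o = self._sign * g_on if channel == "red_green" else g_on
            total += psnr(normalize_output(o), self.reference,
                          self.psnr_ceiling)
        return total / q.shape[0]


def build_image_library(pattern: ReferencePattern, library: SpectralLibrary,
                        illuminant: Spectrum, config: SceneConfig,
                        rng: np.random.Generator) -> list[SpectralImage]:
    """Assemble the per-simulation database of spectral images.

    ``target_background`` pairing builds one image per library target
    against the library's background spectrum. ``draw_pairs`` draws two
    spectra per image randomly without replacement (target and
    background roles assigned in draw order). ``per_pixel_background``
    presents each target against an independent random library spectrum
    in every background pixel. Luminance fields, when enabled, are
    freshly seeded per image from ``rng``.
    """
    nx, ny = pattern.shape
    otfs = (make_otfs(library.grid, (nx, ny), config.optics)
            if config.optics is not None else None)

    def lum_field():
        if not config.luminance_variation:
            return None
        seed = int(rng.integers(0, 2 ** 31 - 1))
        return synth_luminance_field(nx, ny, seed, config.lum_contrast)

    images = []
    if config.pairing == "target_background":
        if library.background is None:
            raise ValueError("library has no background spectrum; set one "
                             "(e.g. the mean-leaf spectrum) first")
        for tgt in library.targets:
            images.append(assemble_image(pattern, tgt, library.background,
                                         illuminant, lum_field(),
                                         config.optics, otfs))
    elif config.pairing == "draw_pairs":
        n_images = config.n_images or len(library.targets)
        for _ in range(n_images):
            i, j = rng.choice(len(library.targets), size=2, replace=False)
            images.append(assemble_image(pattern, library.targets[i],
                                         library.targets[j], illuminant,
                                         lum_field(), config.optics, otfs))
    else:  # per_pixel_background
        n = len(library.targets)
        for tgt in library.targets:
            idx = rng.integers(0, n, size=(nx, ny))
            bg_stack = np.stack([s.values for s in library.targets])[idx]
            images.append(assemble_image(pattern, tgt, bg_stack, illuminant,
                                         lum_field(), config.optics, otfs))
    return images


def score_pair(pair: tuple[float, float], library: SpectralLibrary,
               config: SceneConfig, mosaic: Mosaic,
               channel: str = "red_green",
               illuminant: Spectrum | None = None,
               template: PigmentTemplate | None = None,
               media: OcularMedia | None = None,
               image_seed: int = 0) -> float:
    """Convenience wrapper: build images for one mosaic and score one pair."""
    grid = library.grid
    if illuminant is None:
        illuminant = Spectrum(grid, np.ones(grid.n), role="illuminant",
                              label="flat")
    template = template or PigmentTemplate()
    media = media or OcularMedia.human(grid)
    pattern = make_grating(config.spatial_frequency, config.ny)
    rng = np.random.default_rng(image_seed)
    images = build_image_library(pattern, library, illuminant, config, rng)
    scorer = PairScorer(images, pattern, mosaic, template, media)
    return scorer.score(pair, channel)


@dataclass
class PerformanceSurface:
    """Replicate-averaged scores for every pair plus per-seed optima."""

    grid: SearchGrid
    pairs: list[tuple[float, float]]
    z_per_seed: np.ndarray          # (n_seeds, n_pairs), dB
    seeds: list[int]
    channel: str
    argmax_records: list[dict]      # per seed: pair, z, tie flag

    @property
    def z_mean(self) -> np.ndarray:
        return self.z_per_seed.mean(axis=0)

    @property
    def best_pair(self) -> tuple[float, float]:
        """Pair with the highest replicate-mean score (ties -> shortest)."""
        return self.pairs[int(np.argmax(self.z_mean))]

    @property
    def optimal_m_per_seed(self) -> np.ndarray:
        return np.array([r["pair"][0] for r in self.argmax_records])

    @property
    def optimal_l_per_seed(self) -> np.ndarray:
        return np.array([r["pair"][1] for r in self.argmax_records])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (pair, seed)."""
        rows = []
        for si, seed in enumerate(self.seeds):
            for pi, (m, l) in enumerate(self.pairs):
                rows.append({"lambda_max_m": m, "lambda_max_l": l,
                             "seed": seed, "channel": self.channel,
                             "z": self.z_per_seed[si, pi]})
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _argmax_with_ties(pairs: list[tuple[float, float]],
                      z: np.ndarray) -> tuple[int, bool]:
    """Index of the best score; ties go to the shortest wavelengths.

    ``pairs`` is sorted ascending, so the first occurrence of the
    maximum is the shortest-wavelength winner.
    """
    best = int(np.argmax(z))
    tie = bool(np.sum(np.isclose(z, z[best], rtol=0, atol=1e-12)) > 1)
    return best, tie


def exhaustive_search(grid: SearchGrid, library: SpectralLibrary,
                      config: SceneConfig, seeds: list[int],
                      illuminant: Spectrum | None = None,
                      template: PigmentTemplate | None = None,
                      media: OcularMedia | None = None,
                      channel: str = "red_green",
                      cached_images: list | None = None) -> PerformanceSurface:
    """Score every candidate pair across independently seeded mosaics.

    For each seed a fresh mosaic is drawn and (unless a shared cached
    image list is supplied) a fresh image database is built, so run-to-
    run variation reflects both the mosaic arrangement and the per-image
    luminance fields. Per-seed argmax records use shortest-wavelength
    tie-breaking and carry a tie flag.
    """
    pairs = grid.pairs
    sgrid = library.grid
    if illuminant is None:
        illuminant = Spectrum(sgrid, np.ones(sgrid.n), role="illuminant",
                              label="flat")
    template = template or PigmentTemplate()
    media = media or OcularMedia.human(sgrid)
    pattern = make_grating(config.spatial_frequency, config.ny)
    nx, ny = pattern.shape

    z = np.empty((len(seeds), len(pairs)))
    records = []
    for si, seed in enumerate(seeds):
        ss = np.random.SeedSequence(seed)
        mosaic_seed, image_seed = (int(c.generate_state(1)[0] % (2 ** 31))
                                   for c in ss.spawn(2))
        mosaic = make_mosaic(nx, ny, 0.5, mosaic_seed)
        if cached_images is not None:
            images = cached_images
        else:
            rng = np.random.default_rng(image_seed)
            images = build_image_library(pattern, library, illuminant,
                                         config, rng)
        scorer = PairScorer(images, pattern, mosaic, template, media)
        for pi, pair in enumerate(pairs):
            z[si, pi] = scorer.score(pair, channel)
        best, tie = _argmax_with_ties(pairs, z[si])
        records.append({"seed": seed, "pair": pairs[best],
                        "z": float(z[si, best]), "tie": tie})
    return PerformanceSurface(grid, pairs, z, list(seeds), channel, records)


def aggregate_optima(surface: PerformanceSurface,
                     ci_z: float = 1.96) -> dict:
    """Mean, SD, and normal-theory 95% CI of the per-seed optimal M peak."""
    m = surface.optimal_m_per_seed
    n = m.size
    mean = float(m.mean())
    sd = float(m.std(ddof=1)) if n > 1 else 0.0
    half = ci_z * sd / np.sqrt(n) if n > 1 else 0.0
    return {
        "n": int(n),
        "mean": mean,
        "sd": sd,
        "ci_low": mean - half,
        "ci_high": mean + half,
        "n_ties": int(sum(r["tie"] for r in surface.argmax_records)),
        "optimal_l_mean": float(surface.optimal_l_per_seed.mean()),
    }


def compare_frequencies(optima_a, optima_b,
                        equal_var: bool = False) -> tuple[float, float]:
    """Two-sample t-test (Welch by default) on per-seed optimal M peaks."""
    a = np.asarray(optima_a, dtype=float)
    b = np.asarray(optima_b, dtype=float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate: no within-group variance
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
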