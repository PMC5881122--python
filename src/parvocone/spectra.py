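"""Spectral containers and synthetic reflectance/illuminant generation.

Everything downstream of this module works on a single shared wavelength
grid: by default 400-700 nm sampled every 4 nm (76 samples), the range
relevant to primate photopic vision. A :class:`Spectrum` is a nonnegative
vector on that grid with a *role* (reflectance, illuminant, radiance, or
sensitivity); a :class:`SpectralLibrary` bundles many spectra of one
provenance, optionally together with a designated background spectrum.

The synthetic generators stand in for measured datasets of natural
spectra: a "fruit" family dominated by long-pass (red/orange/yellow)
reflectance edges, a tight "leaf" family of chlorophyll-type curves
peaking in the green, a "munsell" family of smooth, spectrally diverse
surface colours, and a broad greenish forest-shade illuminant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "SpectralLibrary",
    "DEFAULT_GRID",
    "read_spectra",
    "mean_background",
    "apply_illuminant",
    "synth_spectra",
    "total_variation",
]

ROLES = ("reflectance", "illuminant", "radiance", "sensitivity")


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength sampling grid in nanometres.

    The default covers 400-700 nm at 4 nm steps, giving 76 samples.
    """

    start: float = 400.0
    stop: float = 700.0
    step: float = 4.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("wavelength step must be positive")
        if self.stop <= self.start:
            raise ValueError("stop must exceed start")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("grid span must be an integer number of steps")

    @property
    def values(self) -> np.ndarray:
        """Sampling positions, inclusive of both endpoints."""
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    @property
    def n(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n


DEFAULT_GRID = WavelengthGrid()


@dataclass
class Spectrum:
    """A nonnegative spectral vector on a :class:`WavelengthGrid`.

    Reflectances are dimensionless in [0, 1] (a small tolerance above 1
    accommodates measurement noise; such values are clipped). Illuminants
    and radiances are in relative quantal units.
    """

    grid: WavelengthGrid
    values: np.ndarray
    role: str = "reflectance"
    label: str = ""
    reflectance_tolerance: float = 0.05

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != self.grid.n:
            raise ValueError(
                f"spectrum length {v.size} does not match grid length {self.grid.n}"
            )
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if v.min() < -1e-12:
            raise ValueError("spectrum values must be nonnegative")
        v = np.clip(v, 0.0, None)
        if self.role == "reflectance":
            if v.max() > 1.0 + self.reflectance_tolerance:
                raise ValueError(
                    f"reflectance exceeds 1 beyond tolerance (max={v.max():.4f})"
                )
            v = np.minimum(v, 1.0)
        self.values = v

    def copy(self, **changes) -> "Spectrum":
        kw = dict(grid=self.grid, values=self.values.copy(), role=self.role,
                  label=self.label)
        kw.update(changes)
        return Spectrum(**kw)


@dataclass
class SpectralLibrary:
    """A collection of target spectra plus an optional background spectrum."""

    targets: list[Spectrum]
    background: Spectrum | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.targets) < 1:
            raise ValueError("a spectral library needs at least one spectrum")
        grid = self.targets[0].grid
        for s in self.targets:
            if s.grid != grid:
                raise ValueError("all library spectra must share one grid")
        if self.background is not None and self.background.grid != grid:
            raise ValueError("background grid differs from target grid")

    @property
    def grid(self) -> WavelengthGrid:
        return self.targets[0].grid

    def __len__(self) -> int:
        return len(self.targets)

    def to_frame(self) -> pd.DataFrame:
        """Wide-format table: wavelength column plus one column per spectrum."""
        data = {"wavelength": self.grid.values}
        for k, s in enumerate(self.targets):
            data[s.label or f"s{k}"] = s.values
        return pd.DataFrame(data)

    def save(self, path: str | Path) -> None:
        """Write spectra as CSV with a JSON manifest alongside."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        manifest = {
            "provenance": self.provenance,
            "n_spectra": len(self),
            "roles": sorted({s.role for s in self.targets}),
            "grid": {"start": self.grid.start, "stop": self.grid.stop,
                     "step": self.grid.step},
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def resample(wavelengths: np.ndarray, values: np.ndarray,
             grid: WavelengthGrid = DEFAULT_GRID) -> np.ndarray:
    """Linearly interpolate a measured spectrum onto the target grid.

    A spectrum already sampled on the grid is returned unchanged (the
    interpolation is exact at the nodes).
    """
    return np.interp(grid.values, wavelengths, values)


def read_spectra(path: str | Path, dialect: str = "wide",
                 grid: WavelengthGrid = DEFAULT_GRID,
                 role: str = "reflectance") -> SpectralLibrary:
    """Read delimited-text spectra and resample them onto ``grid``.

    The expected layout ("wide" dialect) is a header row of labels, a
    first column of wavelengths in nm, and one column per spectrum.
    Wavelengths must be strictly increasing and must cover the full grid
    range; values are clipped at 0 after interpolation.
    """
    path = Path(path)
    if dialect != "wide":
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path.name}: need a wavelength column and >=1 spectrum")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError(f"{path.name}: wavelength column must be strictly increasing")
    if wl[0] > grid.start or wl[-1] < grid.stop:
        raise ValueError(
            f"{path.name}: wavelengths cover [{wl[0]:g}, {wl[-1]:g}] nm but the "
            f"grid requires [{grid.start:g}, {grid.stop:g}] nm"
        )
    targets = []
    for col in df.columns[1:]:
        v = np.clip(resample(wl, df[col].to_numpy(dtype=float), grid), 0.0, None)
        targets.append(Spectrum(grid, v, role=role, label=str(col)))
    return SpectralLibrary(targets, provenance=str(path))


def mean_background(library: SpectralLibrary) -> Spectrum:
    """Pointwise arithmetic mean of all spectra in the library.

    Used to form the fixed background (e.g. the mean of all mature-leaf
    reflectances) against which every target is presented.
    """
    stack = np.stack([s.values for s in library.targets])
    return Spectrum(library.grid, stack.mean(axis=0),
                    role=library.targets[0].role, label="mean_background")


def apply_illuminant(s: Spectrum, i: Spectrum) -> Spectrum:
    """Element-wise product of a reflectance and an illuminant -> radiance."""
    if s.grid != i.grid:
        raise ValueError("spectrum and illuminant grids differ")
    return Spectrum(s.grid, s.values * i.values, role="radiance",
                    label=s.label)


def total_variation(s: Spectrum | np.ndarray) -> float:
    """Sum of absolute first differences; a smoothness measure."""
    v = s.values if isinstance(s, Spectrum) else np.asarray(s)
    return float(np.abs(np.diff(v)).sum())


# ---------------------------------------------------------------------------
# Synthetic spectra
# ---------------------------------------------------------------------------

_FRUIT_DEFAULTS = dict(
    edge_range=(500.0, 640.0),    # logistic inflection, nm
    width_range=(8.0, 20.0),      # logistic width, nm
    amp_range=(0.15, 0.55),       # long-wavelength plateau reflectance
    base_range=(0.02, 0.08),      # short-wavelength pedestal
    green_fraction=0.25,          # unripe/green/cryptic fruits
    dark_fraction=0.10,           # dark (e.g. purple/black) fruits
)

_LEAF_DEFAULTS = dict(
    pedestal_range=(0.03, 0.05),
    bump_amp_range=(0.08, 0.15),
    bump_centre_range=(542.0, 558.0),  # chlorophyll green peak, nm
    bump_sigma_range=(28.0, 38.0),
    red_edge_amp_range=(0.03, 0.06),   # onset of the far-red rise
)

_MUNSELL_DEFAULTS = dict(
    n_basis=6,
    basis_sigma=55.0,
    coef_sigma=1.2,
    lo=0.04,
    hi=0.95,
)

_ILLUM_DEFAULTS = dict(
    centre=560.0,
    breadth=150.0,
    green_bias=0.6,        # canopy-filtered light is green-dominated
    green_sigma=50.0,
)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _synth_fruit(n, rng, lam, p):
    kinds = rng.choice(
        ["edge", "green", "dark"], size=n,
        p=[1 - p["green_fraction"] - p["dark_fraction"],
           p["green_fraction"], p["dark_fraction"]])
    out = np.empty((n, lam.size))
    for k, kind in enumerate(kinds):
        if kind == "edge":
            lam0 = rng.uniform(*p["edge_range"])
            w = rng.uniform(*p["width_range"])
            amp = rng.uniform(*p["amp_range"])
            base = rng.uniform(*p["base_range"])
            out[k] = base + amp * _logistic((lam - lam0) / w)
        elif kind == "green":
            ped = rng.uniform(0.02, 0.06)
            amp = rng.uniform(0.15, 0.35)
            mu = rng.uniform(530.0, 560.0)
            sig = rng.uniform(25.0, 40.0)
            out[k] = ped + amp * np.exp(-0.5 * ((lam - mu) / sig) ** 2)
        else:  # dark
            level = rng.uniform(0.02, 0.08)
            tilt = rng.uniform(0.0, 0.03)
            out[k] = level + tilt * (lam - lam[0]) / (lam[-1] - lam[0])
    return out, kinds


def _synth_leaf(n, rng, lam, p):
    out = np.empty((n, lam.size))
    for k in range(n):
        ped = rng.uniform(*p["pedestal_range"])
        amp = rng.uniform(*p["bump_amp_range"])
        mu = rng.uniform(*p["bump_centre_range"])
        sig = rng.uniform(*p["bump_sigma_range"])
        red = rng.uniform(*p["red_edge_amp_range"])
        out[k] = (ped
                  + amp * np.exp(-0.5 * ((lam - mu) / sig) ** 2)
                  + red * _logistic((lam - 695.0) / 6.0))
    return out


def _synth_munsell(n, rng, lam, p):
    centres = np.linspace(lam[0] + 10, lam[-1] - 10, p["n_basis"])
    basis = np.exp(-0.5 * ((lam[None, :] - centres[:, None])
                           / p["basis_sigma"]) ** 2)
    coefs = rng.normal(0.0, p["coef_sigma"], size=(n, p["n_basis"]))
    offset = rng.normal(0.0, 0.8, size=(n, 1))
    z = offset + coefs @ basis
    return p["lo"] + (p["hi"] - p["lo"]) * _logistic(z)


def _synth_illuminant(n, rng, lam, p):
    out = np.empty((n, lam.size))
    for k in range(n):
        centre = p["centre"] + rng.normal(0.0, 5.0)
        bias = max(0.0, p["green_bias"] + rng.normal(0.0, 0.05))
        base = np.exp(-0.5 * ((lam - centre) / p["breadth"]) ** 2)
        canopy = 1.0 + bias * np.exp(-0.5 * ((lam - 550.0) / p["green_sigma"]) ** 2)
        v = base * canopy
        out[k] = v / v.mean()
    return out


def synth_spectra(family: str, n: int, seed: int,
                  params: dict | None = None,
                  grid: WavelengthGrid = DEFAULT_GRID) -> SpectralLibrary:
    """Generate a reproducible synthetic spectral library.

    Parameters
    ----------
    family
        One of ``fruit``, ``leaf``, ``munsell``, ``illuminant``.
    n
        Number of spectra to generate (>= 1).
    seed
        Seed for the generator; identical arguments give bit-identical
        libraries.
    params
        Optional overrides of the family's default parameters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lam = grid.values
    defaults = {"fruit": _FRUIT_DEFAULTS, "leaf": _LEAF_DEFAULTS,
                "munsell": _MUNSELL_DEFAULTS, "illuminant": _ILLUM_DEFAULTS}
    if family not in defaults:
        raise ValueError(f"unknown spectral family {family!r}")
    p = dict(defaults[family])
    if params:
        p.update(params)

    labels = None
    if family == "fruit":
        values, kinds = _synth_fruit(n, rng, lam, p)
        labels = [f"fruit_{kind}_{k}" for k, kind in enumerate(kinds)]
        role = "reflectance"
    elif family == "leaf":
        values = _synth_leaf(n, rng, lam, p)
        role = "reflectance"
    elif family == "munsell":
        values = _synth_munsell(n, rng, lam, p)
        role = "reflectance"
    else:
        values = _synth_illuminant(n, rng, lam, p)
        role = "illuminant"

    if role == "reflectance":
        values = np.clip(values, 0.0, 1.0)
    if labels is None:
        labels = [f"{family}_{k}" for k in range(n)]
    targets = [Spectrum(grid, values[k], role=role, label=labels[k])
               for k in range(n)]
    return SpectralLibrary(targets, provenance=f"synthetic:{family}:seed={seed}")
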