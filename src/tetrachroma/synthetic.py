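"""Synthetic inputs: species parameter sets, illuminants, carotenoid
libraries, and noisy droplet observations.

The generator emulates the structure of the study inputs — violet- (VS)
and ultraviolet-sensitive (UVS) avian visual systems, a seven-component
retinal carotenoid library, and microspectrophotometric absorbance traces
of expanded C-type oil droplets — so every pipeline stage is testable
without measured data.  Every output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral_core import DEFAULT_GRID, Spectrum, WavelengthGrid, gompertz_longpass

__all__ = [
    "GeneratorConfig",
    "PureLibrary",
    "make_species_params",
    "make_pure_spectra",
    "make_droplet_observation",
    "standard_illuminant",
    "synthetic_ocular_media",
    "SPECIES_COLUMNS",
]

# CIE standard illuminant D65, relative spectral power (energy units),
# 300-700 nm at 5 nm, from the public CIE tabulation.
_D65_WL = np.arange(300.0, 701.0, 5.0)
_D65_SPD = np.array([
    0.0341, 1.6643, 3.2945, 11.7652, 20.2360, 28.6447, 37.0535, 38.5011,
    39.9488, 42.4302, 44.9117, 45.7750, 46.6383, 49.3637, 52.0891, 51.0323,
    49.9755, 52.3118, 54.6482, 68.7015, 82.7549, 87.1204, 91.4860, 92.4589,
    93.4318, 90.0570, 86.6823, 95.7736, 104.865, 110.936, 117.008, 117.410,
    117.812, 116.336, 114.861, 115.392, 115.923, 112.367, 108.811, 109.082,
    109.354, 108.578, 107.802, 106.296, 104.790, 106.239, 107.689, 106.047,
    104.405, 104.225, 104.046, 102.023, 100.000, 98.1671, 96.3342, 96.0611,
    95.7880, 92.2368, 88.6856, 89.3459, 90.0062, 89.8026, 89.5991, 88.6489,
    87.6987, 85.4936, 83.2886, 83.4939, 83.6992, 81.8630, 80.0268, 80.1207,
    80.2146, 81.2462, 82.2778, 80.2810, 78.2842, 74.0027, 69.7213, 70.6652,
    71.6091,
])

SPECIES_COLUMNS = [
    "species", "class", "sws1_lmax", "sws2_lmax", "mws_lmax", "lws_lmax",
    "c_cut", "c_bmid", "y_cut", "y_bmid", "r_cut", "r_bmid",
    "ocular_media_file", "ocular_cut",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration for the synthetic-data generator (seed mandatory)."""

    seed: int
    n_species: int = 18
    noise_sd: float = 0.01  # absorbance units on droplet observations
    class_mix: float = 0.5  # fraction of UVS species

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.class_mix <= 1.0):
            raise ValueError("class_mix must lie in [0, 1]")


def make_species_params(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a species visual-system parameter table.

    Pigment λmax values are drawn uniformly from the ranges spanned by
    published avian microspectrophotometry: SWS1 355–375 nm (UVS) or
    402–426 nm (VS), SWS2 440–475, MWS 497–510, LWS 543–571.  The C-type
    droplet cutoff tracks SWS1 tuning linearly (VS species filter near
    457 nm, UVS near 425 nm) with 4 nm jitter, reproducing the observed
    positive SWS1–λcut correlation.  UVS ocular media cut on shorter
    wavelengths than VS.
    """
    if config.n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(config.seed)
    n_uvs = int(round(config.n_species * config.class_mix))
    classes = ["UVS"] * n_uvs + ["VS"] * (config.n_species - n_uvs)
    rows = []
    for i, cls in enumerate(classes):
        if cls == "UVS":
            sws1 = rng.uniform(355.0, 375.0)
            ocular_cut = rng.uniform(318.0, 330.0)
        else:
            sws1 = rng.uniform(402.0, 426.0)
            ocular_cut = rng.uniform(340.0, 355.0)
        # class-appropriate C-cut: ~425 nm at SWS1 365 (UVS), ~457 at 414 (VS)
        c_cut = 187.75 + 0.65 * sws1 + rng.normal(0.0, 4.0)
        rows.append({
            "species": f"synth_{cls.lower()}_{i:02d}",
            "class": cls,
            "sws1_lmax": round(sws1, 1),
            "sws2_lmax": round(rng.uniform(440.0, 475.0), 1),
            "mws_lmax": round(rng.uniform(497.0, 510.0), 1),
            "lws_lmax": round(rng.uniform(543.0, 571.0), 1),
            "c_cut": round(float(np.clip(c_cut, 370.0, 500.0)), 1),
            "c_bmid": round(rng.uniform(0.07, 0.09), 3),
            "y_cut": round(rng.uniform(505.0, 516.0), 1),
            "y_bmid": round(rng.uniform(0.07, 0.09), 3),
            "r_cut": round(rng.uniform(558.0, 572.0), 1),
            "r_bmid": round(rng.uniform(0.07, 0.09), 3),
            "ocular_media_file": "",
            "ocular_cut": round(ocular_cut, 1),
        })
    return pd.DataFrame(rows, columns=SPECIES_COLUMNS)


@dataclass(frozen=True)
class PureLibrary:
    """Library of unit-peak pure carotenoid absorbance spectra."""

    names: tuple[str, ...]
    spectra: tuple[Spectrum, ...]

    def __post_init__(self) -> None:
        if len(self.names) < 2 or len(self.names) != len(self.spectra):
            raise ValueError("library needs >= 2 named components")
        grid = self.spectra[0].grid
        if any(s.grid != grid for s in self.spectra):
            raise ValueError("library spectra must share one grid")

    @property
    def grid(self) -> WavelengthGrid:
        return self.spectra[0].grid

    def matrix(self) -> np.ndarray:
        """Component spectra stacked as columns, shape (n_wavelengths, n)."""
        return np.column_stack([s.values for s in self.spectra])


# (name, peak nm, vibronic structure?) for the seven-component retinal
# library; galloxanthin/dihydrogalloxanthin peaks at 402/380 nm, the keto
# carotenoids are single broad bands, the rest spread over 440-505 nm.
_PURE_COMPONENTS = (
    ("dihydrogalloxanthin", 380.0, True),
    ("galloxanthin", 402.0, True),
    ("apo1", 440.0, True),
    ("lutein", 455.0, True),
    ("zeaxanthin", 470.0, True),
    ("canthaxanthin", 485.0, False),
    ("astaxanthin", 505.0, False),
)


def _vibronic_curve(peak: float, wavelengths: np.ndarray, fine: bool) -> np.ndarray:
    """Three-Gaussian vibronic envelope (main peak + ~1400 cm⁻¹ side
    bands) or a single broad band for keto carotenoids."""
    lam = np.asarray(wavelengths, float)
    if not fine:
        return np.exp(-(((lam - peak) / 42.0) ** 2))
    # side bands offset by ~1400 cm^-1 in wavenumber
    nu0 = 1.0e7 / peak
    lo = 1.0e7 / (nu0 + 1400.0)
    hi = 1.0e7 / (nu0 - 1400.0)
    curve = (
        np.exp(-(((lam - peak) / 14.0) ** 2))
        + 0.72 * np.exp(-(((lam - lo) / 12.0) ** 2))
        + 0.60 * np.exp(-(((lam - hi) / 17.0) ** 2))
    )
    return curve


def make_pure_spectra(
    config: GeneratorConfig, grid: WavelengthGrid = DEFAULT_GRID
) -> PureLibrary:
    """Seven-component synthetic pure-spectrum library, unit-peak each."""
    names, spectra = [], []
    for name, peak, fine in _PURE_COMPONENTS:
        v = _vibronic_curve(peak, grid.wavelengths, fine)
        spectra.append(Spectrum(grid, v / v.max()))
        names.append(name)
    return PureLibrary(names=tuple(names), spectra=tuple(spectra))


def make_droplet_observation(
    weights, library: PureLibrary, config: GeneratorConfig, draw: int = 0
) -> Spectrum:
    """Noisy additive mixture Σ wⱼ·pureⱼ + N(0, noise_sd), clipped at 0.

    ``draw`` indexes independent observations under one config seed.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(library.names),):
        raise ValueError("one weight per library component required")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(weights > 0) and config.noise_sd == 0:
        raise ValueError("all-zero weights with zero noise is degenerate")
    clean = library.matrix() @ weights
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, draw]))
    noisy = clean + rng.normal(0.0, config.noise_sd, size=clean.shape)
    return Spectrum(library.grid, np.clip(noisy, 0.0, None))


def standard_illuminant(
    kind: str = "d65", grid: WavelengthGrid = DEFAULT_GRID
) -> Spectrum:
    """Normalized illuminant photon spectrum j(λ) with max 1.

    ``d65`` interpolates the embedded CIE table (converted from energy to
    photon units by multiplying by λ); ``flat`` is equal photon flux;
    ``green_foliage`` is d65 filtered by a fixed chlorophyll-like
    transmission curve peaking near 550 nm.
    """
    lam = grid.wavelengths
    if kind == "flat":
        return Spectrum.constant(1.0, grid)
    if kind == "d65":
        spd = np.interp(lam, _D65_WL, _D65_SPD)
        photons = spd * lam
        return Spectrum(grid, photons / photons.max())
    if kind == "green_foliage":
        d65 = standard_illuminant("d65", grid)
        leaf = 0.12 + 0.88 * np.exp(-(((lam - 550.0) / 55.0) ** 2))
        v = d65.values * leaf
        return Spectrum(grid, v / v.max())
    raise ValueError(f"unknown illuminant kind {kind!r}")


def synthetic_ocular_media(
    cutoff_nm: float, grid: WavelengthGrid = DEFAULT_GRID, b_mid: float = 0.1
) -> Spectrum:
    """Sigmoidal UV-cutoff ocular-media transmittance (Gompertz form)."""
    return Spectrum(grid, gompertz_longpass(cutoff_nm, b_mid, grid.wavelengths))
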