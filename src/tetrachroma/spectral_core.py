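"""Wavelength grids and the component spectra of avian cone sensitivity.

An avian single-cone's spectral sensitivity is the pointwise product of
three factors: the visual-pigment absorbance ``v(λ)`` (an A1 rhodopsin
nomogram), the transmittance of the carotenoid-pigmented oil droplet
``p(λ)`` (a long-pass cutoff filter), and the transmittance of the ocular
media ``o(λ)``.  All spectra here are sampled functions of wavelength on a
shared, evenly spaced grid; integrals over λ use the trapezoid rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "OilDropletSpec",
    "ReceptorSpec",
    "DEFAULT_GRID",
    "DEFAULT_B_MID",
    "make_grid",
    "pigment_absorbance",
    "govardovskii_a1",
    "droplet_transmittance",
    "gompertz_longpass",
    "receptor_sensitivity",
    "resample",
]

#: Default droplet slope when a species table omits it (1/nm).
DEFAULT_B_MID = 0.08


@dataclass(frozen=True)
class WavelengthGrid:
    """Evenly spaced closed wavelength grid, ``min_nm`` to at most ``max_nm``."""

    min_nm: float
    max_nm: float
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")
        if self.min_nm >= self.max_nm:
            raise ValueError(
                f"inverted bounds: min_nm={self.min_nm} >= max_nm={self.max_nm}"
            )

    @property
    def n_samples(self) -> int:
        return int(math.floor((self.max_nm - self.min_nm) / self.step_nm + 1e-9)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.min_nm + self.step_nm * np.arange(self.n_samples)

    def __len__(self) -> int:
        return self.n_samples


def make_grid(min_nm: float, max_nm: float, step_nm: float = 1.0) -> WavelengthGrid:
    """Build an evenly spaced wavelength grid (closed at ``min_nm``)."""
    return WavelengthGrid(min_nm, max_nm, step_nm)


#: The paper-standard visible range for birds, 300-700 nm at 1 nm.
DEFAULT_GRID = WavelengthGrid(300.0, 700.0, 1.0)


@dataclass(frozen=True)
class Spectrum:
    """A sampled function of wavelength (sensitivity, transmittance,
    absorbance, or photon radiance) on a :class:`WavelengthGrid`."""

    grid: WavelengthGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.grid.n_samples,):
            raise ValueError(
                f"values length {values.shape} does not match grid "
                f"({self.grid.n_samples} samples)"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("spectrum contains non-finite values")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def at(self, lambda_nm: float) -> float:
        """Linearly interpolated value at ``lambda_nm`` (must lie in span)."""
        w = self.wavelengths
        if not (w[0] <= lambda_nm <= w[-1]):
            raise ValueError(f"{lambda_nm} nm outside spectrum span [{w[0]}, {w[-1]}]")
        return float(np.interp(lambda_nm, w, self.values))

    def integral(self) -> float:
        """Trapezoid-rule integral over the full grid."""
        return float(np.trapezoid(self.values, self.wavelengths))

    def __mul__(self, other: "Spectrum | float") -> "Spectrum":
        if isinstance(other, Spectrum):
            if other.grid != self.grid:
                raise ValueError("grid mismatch in spectrum product; resample first")
            return Spectrum(self.grid, self.values * other.values)
        return Spectrum(self.grid, self.values * float(other))

    __rmul__ = __mul__

    @classmethod
    def constant(cls, value: float, grid: WavelengthGrid = DEFAULT_GRID) -> "Spectrum":
        return cls(grid, np.full(grid.n_samples, float(value)))


def resample(spectrum: Spectrum, grid: WavelengthGrid) -> Spectrum:
    """Linear interpolation of ``spectrum`` onto ``grid`` (no extrapolation)."""
    src = spectrum.wavelengths
    if grid.min_nm < src[0] - 1e-9 or grid.max_nm > src[-1] + 1e-9:
        raise ValueError(
            f"target grid [{grid.min_nm}, {grid.max_nm}] extends beyond source "
            f"span [{src[0]}, {src[-1]}]"
        )
    return Spectrum(grid, np.interp(grid.wavelengths, src, spectrum.values))


@dataclass(frozen=True)
class OilDropletSpec:
    """Long-pass cutoff filter of a cone oil droplet.

    ``lambda_cut`` is the x-intercept of the tangent to the transmittance
    curve at its mid-slope point λ_mid; with the Gompertz parameterisation
    used here λ_mid = λ_cut + 1/b_mid.  ``lambda_cut=None`` encodes a
    transparent (T-type) droplet.
    """

    lambda_cut: float | None
    b_mid: float = DEFAULT_B_MID

    def __post_init__(self) -> None:
        if self.b_mid <= 0:
            raise ValueError(f"b_mid must be positive, got {self.b_mid}")
        if self.lambda_cut is not None and not (300.0 <= self.lambda_cut <= 700.0):
            raise ValueError(f"lambda_cut {self.lambda_cut} outside [300, 700] nm")

    @property
    def transparent(self) -> bool:
        return self.lambda_cut is None

    @classmethod
    def clear(cls) -> "OilDropletSpec":
        return cls(lambda_cut=None)


@dataclass(frozen=True)
class ReceptorSpec:
    """One avian single cone: pigment λmax, oil droplet, and ocular media."""

    name: str
    pigment_lambda_max: float
    droplet: OilDropletSpec = field(default_factory=OilDropletSpec.clear)
    ocular_media: Spectrum | None = None  # None -> perfectly transmissive

    def __post_init__(self) -> None:
        if not (300.0 <= self.pigment_lambda_max <= 700.0):
            raise ValueError(
                f"pigment lambda_max {self.pigment_lambda_max} outside [300, 700] nm"
            )


def govardovskii_a1(lambda_max: float, wavelengths: np.ndarray) -> np.ndarray:
    """A1 visual-pigment nomogram (alpha plus beta band), unnormalized.

    The alpha band is the standard four-exponential template in
    x = λmax/λ with A=69.7, B=28, C=-14.9, D=0.674, b=0.922, c=1.104 and
    a = 0.8795 + 0.0459·exp(−(λmax−300)²/11940); the beta band is a
    Gaussian at λmβ = 189 + 0.315·λmax with bandwidth −40.5 + 0.195·λmax
    and amplitude 0.26.
    """
    lam = np.asarray(wavelengths, dtype=float)
    x = lambda_max / lam
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lmb = 189.0 + 0.315 * lambda_max
    bb = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((lam - lmb) / bb) ** 2))
    return alpha + beta


def pigment_absorbance(
    lambda_max: float,
    grid: WavelengthGrid = DEFAULT_GRID,
    template: Callable[[float, np.ndarray], np.ndarray] = govardovskii_a1,
) -> Spectrum:
    """Unit-peak visual-pigment absorbance curve from an A1 template.

    The curve is renormalized so its maximum sample equals 1; with the
    default template that maximum falls within one grid step of
    ``lambda_max``.
    """
    w = grid.wavelengths
    if not (w[0] <= lambda_max <= w[-1]):
        raise ValueError(f"lambda_max {lambda_max} outside grid span [{w[0]}, {w[-1]}]")
    values = template(lambda_max, w)
    return Spectrum(grid, values / values.max())


def gompertz_longpass(
    lambda_cut: float, b_mid: float, wavelengths: np.ndarray
) -> np.ndarray:
    """Gompertz long-pass transmittance T(λ)=exp(−exp(−b_mid(λ−λ_mid))),
    λ_mid = λ_cut + 1/b_mid (tangent-intercept definition of λ_cut)."""
    lam_mid = lambda_cut + 1.0 / b_mid
    return np.exp(-np.exp(-b_mid * (np.asarray(wavelengths, float) - lam_mid)))


def droplet_transmittance(
    droplet: OilDropletSpec, grid: WavelengthGrid = DEFAULT_GRID
) -> Spectrum:
    """Oil-droplet transmittance on ``grid``; transparent droplets pass all."""
    if droplet.transparent:
        return Spectrum.constant(1.0, grid)
    return Spectrum(
        grid, gompertz_longpass(droplet.lambda_cut, droplet.b_mid, grid.wavelengths)
    )


def receptor_sensitivity(
    receptor: ReceptorSpec, grid: WavelengthGrid = DEFAULT_GRID
) -> Spectrum:
    """Cone spectral sensitivity R(λ) = v(λ)·p(λ)·o(λ)."""
    r = pigment_absorbance(receptor.pigment_lambda_max, grid) * droplet_transmittance(
        receptor.droplet, grid
    )
    if receptor.ocular_media is not None:
        om = receptor.ocular_media
        if om.grid != grid:
            om = resample(om, grid)
        r = r * om
    return r
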