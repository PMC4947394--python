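"""Receptor-noise-limited increment spectral sensitivity.

A monochromatic test light of intensity I_t at wavelength λ is detected
against a large adapting background I_b when the chromatic contrast ΔS
between test-plus-background and background reaches 1 just-noticeable
difference.  Receptor signals enter as relative catch differences
Δqᵢ = Rᵢ(λ)·I_t / ∫Rᵢ·I_b dλ, and ΔS is the standard RNL combination of
the pairwise Δq differences weighted by the receptor Weber fractions
ωᵢ = vᵢ/√ηᵢ (noise-to-signal ratio over the square root of relative cone
abundance).  Because Δq is linear in I_t, the threshold is closed-form:
I_t* = 1/ΔS(I_t=1), and sensitivity = 1/I_t* = ΔS(I_t=1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral_core import DEFAULT_GRID, Spectrum, WavelengthGrid
from .species import Species
from .synthetic import standard_illuminant

__all__ = [
    "DEFAULT_ABUNDANCES",
    "OMEGA_LWS",
    "IncrementModel",
    "ThresholdSpectrum",
    "weber_from_abundance",
    "weber_set",
    "delta_q",
    "chromatic_contrast",
    "threshold_intensity",
    "sensitivity_spectrum",
    "mismatch_experiment",
]

#: Relative cone abundances SWS1:SWS2:MWS:LWS.
DEFAULT_ABUNDANCES = (1.0, 2.0, 2.0, 4.0)

#: The Weber fraction of the LWS mechanism that anchors the noise scale.
OMEGA_LWS = 0.05

#: Background calibration: LWS background catch (photons), bright anchor.
DEFAULT_LWS_BACKGROUND_CATCH = 1.0e5


def weber_from_abundance(v: float, eta: float) -> float:
    """ω = v/√η: spatial summation over η cones divides the noise-to-
    signal ratio v by √η."""
    if v <= 0 or eta <= 0:
        raise ValueError("noise-to-signal ratio and abundance must be positive")
    return v / math.sqrt(eta)


def weber_set(
    abundances=DEFAULT_ABUNDANCES, omega_anchor: float = OMEGA_LWS
) -> np.ndarray:
    """Weber fractions for all cones, anchored at ω = 0.05 for the most
    abundant (last, LWS) class: v = ω_LWS·√η_LWS, ωᵢ = v/√ηᵢ."""
    eta = np.asarray(abundances, dtype=float)
    v = omega_anchor * math.sqrt(eta[-1])
    return np.array([weber_from_abundance(v, e) for e in eta])


@dataclass(frozen=True)
class IncrementModel:
    """Receptors, adapting background, and noise terms for the model."""

    sensitivities: tuple[Spectrum, ...]
    background: Spectrum  # photon radiance I_b(λ), absolute scale
    omega: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "omega", np.asarray(self.omega, dtype=float))
        if len(self.omega) != len(self.sensitivities):
            raise ValueError("one Weber fraction per receptor required")
        if np.any(self.omega <= 0):
            raise ValueError("Weber fractions must be positive")
        if any(s.grid != self.background.grid for s in self.sensitivities):
            raise ValueError("sensitivities and background must share a grid")

    @property
    def grid(self) -> WavelengthGrid:
        return self.background.grid

    @property
    def background_catches(self) -> np.ndarray:
        q = np.array([(R * self.background).integral() for R in self.sensitivities])
        if np.any(q <= 0):
            raise ValueError("a receptor catches no light from the background")
        return q

    @classmethod
    def for_species(
        cls,
        species: Species,
        grid: WavelengthGrid = DEFAULT_GRID,
        c_cut_override: float | None = None,
        background_kind: str = "d65",
        lws_background_catch: float = DEFAULT_LWS_BACKGROUND_CATCH,
        abundances=DEFAULT_ABUNDANCES,
    ) -> "IncrementModel":
        """Model for a species on a daylight background scaled so the LWS
        cone's background catch equals ``lws_background_catch``."""
        from .spectral_core import receptor_sensitivity

        shape = standard_illuminant(background_kind, grid)
        sens = tuple(
            receptor_sensitivity(r, grid)
            for r in species.receptors(grid, c_cut_override)
        )
        q_lws = (sens[-1] * shape).integral()
        background = Spectrum(grid, shape.values * (lws_background_catch / q_lws))
        return cls(sensitivities=sens, background=background, omega=weber_set(abundances))


def delta_q(
    receptor: Spectrum, test_lambda: float, I_t: float, background: Spectrum
) -> float:
    """Relative catch difference Δq = R(λ_t)·I_t / ∫R·I_b dλ."""
    denom = (receptor * background).integral()
    if denom <= 0:
        raise ValueError("receptor catches no light from the background")
    return receptor.at(test_lambda) * I_t / denom


def chromatic_contrast(dq: np.ndarray, omega: np.ndarray) -> float:
    """RNL chromatic contrast ΔS in JND units for n receptor channels.

    (ΔS)² = Σ_{i<j} (∏_{k∉{i,j}} ω_k)²·(Δq_j−Δq_i)²
            / Σ_i (∏_{k≠i} ω_k)².

    For n = 4 this is exactly the tetrachromatic opponent-free form with
    six pairwise terms over four triple-product weights; only Δq
    differences enter, so a common offset leaves ΔS unchanged.
    """
    dq = np.asarray(dq, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if dq.shape[-1] != omega.shape[0]:
        raise ValueError("Δq and ω must have one entry per receptor")
    if np.any(omega == 0):
        raise ValueError("zero Weber fraction")
    n = omega.shape[0]
    idx = list(range(n))
    num = 0.0
    for i, j in itertools.combinations(idx, 2):
        w = np.prod([omega[k] for k in idx if k not in (i, j)])
        num = num + w**2 * (dq[..., j] - dq[..., i]) ** 2
    den = sum(
        np.prod([omega[k] for k in idx if k != i]) ** 2 for i in idx
    )
    return np.sqrt(num / den)


@dataclass(frozen=True)
class ThresholdSpectrum:
    """Increment thresholds and their reciprocal sensitivity per λ.

    Wavelengths where the Δq vector is achromatic (all channels equal)
    are undetectable through the chromatic mechanism; they are flagged in
    ``detectable`` and carry no threshold value, never a sentinel number.
    """

    grid: WavelengthGrid
    threshold_intensity: np.ndarray
    sensitivity: np.ndarray
    detectable: np.ndarray
    configuration: str = "matched"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "wavelength_nm": self.grid.wavelengths,
            "threshold": np.where(self.detectable, self.threshold_intensity, np.nan),
            "sensitivity": self.sensitivity,
            "detectable": self.detectable,
            "configuration": self.configuration,
        })


def threshold_intensity(
    model: IncrementModel, test_lambda: float
) -> tuple[float | None, bool]:
    """Smallest I_t with ΔS = 1 at ``test_lambda``.

    ΔS is homogeneous of degree 1 in I_t, so I_t* = 1/ΔS(I_t=1).
    Returns (threshold, detectable); threshold is None when the test
    light produces no chromatic signal.
    """
    dq = np.array(
        [delta_q(R, test_lambda, 1.0, model.background) for R in model.sensitivities]
    )
    ds = float(chromatic_contrast(dq, model.omega))
    if ds <= 0.0:
        return None, False
    return 1.0 / ds, True


def sensitivity_spectrum(
    model: IncrementModel, configuration: str = "matched"
) -> ThresholdSpectrum:
    """Increment threshold and sensitivity at every grid wavelength.

    Vectorized over wavelength: ΔS at unit test intensity equals the
    sensitivity, and the threshold is its reciprocal.
    """
    R = np.column_stack([s.values for s in model.sensitivities])  # (nλ, n)
    dq = R / model.background_catches[None, :]
    ds = chromatic_contrast(dq, model.omega)  # (nλ,)
    detectable = ds > 0
    with np.errstate(divide="ignore"):
        thr = np.where(detectable, 1.0 / np.where(detectable, ds, 1.0), 0.0)
    return ThresholdSpectrum(
        grid=model.grid,
        threshold_intensity=thr,
        sensitivity=ds,
        detectable=detectable,
        configuration=configuration,
    )


def mismatch_experiment(
    species: Species,
    alternate_c_cut: float,
    grid: WavelengthGrid = DEFAULT_GRID,
    **model_kwargs,
) -> tuple[ThresholdSpectrum, ThresholdSpectrum]:
    """Paired (matched, mismatched) sensitivity spectra.

    The mismatched configuration replaces the species' C-type droplet
    cutoff with ``alternate_c_cut`` (typically the value typical of the
    opposite visual-system class); background and noise parameters are
    identical in both runs.
    """
    matched = sensitivity_spectrum(
        IncrementModel.for_species(species, grid, **model_kwargs), "matched"
    )
    mismatched = sensitivity_spectrum(
        IncrementModel.for_species(
            species, grid, c_cut_override=alternate_c_cut, **model_kwargs
        ),
        "mismatched",
    )
    return matched, mismatched
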