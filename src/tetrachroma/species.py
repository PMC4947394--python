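"""Species visual-system records: one table row to a VisualSystem.

A species is described by the λmax of its four single-cone pigments, the
cutoffs and slopes of its C-, Y- and R-type oil droplets (the SWS1 cone's
T-type droplet is transparent), and its ocular-media transmittance
(measured file or synthetic sigmoidal UV cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .color_solid import VisualSystem
from .spectral_core import (
    DEFAULT_B_MID,
    DEFAULT_GRID,
    OilDropletSpec,
    ReceptorSpec,
    Spectrum,
    WavelengthGrid,
)
from .synthetic import standard_illuminant, synthetic_ocular_media

__all__ = ["Species", "RECEPTOR_NAMES"]

RECEPTOR_NAMES = ("SWS1", "SWS2", "MWS", "LWS")

# fallback ocular-media UV cutoffs (nm) when neither a measured spectrum
# nor an explicit cutoff is supplied
_OCULAR_CUT_BY_CLASS = {"UVS": 324.0, "VS": 348.0}


@dataclass(frozen=True)
class Species:
    """Visual-system parameters of one species."""

    name: str
    species_class: str  # "VS" | "UVS"
    sws1_lmax: float
    sws2_lmax: float
    mws_lmax: float
    lws_lmax: float
    c_cut: float
    c_bmid: float = DEFAULT_B_MID
    y_cut: float = 510.0
    y_bmid: float = DEFAULT_B_MID
    r_cut: float = 565.0
    r_bmid: float = DEFAULT_B_MID
    ocular_media: Spectrum | None = None
    ocular_cut: float | None = None

    def __post_init__(self) -> None:
        if self.species_class not in ("VS", "UVS"):
            raise ValueError(f"species class must be VS or UVS, got {self.species_class}")

    def ocular_spectrum(self, grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
        if self.ocular_media is not None:
            return self.ocular_media
        cut = self.ocular_cut
        if cut is None:
            cut = _OCULAR_CUT_BY_CLASS[self.species_class]
        return synthetic_ocular_media(cut, grid)

    def receptors(
        self,
        grid: WavelengthGrid = DEFAULT_GRID,
        c_cut_override: float | None = None,
    ) -> tuple[ReceptorSpec, ...]:
        """The four single-cone receptor specs, optionally with the C-type
        droplet cutoff replaced (the knob of the filtering sweep)."""
        om = self.ocular_spectrum(grid)
        c_cut = self.c_cut if c_cut_override is None else c_cut_override
        return (
            ReceptorSpec("SWS1", self.sws1_lmax, OilDropletSpec.clear(), om),
            ReceptorSpec("SWS2", self.sws2_lmax, OilDropletSpec(c_cut, self.c_bmid), om),
            ReceptorSpec("MWS", self.mws_lmax, OilDropletSpec(self.y_cut, self.y_bmid), om),
            ReceptorSpec("LWS", self.lws_lmax, OilDropletSpec(self.r_cut, self.r_bmid), om),
        )

    def visual_system(
        self,
        illuminant: Spectrum | None = None,
        grid: WavelengthGrid = DEFAULT_GRID,
        c_cut_override: float | None = None,
        **kwargs,
    ) -> VisualSystem:
        if illuminant is None:
            illuminant = standard_illuminant("d65", grid)
        return VisualSystem.from_receptors(
            self.receptors(illuminant.grid, c_cut_override), illuminant, **kwargs
        )

    def with_c_cut(self, c_cut: float) -> "Species":
        return replace(self, c_cut=c_cut)
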