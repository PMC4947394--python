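import numpy as np
import pytest

from tetrachroma.color_solid import VisualSystem
from tetrachroma.species import Species
from tetrachroma.spectral_core import Spectrum, make_grid
from tetrachroma.synthetic import GeneratorConfig, make_pure_spectra


@pytest.fixture(scope="session")
def grid():
    return make_grid(300, 700, 1)


@pytest.fixture(scope="session")
def flat(grid):
    return Spectrum.constant(1.0, grid)


@pytest.fixture(scope="session")
def rect(grid):
    """Factory for rectangular (top-hat) sensitivity spectra."""

    def _rect(lo, hi, height=1.0):
        v = ((grid.wavelengths >= lo) & (grid.wavelengths <= hi)).astype(float)
        return Spectrum(grid, v * height)

    return _rect


@pytest.fixture(scope="session")
def cube_system(rect, flat):
    """Four disjoint rectangular receptors under a flat illuminant whose
    object-color solid is exactly the unit 4-cube (supports strictly
    inside 100 nm transition bins)."""
    sens = (rect(310, 390), rect(410, 490), rect(510, 590), rect(610, 690))
    return VisualSystem(sensitivities=sens, illuminant=flat)


@pytest.fixture(scope="session")
def uvs_species():
    return Species(
        name="synthetic-uvs", species_class="UVS", sws1_lmax=365.0,
        sws2_lmax=455.0, mws_lmax=505.0, lws_lmax=560.0, c_cut=425.0,
        ocular_cut=324.0,
    )


@pytest.fixture(scope="session")
def vs_species():
    return Species(
        name="synthetic-vs", species_class="VS", sws1_lmax=414.0,
        sws2_lmax=455.0, mws_lmax=505.0, lws_lmax=560.0, c_cut=457.0,
        ocular_cut=348.0,
    )


@pytest.fixture(scope="session")
def pure_library():
    return make_pure_spectra(GeneratorConfig(seed=42))
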