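import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetrachroma.increment import (
    IncrementModel,
    chromatic_contrast,
    delta_q,
    mismatch_experiment,
    sensitivity_spectrum,
    threshold_intensity,
    weber_from_abundance,
    weber_set,
)
from tetrachroma.spectral_core import Spectrum


class TestWeberFromAbundance:
    def test_lws_anchor(self):
        # v recovered from the LWS anchor: 0.05 * sqrt(4) = 0.1
        assert weber_from_abundance(0.1, 4.0) == pytest.approx(0.05)

    def test_full_avian_set(self):
        w = weber_set()
        assert w == pytest.approx([0.1, 0.1 / np.sqrt(2), 0.1 / np.sqrt(2), 0.05])

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            weber_from_abundance(0.0, 4.0)
        with pytest.raises(ValueError):
            weber_from_abundance(0.1, -1.0)


class TestDeltaQ:
    def test_zero_and_linear_in_test_intensity(self, rect, flat):
        R = rect(400, 500)
        assert delta_q(R, 450.0, 0.0, flat) == 0.0
        one = delta_q(R, 450.0, 1.0, flat)
        assert delta_q(R, 450.0, 2.0, flat) == pytest.approx(2 * one)

    def test_rectangular_receptor_analytic(self, rect, flat):
        # Δq = I_t * R(λ_t) / bandwidth for a top-hat on a flat background
        # (trapezoid rule adds half a grid step at each edge: 101 nm)
        R = rect(400, 500)
        assert delta_q(R, 450.0, 5.0, flat) == pytest.approx(5.0 / 101.0, rel=1e-9)

    def test_blind_receptor_rejected(self, grid, flat):
        with pytest.raises(ValueError):
            delta_q(Spectrum.constant(0.0, grid), 450.0, 1.0, flat)


class TestChromaticContrast:
    OMEGA = weber_set()

    def test_achromatic_signal_is_zero(self):
        assert chromatic_contrast(np.full(4, 0.3), self.OMEGA) == pytest.approx(0.0)

    def test_frozen_literal_transcription_value(self):
        """Frozen from a term-by-term transcription of the printed
        six-pair/four-triple tetrachromatic contrast formula."""
        ds = chromatic_contrast(np.array([1.0, 0.0, 0.0, 0.0]), self.OMEGA)
        assert ds == pytest.approx(9.428090415820632, rel=1e-12)

    @given(scale=st.floats(0.01, 100), offset=st.floats(-5, 5))
    @settings(max_examples=30, deadline=None)
    def test_homogeneous_and_offset_invariant(self, scale, offset):
        dq = np.array([0.4, 0.1, -0.2, 0.05])
        base = chromatic_contrast(dq, self.OMEGA)
        assert chromatic_contrast(dq * scale, self.OMEGA) == pytest.approx(
            scale * base, rel=1e-9
        )
        assert chromatic_contrast(dq + offset, self.OMEGA) == pytest.approx(
            base, rel=1e-9
        )

    def test_dichromat_limit_is_finite(self):
        # two mechanisms drowned in noise: contrast degenerates gracefully
        omega = np.array([0.1, 0.05, 1e6, 1e6])
        ds = chromatic_contrast(np.array([0.5, 0.0, 0.2, 0.1]), omega)
        assert np.isfinite(ds) and ds > 0

    def test_zero_weber_rejected(self):
        with pytest.raises(ValueError):
            chromatic_contrast(np.zeros(4), np.array([0.0, 0.1, 0.1, 0.1]))


@pytest.fixture(scope="module")
def uvs_model(uvs_species):
    return IncrementModel.for_species(uvs_species)


class TestThreshold:
    def test_closed_form_equals_bisection(self, uvs_model):
        thr, ok = threshold_intensity(uvs_model, 420.0)
        assert ok
        # oracle: bisection on ΔS(I_t) − 1
        from tetrachroma.increment import delta_q as dq_fn

        def ds_at(it):
            dq = np.array([
                dq_fn(R, 420.0, it, uvs_model.background)
                for R in uvs_model.sensitivities
            ])
            return chromatic_contrast(dq, uvs_model.omega)

        lo, hi = 0.0, 1e12
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if ds_at(mid) < 1.0:
                lo = mid
            else:
                hi = mid
        assert thr == pytest.approx(0.5 * (lo + hi), rel=1e-9)

    def test_halving_weber_doubles_contrast_and_halves_threshold(self, uvs_species):
        m1 = IncrementModel.for_species(uvs_species)
        m2 = IncrementModel(
            sensitivities=m1.sensitivities, background=m1.background,
            omega=m1.omega / 2,
        )
        t1, _ = threshold_intensity(m1, 430.0)
        t2, _ = threshold_intensity(m2, 430.0)
        assert t2 == pytest.approx(t1 / 2, rel=1e-9)


class TestSensitivitySpectrum:
    def test_sensitivity_is_reciprocal_threshold(self, uvs_model):
        ts = sensitivity_spectrum(uvs_model)
        ok = ts.detectable
        assert np.allclose(ts.sensitivity[ok], 1.0 / ts.threshold_intensity[ok])

    def test_background_scale_shifts_thresholds_proportionally(self, uvs_model):
        scaled = IncrementModel(
            sensitivities=uvs_model.sensitivities,
            background=uvs_model.background * 3.0,
            omega=uvs_model.omega,
        )
        t1 = sensitivity_spectrum(uvs_model)
        t2 = sensitivity_spectrum(scaled)
        ok = t1.detectable
        assert np.allclose(
            t2.threshold_intensity[ok], 3.0 * t1.threshold_intensity[ok], rtol=1e-9
        )

    def test_vs_typical_droplet_depresses_uvs_400_450_band(self, uvs_species):
        matched, mismatched = mismatch_experiment(uvs_species, 457.0)
        lam = matched.grid.wavelengths
        band = (lam >= 400) & (lam <= 450)
        ratio = mismatched.sensitivity[band] / matched.sensitivity[band]
        assert ratio.min() < 0.5  # a deep spectral notch appears


class TestMismatchExperiment:
    def test_own_droplet_gives_identical_pair(self, uvs_species):
        matched, mismatched = mismatch_experiment(uvs_species, uvs_species.c_cut)
        assert np.array_equal(matched.sensitivity, mismatched.sensitivity)

    def test_pair_shares_grid_and_background(self, uvs_species):
        m1, m2 = mismatch_experiment(uvs_species, 457.0)
        assert m1.grid == m2.grid
        assert m1.configuration == "matched" and m2.configuration == "mismatched"

    def test_uvs_to_vs_swap_is_more_damaging_than_reverse(
        self, uvs_species, vs_species
    ):
        m_u, mm_u = mismatch_experiment(uvs_species, vs_species.c_cut)
        m_v, mm_v = mismatch_experiment(vs_species, uvs_species.c_cut)
        lam = m_u.grid.wavelengths
        band = (lam >= 400) & (lam <= 450)
        full = lam >= 320
        uvs_drop = (m_u.sensitivity[band] / mm_u.sensitivity[band]).max()
        vs_change = np.abs(
            np.log(mm_v.sensitivity[full] / m_v.sensitivity[full])
        ).max()
        assert uvs_drop > np.exp(vs_change)

    def test_lcut_perturbation_changes_thresholds_continuously(self, uvs_species):
        m0, m1 = mismatch_experiment(uvs_species, uvs_species.c_cut + 1.0)
        ok = m0.detectable & m1.detectable
        rel = np.abs(
            np.log(m1.threshold_intensity[ok] / m0.threshold_intensity[ok])
        )
        assert rel.max() < 0.2
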