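import math

import numpy as np
import pytest

from tetrachroma.color_solid import (
    NoiseRegime,
    VisualSystem,
    build_color_solid,
    count_colors_qspace,
    discriminable_colors,
    normalize_receptors,
    optimal_color_stimuli,
    quantum_catch,
    receptor_noise,
    shape_factor,
)
from tetrachroma.spectral_core import Spectrum, pigment_absorbance
from tetrachroma.synthetic import standard_illuminant


class TestQuantumCatch:
    def test_integral_of_ones(self, flat):
        assert quantum_catch(flat, flat, flat) == pytest.approx(400.0)

    def test_zero_reflectance(self, grid, flat):
        zero = Spectrum.constant(0.0, grid)
        assert quantum_catch(flat, zero, flat) == 0.0

    def test_matches_independent_quadrature(self, grid):
        R = pigment_absorbance(560.0, grid)
        d65 = standard_illuminant("d65", grid)
        expected = np.trapezoid(R.values * d65.values, grid.wavelengths)
        assert quantum_catch(R, Spectrum.constant(1.0, grid), d65) == pytest.approx(
            expected
        )


class TestNormalizeReceptors:
    def test_r_spectra_integrate_to_one(self, cube_system):
        k, r = normalize_receptors(
            cube_system.sensitivities, cube_system.illuminant
        )
        for ri in r:
            assert (ri * cube_system.illuminant).integral() == pytest.approx(
                1.0, abs=1e-9
            )
        assert k[-1] == pytest.approx(1.0)

    def test_k_ratio_equals_bandwidth_ratio(self, rect, flat):
        # rectangles covering 80 nm vs 160 nm of a flat illuminant
        k, _ = normalize_receptors([rect(310, 390), rect(510, 670)], flat)
        # trapezoid edges add half a step to each top-hat
        assert k[0] / k[1] == pytest.approx(81.0 / 161.0, rel=1e-9)

    def test_blind_receptor_rejected(self, rect, flat, grid):
        with pytest.raises(ValueError, match="catch no light"):
            normalize_receptors([Spectrum.constant(0.0, grid), rect(310, 390)], flat)


class TestOptimalColorStimuli:
    def test_three_bins_all_patterns(self):
        pats = optimal_color_stimuli(3, 3)
        assert len(pats) == 8
        assert len(np.unique(pats, axis=0)) == 8

    def test_counts_match_brute_force(self):
        # 4 bins, <=1 transition: brute-force over all 16 patterns
        def transitions(p):
            return int(np.sum(np.abs(np.diff(p))))

        brute = [
            p
            for p in (np.array([(i >> b) & 1 for b in range(4)]) for i in range(16))
            if transitions(p) <= 1
        ]
        pats = optimal_color_stimuli(4, 1)
        assert len(pats) == len(brute) == 8

    def test_zero_transitions_black_and_white_only(self):
        pats = optimal_color_stimuli(7, 0)
        assert len(pats) == 2
        assert {tuple(p) for p in pats.astype(int)} == {(0,) * 7, (1,) * 7}


class TestReceptorNoise:
    def test_dark_noise_independent_of_signal(self):
        assert receptor_noise(0.0, NoiseRegime.VERY_DIM, dark=50) == 50.0
        assert receptor_noise(1e6, NoiseRegime.VERY_DIM, dark=50) == 50.0

    def test_shot_noise_is_sqrt(self):
        assert receptor_noise(100.0, NoiseRegime.DIM) == pytest.approx(10.0)

    def test_bright_combines_shot_and_weber(self):
        # sqrt(100 + 0.1^2 * 100^2) = sqrt(200)
        assert receptor_noise(100.0, NoiseRegime.BRIGHT, omega=0.1) == pytest.approx(
            math.sqrt(200.0)
        )

    def test_bright_approaches_weber_form_at_high_catch(self):
        q = 1e12
        assert receptor_noise(q, NoiseRegime.BRIGHT, omega=0.1) == pytest.approx(
            0.1 * q, rel=1e-4
        )

    def test_negative_catch_rejected(self):
        with pytest.raises(ValueError):
            receptor_noise(-1.0, NoiseRegime.DIM)


class TestColorSolidGeometry:
    def test_disjoint_rectangles_fill_the_unit_cube(self, cube_system):
        solid = build_color_solid(cube_system, resolution=100.0)
        assert solid.volume == pytest.approx(1.0, rel=1e-6)
        assert np.allclose(solid.x_max, 1.0)
        assert solid.contains(np.zeros((1, 4)))[0]  # black apex
        assert solid.contains(np.ones((1, 4)))[0]  # white apex

    def test_identical_receptors_are_degenerate(self, rect, flat):
        s = rect(400, 500)
        system = VisualSystem(
            sensitivities=(s, s), illuminant=flat, weber=(0.1, 0.1),
            dark_noise=(50.0, 50.0),
        )
        with pytest.raises(ValueError, match="degenerate"):
            build_color_solid(system, resolution=50.0)

    def test_images_of_bin_reflectances_lie_inside(self, uvs_species):
        system = uvs_species.visual_system()
        solid = build_color_solid(system, resolution=20.0)
        rng = np.random.default_rng(7)
        S = rng.random((500, solid.generators.shape[1]))
        x = S @ solid.generators.T
        assert solid.contains(x).all()

    def test_convexity_midpoints_achievable(self, uvs_species):
        system = uvs_species.visual_system()
        solid = build_color_solid(system, resolution=20.0)
        rng = np.random.default_rng(11)
        idx = rng.integers(0, len(solid.extreme_points), size=(200, 2))
        mids = solid.extreme_points[idx].mean(axis=1)
        assert solid.contains(mids).all()


class TestShapeFactor:
    def test_unit_cube_very_dim_is_one(self, cube_system):
        solid = build_color_solid(cube_system, resolution=100.0)
        G, se = shape_factor(solid, NoiseRegime.VERY_DIM, cube_system, 100_000, seed=1)
        assert abs(G - 1.0) <= 3 * se

    def test_unit_cube_dim_is_sixteen(self, cube_system):
        solid = build_color_solid(cube_system, resolution=100.0)
        G, se = shape_factor(solid, NoiseRegime.DIM, cube_system, 100_000, seed=1)
        assert abs(G - 16.0) <= max(3 * se, 1e-9)

    def test_unit_square_dim_matches_grid_quadrature(self, rect, flat):
        system = VisualSystem(
            sensitivities=(rect(310, 490), rect(510, 690)), illuminant=flat,
            weber=(0.1, 0.1), dark_noise=(50.0, 50.0),
        )
        solid = build_color_solid(system, resolution=100.0)
        G, se = shape_factor(solid, NoiseRegime.DIM, system, 50_000, seed=2)
        # deterministic quadrature of the separable (xy)^(-1/2) integrand
        from scipy.integrate import quad

        one_d, _ = quad(lambda u: u**-0.5, 0.0, 1.0)
        assert abs(G - one_d**2) <= max(3 * se, 1e-6)

    def test_overlapping_two_receptor_mc_matches_quadrature(self, rect, flat):
        """MC shape factor vs deterministic 2-D grid quadrature on an
        overlapping-receptor toy (non-trivial solid geometry)."""
        system = VisualSystem(
            sensitivities=(rect(310, 530), rect(410, 690)), illuminant=flat,
            weber=(0.1, 0.1), dark_noise=(50.0, 50.0),
        )
        solid = build_color_solid(system, resolution=20.0)
        G, se = shape_factor(solid, NoiseRegime.VERY_DIM, system, 60_000, seed=3)
        # quadrature: area of the zonotope via dense membership on a grid
        u = (np.arange(250) + 0.5) / 250
        X, Y = np.meshgrid(u * solid.x_max[0], u * solid.x_max[1])
        pts = np.column_stack([X.ravel(), Y.ravel()])
        area = solid.contains(pts).mean() * solid.x_max.prod()
        assert abs(G - area) <= 3 * se + 0.01

    def test_permutation_of_receptors_leaves_G_invariant(self, rect, flat):
        a, b = rect(310, 530), rect(410, 690)
        s1 = VisualSystem(sensitivities=(a, b), illuminant=flat,
                          weber=(0.1, 0.1), dark_noise=(50.0, 50.0))
        s2 = VisualSystem(sensitivities=(b, a), illuminant=flat,
                          weber=(0.1, 0.1), dark_noise=(50.0, 50.0))
        G1, se1 = shape_factor(build_color_solid(s1, 20.0), NoiseRegime.VERY_DIM,
                               s1, 50_000, seed=4)
        G2, se2 = shape_factor(build_color_solid(s2, 20.0), NoiseRegime.VERY_DIM,
                               s2, 50_000, seed=5)
        assert abs(G1 - G2) <= 3 * (se1 + se2)

    def test_wider_receptor_separation_increases_very_dim_G(self, rect, flat):
        near = VisualSystem(sensitivities=(rect(310, 530), rect(350, 570)),
                            illuminant=flat, weber=(0.1, 0.1),
                            dark_noise=(50.0, 50.0))
        far = VisualSystem(sensitivities=(rect(310, 530), rect(470, 690)),
                           illuminant=flat, weber=(0.1, 0.1),
                           dark_noise=(50.0, 50.0))
        Gn, sen = shape_factor(build_color_solid(near, 20.0), NoiseRegime.VERY_DIM,
                               near, 40_000, seed=6)
        Gf, sef = shape_factor(build_color_solid(far, 20.0), NoiseRegime.VERY_DIM,
                               far, 40_000, seed=6)
        assert Gf > Gn + 3 * (sen + sef)


class TestDiscriminableColors:
    def test_very_dim_toy_count_closed_form(self, cube_system):
        # unit 4-cube, T=10, k=1, d=50: N = 10^4 / 50^4 = 0.0016
        solid = build_color_solid(cube_system, resolution=100.0)
        res = discriminable_colors(
            cube_system, NoiseRegime.VERY_DIM, solid=solid, T=10.0, seed=1
        )
        assert res.N == pytest.approx(1e4 / 50**4, rel=0.02)

    @pytest.mark.parametrize(
        "regime,factor",
        [(NoiseRegime.VERY_DIM, 16.0), (NoiseRegime.DIM, 4.0)],
    )
    def test_doubling_T_scales_N_exactly(self, uvs_species, regime, factor):
        system = uvs_species.visual_system()
        solid = build_color_solid(system, resolution=16.0)
        n1 = discriminable_colors(system, regime, solid=solid, T=100.0,
                                  n_samples=20_000, seed=9).N
        n2 = discriminable_colors(system, regime, solid=solid, T=200.0,
                                  n_samples=20_000, seed=9).N
        assert n2 / n1 == pytest.approx(factor, rel=1e-12)

    def test_bright_reduces_to_dim_as_weber_vanishes(self, uvs_species):
        system = uvs_species.visual_system()
        tiny = VisualSystem(
            sensitivities=system.sensitivities, illuminant=system.illuminant,
            weber=(1e-9,) * 4, dark_noise=system.dark_noise,
        )
        solid = build_color_solid(tiny, resolution=16.0)
        nb = discriminable_colors(tiny, NoiseRegime.BRIGHT, solid=solid,
                                  T=100.0, n_samples=20_000, seed=12)
        nd = discriminable_colors(tiny, NoiseRegime.DIM, solid=solid,
                                  T=100.0, n_samples=20_000, seed=12)
        assert nb.N == pytest.approx(nd.N, rel=1e-6)

    def test_identical_seed_reproduces_result_exactly(self, uvs_species):
        system = uvs_species.visual_system()
        solid = build_color_solid(system, resolution=16.0)
        r1 = discriminable_colors(system, NoiseRegime.BRIGHT, solid=solid,
                                  n_samples=10_000, seed=33)
        r2 = discriminable_colors(system, NoiseRegime.BRIGHT, solid=solid,
                                  n_samples=10_000, seed=33)
        assert r1.N == r2.N and r1.G == r2.G and r1.mc_error == r2.mc_error

    def test_qspace_route_agrees_with_shape_factor_route(self, uvs_species):
        """Counting colors directly in quantum-catch space validates the
        radical reconstruction of the shape-factor formulas."""
        system = uvs_species.visual_system()
        solid = build_color_solid(system, resolution=16.0)
        for regime in NoiseRegime:
            res = discriminable_colors(system, regime, solid=solid,
                                       n_samples=40_000, seed=5)
            nq, seq = count_colors_qspace(system, regime, solid,
                                          n_samples=40_000, seed=17)
            assert abs(res.N - nq) <= 3 * math.hypot(res.mc_error, seq)
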