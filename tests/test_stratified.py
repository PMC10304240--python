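"""Thin-film optics: Fresnel limits, conservation, oracles."""

import numpy as np
import pytest

from mitolens.stratified import (
    Layer,
    StratifiedStack,
    layer_matrix,
    reflectance_grid,
    refraction_chain,
    stack_rt,
    stack_rt_arrays,
)


def airy_recursion(stack, theta0, wavelength, polarization):
    """Independent oracle: recursive Fresnel (Airy) summation.

    r_j at each interface combined backwards:
    r = (r01 + r' e^{2 i beta}) / (1 + r01 r' e^{2 i beta}).
    """
    ns = [stack.n_incident] + [l.n for l in stack.layers] + [stack.n_substrate]
    ds = [l.d for l in stack.layers]
    s0 = stack.n_incident * np.sin(theta0)
    cos = [np.sqrt(1 - (s0 / n) ** 2 + 0j) for n in ns]

    def r_interface(i):
        n1, n2, c1, c2 = ns[i], ns[i + 1], cos[i], cos[i + 1]
        if polarization == "s":
            return (n1 * c1 - n2 * c2) / (n1 * c1 + n2 * c2)
        return (n2 / c2 - n1 / c1) / (n2 / c2 + n1 / c1) * (-1)

    r = r_interface(len(ds))
    k0 = 2 * np.pi / wavelength
    for j in range(len(ds) - 1, -1, -1):
        beta = k0 * ns[j + 1] * ds[j] * cos[j + 1]
        rj = r_interface(j)
        # e^{-2i beta} matches the characteristic-matrix phase convention
        e = np.exp(-2j * beta)
        r = (rj + r * e) / (1 + rj * r * e)
    return r


class TestFresnelLimits:
    def test_normal_incidence_sign_convention(self):
        res = stack_rt(StratifiedStack(1.0, (), 1.5), 0.0, 550.0, "s")
        assert res.r == pytest.approx(-0.2, abs=1e-12)
        assert res.R == pytest.approx(0.04, abs=1e-12)

    def test_brewster_null_for_p(self):
        st = StratifiedStack(1.0, (), 1.5)
        res = stack_rt(st, np.arctan(1.5), 550.0, "p")
        assert res.R <= 1e-10

    def test_s_equals_p_at_normal_incidence(self, rng):
        layers = tuple(Layer(rng.uniform(1, 2), rng.uniform(1, 150)) for _ in range(4))
        st = StratifiedStack(1.2, layers, 1.6)
        rs = stack_rt(st, 0.0, 500.0, "s")
        rp = stack_rt(st, 0.0, 500.0, "p")
        assert rs.R == pytest.approx(rp.R, abs=1e-12)
        assert rs.T == pytest.approx(rp.T, abs=1e-12)

    def test_tir_at_dense_to_rare_interface(self):
        res = stack_rt(StratifiedStack(1.48, (), 1.33), np.deg2rad(80), 550.0, "s")
        assert res.tir and res.R == 1.0 and res.T == 0.0


class TestLayerMatrix:
    def test_zero_thickness_is_identity(self):
        st = StratifiedStack(1.33, (Layer(1.5, 0.0),), 1.33)
        ch = refraction_chain(st, 0.3, 550.0)
        m = layer_matrix(Layer(1.5, 0.0), ch, "s")
        assert m.m11 == pytest.approx(1) and m.m22 == pytest.approx(1)
        assert abs(m.m12) < 1e-15 and abs(m.m21) < 1e-15

    def test_quarter_wave_closed_form(self):
        lam, n = 550.0, 1.38
        d = lam / (4 * n)
        st = StratifiedStack(1.33, (Layer(n, d),), 1.33)
        ch = refraction_chain(st, 0.0, lam)
        m = layer_matrix(Layer(n, d), ch, "s")
        gamma = n  # n cos(0)
        assert abs(m.m11) < 1e-12 and abs(m.m22) < 1e-12
        assert m.m12 == pytest.approx(1j / gamma, abs=1e-12)
        assert m.m21 == pytest.approx(1j * gamma, abs=1e-12)

    @pytest.mark.parametrize("theta_deg", [0.0, 25.0, 60.0, 85.0])
    def test_determinant_unity(self, theta_deg, rng):
        layers = tuple(Layer(rng.uniform(1, 2), rng.uniform(0, 200)) for _ in range(5))
        st = StratifiedStack(1.33, layers, 1.48)
        ch = refraction_chain(st, np.deg2rad(theta_deg), 600.0)
        m = None
        for layer in layers:
            lm = layer_matrix(layer, ch, "p")
            assert abs(lm.determinant - 1) < 1e-10
            m = lm if m is None else m @ lm
        assert abs(m.determinant - 1) < 1e-9


class TestRefractionChain:
    def test_index_matched_keeps_angle(self):
        st = StratifiedStack(1.4, (Layer(1.4, 50.0),), 1.4)
        ch = refraction_chain(st, 0.7, 550.0)
        assert ch.cos_layers[0] == pytest.approx(np.cos(0.7))
        assert not ch.tir

    def test_substrate_evanescent_beyond_critical(self):
        st = StratifiedStack(1.48, (), 1.33)
        ch = refraction_chain(st, np.deg2rad(80.0), 550.0)
        assert ch.tir
        assert ch.cos_substrate.imag > 0

    def test_normal_incidence_all_zero(self):
        st = StratifiedStack(1.33, (Layer(1.7, 10.0),), 1.48)
        ch = refraction_chain(st, 0.0, 550.0)
        assert ch.cos_layers[0] == pytest.approx(1.0)
        assert ch.cos_substrate == pytest.approx(1.0)


class TestConservationAndSymmetry:
    def test_energy_conservation_random_stacks(self, rng):
        """R + T = 1 to 1e-9 on random lossless stacks below TIR."""
        for _ in range(400):
            nl = int(rng.integers(0, 6))
            layers = tuple(Layer(rng.uniform(1, 2), rng.uniform(0, 200)) for _ in range(nl))
            st = StratifiedStack(rng.uniform(1, 2), layers, rng.uniform(1, 2))
            crit = np.arcsin(min(st.n_substrate / st.n_incident, 1.0))
            theta = rng.uniform(0, 0.98 * crit)
            for pol in ("s", "p"):
                res = stack_rt(st, theta, rng.uniform(350, 900), pol)
                assert not res.tir
                assert res.R + res.T == pytest.approx(1.0, abs=1e-9)

    def test_adjacent_equal_layers_merge(self):
        a = StratifiedStack(1.33, (Layer(1.5, 40.0), Layer(1.5, 60.0), Layer(1.7, 10.0)), 1.48)
        b = StratifiedStack(1.33, (Layer(1.5, 100.0), Layer(1.7, 10.0)), 1.48)
        for pol in ("s", "p"):
            ra = stack_rt(a, 0.4, 550.0, pol)
            rb = stack_rt(b, 0.4, 550.0, pol)
            assert ra.r == pytest.approx(rb.r, abs=1e-12)
            assert ra.t == pytest.approx(rb.t, abs=1e-12)

    def test_reciprocity_of_transmittance(self, rng):
        for _ in range(25):
            layers = tuple(Layer(rng.uniform(1, 2), rng.uniform(0, 150)) for _ in range(4))
            st = StratifiedStack(1.33, layers, 1.48)
            theta = rng.uniform(0, 0.6)
            rev_theta = np.arcsin(st.n_incident * np.sin(theta) / st.n_substrate)
            for pol in ("s", "p"):
                t_fwd = stack_rt(st, theta, 550.0, pol).T
                t_rev = stack_rt(st.reversed(), rev_theta, 550.0, pol).T
                assert t_fwd == pytest.approx(t_rev, abs=1e-9)

    def test_matches_airy_recursion_on_three_layer_stacks(self, rng):
        for _ in range(30):
            layers = tuple(Layer(rng.uniform(1, 2), rng.uniform(1, 150)) for _ in range(3))
            st = StratifiedStack(rng.uniform(1.2, 1.6), layers, rng.uniform(1.2, 1.6))
            theta = rng.uniform(0, 0.9)
            lam = rng.uniform(350, 900)
            for pol in ("s", "p"):
                r_matrix = stack_rt(st, theta, lam, pol).r
                r_oracle = airy_recursion(st, theta, lam, pol)
                assert r_matrix == pytest.approx(r_oracle, abs=1e-8)


class TestReflectanceGrid:
    def test_default_grid_shape(self, wall):
        table = reflectance_grid(wall)
        assert len(table) == 81 * 91
        assert table["wavelength_nm"].nunique() == 81
        assert table["angle_deg"].nunique() == 91

    def test_single_cell_matches_stack_rt(self, wall):
        table = reflectance_grid(wall, wavelengths=[550.0], angles_deg=[30.0])
        assert len(table) == 1
        rs = stack_rt(wall, np.deg2rad(30.0), 550.0, "s").R
        rp = stack_rt(wall, np.deg2rad(30.0), 550.0, "p").R
        assert table["R_s"].iloc[0] == pytest.approx(rs, abs=1e-12)
        assert table["R_p"].iloc[0] == pytest.approx(rp, abs=1e-12)

    def test_bare_interface_grid_matches_fresnel(self):
        st = StratifiedStack(1.0, (), 1.5)
        angles = np.arange(0.0, 90.0, 5.0)
        table = reflectance_grid(st, wavelengths=[500.0], angles_deg=angles)
        th = np.deg2rad(angles)
        ct = np.sqrt(1 - (np.sin(th) / 1.5) ** 2)
        rs = ((np.cos(th) - 1.5 * ct) / (np.cos(th) + 1.5 * ct)) ** 2
        rp = ((ct - 1.5 * np.cos(th)) / (ct + 1.5 * np.cos(th))) ** 2
        np.testing.assert_allclose(table["R_s"].to_numpy(), rs, atol=1e-10)
        np.testing.assert_allclose(table["R_p"].to_numpy(), rp, atol=1e-10)

    def test_wall_conserves_at_sodium_line(self, wall):
        res_s = stack_rt(wall, 0.0, 587.56, "s")
        assert res_s.R + res_s.T == pytest.approx(1.0, abs=1e-9)
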