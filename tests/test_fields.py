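"""Near-field integration: coherence, conservation, observables."""

import numpy as np
import pytest

from mitolens.fields import (
    FirstOrderIntegrator,
    accumulate_first_order,
    find_focus,
    flux_ratio_spectrum,
    geometric_disk_flux,
    patch_integrate,
    rotation_sweep,
    waveguide_diagnostics,
)
from mitolens.fixtures import make_fixture
from mitolens.transport import ExitRecords, SourceGrid, trace


def _two_records(model, phase_shift=0.0, separation=0.0):
    """Two co-propagating records near the rear pole."""
    x = model.center[0] + model.radius
    pos = np.array([[x - 1.0, 0.0, 0.0], [x - 1.0, separation, 0.0]])
    dirs = np.tile([1.0, 0.0, 0.0], (2, 1))
    svec = np.tile([0.0, 1.0, 0.0], (2, 1))
    amps = np.array([1.0, np.exp(1j * phase_shift)])
    return ExitRecords(pos, dirs, amps, np.zeros(2, complex), svec, 550.0)


class TestCoherentAddition:
    def test_in_phase_records_quadruple_the_peak(self, null_model):
        one = ExitRecords(
            np.array([[999.0, 0.0, 0.0]]), np.array([[1.0, 0.0, 0.0]]),
            np.array([1.0 + 0j]), np.zeros(1, complex),
            np.array([[0.0, 1.0, 0.0]]), 550.0,
        )
        two = _two_records(null_model, phase_shift=0.0)
        m1 = accumulate_first_order(one, null_model, 1000.0)
        m2 = accumulate_first_order(two, null_model, 1000.0)
        assert m2.peak()[0] == pytest.approx(4.0 * m1.peak()[0], rel=1e-6)

    def test_opposite_phase_records_cancel(self, null_model):
        con = accumulate_first_order(_two_records(null_model, 0.0), null_model, 1000.0)
        des = accumulate_first_order(_two_records(null_model, np.pi), null_model, 1000.0)
        assert des.peak()[0] < 1e-4 * con.peak()[0]


class TestNullModel:
    def test_plane_power_matches_input(self, null_model):
        records, ledger = trace(null_model, SourceGrid(spacing=28.0, wavelength=550.0))
        integ = FirstOrderIntegrator(records, null_model, source_spacing=28.0)
        power = integ.map_at(1000.0).total_power
        assert power == pytest.approx(ledger.input, rel=0.10)

    def test_flux_ratio_is_flat_unity(self, null_model):
        fs = flux_ratio_spectrum(null_model, [450.0, 650.0], [1.0, 3.0, 5.0],
                                 spacing=40.0)
        np.testing.assert_allclose(fs.ratio, 1.0, atol=0.02)

    def test_geometric_disk_flux_conserves(self, null_model):
        records, ledger = trace(null_model, SourceGrid(spacing=40.0, wavelength=550.0))
        flux = geometric_disk_flux(records, null_model, 2000.0, null_model.radius)
        assert flux == pytest.approx(ledger.input, rel=1e-9)


class TestPatchModel:
    def test_plane_wave_reconstruction_conserves_power(self, null_model):
        records, ledger = trace(null_model, SourceGrid(spacing=28.0, wavelength=550.0))
        pm = patch_integrate(records, null_model, 1000.0, cell_area=28.0**2)
        assert pm.total_power == pytest.approx(ledger.input, rel=0.05)

    def test_single_patch_inverse_square_falloff(self, null_model):
        one = ExitRecords(
            np.array([[999.9, 0.0, 0.0]]), np.array([[1.0, 0.0, 0.0]]),
            np.array([1.0 + 0j]), np.zeros(1, complex),
            np.array([[0.0, 1.0, 0.0]]), 550.0,
        )
        p_near = patch_integrate(one, null_model, 2000.0).total_power
        p_far = patch_integrate(one, null_model, 4000.0).total_power
        # total captured power shrinks with the solid angle of the map
        assert p_near > p_far

        near_axis = patch_integrate(one, null_model, 2000.0)
        far_axis = patch_integrate(one, null_model, 4000.0)
        n = near_axis.intensity.shape[0] // 2
        ratio = near_axis.intensity[n, n] / far_axis.intensity[n, n]
        assert ratio == pytest.approx(4.0, rel=0.1)

    def test_agrees_with_first_order_model(self, default_model):
        """The two integration models agree on where the light is:
        same best plane (within two half-micron steps) and comparable
        far-plane power."""
        records, _ = trace(default_model, SourceGrid(spacing=20.0, wavelength=550.0),
                           epsilon=1e-6)
        integ = FirstOrderIntegrator(records, default_model, source_spacing=20.0)
        planes = np.arange(1.0, 4.01, 0.5) * 1000.0
        wave_peaks, patch_peaks = [], []
        for z in planes:
            wave_peaks.append(integ.map_at(z).peak()[0])
            pm = patch_integrate(records, default_model, z, cell_area=400.0,
                                 half_width=2500.0)
            patch_peaks.append(pm.peak()[0])
            if z >= 2000.0:
                assert pm.total_power == pytest.approx(
                    integ.map_at(z).total_power, rel=0.3)
        i_wave = int(np.argmax(wave_peaks))
        i_patch = int(np.argmax(patch_peaks))
        assert abs(i_wave - i_patch) <= 2


class TestBallLens:
    def test_focus_against_closed_form_wave_oracle(self):
        """Independent oracle: exact two-refraction ball-lens ray trace
        (closed-form trigonometry) feeding a radial Rayleigh-Sommerfeld
        on-axis integral; the full pipeline must peak at the same plane.
        """
        n1, n2, R, lam = 1.33, 1.43, 1000.0, 550.0
        k = 2 * np.pi * n1 / lam
        h = np.linspace(0.5, 999.0, 6000)
        th1 = np.arcsin(h / R)
        th2 = np.arcsin(np.clip(n1 * np.sin(th1) / n2, 0, 1))
        phi = th1 - th2
        chord = 2 * R * np.cos(th2)
        x1 = -np.sqrt(R**2 - h**2)
        x2 = x1 + chord * np.cos(phi)
        y2 = h - chord * np.sin(phi)
        delta = 2 * phi
        dxp = (R - x2) / np.cos(delta)
        y_land = y2 - dxp * np.sin(delta)
        opl = n1 * (x1 + 2000.0) + n2 * chord + n1 * dxp
        rbins = np.linspace(0, 1100, 221)
        U = np.zeros(len(rbins) - 1, complex)
        idx = np.digitize(np.abs(y_land), rbins) - 1
        dh = h[1] - h[0]
        np.add.at(U, idx[(idx >= 0) & (idx < len(U))],
                  (np.exp(1j * 2 * np.pi * opl / lam) * h * dh)[(idx >= 0) & (idx < len(U))])
        rc = 0.5 * (rbins[1:] + rbins[:-1])
        ring = np.maximum(rc * (rbins[1] - rbins[0]), 1e-9)
        amp = U / ring
        zs = np.arange(100.0, 8000.0, 100.0)
        inten = []
        for z in zs:
            ell = np.sqrt(z**2 + rc**2)
            inten.append(abs(np.sum(amp * np.exp(1j * k * ell) / ell * (z / ell) * ring)) ** 2)
        oracle_um = zs[int(np.argmax(inten))] / 1000.0

        ball = make_fixture("ball_lens")
        res = find_focus(ball, lam, plane_range_um=(0.2, 8.0), step_um=0.1, spacing=28.0)
        assert res.focus_found and res.centered
        assert res.focus_um == pytest.approx(oracle_um, abs=0.5)


class TestRotationSweep:
    def test_single_angle_has_zero_variation(self, default_model):
        sw = rotation_sweep(default_model, [0.0], wavelength=550.0, spacing=40.0)
        assert sw["energy_variation"] == 0.0
        assert sw["central_variation"] == 0.0


class TestWaveguide:
    def test_equal_index_model_shows_no_guiding(self, wall):
        from mitolens.geometry import build_mitochondrion

        flat = build_mitochondrion(n_A=1.40, n_B=1.40, wall_stack=wall)
        rep = waveguide_diagnostics(flat, wavelengths=(550.0,), spacing=40.0)
        assert rep["no_waveguide"]
        assert rep["channel_energy_fraction"][0] == pytest.approx(
            rep["channel_area_fraction"], abs=0.05)

    def test_high_index_channels_capture_excess_energy(self, default_model):
        rep = waveguide_diagnostics(default_model, wavelengths=(550.0, 750.0),
                                    spacing=40.0)
        assert not rep["no_waveguide"]
        assert np.all(rep["enhancement"] > 0)
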