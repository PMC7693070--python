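"""Prescan pipeline: unwrapping, field maps, masks, gradients, selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import zshim
from zshim import (
    FieldGradientMap,
    field_map,
    gradient_map,
    make_mask,
    quantize_gz,
    select_slice_gradients,
    unwrap_phase,
)

UT = zshim.UT_PER_M


def wrap(phi):
    return np.angle(np.exp(1j * phi))


class TestUnwrap:
    def test_smooth_phase_unchanged_up_to_2pi(self):
        x = np.linspace(0, 1.5 * np.pi, 24)
        phi = np.broadcast_to(x, (8, 8, 24)).copy() - np.pi / 2
        out = unwrap_phase(wrap(phi))
        offs = out - phi
        assert np.allclose(offs, offs.flat[0], atol=1e-9)
        assert np.isclose(offs.flat[0] % (2 * np.pi), 0, atol=1e-9) or np.isclose(
            offs.flat[0] % (2 * np.pi), 2 * np.pi, atol=1e-9
        )

    def test_recovers_6pi_ramp(self):
        x = np.linspace(0, 6 * np.pi, 32)
        phi = np.broadcast_to(x, (6, 6, 32)).copy()
        out = unwrap_phase(wrap(phi))
        d = out - phi
        assert np.allclose(d, d.flat[0], atol=1e-6)

    def test_noise_output_congruent_mod_2pi(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(-np.pi, np.pi, (6, 6, 6))
        out = unwrap_phase(phi)
        assert np.allclose(wrap(out - phi), 0.0, atol=1e-9)


class TestFieldMap:
    def test_closed_form(self):
        te1, te3 = 2.7e-3, 6.9e-3
        f = field_map(np.zeros((2, 2, 2)), np.full((2, 2, 2), np.pi), te1, te3)
        assert np.allclose(f, 1 / (2 * 4.2e-3))  # ≈ 119.05 Hz
        assert f.flat[0] == pytest.approx(119.05, rel=1e-3)

    def test_zero_and_sign_flip(self):
        z = np.zeros((2, 2, 2))
        p = np.full((2, 2, 2), 0.5)
        assert np.all(field_map(z, z, 1e-3, 2e-3) == 0)
        assert np.allclose(field_map(z, p, 1e-3, 2e-3),
                           -field_map(p, z, 1e-3, 2e-3))

    def test_equal_tes_rejected(self):
        z = np.zeros((2, 2, 2))
        with pytest.raises(ValueError):
            field_map(z, z, 2e-3, 2e-3)


class TestMask:
    def test_radius_zero_keeps_threshold_mask(self):
        mag = np.ones((8, 8, 3))
        assert make_mask(mag, threshold=0.5, erosion_radius_px=0).all()

    def test_disk_erosion_shrinks_disk_by_radius(self):
        from skimage.morphology import disk

        big = disk(20).astype(float)  # 41x41 disk object
        mag = np.pad(big, 5)[..., None] * np.ones(3)
        mask = make_mask(mag, threshold=0.5, erosion_radius_px=5)
        area = mask[..., 0].sum()
        r_eff = np.sqrt(area / np.pi)
        assert abs(r_eff - 15) <= 1.0

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning):
            mask = make_mask(np.zeros((6, 6, 2)), threshold=1.0,
                             erosion_radius_px=0)
        assert not mask.any()


class TestGradientMap:
    voxel = (2e-3, 2e-3, 4e-3)

    def _field_hz(self, b0_t):
        return b0_t * zshim.GAMMA_BAR

    def test_linear_field_exact(self):
        g = 120e-6  # T/m
        z = np.arange(10) * self.voxel[2]
        b0 = np.broadcast_to(g * z, (6, 6, 10)).copy()
        mask = np.ones(b0.shape, bool)
        out = gradient_map(self._field_hz(b0), mask, self.voxel,
                           smoothing_kernel=1.0)
        assert np.allclose(out.gz[out.mask], g, rtol=1e-9)

    def test_constant_field_zero_gradient(self):
        b0 = np.full((5, 5, 6), 3e-6)
        out = gradient_map(self._field_hz(b0), np.ones(b0.shape, bool),
                           self.voxel)
        assert np.allclose(out.gz, 0.0, atol=1e-15)

    def test_quadratic_field_central_difference_exact_interior(self):
        a = 2e-3  # T/m^2
        z = np.arange(12) * self.voxel[2]
        b0 = np.broadcast_to(a * z**2, (4, 4, 12)).copy()
        out = gradient_map(self._field_hz(b0), np.ones(b0.shape, bool),
                           self.voxel, smoothing_kernel=0.0)
        interior = slice(1, -1)
        expected = 2 * a * z[interior]
        assert np.allclose(out.gz[2, 2, interior], expected, rtol=1e-9)

    def test_single_slice_rejected(self):
        with pytest.raises(ValueError):
            gradient_map(np.zeros((4, 4, 1)), np.ones((4, 4, 1), bool),
                         self.voxel)

    def test_one_sided_at_mask_boundary(self):
        g = 50e-6
        z = np.arange(8) * self.voxel[2]
        b0 = np.broadcast_to(g * z, (4, 4, 8)).copy()
        mask = np.ones(b0.shape, bool)
        mask[..., 4:] = False  # mask ends mid-volume
        out = gradient_map(self._field_hz(b0), mask, self.voxel,
                           smoothing_kernel=0.0)
        assert np.allclose(out.gz[out.mask], g, rtol=1e-9)
        assert not out.mask[..., 4:].any()


class TestQuantize:
    def _map(self, values):
        arr = np.asarray(values, float).reshape(1, 1, -1)
        return FieldGradientMap(arr, np.ones(arr.shape, bool), (1e-3,) * 3)

    @pytest.mark.parametrize(
        "gz_uT,expected_uT",
        [(122.0, 125.0), (-51.0, -55.0), (1e-6, 5.0), (-1e-6, -5.0)],
    )
    def test_bin_centre_rule(self, gz_uT, expected_uT):
        out = quantize_gz(self._map([gz_uT * UT]), 10e-6)
        assert out.gz.flat[0] == pytest.approx(expected_uT * UT, rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-400, 400))
    def test_idempotent(self, gz_uT):
        m1 = quantize_gz(self._map([gz_uT * UT]), 10e-6)
        m2 = quantize_gz(m1, 10e-6)
        assert m1.gz.flat[0] == m2.gz.flat[0]

    def test_bad_interval(self):
        with pytest.raises(ValueError):
            quantize_gz(self._map([0.0]), 0.0)


class TestSelection:
    def _map_slices(self, per_slice_values):
        nz = len(per_slice_values)
        width = max(len(v) for v in per_slice_values)
        gz = np.zeros((1, width, nz))
        mask = np.zeros((1, width, nz), bool)
        for k, vals in enumerate(per_slice_values):
            gz[0, : len(vals), k] = vals
            mask[0, : len(vals), k] = True
        return FieldGradientMap(gz, mask, (1e-3,) * 3)

    def test_all_negative_slice_gives_five_fraction_source(self):
        sels = select_slice_gradients(
            self._map_slices([np.array([-125.0, -95.0, -65.0]) * UT])
        )
        assert sels[0].g_plus == pytest.approx(125e-6)
        assert sels[0].g_minus == 0.0

    def test_mixed_slice(self):
        sels = select_slice_gradients(
            self._map_slices([np.array([-80.0, -10.0, 5.0, 30.0]) * UT])
        )
        assert sels[0].g_plus == pytest.approx(80e-6)
        assert sels[0].g_minus == pytest.approx(-30e-6)

    def test_all_positive_slice(self):
        sels = select_slice_gradients(
            self._map_slices([np.array([15.0, 45.0]) * UT])
        )
        assert sels[0].g_plus == 0.0
        assert sels[0].g_minus == pytest.approx(-45e-6)

    def test_empty_slice_warns_and_zeroes(self):
        fmap = self._map_slices([np.array([25.0]) * UT])
        fmap.mask[..., 0] = False
        with pytest.warns(UserWarning):
            sels = select_slice_gradients(fmap)
        assert (sels[0].g_plus, sels[0].g_minus) == (0.0, 0.0)

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-300, 300), min_size=1, max_size=6))
    def test_sign_contract(self, values_uT):
        sels = select_slice_gradients(
            self._map_slices([np.asarray(values_uT) * UT])
        )
        assert sels[0].g_plus >= 0 >= sels[0].g_minus


class TestEndToEnd:
    @pytest.mark.parametrize("g_uT", [-173.0, -51.0, 38.0, 122.0])
    def test_linear_field_selection_exact(self, g_uT):
        # constant Gz everywhere: the pipeline must return exactly the
        # quantized imposed gradient on every slice
        g = g_uT * UT
        nz = 10
        z = np.arange(nz) * 4e-3
        b0 = np.broadcast_to(g * z, (12, 12, nz)).copy()
        ph = zshim.DigitalPhantom(
            s0=np.ones(b0.shape), r2star=np.full(b0.shape, 6.4), b0=b0,
            voxel_size=(2e-3, 2e-3, 4e-3),
        )
        pres = zshim.simulate_prescan(ph, zshim.prescan_echo_times())
        _, sels = zshim.process_prescan(
            pres.magnitude, pres.phase, pres.echo_times, ph.voxel_size,
            threshold=0.5, erosion_radius_px=1,
        )
        q = (np.floor(g / 10e-6) + 0.5) * 10e-6
        expected = (-q, 0.0) if q < 0 else (0.0, -q)
        for s in sels:
            assert s.g_plus == pytest.approx(expected[0], abs=1e-12)
            assert s.g_minus == pytest.approx(expected[1], abs=1e-12)

    def test_polynomial_field_interior_slices_exact(self, agar_phantom):
        ph = agar_phantom
        pres = zshim.simulate_prescan(ph, zshim.prescan_echo_times())
        _, sels = zshim.process_prescan(
            pres.magnitude, pres.phase, pres.echo_times, ph.voxel_size,
            erosion_radius_px=1,
        )
        gz_true = ph.gz_map()[8, 8, :]  # in-plane constant by construction
        q = (np.floor(gz_true / 10e-6) + 0.5) * 10e-6
        # Gaussian smoothing (σ=1, truncated at 4σ) and one-sided
        # differences disturb only slices near the stack edges
        for n in range(5, ph.n_slices - 5):
            expected = (-q[n], 0.0) if q[n] < 0 else (0.0, -q[n])
            assert sels[n].g_plus == pytest.approx(expected[0], abs=1e-12)
            assert sels[n].g_minus == pytest.approx(expected[1], abs=1e-12)

    def test_noisy_prescan_within_one_bin(self, agar_phantom):
        ph = agar_phantom
        pres = zshim.simulate_prescan(ph, zshim.prescan_echo_times(),
                                      noise_sd=1 / 50, seed=7)
        _, sels = zshim.process_prescan(
            pres.magnitude, pres.phase, pres.echo_times, ph.voxel_size,
            erosion_radius_px=1,
        )
        pres0 = zshim.simulate_prescan(ph, zshim.prescan_echo_times())
        _, sels0 = zshim.process_prescan(
            pres0.magnitude, pres0.phase, pres0.echo_times, ph.voxel_size,
            erosion_radius_px=1,
        )
        for a, b in zip(sels, sels0):
            assert abs(a.g_plus - b.g_plus) <= 10e-6 + 1e-12
            assert abs(a.g_minus - b.g_minus) <= 10e-6 + 1e-12
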