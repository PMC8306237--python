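"""Phantom generator: geometry, signal model, noise, bias and shifts."""

import numpy as np
import pytest
from scipy.ndimage import label as cc_label

import ivimhsi as hs
from ivimhsi import phantom as ph
from ivimhsi.errors import ConfigurationError, InvalidSpecError


class TestLabelMap:
    def test_ellipse_lesion_matches_direct_enumeration(self):
        shape = (64, 64)
        lesion = ph.EllipseLesion(center=(32, 32), axes=(5, 7))
        breast = ph.Ellipse(center=(32, 32), axes=(27, 27))
        labels = ph.make_label_map(shape, lesion, breast)
        # independent oracle: enumerate the ellipse inequality pixel by pixel
        expected = sum(
            ((r - 32) / 5) ** 2 + ((c - 32) / 7) ** 2 <= 1
            for r in range(64)
            for c in range(64)
        )
        assert (labels == ph.LESION).sum() == expected
        assert expected > 0
        _, n_comp = cc_label(labels == ph.LESION)
        assert n_comp == 1
        assert not ((labels == ph.LESION) & ~breast.contains(*np.mgrid[0:64, 0:64])).any()

    def test_zero_axes_lesion_rejected(self):
        with pytest.raises(InvalidSpecError):
            ph.make_label_map(
                (64, 64),
                ph.EllipseLesion(center=(32, 32), axes=(0, 0)),
                ph.Ellipse(center=(32, 32), axes=(27, 27)),
            )

    def test_lesion_outside_breast_rejected(self):
        with pytest.raises(InvalidSpecError):
            ph.make_label_map(
                (64, 64),
                ph.EllipseLesion(center=(5, 5), axes=(4, 4)),
                ph.Ellipse(center=(40, 40), axes=(15, 15)),
            )

    def test_blob_lesion_component_count(self):
        lesion = ph.BlobLesion(
            centers=((25, 25), (25, 40), (40, 25), (40, 40)), radius=2.5
        )
        labels = ph.make_label_map(
            (64, 64), lesion, ph.Ellipse(center=(32, 32), axes=(27, 27))
        )
        _, n_comp = cc_label(labels == ph.LESION)
        assert n_comp == 4


class TestSimulateCube:
    def test_b0_band_equals_s0_noise_free(self, clean_phantom):
        b0 = clean_phantom.cube.band(0)
        labels = clean_phantom.labels
        assert np.all(b0[labels == ph.LESION] == ph.MASS.S0)
        assert np.all(b0[labels == ph.NORMAL] == ph.NORMAL_TISSUE.S0)
        assert np.all(b0[labels == ph.BACKGROUND] == 0)

    def test_mass_preset_value_at_b1000(self):
        # direct substitution into the bi-exponential decay
        expected = 100.0 * (0.77 * np.exp(-0.84) + 0.23 * np.exp(-6.10))
        got = ph.MASS.signal(np.array([1000.0]))[0]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_pf_is_mono_exponential(self, bvals):
        p = ph.TissueClassParams("t", S0=50.0, D=1.5e-3, Dstar=8e-3, PF=0.0)
        np.testing.assert_allclose(
            p.signal(bvals), 50.0 * np.exp(-bvals * 1.5e-3), rtol=1e-14
        )

    def test_noise_free_cube_matches_model_pointwise(self, clean_phantom, bvals):
        labels = clean_phantom.labels
        cube = clean_phantom.cube.data
        for code, p in ((ph.LESION, ph.MASS), (ph.NORMAL, ph.NORMAL_TISSUE)):
            expected = np.tile(p.signal(bvals), ((labels == code).sum(), 1))
            np.testing.assert_allclose(cube[labels == code], expected, rtol=1e-14)

    def test_noise_free_signal_non_increasing_in_b(self, clean_phantom):
        diffs = np.diff(clean_phantom.cube.data, axis=2)
        assert np.all(diffs <= 1e-12)

    def test_missing_class_params_rejected(self, bvals):
        labels = np.ones((8, 8), np.int8)
        with pytest.raises(ConfigurationError):
            ph.simulate_cube(labels, {0: ph.AIR}, bvals)

    def test_determinism(self, bvals):
        spec = hs.PhantomSpec(noise_sigma=2.0, bias_amplitude=0.2, seed=11)
        a = hs.generate_phantom(spec)
        b = hs.generate_phantom(spec)
        np.testing.assert_array_equal(a.cube.data, b.cube.data)
        np.testing.assert_array_equal(a.truth_mask, b.truth_mask)

    def test_rician_mean_bias_grows_with_sigma(self, bvals):
        # magnitude noise biases the mean upward, increasingly with sigma
        labels = np.full((80, 80), ph.NORMAL, np.int8)
        params = {ph.NORMAL: ph.NORMAL_TISSUE}
        means = []
        for sigma in (0.5, 5.0, 20.0):
            cube = ph.simulate_cube(labels, params, bvals, sigma, seed=3)
            means.append(cube.band(0).mean())
        s0 = ph.NORMAL_TISSUE.S0
        biases = [m - s0 for m in means]
        assert biases[0] < biases[1] < biases[2]
        assert abs(biases[0]) < 0.05 * s0

    def test_invalid_tissue_params_rejected(self):
        with pytest.raises(InvalidSpecError):
            ph.TissueClassParams("bad", S0=1.0, D=1e-3, Dstar=1e-3, PF=1.5)
        with pytest.raises(InvalidSpecError):
            ph.TissueClassParams("bad", S0=1.0, D=-1e-3, Dstar=1e-3, PF=0.1)


class TestBiasField:
    def test_zero_amplitude_identity(self, clean_phantom):
        out, fld = hs.apply_bias_field(clean_phantom.cube, 0.0, seed=1)
        np.testing.assert_array_equal(out.data, clean_phantom.cube.data)
        np.testing.assert_array_equal(fld, 1.0)

    def test_field_is_band_independent(self, noisy_phantom):
        cube = noisy_phantom.cube
        out, fld = hs.apply_bias_field(cube, 0.3, seed=2)
        nz = cube.data > 0
        ratio = np.where(nz, out.data / np.where(nz, cube.data, 1.0), np.nan)
        for j in range(1, cube.n_bands):
            np.testing.assert_allclose(
                ratio[:, :, j][nz[:, :, j]],
                fld[nz[:, :, j].nonzero()],
                rtol=1e-12,
            )

    def test_field_mean_one_and_bounded(self):
        fld = ph.make_bias_field((64, 64), 0.3, seed=7)
        assert abs(fld.mean() - 1.0) <= 1e-9
        assert np.abs(fld - 1.0).max() <= 0.3 + 1e-12

    def test_amplitude_one_rejected(self, clean_phantom):
        with pytest.raises(InvalidSpecError):
            hs.apply_bias_field(clean_phantom.cube, 1.0)


class TestShifts:
    def test_zero_shifts_identity(self, clean_phantom):
        shifts = [(0, 0)] * clean_phantom.cube.n_bands
        out = hs.apply_shifts(clean_phantom.cube, shifts)
        np.testing.assert_array_equal(out.data, clean_phantom.cube.data)

    def test_shift_semantics_on_one_band(self, clean_phantom):
        cube = clean_phantom.cube
        shifts = [(0, 0)] * cube.n_bands
        shifts[5] = (2, 0)
        out = hs.apply_shifts(cube, shifts)
        np.testing.assert_array_equal(out.data[2:, :, 5], cube.data[:-2, :, 5])
        np.testing.assert_array_equal(out.data[:2, :, 5], 0.0)

    def test_band0_never_shifted(self, clean_phantom):
        cube = clean_phantom.cube
        shifts = [(3, 3)] + [(0, 0)] * (cube.n_bands - 1)
        out = hs.apply_shifts(cube, shifts)
        np.testing.assert_array_equal(out.data[:, :, 0], cube.data[:, :, 0])

    def test_shift_unshift_restores_interior(self, clean_phantom):
        cube = clean_phantom.cube
        shifts = [(0, 0)] + [(2, -3)] * (cube.n_bands - 1)
        inverse = [(-dy, -dx) for dy, dx in shifts]
        back = hs.apply_shifts(hs.apply_shifts(cube, shifts), inverse)
        m = 3
        np.testing.assert_array_equal(
            back.data[m:-m, m:-m, :], cube.data[m:-m, m:-m, :]
        )

    def test_oversized_shift_clipped_with_warning(self, clean_phantom):
        cube = clean_phantom.cube
        shifts = [(0, 0)] * cube.n_bands
        shifts[3] = (9, 0)
        with pytest.warns(UserWarning, match="clipped"):
            out = hs.apply_shifts(cube, shifts, max_shift=5)
        np.testing.assert_array_equal(out.data[5:, :, 3], cube.data[:-5, :, 3])
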