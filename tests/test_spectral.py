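"""Wavelength grid, spectra, band integrals and the two render conventions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpmcollagen import (
    ROI,
    AcquisitionMeta,
    DegenerateInputError,
    EmissionSpectrum,
    LambdaStack,
    SpecError,
    TwoChannelImage,
    WavelengthGrid,
    band_integrate,
    channel_labels,
    combine_spectral_image,
    nearest_channel,
    normalize_spectrum,
    overlay_tpef_shg,
    roi_mean_spectrum,
    shg_wavelength,
)


class TestWavelengthGrid:
    def test_default_grid_labels(self, default_grid):
        labels = channel_labels(default_grid)
        assert labels.shape == (32,)
        assert labels[0] == 382.0
        assert labels[2] == 404.0  # the channel that carries the SHG peak
        assert labels[-1] == 382.0 + 31 * 11.0 == 723.0

    def test_trivial_grid(self):
        assert channel_labels(WavelengthGrid(0.0, 1.0, 3)).tolist() == [0.0, 1.0, 2.0]

    def test_labels_affine(self, default_grid):
        assert np.allclose(np.diff(channel_labels(default_grid)), default_grid.step_nm)

    def test_invalid_grid_rejected(self):
        with pytest.raises(SpecError):
            WavelengthGrid(n_channels=0)
        with pytest.raises(SpecError):
            WavelengthGrid(step_nm=0.0)


class TestShgWavelength:
    @pytest.mark.parametrize("excitation,emission", [(810.0, 405.0), (800.0, 400.0), (920.0, 460.0)])
    def test_halving(self, excitation, emission):
        assert shg_wavelength(excitation) == emission
        assert shg_wavelength(AcquisitionMeta(excitation_nm=excitation)) == emission

    def test_shg_inside_default_band(self, default_meta):
        lo, hi = default_meta.shg_band
        assert lo <= shg_wavelength(default_meta) <= hi

    def test_nonpositive_excitation_rejected(self):
        with pytest.raises(SpecError):
            shg_wavelength(0.0)


class TestNearestChannel:
    def test_shg_channel_is_404(self, default_grid):
        k, label = nearest_channel(default_grid, shg_wavelength(810.0))
        assert (k, label) == (2, 404.0)

    def test_exact_hit(self, default_grid):
        assert nearest_channel(default_grid, 382.0) == (0, 382.0)

    def test_tie_breaks_low(self, default_grid):
        # 387.5 is equidistant from 382 and 393; the lower index wins
        assert nearest_channel(default_grid, 387.5)[0] == 0


class TestRoiMeanSpectrum:
    def test_constant_stack(self, default_grid, default_meta):
        stack = LambdaStack(np.full((4, 5, 32), 3.0), default_grid, default_meta)
        s = roi_mean_spectrum(stack, ROI.full((4, 5)))
        assert np.allclose(s.intensities, 3.0)
        assert not s.normalized

    def test_two_pixel_mean(self):
        grid = WavelengthGrid(400.0, 10.0, 2)
        pixels = np.array([[[1.0, 3.0]], [[3.0, 5.0]]])  # 2x1x2
        stack = LambdaStack(pixels, grid)
        s = roi_mean_spectrum(stack, ROI.full((2, 1)))
        assert np.allclose(s.intensities, [2.0, 4.0])

    def test_single_pixel_roi_is_exact(self, rng, default_grid):
        pixels = rng.random((6, 6, 32))
        stack = LambdaStack(pixels, default_grid)
        s = roi_mean_spectrum(stack, ROI.from_bounds((6, 6), 2, 3, 4, 5))
        assert np.array_equal(s.intensities, pixels[2, 4])

    def test_empty_roi_rejected(self):
        with pytest.raises(SpecError):
            ROI(np.zeros((4, 4), dtype=bool))


class TestNormalizeSpectrum:
    def test_scaling(self):
        s = EmissionSpectrum([400.0, 500.0, 600.0], [2.0, 4.0, 8.0])
        out = normalize_spectrum(s)
        assert np.allclose(out.intensities, [0.25, 0.5, 1.0])
        assert out.normalized

    def test_idempotent(self):
        s = EmissionSpectrum([400.0, 500.0], [0.5, 1.0], normalized=True)
        out = normalize_spectrum(s)
        assert np.array_equal(out.intensities, s.intensities)

    @given(scale=st.floats(min_value=1e-6, max_value=1e6))
    @settings(deadline=None, derandomize=True)
    def test_scale_invariant(self, scale):
        base = np.array([0.1, 0.9, 0.4])
        lam = np.array([400.0, 500.0, 600.0])
        a = normalize_spectrum(EmissionSpectrum(lam, base))
        b = normalize_spectrum(EmissionSpectrum(lam, scale * base))
        assert np.allclose(a.intensities, b.intensities)

    def test_all_zero_degenerate(self):
        with pytest.raises(DegenerateInputError):
            normalize_spectrum(EmissionSpectrum([400.0, 500.0], [0.0, 0.0]))


class TestBandIntegrate:
    def test_shg_band_selects_three_channels(self, default_grid, default_meta):
        # value of channel k = k, so the band sum identifies which channels count
        pixels = np.broadcast_to(np.arange(32, dtype=float), (2, 2, 32)).copy()
        stack = LambdaStack(pixels, default_grid, default_meta)
        out = band_integrate(stack, default_meta.shg_band)
        assert np.allclose(out, 1 + 2 + 3)  # labels 393, 404, 415

    def test_full_band_is_total(self, rng, default_grid):
        stack = LambdaStack(rng.random((3, 3, 32)), default_grid)
        out = band_integrate(stack, (300.0, 800.0))
        assert np.allclose(out, stack.pixels.sum(axis=2))

    def test_disjoint_bands_conserve(self, rng, default_grid):
        stack = LambdaStack(rng.random((3, 3, 32)), default_grid)
        lo, hi = 382.0, 723.0
        split = 500.0
        a = band_integrate(stack, (lo, split))
        b = band_integrate(stack, (split + 1e-9, hi))
        assert np.allclose(a + b, stack.pixels.sum(axis=2))

    def test_empty_band_rejected(self, default_grid):
        stack = LambdaStack(np.ones((2, 2, 32)), default_grid)
        with pytest.raises(SpecError):
            band_integrate(stack, (1000.0, 1100.0))


class TestRenders:
    def _stack_with_band(self, band_channels, default_grid, default_meta):
        pixels = np.zeros((4, 4, 32))
        pixels[:2, :2, band_channels] = 5.0
        return LambdaStack(pixels, default_grid, default_meta)

    def test_combine_shg_only_is_purple(self, default_grid, default_meta):
        stack = self._stack_with_band([2], default_grid, default_meta)  # 404 nm
        rgb = combine_spectral_image(stack)
        assert np.allclose(rgb[0, 0], [1.0, 0.0, 1.0])  # purple: red == blue
        assert np.allclose(rgb[3, 3], 0.0)

    def test_combine_tpef_only_is_blue(self, default_grid, default_meta):
        stack = self._stack_with_band([10], default_grid, default_meta)  # 492 nm
        rgb = combine_spectral_image(stack)
        assert np.allclose(rgb[0, 0], [0.0, 0.0, 1.0])

    def test_combine_zero_stack_is_black(self, default_grid, default_meta):
        stack = LambdaStack(np.zeros((3, 3, 32)), default_grid, default_meta)
        assert combine_spectral_image(stack).max() == 0.0

    def test_combine_scale_invariant(self, rng, default_grid, default_meta):
        pixels = rng.random((4, 4, 32))
        a = combine_spectral_image(LambdaStack(pixels, default_grid, default_meta))
        b = combine_spectral_image(LambdaStack(7.5 * pixels, default_grid, default_meta))
        assert np.allclose(a, b)

    def test_overlay_color_coding(self):
        shg = np.array([[1.0, 0.0], [0.0, 1.0]])
        tpef = np.array([[0.0, 1.0], [0.0, 1.0]])
        rgb = overlay_tpef_shg(TwoChannelImage(shg, tpef))
        assert np.allclose(rgb[0, 0], [0.0, 1.0, 0.0])  # SHG only: green
        assert np.allclose(rgb[0, 1], [1.0, 0.0, 0.0])  # TPEF only: red
        assert np.allclose(rgb[1, 1], [1.0, 1.0, 0.0])  # both: yellow
        assert np.allclose(rgb[1, 0], 0.0)

    def test_overlay_zero_is_black(self):
        img = TwoChannelImage(np.zeros((2, 2)), np.zeros((2, 2)))
        assert overlay_tpef_shg(img).max() == 0.0


class TestValidation:
    def test_negative_intensities_rejected(self, default_grid):
        with pytest.raises(SpecError):
            LambdaStack(-np.ones((2, 2, 32)), default_grid)

    def test_channel_count_mismatch_rejected(self, default_grid):
        with pytest.raises(SpecError):
            LambdaStack(np.ones((2, 2, 31)), default_grid)

    def test_two_channel_shape_mismatch_rejected(self):
        with pytest.raises(SpecError):
            TwoChannelImage(np.ones((2, 2)), np.ones((3, 3)))

    def test_overlapping_bands_rejected(self):
        with pytest.raises(SpecError):
            AcquisitionMeta(shg_band=(389.0, 440.0), tpef_band=(430.0, 716.0))

    def test_normalized_flag_requires_unit_peak(self):
        with pytest.raises(SpecError):
            EmissionSpectrum([400.0, 500.0], [0.2, 0.5], normalized=True)
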