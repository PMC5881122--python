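"""Mosaic, cone fundamentals, DoG opponency, and channel integration."""

import numpy as np
import pytest

from parvocone import (Mosaic, OcularMedia, PigmentTemplate, Spectrum,
                       assemble_image, build_sensitivity_mosaic,
                       cone_fundamental, identifier_masks, integrate_channels,
                       make_grating, make_mosaic, make_receptive_fields,
                       quantal_catch, rgc_responses, synth_luminance_field,
                       trim_border)
from parvocone.retina import SensitivityMosaic, load_mosaic, save_mosaic
from parvocone.scene import ReferencePattern, SpectralImage


class TestMosaic:
    def test_degenerate_ratios(self):
        assert (make_mosaic(8, 8, 1.0, 0).labels == "L").all()
        assert (make_mosaic(8, 8, 0.0, 0).labels == "M").all()

    def test_l_fraction_within_binomial_bounds(self):
        m = make_mosaic(60, 30, 0.5, seed=123)
        frac = m.is_l.mean()
        assert 0.42 <= frac <= 0.58   # 99.99% binomial interval for n=1800

    def test_seeded_reproducibility(self):
        assert np.array_equal(make_mosaic(20, 20, 0.5, 5).labels,
                              make_mosaic(20, 20, 0.5, 5).labels)

    def test_text_roundtrip(self, tmp_path):
        m = make_mosaic(12, 9, 0.5, 3)
        save_mosaic(m, tmp_path / "mosaic.txt")
        back = load_mosaic(tmp_path / "mosaic.txt")
        assert np.array_equal(m.labels, back.labels)
        assert back.seed == 3


class TestConeFundamental:
    @pytest.mark.parametrize("lmax", [450.0, 500.0, 535.0, 562.0, 600.0])
    def test_template_peaks_at_lambda_max(self, lmax, grid, template):
        psi = template.absorbance(grid.values, lmax)
        assert abs(grid.values[np.argmax(psi)] - lmax) <= grid.step / 2 + 1e-9
        assert psi.max() == 1.0

    @pytest.mark.parametrize("lmax", [430.0, 630.0])
    def test_out_of_range_peak_rejected(self, lmax, template, media):
        with pytest.raises(ValueError, match="lambda_max"):
            cone_fundamental(lmax, template, media)

    def test_high_density_limit_absorbs_everything_at_peak(self, clear_media):
        dense = PigmentTemplate(peak_optical_density=1000.0)
        s = cone_fundamental(540.0, dense, clear_media)
        assert s.values.max() == pytest.approx(1.0, abs=1e-9)

    def test_deterministic(self, template, media):
        a = cone_fundamental(530.0, template, media)
        b = cone_fundamental(530.0, template, media)
        assert np.array_equal(a.values, b.values)

    def test_ocular_media_attenuates_short_wavelengths(self, grid, template,
                                                       media, clear_media):
        with_media = cone_fundamental(535.0, template, media)
        without = cone_fundamental(535.0, template, clear_media)
        ratio = with_media.values / without.values
        np.testing.assert_allclose(ratio, media.transmission, rtol=1e-12)
        assert ratio[0] < 0.2 < ratio[-1]

    def test_peak_normalisation_flag(self, template, media):
        s = cone_fundamental(520.0, template, media, normalize_peak=True)
        assert s.values.max() == pytest.approx(1.0)


class TestSensitivityMosaic:
    def test_equal_pair_spatially_uniform(self, template, clear_media):
        mosaic = make_mosaic(10, 10, 0.5, 1)
        C = build_sensitivity_mosaic((530.0, 530.0), mosaic, template,
                                     clear_media)
        assert np.ptp(C.values, axis=(0, 1)).max() == 0.0

    def test_pixels_hold_matching_prototype(self, template, media):
        mosaic = make_mosaic(10, 10, 0.5, 2)
        C = build_sensitivity_mosaic((520.0, 562.0), mosaic, template, media)
        cm = cone_fundamental(520.0, template, media).values
        cl = cone_fundamental(562.0, template, media).values
        xm, ym = np.argwhere(~mosaic.is_l)[0]
        xl, yl = np.argwhere(mosaic.is_l)[0]
        np.testing.assert_array_equal(C.values[xm, ym], cm)
        np.testing.assert_array_equal(C.values[xl, yl], cl)


class TestQuantalCatch:
    def _image(self, grid, values, pattern_shape):
        pat = ReferencePattern(np.zeros(pattern_shape), 4.0, 30)
        return SpectralImage(values, grid, pat)

    def test_zero_image_zero_catch(self, grid, template, media):
        mosaic = make_mosaic(12, 10, 0.5, 0)
        C = build_sensitivity_mosaic((520.0, 562.0), mosaic, template, media)
        im = self._image(grid, np.zeros((12, 10, grid.n)), (12, 10))
        assert not quantal_catch(im, C).any()

    def test_unit_image_unit_sensitivity_counts_samples(self, grid):
        mosaic = make_mosaic(6, 5, 0.5, 0)
        ones = np.ones(grid.n)
        C = SensitivityMosaic((520.0, 562.0), mosaic, ones, ones, grid)
        im = self._image(grid, np.ones((6, 5, grid.n)), (6, 5))
        np.testing.assert_allclose(quantal_catch(im, C), grid.n)  # = 76

    def test_matches_explicit_triple_loop(self, grid, template, media):
        rng = np.random.default_rng(8)
        mosaic = make_mosaic(7, 6, 0.5, 4)
        C = build_sensitivity_mosaic((510.0, 580.0), mosaic, template, media)
        values = rng.random((7, 6, grid.n))
        im = self._image(grid, values, (7, 6))
        got = quantal_catch(im, C)
        stack = C.values
        for x in range(7):
            for y in range(6):
                acc = 0.0
                for k in range(grid.n):
                    acc += values[x, y, k] * stack[x, y, k]
                assert got[x, y] == pytest.approx(acc, rel=1e-12)


class TestReceptiveField:
    def test_centre_weight_is_one_minus_omega(self):
        rf = make_receptive_fields()
        assert rf.w_on[4, 4] == pytest.approx(0.45, abs=1e-15)

    def test_off_centre_weight_matches_independent_evaluation(self):
        rf = make_receptive_fields()
        expected = np.exp(-1.0 / (2 * 0.25 ** 2)) \
            - 0.55 * np.exp(-1.0 / (2 * 1.66 ** 2))
        assert abs(rf.w_on[5, 4] - expected) < 1e-12

    def test_off_kernel_is_exact_negation(self):
        rf = make_receptive_fields()
        assert np.array_equal(rf.w_off, -rf.w_on)

    def test_quarter_turn_symmetry(self):
        rf = make_receptive_fields()
        np.testing.assert_array_equal(rf.w_on, np.rot90(rf.w_on))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            make_receptive_fields(nw=8)


class TestRgcResponses:
    def test_constant_input_scales_kernel_sum(self):
        rf = make_receptive_fields()
        g = rgc_responses(np.full((20, 15), 3.0), rf)
        np.testing.assert_allclose(g.g_on, 3.0 * rf.w_on.sum(), rtol=1e-12)

    def test_valid_convolution_output_dims(self):
        rf = make_receptive_fields()
        g = rgc_responses(np.ones((60, 30)), rf)
        assert g.g_on.shape == (52, 22)
        assert np.array_equal(g.g_off, -g.g_on)

    def test_matches_explicit_nested_loop(self):
        rng = np.random.default_rng(3)
        rf = make_receptive_fields()
        Q = rng.random((12, 11))
        got = rgc_responses(Q, rf).g_on
        for px in range(12 - 8):
            for py in range(11 - 8):
                acc = 0.0
                for u in range(9):
                    for v in range(9):
                        acc += Q[px + u, py + v] * rf.w_on[u, v]
                assert got[px, py] == pytest.approx(acc, rel=1e-12)

    def test_image_smaller_than_window_rejected(self):
        with pytest.raises(ValueError):
            rgc_responses(np.ones((5, 5)), make_receptive_fields())


class TestMasksAndChannels:
    def test_masks_are_complementary(self):
        mosaic = make_mosaic(10, 8, 0.5, 6)
        masks = identifier_masks(mosaic)
        np.testing.assert_array_equal(masks.l + masks.m, 1.0)

    def test_two_by_two_example(self):
        mosaic = Mosaic(np.array([["M", "L"], ["L", "M"]]), 0.5, 0)
        masks = identifier_masks(mosaic)
        np.testing.assert_array_equal(masks.l, [[0, 1], [1, 0]])

    def test_all_l_mosaic_red_green_equals_on_map(self):
        rf = make_receptive_fields()
        rng = np.random.default_rng(1)
        Q = rng.random((20, 15))
        g = rgc_responses(Q, rf)
        rg, lum = integrate_channels(g, identifier_masks(
            make_mosaic(20, 15, 1.0, 0)))
        np.testing.assert_array_equal(rg.values, g.g_on)
        np.testing.assert_array_equal(lum.values, g.g_on)

    def test_all_m_mosaic_red_green_is_negated(self):
        rf = make_receptive_fields()
        rng = np.random.default_rng(2)
        Q = rng.random((20, 15))
        g = rgc_responses(Q, rf)
        rg, _ = integrate_channels(g, identifier_masks(
            make_mosaic(20, 15, 0.0, 0)))
        np.testing.assert_array_equal(rg.values, -g.g_on)

    def test_luminance_channel_always_equals_on_map(self):
        rf = make_receptive_fields()
        rng = np.random.default_rng(4)
        Q = rng.random((16, 14))
        g = rgc_responses(Q, rf)
        _, lum = integrate_channels(g, identifier_masks(
            make_mosaic(16, 14, 0.5, 9)))
        np.testing.assert_array_equal(lum.values, g.g_on)


class TestPipelineProperties:
    def _red_green(self, image, pair, mosaic, template, media):
        C = build_sensitivity_mosaic(pair, mosaic, template, media)
        Q = quantal_catch(image, C)
        g = rgc_responses(Q, make_receptive_fields())
        rg, _ = integrate_channels(g, identifier_masks(mosaic))
        return Q, rg.values

    def test_output_homogeneous_in_image_intensity(self, grid, fruit_library,
                                                   forest_illuminant,
                                                   template, media):
        p = make_grating(4.0)
        im = assemble_image(p, fruit_library.targets[0],
                            fruit_library.background, forest_illuminant,
                            synth_luminance_field(*p.shape, 5), None)
        mosaic = make_mosaic(*p.shape, 0.5, 11)
        _, o1 = self._red_green(im, (525.0, 562.0), mosaic, template, media)
        im10 = SpectralImage(10.0 * im.values, grid, im.pattern_ref)
        _, o10 = self._red_green(im10, (525.0, 562.0), mosaic, template,
                                 media)
        np.testing.assert_allclose(o10, 10.0 * o1, rtol=1e-12)

    def test_uniform_scene_equal_peaks_gives_constant_output(
            self, grid, flat_illuminant, template, media):
        pat = ReferencePattern(np.ones((20, 16)), 4.0, 30)
        s = Spectrum(grid, np.full(grid.n, 0.5))
        im = assemble_image(pat, s, s, flat_illuminant, None, None)
        mosaic = make_mosaic(20, 16, 0.5, 3)
        Q, o = self._red_green(im, (530.0, 530.0), mosaic, template, media)
        rf = make_receptive_fields()
        q = Q[0, 0]
        np.testing.assert_allclose(np.abs(o), q * abs(rf.w_on.sum()),
                                   rtol=1e-9)

    def test_full_pipeline_matches_single_pixel_oracle(
            self, grid, fruit_library, forest_illuminant, template, media):
        # explicit 9x9 window x 76 wavelength loop at 20 random pixels
        p = make_grating(4.0)
        im = assemble_image(p, fruit_library.targets[2],
                            fruit_library.background, forest_illuminant,
                            synth_luminance_field(*p.shape, 8),
                            optics=None)
        mosaic = make_mosaic(*p.shape, 0.5, 21)
        _, o = self._red_green(im, (520.0, 562.0), mosaic, template, media)
        rf = make_receptive_fields()
        cm = cone_fundamental(520.0, template, media).values
        cl = cone_fundamental(562.0, template, media).values
        rng = np.random.default_rng(0)
        nx_o, ny_o = o.shape
        for _ in range(20):
            px, py = rng.integers(0, nx_o), rng.integers(0, ny_o)
            acc = 0.0
            for u in range(9):
                for v in range(9):
                    x, y = px + u, py + v
                    c = cl if mosaic.is_l[x, y] else cm
                    catch = 0.0
                    for k in range(grid.n):
                        catch += im.values[x, y, k] * c[k]
                    acc += catch * rf.w_on[u, v]
            sign = 1.0 if mosaic.is_l[px + 4, py + 4] else -1.0
            assert o[px, py] == pytest.approx(sign * acc, rel=1e-9)

    def test_red_step_edge_sign_convention(self, grid, fruit_library,
                                           forest_illuminant, template,
                                           media):
        # long-pass target on the right half: red-green output should be
        # higher on the target side when the L peak exceeds the M peak
        step = np.zeros((40, 20))
        step[20:] = 1.0
        pat = ReferencePattern(step, 4.0, 30)
        edge_fruit = next(s for s in fruit_library.targets
                          if "edge" in s.label)
        im = assemble_image(pat, edge_fruit, fruit_library.background,
                            forest_illuminant, None, None)
        mosaic = make_mosaic(40, 20, 0.5, 2)
        _, o = self._red_green(im, (520.0, 562.0), mosaic, template, media)
        ref = trim_border(step)
        assert o[ref > 0.5].mean() > o[ref < 0.5].mean()


def test_trim_border_removes_symmetric_margin():
    arr = np.arange(60 * 30, dtype=float).reshape(60, 30)
    out = trim_border(arr, 9)
    assert out.shape == (52, 22)
    assert out[0, 0] == arr[4, 4]


def test_ocular_media_table_loads_on_grid(grid, media):
    assert media.densities.shape == (grid.n,)
    assert media.densities[0] > 1.0          # strong short-wave filtering
    assert media.densities[-1] < 0.05
    assert np.all(media.transmission <= 1.0)
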