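"""Synthetic microstructure generator: determinism, census, geometry truth."""

import numpy as np
import pytest

from ocufsi.image import FLUID_LABELS, Label, SOLID_LABELS
from ocufsi.microstructure import (MicrostructureParams, PackingError,
                                   expected_pore_count,
                                   generate_microstructure, render_grayscale)


def small_params(**kw):
    base = dict(domain_width_um=16.0, jct_depth_um=10.0, sc_lumen_height_um=7.0,
                vacuole_width_um=6.0, vacuole_length_um=3.5)
    base.update(kw)
    return MicrostructureParams(**base)


class TestParams:
    def test_invalid_lengths(self):
        with pytest.raises(ValueError):
            MicrostructureParams(jct_depth_um=-1.0)

    def test_unresolvable_pixel(self):
        with pytest.raises(ValueError, match="resolve"):
            MicrostructureParams(pixel_size_um=0.4)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            MicrostructureParams(fraction_vacuoles_with_open_pore=1.5)
        with pytest.raises(ValueError):
            MicrostructureParams(intertrabecular_void_fraction=0.0)

    def test_domain_height_derived_from_bands(self):
        p = MicrostructureParams()
        assert p.domain_height_um == pytest.approx(
            p.ac_band_um + p.jct_depth_um + p.basement_membrane_thickness_um
            + p.inner_wall_thickness_um + p.sc_lumen_height_um)


class TestGenerate:
    def test_layered_bands_only_without_objects(self):
        p = small_params(n_vacuoles=0, intertrabecular_void_fraction=1e-9)
        img, truths = generate_microstructure(p, seed=3)
        assert truths == []
        assert np.count_nonzero(img.array == int(Label.PORE)) == 0
        assert np.count_nonzero(img.array == int(Label.VACUOLE_INTERIOR)) == 0
        # each band is a horizontal slab away from the sclera strips
        mid_col = img.array[:, img.shape[1] // 2]
        assert set(np.unique(mid_col)) <= {int(Label.BACKGROUND),
                                           int(Label.JCT_TISSUE),
                                           int(Label.INTERTRABECULAR_SPACE),
                                           int(Label.BASEMENT_MEMBRANE),
                                           int(Label.INNER_WALL_CELL),
                                           int(Label.SC_LUMEN)}

    def test_pore_raster_width(self):
        p = small_params(n_vacuoles=1, fraction_vacuoles_with_open_pore=1.0,
                         pore_diameter_um=1.3, pixel_size_um=0.05)
        img, truths = generate_microstructure(p, seed=2)
        assert truths[0].has_open_pore
        pore_cols = np.any(img.array == int(Label.PORE), axis=0)
        assert abs(np.count_nonzero(pore_cols) - 26) <= 1   # 1.3 / 0.05

    def test_determinism_and_seed_variation(self):
        p = MicrostructureParams()
        a, ta = generate_microstructure(p, seed=1)
        b, tb = generate_microstructure(p, seed=1)
        assert np.array_equal(a.array, b.array)
        assert ta[0].center_x_um == tb[0].center_x_um
        c, tc = generate_microstructure(p, seed=2)
        assert not np.array_equal(a.array, c.array)
        assert tc[0].center_x_um != ta[0].center_x_um
        # same expected label fractions: census within 5% on the solid phase
        fa = sum(a.census()[l] for l in SOLID_LABELS)
        fc = sum(c.census()[l] for l in SOLID_LABELS)
        assert abs(fa - fc) / fa < 0.05

    def test_void_fraction_census(self, label_and_truth, default_params):
        img, _ = label_and_truth
        arr = img.array
        px = img.pixel_size_um
        y = (np.arange(arr.shape[0]) + 0.5) * px
        band = (y >= default_params.y_jct_base) & (y < default_params.y_bm_base)
        sub = arr[band, :]
        void = np.count_nonzero(sub == int(Label.INTERTRABECULAR_SPACE))
        solid = np.count_nonzero(sub == int(Label.JCT_TISSUE))
        measured = void / (void + solid)
        assert measured == pytest.approx(
            default_params.intertrabecular_void_fraction, rel=0.10)

    def test_pore_pixels_bridge_interior_and_lumen(self, label_and_truth):
        img, truths = label_and_truth
        assert truths[0].has_open_pore
        arr = img.array
        pore = arr == int(Label.PORE)
        assert pore.any()
        from scipy import ndimage
        dil = ndimage.binary_dilation(pore, np.ones((3, 3), bool))
        assert (arr[dil] == int(Label.VACUOLE_INTERIOR)).any()
        assert (arr[dil] == int(Label.SC_LUMEN)).any()

    def test_extent_exact(self, label_and_truth):
        img, _ = label_and_truth
        ny, nx = img.shape
        assert img.extent_um == (nx * img.pixel_size_um, ny * img.pixel_size_um)

    def test_truth_matches_raster_within_pixel(self, label_and_truth):
        img, truths = label_and_truth
        tr = truths[0]
        arr = img.array
        px = img.pixel_size_um
        X = (np.arange(arr.shape[1])[None, :] + 0.5) * px
        Y = (np.arange(arr.shape[0])[:, None] + 0.5) * px
        m = (arr == int(Label.VACUOLE_INTERIOR)) & (Y >= tr.center_y_um)
        width = np.count_nonzero(np.any(m, axis=0)) * px
        assert abs(width - tr.width_um) <= px + 1e-9

    def test_infeasible_packing_raises(self):
        p = small_params(n_vacuoles=4, vacuole_width_um=10.0)
        with pytest.raises(PackingError, match="vacuole"):
            generate_microstructure(p, seed=1)

    def test_expected_pore_count_units(self):
        p = MicrostructureParams()
        # wall length x slab thickness at 292 / mm^2
        assert expected_pore_count(p) == pytest.approx(
            292.0 * p.domain_width_um * 0.26 * 1e-6)


class TestRender:
    def test_noiseless_is_piecewise_constant(self, label_and_truth):
        img, _ = label_and_truth
        g = render_grayscale(img, noise_sd=0.0, boundary_shading_strength=0.0)
        assert len(np.unique(g.array)) <= len(Label)

    def test_shading_creates_dark_dots_near_boundary(self, label_and_truth):
        from scipy import ndimage
        img, _ = label_and_truth
        g = render_grayscale(img, noise_sd=0.0, boundary_shading_strength=0.8,
                             seed=5)
        tissue = img.tissue_mask()
        dark = (g.array < 100) & ~tissue
        assert dark.any()
        near = ndimage.binary_dilation(tissue, np.ones((3, 3)), iterations=4)
        assert np.all(near[dark])

    def test_deterministic(self, label_and_truth):
        img, _ = label_and_truth
        a = render_grayscale(img, seed=7)
        b = render_grayscale(img, seed=7)
        assert np.array_equal(a.array, b.array)

    def test_negative_noise_rejected(self, label_and_truth):
        img, _ = label_and_truth
        with pytest.raises(ValueError):
            render_grayscale(img, noise_sd=-1.0)
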