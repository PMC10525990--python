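"""Mesh builder: structured grid arithmetic, part assignment, overlay,
refinement."""

import numpy as np
import pytest

from ocufsi.image import Label, LabelImage
from ocufsi.mesh import (FEMesh, MeshGeometryError, Part, assign_parts,
                         boundary_overlay_error, build_parent_mesh,
                         mesh_convergence, tissue_volume)


def label_image(arr, px=0.05):
    return LabelImage(array=np.asarray(arr, dtype=np.int16), pixel_size_um=px)


class TestParentMesh:
    def test_counts_10x10_quarter_micron(self):
        m = build_parent_mesh((10.0, 10.0), 0.25)
        assert m.n_elements == 1600
        assert m.nodes.shape[0] == 1681

    def test_slab_one_element_through_thickness(self):
        m = build_parent_mesh((12.0, 6.0), 0.25, mode_2d=False,
                              slab_thickness_um=0.26)
        assert m.elements.shape[1] == 8
        assert m.shape == (48, 24, 1)
        zs = np.unique(m.nodes[:, 2])
        assert np.allclose(zs, [0.0, 0.26])

    def test_volume_conservation(self):
        m = build_parent_mesh((7.5, 3.25), 0.25)
        assert m.total_volume() == pytest.approx(7.5 * 3.25, rel=1e-12)

    def test_indivisible_extent_rejected(self):
        with pytest.raises(MeshGeometryError):
            build_parent_mesh((10.1, 10.0), 0.25)

    def test_positive_jacobians(self):
        m = build_parent_mesh((4.0, 2.0), 0.5)
        q = m.nodes[m.elements]
        areas = 0.5 * ((q[:, 2, 0] - q[:, 0, 0]) * (q[:, 3, 1] - q[:, 1, 1])
                       + (q[:, 1, 0] - q[:, 3, 0]) * (q[:, 2, 1] - q[:, 0, 1]))
        assert np.all(areas > 0)

    def test_boundary_node_sets_present(self):
        m = build_parent_mesh((4.0, 2.0), 0.5)
        for k in ("inlet", "outlet", "lateral_left", "lateral_right"):
            assert len(m.node_sets[k]) > 0


class TestAssignParts:
    def test_half_tissue_half_fluid(self):
        arr = np.full((80, 80), int(Label.SC_LUMEN))
        arr[:, :40] = int(Label.JCT_TISSUE)      # left half tissue
        img = label_image(arr, px=0.05)          # 4 x 4 um
        m = build_parent_mesh(img.extent_um, 1.0)
        assign_parts(m, img)
        assert (m.part == int(Part.TISSUE)).sum() == 8
        assert np.isin(m.part, (int(Part.FLUID_AC), int(Part.FLUID_ZERO))).sum() == 8

    def test_tie_resolves_to_tissue(self):
        arr = np.full((20, 20), int(Label.SC_LUMEN))
        arr[:, :10] = int(Label.JCT_TISSUE)      # exact 50/50 in one element
        img = label_image(arr, px=0.05)
        m = build_parent_mesh((1.0, 1.0), 1.0)
        assign_parts(m, img)
        assert m.part[0] == int(Part.TISSUE)

    def test_finer_than_pixel_rejected(self):
        img = label_image(np.zeros((20, 20)), px=0.05)
        m = build_parent_mesh((1.0, 1.0), 0.025)
        with pytest.raises(MeshGeometryError):
            assign_parts(m, img)

    def test_near_wall_zero_pressure_tag(self, standard_setup):
        img, _, mesh = standard_setup
        nx, ny = mesh.shape
        lab = mesh.element_label.reshape(ny, nx)
        part = mesh.part.reshape(ny, nx)
        sc = lab == int(Label.SC_LUMEN)
        assert np.all(part[sc] == int(Part.FLUID_ZERO))
        bg = lab == int(Label.BACKGROUND)
        assert np.all(part[bg] == int(Part.FLUID_AC))

    def test_deep_jct_selector_distance(self, standard_setup):
        img, _, mesh1 = standard_setup
        m2 = build_parent_mesh(img.extent_um, 0.25)
        assign_parts(m2, img, "deep_jct")
        extra = (m2.part == int(Part.FLUID_ZERO)) \
            & (mesh1.part != int(Part.FLUID_ZERO))
        assert extra.any()
        bm_rows = np.nonzero(
            np.any(img.array == int(Label.BASEMENT_MEMBRANE), axis=1))[0]
        y_bm = bm_rows.min() * img.pixel_size_um
        cy = m2.element_centroids()[extra, 1]
        depth = y_bm - cy
        assert np.all((depth >= 3.0 - 1e-9) & (depth <= 5.0 + 1e-9))

    def test_deterministic_and_order_independent(self, standard_setup):
        img, _, mesh = standard_setup
        m2 = build_parent_mesh(img.extent_um, 0.25)
        assign_parts(m2, img)
        assert np.array_equal(m2.part, mesh.part)

    def test_sclera_tether_sets_nonempty(self, standard_setup):
        _, _, mesh = standard_setup
        assert len(mesh.node_sets["sclera_left"]) > 0
        assert len(mesh.node_sets["sclera_right"]) > 0


class TestOverlay:
    def test_exact_at_pixel_resolution(self, standard_setup):
        img, _, _ = standard_setup
        m = build_parent_mesh(img.extent_um, img.pixel_size_um)
        assign_parts(m, img)
        fracs, mean = boundary_overlay_error(m, img)
        assert mean == 0.0

    def test_quarter_micron_below_5pct(self, standard_setup):
        img, _, mesh = standard_setup
        fracs, mean = boundary_overlay_error(mesh, img)
        assert len(fracs) == 5
        assert mean < 0.05

    def test_pure_fluid_zero_mismatch(self):
        img = label_image(np.full((40, 40), int(Label.SC_LUMEN)), px=0.05)
        m = build_parent_mesh(img.extent_um, 0.5)
        assign_parts(m, img)
        _, mean = boundary_overlay_error(m, img, n_sections=3)
        assert mean == 0.0


class TestConvergence:
    def test_tissue_volume_approaches_pixel_count(self, standard_setup):
        img, _, _ = standard_setup
        truth = img.tissue_mask().sum() * img.pixel_size_um ** 2
        table = mesh_convergence(img, [1.0, 0.5, 0.25, 0.125], tissue_volume,
                                 tolerance=0.05)
        metrics = [row["metric"] for row in table]
        errs = [abs(m - truth) / truth for m in metrics]
        assert errs[-1] < errs[0]
        assert table[-1]["relative_change"] < 0.01
        assert table[-1]["converged"]

    def test_single_phase_constant_metric(self):
        img = label_image(np.full((80, 80), int(Label.SC_LUMEN)), px=0.05)
        table = mesh_convergence(img, [1.0, 0.5, 0.25],
                                 lambda m: float(len(np.unique(m.part))))
        assert len({row["metric"] for row in table}) == 1

    def test_metric_failure_names_edge_length(self, standard_setup):
        img, _, _ = standard_setup

        def bad(mesh):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="1.0"):
            mesh_convergence(img, [1.0, 0.5], bad)

    def test_requires_descending(self, standard_setup):
        img, _, _ = standard_setup
        with pytest.raises(ValueError):
            mesh_convergence(img, [0.25, 0.5], tissue_volume)
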