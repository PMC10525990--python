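"""Shared fixtures.

The expensive coupled runs (the standard pressurization fixture and its
flow-controlled variant) are session-scoped and shared between the solver,
postprocessing and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from ocufsi.image import Label, LabelImage
from ocufsi.microstructure import MicrostructureParams, generate_microstructure
from ocufsi.pipeline import standard_fixture
from ocufsi.solver import run_fsi, standard_desk_config


@pytest.fixture(scope="session")
def default_params():
    return MicrostructureParams()


@pytest.fixture(scope="session")
def label_and_truth(default_params):
    return generate_microstructure(default_params, seed=1)


@pytest.fixture(scope="session")
def standard_setup():
    """(label image, truths, part-assigned mesh) of the standard fixture."""
    return standard_fixture(seed=1)


@pytest.fixture(scope="session")
def standard_run(standard_setup):
    """Full pressure-ramp run of the standard fixture (0 -> 7 mmHg)."""
    _, truths, mesh = standard_setup
    series = run_fsi(mesh, config=standard_desk_config())
    return series, mesh, truths


def make_dome_fixture(radius_um=4.0, thickness_um=1.0, pixel_um=0.05,
                      width_um=16.0, height_um=14.0, base_y_um=4.0,
                      base_thickness_um=1.0, slot_um=4.0):
    """Sealed semicircular membrane dome over a pressurized cavity.

    A stiff scleral base wall spans the domain at ``base_y_um`` with a slot
    under the dome, so the inlet pressurizes the cavity; the dome (tissue,
    mid-surface radius ``radius_um``, thickness ``thickness_um``) carries the
    full pressure jump.  Ground truth: Laplace hoop stress p*r/t.  The slot
    is wide so the cavity charges much faster than the desk-scale ramp (the
    charging time is the slot resistance times the membrane compliance).
    """
    px = pixel_um
    nx, ny = int(width_um / px), int(height_um / px)
    X, Y = np.meshgrid((np.arange(nx) + 0.5) * px, (np.arange(ny) + 0.5) * px)
    lab = np.full((ny, nx), int(Label.SC_LUMEN), dtype=np.int16)
    lab[Y < base_y_um] = int(Label.BACKGROUND)
    base = (Y >= base_y_um) & (Y < base_y_um + base_thickness_um)
    lab[base] = int(Label.SCLERA)
    xc = width_um / 2.0
    y0 = base_y_um + base_thickness_um
    r_in = radius_um - thickness_um / 2.0
    r_out = radius_um + thickness_um / 2.0
    rr = np.hypot(X - xc, Y - y0)
    lab[(rr <= r_in) & (Y >= y0)] = int(Label.VACUOLE_INTERIOR)
    lab[(rr > r_in) & (rr <= r_out) & (Y >= y0)] = int(Label.INNER_WALL_CELL)
    slot = (np.abs(X - xc) <= slot_um / 2.0) & base
    lab[slot] = int(Label.VACUOLE_INTERIOR)
    return LabelImage(array=lab, pixel_size_um=px)


@pytest.fixture(scope="session")
def dome_run():
    """Pressurized sealed-dome run (Laplace / membrane-seal oracle)."""
    from ocufsi.mesh import assign_parts, build_parent_mesh

    img = make_dome_fixture()
    mesh = build_parent_mesh(img.extent_um, 0.25)
    assign_parts(mesh, img)
    # hold long enough for the cavity to charge through the slot (the
    # charging time is slot resistance x membrane compliance)
    cfg = standard_desk_config(target_pressure_mmHg=0.5,
                               ramp_duration_s=6e-5, n_output_steps=10,
                               hold_fraction=4.0)
    series = run_fsi(mesh, config=cfg)
    return series, mesh


def rng(seed=0):
    return np.random.default_rng(seed)
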