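"""Derived quantities of the coupled run: principal stress/strain fields,
fluid shear stress and wall shear stress, region-restricted volumetric
averages, recirculation (eddy) detection, giant-vacuole morphometry and the
analytic pore-velocity / Reynolds-number calculators.

Region conventions: JCT_SPACES are the intertrabecular spaces plus giant
vacuole interiors; SC_LUMEN is the canal lumen; cells within the near-sclera
exclusion distance of the scleral tether are always removed before averaging
(the tether perturbs the local hydrodynamics); cells mostly covered by solid
at the evaluated state are excluded from fluid statistics.

The reported "volumetric average shear stress" is the volume-weighted mean of
the fluid shear-stress magnitude over the region (primary route); per-face
wall shear stress on tissue surfaces is computed separately (secondary
route), since the two readings of the quantity differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import Label
from .mesh import FEMesh, Part
from .solver.driver import ResultSeries, SimulationState


# --------------------------------------------------------------------------
# tensor field reductions
# --------------------------------------------------------------------------

def first_principal(tensors: np.ndarray) -> np.ndarray:
    """Largest eigenvalue of each symmetric tensor in a (..., d, d) field."""
    tensors = np.asarray(tensors, dtype=float)
    if not np.allclose(tensors, np.swapaxes(tensors, -1, -2), atol=1e-9):
        raise ValueError("tensor field must be symmetric")
    return np.linalg.eigvalsh(tensors)[..., -1]


def volumetric_average(field: np.ndarray, region: np.ndarray,
                       volumes: np.ndarray | None = None) -> float:
    """Volume-weighted mean of ``field`` over boolean ``region``."""
    region = np.asarray(region, bool)
    if not np.any(region):
        raise ValueError("region is empty after exclusions")
    f = np.asarray(field, float)[region]
    if volumes is None:
        return float(f.mean())
    v = np.asarray(volumes, float)[region]
    return float(np.sum(f * v) / np.sum(v))


# --------------------------------------------------------------------------
# fluid shear
# --------------------------------------------------------------------------

def shear_stress_magnitude(u: np.ndarray, v: np.ndarray, dx: float,
                           mu_dyn: float) -> np.ndarray:
    """Deviatoric viscous shear-stress magnitude per cell [Pa].

    tau = 2 mu dev(sym grad u); the magnitude sqrt(0.5 tau:tau) reduces to
    the familiar mu*du/dy in simple shear.
    """
    dudy, dudx = np.gradient(np.asarray(u, float), dx)
    dvdy, dvdx = np.gradient(np.asarray(v, float), dx)
    div_half = 0.5 * (dudx + dvdy)
    txx = 2.0 * mu_dyn * (dudx - div_half)
    tyy = 2.0 * mu_dyn * (dvdy - div_half)
    txy = mu_dyn * (dudy + dvdx)
    return np.sqrt(0.5 * (txx ** 2 + tyy ** 2) + txy ** 2)


def wall_shear_stress(state: SimulationState, wall_mask: np.ndarray,
                      dx: float, mu_dyn: float):
    """Per-face wall shear stress on the faces between open fluid cells and
    wall cells, by one-sided difference with no-slip at the wall.

    Returns (values, positions, max).  Faces with a degenerate normal are
    skipped.  WSS is exactly linear in ``mu_dyn``.
    """
    wall = np.asarray(wall_mask, bool)
    u = np.asarray(state.fluid_u, float)
    v = np.asarray(state.fluid_v, float)
    ny, nx = wall.shape
    vals, pos = [], []
    # x-normal faces: fluid cell left/right of a wall cell -> tangential v
    for shift, sgn in ((1, 1), (-1, -1)):
        fluid_adj = ~wall & np.roll(wall, -shift, axis=1)
        if shift == 1:
            fluid_adj[:, -1] = False
        else:
            fluid_adj[:, 0] = False
        ii, jj = np.nonzero(fluid_adj)
        vals.append(mu_dyn * np.abs(v[ii, jj]) / (dx / 2.0))
        pos.append(np.column_stack([(jj + 0.5 + 0.5 * sgn) * dx,
                                    (ii + 0.5) * dx]))
    # y-normal faces -> tangential u
    for shift, sgn in ((1, 1), (-1, -1)):
        fluid_adj = ~wall & np.roll(wall, -shift, axis=0)
        if shift == 1:
            fluid_adj[-1, :] = False
        else:
            fluid_adj[0, :] = False
        ii, jj = np.nonzero(fluid_adj)
        vals.append(mu_dyn * np.abs(u[ii, jj]) / (dx / 2.0))
        pos.append(np.column_stack([(jj + 0.5) * dx,
                                    (ii + 0.5 + 0.5 * sgn) * dx]))
    values = np.concatenate(vals) if vals else np.empty(0)
    positions = np.vstack(pos) if pos else np.empty((0, 2))
    vmax = float(values.max()) if values.size else 0.0
    return values, positions, vmax


# --------------------------------------------------------------------------
# region masks
# --------------------------------------------------------------------------

@dataclass
class RegionMask:
    """Cell-level region masks on the fluid grid plus the membrane-element
    mask on the solid, with the near-sclera exclusion already applied."""

    jct_spaces: np.ndarray          # (ny, nx) bool
    sc_lumen: np.ndarray
    pore: np.ndarray
    near_sclera_exclusion: np.ndarray
    membrane_elements: np.ndarray   # bool over the mesh's elements
    exclusion_distance_um: float


def build_region_masks(mesh: FEMesh, state: SimulationState | None = None,
                       exclusion_distance_um: float = 2.0) -> RegionMask:
    """Classify fluid cells by the majority micrograph label of the element
    grid, excluding the near-sclera zone and (if a state is given) cells
    mostly covered by solid at that state."""
    if mesh.element_label is None:
        raise ValueError("mesh has no element labels; run assign_parts first")
    nx, ny = mesh.shape[:2]
    lab = mesh.element_label.reshape(ny, nx)
    sclera = lab == int(Label.SCLERA)
    dist = ndimage.distance_transform_edt(~sclera) * mesh.edge_length_um
    excl = dist < exclusion_distance_um
    open_cell = np.ones_like(excl)
    if state is not None:
        open_cell = state.fluid_volume_fraction > 0.5
    jct = np.isin(lab, (int(Label.INTERTRABECULAR_SPACE),
                        int(Label.VACUOLE_INTERIOR))) & ~excl & open_cell
    sc = (lab == int(Label.SC_LUMEN)) & ~excl & open_cell
    pore = (lab == int(Label.PORE)) & open_cell
    # membrane elements, with the near-sclera zone removed as well (reported
    # stresses/strains exclude the tether's artifact zone)
    membrane = np.isin(mesh.element_label,
                       (int(Label.INNER_WALL_CELL),
                        int(Label.BASEMENT_MEMBRANE))) & ~excl.ravel()
    return RegionMask(jct_spaces=jct, sc_lumen=sc, pore=pore,
                      near_sclera_exclusion=excl,
                      membrane_elements=membrane,
                      exclusion_distance_um=exclusion_distance_um)


# --------------------------------------------------------------------------
# recirculation
# --------------------------------------------------------------------------

def swirling_strength(u: np.ndarray, v: np.ndarray, dx: float) -> np.ndarray:
    """2-D swirling strength (imaginary part of the velocity-gradient
    eigenvalues); positive only inside locally rotating flow."""
    dudy, dudx = np.gradient(np.asarray(u, float), dx)
    dvdy, dvdx = np.gradient(np.asarray(v, float), dx)
    tr = dudx + dvdy
    det = dudx * dvdy - dudy * dvdx
    disc = tr ** 2 - 4.0 * det
    return np.where(disc < 0.0, 0.5 * np.sqrt(np.maximum(-disc, 0.0)), 0.0)


def detect_recirculation(u: np.ndarray, v: np.ndarray, dx: float,
                         region: np.ndarray | None = None,
                         rel_threshold: float = 0.1,
                         min_cells: int = 3):
    """Count contiguous swirling (recirculating) regions.

    Cells whose swirling strength exceeds ``rel_threshold`` times the field
    maximum (within ``region`` if given) are grouped by connectivity; groups
    of at least ``min_cells`` cells count as eddies.  Returns (count,
    centroid list in metres).  Shear-parallel flow has zero swirling
    strength, so uniform and channel flows report no eddies.
    """
    lam = swirling_strength(u, v, dx)
    if region is not None:
        lam = np.where(region, lam, 0.0)
    peak = lam.max()
    if peak <= 0.0:
        return 0, []
    mask = lam > rel_threshold * peak
    labels, n = ndimage.label(mask)
    cents = []
    for k in range(1, n + 1):
        ii, jj = np.nonzero(labels == k)
        if ii.size < min_cells:
            continue
        w = lam[ii, jj]
        cents.append(((jj * w).sum() / w.sum() * dx + 0.5 * dx,
                      (ii * w).sum() / w.sum() * dx + 0.5 * dx))
    return len(cents), cents


# --------------------------------------------------------------------------
# vacuole morphometry
# --------------------------------------------------------------------------

@dataclass
class MorphometryRecord:
    vacuole_id: int
    width_ref_um: float
    width_loaded_um: float
    length_ref_um: float
    length_loaded_um: float
    width_change_pct: float
    length_change_pct: float
    diameter_ref_um: float          # least-squares circle fit
    diameter_loaded_um: float
    sphere_volume_ref_um3: float    # (pi/6) d^3
    sphere_volume_loaded_um3: float
    volume_change_um3: float
    collapsed: bool = False


def fit_circle(points: np.ndarray):
    """Least-squares (Kasa) circle fit; returns (cx, cy, radius)."""
    pts = np.asarray(points, float)
    A = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(len(pts))])
    b = (pts ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = np.sqrt(c + cx ** 2 + cy ** 2)
    return float(cx), float(cy), float(r)


def _sphere_volume(d_um: float) -> float:
    return np.pi / 6.0 * d_um ** 3


def track_vacuole_boundary_nodes(series: ResultSeries, truth,
                                 dilation_um: float = 0.4) -> np.ndarray:
    """Solid-boundary node indices lining one vacuole cavity (reference
    configuration membership; the Lagrangian mesh provides correspondence
    between states)."""
    ref = series.solid_reference * 1e6       # um
    # boundary nodes of the solid
    elements = series.solid_elements_local()
    edges = np.concatenate([elements[:, [0, 1]], elements[:, [1, 2]],
                            elements[:, [2, 3]], elements[:, [3, 0]]], axis=0)
    key = np.sort(edges, axis=1)
    _, idx, cnt = np.unique(key, axis=0, return_index=True, return_counts=True)
    bnodes = np.unique(edges[idx[cnt == 1]])
    r = ref[bnodes]
    # cavity lining = boundary nodes adjacent to this vacuole's interior
    # cells, above the cavity base (nodes down the basal slot do not belong
    # to the wall-normal extent)
    nx, ny = series.mesh.shape[:2]
    lab = series.mesh.element_label.reshape(ny, nx)
    h = series.mesh.edge_length_um
    col = np.clip(np.round(r[:, 0] / h).astype(int), 0, nx)
    row = np.clip(np.round(r[:, 1] / h).astype(int), 0, ny)
    adj = np.zeros(len(bnodes), bool)
    for dr in (-1, 0):
        for dc in (-1, 0):
            rr = np.clip(row + dr, 0, ny - 1)
            cc = np.clip(col + dc, 0, nx - 1)
            adj |= lab[rr, cc] == int(Label.VACUOLE_INTERIOR)
    aw = truth.width_um / 2.0 + dilation_um
    inside = adj & (np.abs(r[:, 0] - truth.center_x_um) <= aw) \
        & (r[:, 1] >= truth.center_y_um - 1e-6)
    return bnodes[inside]


def vacuole_morphometry(series: ResultSeries, truths,
                        states: tuple[int, int] = (0, -1)
                        ) -> list[MorphometryRecord]:
    """Width (wall-parallel), length (wall-normal), circle-fit diameter and
    reconstructed sphere volume of each vacuole at the reference and loaded
    snapshots, with percent changes."""
    k0, k1 = states
    recs = []
    for tr in truths:
        nodes = track_vacuole_boundary_nodes(series, tr)
        if nodes.size < 4:
            recs.append(MorphometryRecord(tr.id, 0, 0, 0, 0, 0, 0, 0, 0,
                                          0, 0, 0, collapsed=True))
            continue
        out = []
        for k in (k0, k1):
            pts = (series.solid_reference[nodes]
                   + series.states[k].solid_displacement[nodes]) * 1e6
            w = pts[:, 0].max() - pts[:, 0].min()
            ln = pts[:, 1].max() - pts[:, 1].min()
            _, _, r = fit_circle(pts)
            out.append((w, ln, 2 * r))
        (w0, l0, d0), (w1, l1, d1) = out
        collapsed = min(w1, l1) <= 0
        recs.append(MorphometryRecord(
            vacuole_id=tr.id,
            width_ref_um=w0, width_loaded_um=w1,
            length_ref_um=l0, length_loaded_um=l1,
            width_change_pct=100.0 * (w1 / w0 - 1.0) if w0 else 0.0,
            length_change_pct=100.0 * (l1 / l0 - 1.0) if l0 else 0.0,
            diameter_ref_um=d0, diameter_loaded_um=d1,
            sphere_volume_ref_um3=_sphere_volume(d0),
            sphere_volume_loaded_um3=_sphere_volume(d1),
            volume_change_um3=_sphere_volume(d1) - _sphere_volume(d0),
            collapsed=collapsed))
    return recs


# --------------------------------------------------------------------------
# analytic pore flow
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PoreFlowModel:
    """Q = V A bookkeeping for flow through N circular inner-wall pores."""

    Q_ul_min: float         # aqueous outflow rate [uL/min]
    N: int                  # number of pores
    d_um: float             # pore diameter [um]

    def __post_init__(self):
        if self.Q_ul_min <= 0 or self.N <= 0 or self.d_um <= 0:
            raise ValueError("Q, N and d must all be positive")

    @property
    def Q_m3_s(self) -> float:
        return self.Q_ul_min * 1e-9 / 60.0

    @property
    def total_pore_area_m2(self) -> float:
        return self.N * np.pi * (self.d_um * 1e-6 / 2.0) ** 2


def pore_velocity(model: PoreFlowModel) -> float:
    """Mean trans-pore velocity V = Q / (N pi (d/2)^2) [m/s]."""
    return model.Q_m3_s / model.total_pore_area_m2


def reynolds_number(rho: float, velocity: float, length: float,
                    mu_dyn: float) -> float:
    """Re = rho v L / mu."""
    if rho <= 0 or length <= 0 or mu_dyn <= 0 or velocity < 0:
        raise ValueError("rho, L, mu must be positive; velocity non-negative")
    return rho * velocity * length / mu_dyn
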