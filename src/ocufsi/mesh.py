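"""Pixel/voxel-to-finite-element meshing.

A structured parent grid of 4-node quadrilaterals (2-D plane-strain mode, the
desk-scale default) or 8-node hexahedra (one-element-thick slab mode) is laid
over the imaged extent; each element is then assigned to a part by majority
vote over the pixels it covers, with a tissue-wins tie-break (conservative
toward retaining the flow-resisting solid phase).  Validation mirrors the
imaging workflow: boundary overlay mismatch at evenly spaced cross-sections
and mesh-density (refinement) analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .image import Label, LabelImage, SOLID_LABELS


class Part(IntEnum):
    TISSUE = 1
    SCLERA = 2
    FLUID_AC = 3     # aqueous humor, anterior-chamber pressure component
    FLUID_ZERO = 4   # aqueous humor initialized at 0 gauge


FLUID_PARTS = (Part.FLUID_AC, Part.FLUID_ZERO)

#: near-wall fluid labels that start at 0 gauge in Model #1
_NEAR_WALL_ZERO = {Label.SC_LUMEN, Label.PORE, Label.VACUOLE_INTERIOR}


class MeshGeometryError(ValueError):
    pass


@dataclass
class FEMesh:
    """Structured conforming mesh with per-element part labels."""

    nodes: np.ndarray           # (n_nodes, dim) um
    elements: np.ndarray        # (n_el, 4) quads or (n_el, 8) hexes
    part: np.ndarray            # (n_el,) Part codes
    edge_length_um: float
    shape: tuple[int, ...]      # elements per axis (nex, ney[, nez])
    mode: str = "2d"            # "2d" | "slab3d"
    node_sets: dict = field(default_factory=dict)
    element_label: np.ndarray | None = None   # majority Label per element
    pixel_size_um: float | None = None
    slab_thickness_um: float | None = None

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def extent_um(self) -> tuple[float, ...]:
        return tuple(n * self.edge_length_um for n in self.shape[:2]) + (
            (self.slab_thickness_um,) if self.mode == "slab3d" else ())

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def total_volume(self) -> float:
        """Sum of element areas (2-D, um^2) or volumes (slab, um^3)."""
        if self.mode == "2d":
            return self.n_elements * self.edge_length_um ** 2
        dz = self.slab_thickness_um / self.shape[2]
        return self.n_elements * self.edge_length_um ** 2 * dz


def build_parent_mesh(extent_um, edge_length_um: float,
                      mode_2d: bool = True,
                      slab_thickness_um: float = 0.26) -> FEMesh:
    """Axis-aligned structured parent mesh covering ``extent_um``.

    ``extent_um`` is (width, height); in slab mode one hexahedral element
    spans ``slab_thickness_um`` through z.  The edge length must divide the
    extent to within rounding.
    """
    if edge_length_um <= 0:
        raise MeshGeometryError("edge length must be positive")
    ext = tuple(float(v) for v in extent_um)[:2]
    counts = []
    for v in ext:
        n = v / edge_length_um
        if abs(n - round(n)) > 1e-6 * max(1.0, n):
            raise MeshGeometryError(
                f"edge length {edge_length_um} does not divide extent {v}")
        counts.append(int(round(n)))
    nex, ney = counts
    h = edge_length_um
    xs = np.arange(nex + 1) * h
    ys = np.arange(ney + 1) * h
    XX, YY = np.meshgrid(xs, ys)
    nodes2d = np.column_stack([XX.ravel(), YY.ravel()])

    nn_x = nex + 1
    jj, ii = np.meshgrid(np.arange(nex), np.arange(ney))
    n0 = (ii * nn_x + jj).ravel()
    quad = np.column_stack([n0, n0 + 1, n0 + 1 + nn_x, n0 + nn_x])

    if mode_2d:
        nodes, elements, shape, mode = nodes2d, quad, (nex, ney), "2d"
    else:
        nz = 1
        n_layer = nodes2d.shape[0]
        bot = np.column_stack([nodes2d, np.zeros(n_layer)])
        top = np.column_stack([nodes2d, np.full(n_layer, slab_thickness_um)])
        nodes = np.vstack([bot, top])
        elements = np.column_stack([quad, quad + n_layer])
        shape, mode = (nex, ney, nz), "slab3d"

    mesh = FEMesh(nodes=nodes, elements=elements,
                  part=np.full(elements.shape[0], int(Part.FLUID_AC), dtype=np.int8),
                  edge_length_um=edge_length_um, shape=shape, mode=mode,
                  slab_thickness_um=slab_thickness_um if not mode_2d else None)
    _build_boundary_node_sets(mesh, ext)
    return mesh


def _build_boundary_node_sets(mesh: FEMesh, ext) -> None:
    x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
    tol = 1e-9
    ns = {
        "inlet": np.flatnonzero(np.abs(y) < tol),
        "outlet": np.flatnonzero(np.abs(y - ext[1]) < tol),
        "lateral_left": np.flatnonzero(np.abs(x) < tol),
        "lateral_right": np.flatnonzero(np.abs(x - ext[0]) < tol),
    }
    if mesh.mode == "slab3d":
        z = mesh.nodes[:, 2]
        ns["slab_front"] = np.flatnonzero(np.abs(z) < tol)
        ns["slab_back"] = np.flatnonzero(np.abs(z - mesh.slab_thickness_um) < tol)
    mesh.node_sets.update(ns)


def _pixel_to_element_index(label: LabelImage, mesh: FEMesh):
    px = label.pixel_size_um
    h = mesh.edge_length_um
    ny, nx = label.array.shape
    nex, ney = mesh.shape[:2]
    col_e = np.minimum(((np.arange(nx) + 0.5) * px / h).astype(int), nex - 1)
    row_e = np.minimum(((np.arange(ny) + 0.5) * px / h).astype(int), ney - 1)
    return row_e, col_e


def assign_parts(mesh: FEMesh, label: LabelImage,
                 zero_pressure_selector: str | None = None,
                 deep_jct_range_um: tuple[float, float] = (3.0, 5.0)) -> FEMesh:
    """Assign each element a part from the label image by majority vote.

    Tissue labels map to TISSUE, sclera to SCLERA, everything else to fluid.
    The FLUID_AC / FLUID_ZERO split is an initial-condition tag only:
    ``zero_pressure_selector=None`` (Model #1) zeroes the near-wall spaces
    (SC lumen, pores, vacuole interiors); ``"deep_jct"`` (Model #2) also
    zeroes intertrabecular spaces 3-5 um into the JCT from the basement
    membrane.  Ties between tissue and fluid resolve to TISSUE.
    """
    if zero_pressure_selector not in (None, "near_wall", "deep_jct"):
        raise ValueError(f"unknown selector {zero_pressure_selector!r}")
    if mesh.edge_length_um < label.pixel_size_um - 1e-12:
        raise MeshGeometryError("element edge length cannot be finer than the "
                                "source raster pixel size")
    W, H = label.extent_um
    ew, eh = mesh.shape[0] * mesh.edge_length_um, mesh.shape[1] * mesh.edge_length_um
    if ew > W + 1e-9 or eh > H + 1e-9:
        raise MeshGeometryError("mesh extent exceeds image extent")

    nex, ney = mesh.shape[:2]
    n_el = nex * ney
    row_e, col_e = _pixel_to_element_index(label, mesh)
    el_of_pixel = row_e[:, None] * nex + col_e[None, :]
    n_lab = max(int(v) for v in Label) + 1
    counts = np.zeros((n_el, n_lab), dtype=np.int64)
    np.add.at(counts, (el_of_pixel.ravel(), label.array.ravel()), 1)
    covered = counts.sum(axis=1)
    if np.any(covered == 0):
        bad = int(np.flatnonzero(covered == 0)[0])
        raise MeshGeometryError(f"element {bad} covers zero pixels "
                                "(geometry mismatch between mesh and image)")

    solid_idx = [int(v) for v in SOLID_LABELS if v != Label.SCLERA]
    tissue_ct = counts[:, solid_idx].sum(axis=1)
    sclera_ct = counts[:, int(Label.SCLERA)]
    fluid_ct = covered - tissue_ct - sclera_ct

    part = np.full(n_el, int(Part.FLUID_AC), dtype=np.int8)
    # majority with tissue-wins tie-break: solid wins ties against fluid
    solid_ct = tissue_ct + sclera_ct
    is_solid = solid_ct >= fluid_ct
    is_solid &= solid_ct > 0
    part[is_solid & (sclera_ct > tissue_ct)] = int(Part.SCLERA)
    part[is_solid & (sclera_ct <= tissue_ct)] = int(Part.TISSUE)

    # majority label per element (for region masks downstream)
    maj_label = counts.argmax(axis=1).astype(np.int16)

    fluid = ~is_solid
    fluid_counts = counts.copy()
    for v in (Label.INNER_WALL_CELL, Label.BASEMENT_MEMBRANE,
              Label.JCT_TISSUE, Label.SCLERA):
        fluid_counts[:, int(v)] = 0
    maj_fluid = fluid_counts.argmax(axis=1)
    near_wall_zero = np.isin(maj_fluid, [int(v) for v in _NEAR_WALL_ZERO])
    zero = fluid & near_wall_zero
    if zero_pressure_selector == "deep_jct":
        bm_rows = np.nonzero(np.any(label.array == int(Label.BASEMENT_MEMBRANE),
                                    axis=1))[0]
        if bm_rows.size == 0:
            raise MeshGeometryError("deep_jct selector requires a basement "
                                    "membrane in the image")
        y_bm = bm_rows.min() * label.pixel_size_um
        cy = mesh.element_centroids()[:, 1]
        depth = y_bm - cy
        lo, hi = deep_jct_range_um
        deep = fluid & (maj_fluid == int(Label.INTERTRABECULAR_SPACE)) \
            & (depth >= lo) & (depth <= hi)
        zero |= deep
    part[zero] = int(Part.FLUID_ZERO)

    mesh.part = part
    mesh.element_label = maj_label
    mesh.pixel_size_um = label.pixel_size_um

    # sclera tether faces: lateral boundary nodes belonging to sclera elements
    for side in ("lateral_left", "lateral_right"):
        lat = set(mesh.node_sets[side].tolist())
        scl_nodes = np.unique(mesh.elements[part == int(Part.SCLERA)])
        mesh.node_sets[f"sclera_{side.split('_')[1]}"] = np.array(
            sorted(lat & set(scl_nodes.tolist())), dtype=int)
    return mesh


def boundary_overlay_error(mesh: FEMesh, label: LabelImage,
                           n_sections: int = 5):
    """Tissue/fluid mismatch fraction at ``n_sections`` evenly spaced rows.

    Compares each pixel's tissue-vs-fluid class along a cross-section row
    with the part of the element containing it.  Returns (per-section
    fractions, mean).
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    ny, nx = label.array.shape
    rows = np.linspace(0, ny - 1, n_sections + 2)[1:-1].astype(int)
    row_e, col_e = _pixel_to_element_index(label, mesh)
    nex = mesh.shape[0]
    solid_parts = (int(Part.TISSUE), int(Part.SCLERA))
    fracs = []
    tissue = label.tissue_mask()
    for r in rows:
        el = row_e[r] * nex + col_e
        el_solid = np.isin(mesh.part[el], solid_parts)
        fracs.append(float(np.mean(el_solid != tissue[r])))
    fracs = np.asarray(fracs)
    return fracs, float(fracs.mean())


def mesh_convergence(label: LabelImage, edge_lengths, metric_fn,
                     tolerance: float = 0.05,
                     zero_pressure_selector: str | None = None):
    """Refinement study: run ``metric_fn(mesh)`` per edge length.

    ``edge_lengths`` must be descending (coarse to fine).  Returns a list of
    dicts with edge length, metric and relative change, plus a ``converged``
    flag on the last row (change below ``tolerance``).  Metric failures are
    re-raised with the offending edge length named.
    """
    edges = list(edge_lengths)
    if len(edges) < 2:
        raise ValueError("need at least two edge lengths")
    if any(b >= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edge lengths must be strictly descending")
    table = []
    prev = None
    for h in edges:
        try:
            mesh = build_parent_mesh(label.extent_um, h)
            assign_parts(mesh, label, zero_pressure_selector)
            val = float(metric_fn(mesh))
        except Exception as exc:
            raise RuntimeError(f"metric failed at edge length {h} um") from exc
        change = abs(val - prev) / abs(prev) if prev not in (None, 0.0) else np.nan
        table.append({"edge_length_um": h, "metric": val,
                      "relative_change": change})
        prev = val
    table[-1]["converged"] = bool(table[-1]["relative_change"] < tolerance)
    return table


def tissue_volume(mesh: FEMesh) -> float:
    """Total area (2-D) of TISSUE+SCLERA elements [um^2]; a common metric."""
    solid = np.isin(mesh.part, (int(Part.TISSUE), int(Part.SCLERA)))
    return float(np.count_nonzero(solid)) * mesh.edge_length_um ** 2
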