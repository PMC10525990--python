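"""File I/O: TIFF rasters with pixel-size metadata, CSV tables, a minimal
legacy-VTK writer for meshes and fields, HDF5 result containers and YAML run
configs."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .image import BinaryMask, GrayImage, LabelImage
from .mesh import FEMesh


def _resolution(pixel_size_um: float):
    # TIFF resolution in pixels per centimetre
    ppcm = 1e4 / pixel_size_um
    return (ppcm, ppcm), "CENTIMETER"


def write_label_tiff(path, label: LabelImage) -> None:
    res, unit = _resolution(label.pixel_size_um)
    tifffile.imwrite(path, label.array.astype(np.int16), resolution=res,
                     resolutionunit=unit,
                     metadata={"pixel_size_um": label.pixel_size_um,
                               "slice_thickness_um": label.slice_thickness_um,
                               "n_slices": label.n_slices,
                               "kind": "label"})


def read_label_tiff(path) -> LabelImage:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    return LabelImage(array=arr,
                      pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
                      slice_thickness_um=float(meta.get("slice_thickness_um", 0.13)),
                      n_slices=int(meta.get("n_slices", 1)))


def write_gray_tiff(path, gray: GrayImage) -> None:
    res, unit = _resolution(gray.pixel_size_um)
    tifffile.imwrite(path, gray.array.astype(np.float32), resolution=res,
                     resolutionunit=unit,
                     metadata={"pixel_size_um": gray.pixel_size_um,
                               "slice_thickness_um": gray.slice_thickness_um,
                               "n_slices": gray.n_slices, "kind": "gray"})


def read_gray_tiff(path) -> GrayImage:
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    return GrayImage(array=arr,
                     pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
                     slice_thickness_um=float(meta.get("slice_thickness_um", 0.13)),
                     n_slices=int(meta.get("n_slices", 1)))


def write_mask_tiff(path, mask: BinaryMask) -> None:
    res, unit = _resolution(mask.pixel_size_um)
    tifffile.imwrite(path, mask.array.astype(np.uint8), resolution=res,
                     resolutionunit=unit,
                     metadata={"pixel_size_um": mask.pixel_size_um, "kind": "mask"})


def write_vacuole_truth_csv(path, truths) -> None:
    import csv
    rows = [asdict(t) for t in truths]
    with open(path, "w", newline="") as fh:
        if not rows:
            fh.write("")
            return
        w = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        w.writeheader()
        w.writerows(rows)


def write_boundaries_csv(path, polylines) -> None:
    """Vertex lists, one polyline id per row group (x_um, y_um)."""
    with open(path, "w") as fh:
        fh.write("polyline_id,x_um,y_um\n")
        for k, poly in enumerate(polylines):
            for x, y in poly:
                fh.write(f"{k},{x:.6f},{y:.6f}\n")


def write_config_yaml(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_node_sets_json(path, mesh: FEMesh) -> None:
    with open(path, "w") as fh:
        json.dump({k: np.asarray(v).tolist() for k, v in mesh.node_sets.items()},
                  fh)


def write_mesh_vtk(path, mesh: FEMesh, cell_data: dict | None = None) -> None:
    """Legacy ASCII VTK unstructured grid with per-cell fields."""
    nodes = mesh.nodes
    if nodes.shape[1] == 2:
        nodes = np.column_stack([nodes, np.zeros(len(nodes))])
    cells = mesh.elements
    ctype = 9 if cells.shape[1] == 4 else 12   # VTK_QUAD / VTK_HEXAHEDRON
    data = {"part": mesh.part}
    if mesh.element_label is not None:
        data["label"] = mesh.element_label
    data.update(cell_data or {})
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nocufsi mesh\nASCII\n"
                 "DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        np.savetxt(fh, nodes, fmt="%.9g")
        fh.write(f"CELLS {len(cells)} {len(cells) * (cells.shape[1] + 1)}\n")
        np.savetxt(fh, np.column_stack(
            [np.full(len(cells), cells.shape[1]), cells]), fmt="%d")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        np.savetxt(fh, np.full(len(cells), ctype), fmt="%d")
        fh.write(f"CELL_DATA {len(cells)}\n")
        for name, arr in data.items():
            arr = np.asarray(arr)
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.astype(float), fmt="%.9g")


def write_state_vtk(path, series, k: int = -1) -> None:
    """Legacy-VTK snapshot: the deformed solid with first-principal stress /
    strain as cell data, plus the fluid grid as a second file
    (``<path>.fluid.vtk``) with pressure and velocity."""
    from .postprocess import first_principal

    state = series.states[k]
    nodes = (series.solid_reference + state.solid_displacement) * 1e6  # um
    elements = series.solid_elements_local()
    nodes3 = np.column_stack([nodes, np.zeros(len(nodes))])
    s1 = first_principal(state.stress_tensors())
    e1 = first_principal(state.strain_tensors())
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nocufsi solid state\nASCII\n"
                 "DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes3)} double\n")
        np.savetxt(fh, nodes3, fmt="%.9g")
        fh.write(f"CELLS {len(elements)} {len(elements) * 5}\n")
        np.savetxt(fh, np.column_stack(
            [np.full(len(elements), 4), elements]), fmt="%d")
        fh.write(f"CELL_TYPES {len(elements)}\n")
        np.savetxt(fh, np.full(len(elements), 9), fmt="%d")
        fh.write(f"CELL_DATA {len(elements)}\n")
        for name, arr in (("first_principal_stress_pa", s1),
                          ("first_principal_strain", e1)):
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr.astype(float), fmt="%.9g")

    ny, nx = state.fluid_pressure.shape
    dx_um = series.dx * 1e6
    fpath = str(path) + ".fluid.vtk"
    with open(fpath, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nocufsi fluid state\nASCII\n"
                 "DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} 1\n")
        fh.write(f"ORIGIN {dx_um / 2} {dx_um / 2} 0\n")
        fh.write(f"SPACING {dx_um} {dx_um} {dx_um}\n")
        fh.write(f"POINT_DATA {nx * ny}\n")
        fh.write("SCALARS pressure_pa double 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, np.asarray(state.fluid_pressure, float).ravel(),
                   fmt="%.9g")
        fh.write("VECTORS velocity_m_s double\n")
        vel = np.column_stack([np.asarray(state.fluid_u, float).ravel(),
                               np.asarray(state.fluid_v, float).ravel(),
                               np.zeros(nx * ny)])
        np.savetxt(fh, vel, fmt="%.9g")


def write_results_h5(path, series) -> None:
    """ResultSeries snapshots into one HDF5 container."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["dx_m"] = series.dx
        h5.attrs["c_eff_m_s"] = series.c_eff
        h5.attrs["dt_s"] = series.dt
        h5.attrs["config_json"] = json.dumps(series.config.to_dict())
        h5.create_dataset("solid_node_ids", data=series.solid_node_ids)
        h5.create_dataset("solid_element_ids", data=series.solid_element_ids)
        h5.create_dataset("solid_reference_m", data=series.solid_reference)
        for k, s in enumerate(series.states):
            g = h5.create_group(f"state_{k:04d}")
            g.attrs["time_s"] = s.time
            g.attrs["inlet_pressure_pa"] = s.inlet_pressure_pa
            for name in ("solid_displacement", "solid_velocity",
                         "solid_stress", "solid_strain", "fluid_rho",
                         "fluid_u", "fluid_v", "fluid_energy",
                         "fluid_pressure", "fluid_volume_fraction"):
                g.create_dataset(name, data=getattr(s, name),
                                 compression="gzip", compression_opts=1)
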