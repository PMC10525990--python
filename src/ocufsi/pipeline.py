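"""End-to-end orchestration: generate -> segment -> mesh -> run -> post.

A single YAML/dict config drives all stages; every stage is deterministic
under the config seed, outputs land in a run directory named by the config
hash, and completed stages are resumed from their cached outputs on re-run
(caching never changes results: the cache key is the full config hash).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as oio
from .image import Label
from .mesh import (FEMesh, Part, assign_parts, boundary_overlay_error,
                   build_parent_mesh)
from .microstructure import (MicrostructureParams, generate_microstructure,
                             render_grayscale)
from .postprocess import (build_region_masks, detect_recirculation,
                          first_principal, shear_stress_magnitude,
                          vacuole_morphometry, volumetric_average,
                          track_vacuole_boundary_nodes)
from .segmentation import binarize, mask_from_labels, remove_boundary_artifacts
from .solver import SolverConfig, run_fsi, standard_desk_config

DEFAULT_CONFIG = {
    "seed": 1,
    "microstructure": {},          # MicrostructureParams overrides
    "render": {"noise_sd": 4.0, "boundary_shading_strength": 0.5},
    "segmentation": {"min_component_px": 64, "max_artifact_distance_px": 5},
    "mesh": {"edge_length_um": 0.25, "model": 1},
    "solver": {"ramp_duration_s": 2.0e-4, "n_output_steps": 60},
    "post": {"exclusion_distance_um": 2.0},
}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    outputs: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    failed_stage: str | None = None
    error: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _merged(config: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (config or {}).items():
        if isinstance(v, dict) and k in cfg:
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def standard_fixture(seed: int = 1, model: int = 1,
                     edge_length_um: float = 0.25,
                     params: MicrostructureParams | None = None):
    """The standard desk-scale fixture: default microstructure (one giant
    vacuole with an open pore over a ~20 um JCT), meshed and part-labeled.
    Returns (label image, vacuole truths, mesh)."""
    p = params or MicrostructureParams()
    img, truths = generate_microstructure(p, seed=seed)
    mesh = build_parent_mesh(img.extent_um, edge_length_um)
    assign_parts(mesh, img,
                 None if model == 1 else "deep_jct")
    return img, truths, mesh


def tracked_pore_cells(series, mesh: FEMesh, state_idx: int = -1,
                       pad_um: float = 0.15) -> np.ndarray:
    """Open fluid cells across the (displaced) pore throat at a snapshot.

    The pore rim is tracked by the Lagrangian boundary nodes that start
    adjacent to PORE-labeled cells; the returned mask covers the mid-height
    rows of their displaced bounding box (the throat cross-section), so the
    mean speed over it is the mean velocity crossing the pore.
    """
    nx, ny = mesh.shape[:2]
    lab = mesh.element_label.reshape(ny, nx)
    ii, jj = np.nonzero(lab == int(Label.PORE))
    if ii.size == 0:
        return np.zeros((ny, nx), bool)
    h = mesh.edge_length_um * 1e-6
    ref = series.solid_reference
    x0, x1 = (jj.min()) * h - pad_um * 1e-6, (jj.max() + 1) * h + pad_um * 1e-6
    y0, y1 = (ii.min()) * h - pad_um * 1e-6, (ii.max() + 1) * h + pad_um * 1e-6
    near = ((ref[:, 0] >= x0 - h) & (ref[:, 0] <= x1 + h)
            & (ref[:, 1] >= y0 - h) & (ref[:, 1] <= y1 + h))
    if not np.any(near):
        return np.zeros((ny, nx), bool)
    state = series.states[state_idx]
    pos = ref[near] + state.solid_displacement[near]
    bx0, bx1 = pos[:, 0].min(), pos[:, 0].max()
    ym = 0.5 * (pos[:, 1].min() + pos[:, 1].max())
    xc = (np.arange(nx) + 0.5) * h
    yc = (np.arange(ny) + 0.5) * h
    box = (xc[None, :] >= bx0) & (xc[None, :] <= bx1) \
        & (np.abs(yc[:, None] - ym) <= h)
    return box & (state.fluid_volume_fraction > 0.5)


def summarize_run(series, mesh: FEMesh, truths,
                  exclusion_distance_um: float = 2.0,
                  mu_dyn: float = 0.7185e-3) -> dict:
    """Headline quantities of a standard-fixture run (units as reported in
    the outflow literature: kPa, %, Pa, m/s)."""
    final = series.states[-1]
    masks = build_region_masks(mesh, final, exclusion_distance_um)
    el_ids = series.solid_element_ids
    memb = masks.membrane_elements[el_ids]

    s1 = first_principal(final.stress_tensors()[memb])
    e1 = first_principal(final.strain_tensors()[memb])
    tau = shear_stress_magnitude(final.fluid_u, final.fluid_v, series.dx,
                                 mu_dyn)
    speed = np.hypot(final.fluid_u, final.fluid_v)
    pore_cells = tracked_pore_cells(series, mesh)
    morph = vacuole_morphometry(series, truths)
    n_eddies, _ = detect_recirculation(final.fluid_u, final.fluid_v,
                                       series.dx, region=masks.sc_lumen)
    out = {
        "peak_membrane_stress_kpa": float(s1.max()) / 1e3,
        "peak_membrane_strain_pct": float(e1.max()) * 100.0,
        "avg_shear_jct_spaces_pa": volumetric_average(tau, masks.jct_spaces),
        "avg_shear_sc_lumen_pa": volumetric_average(tau, masks.sc_lumen),
        "mean_pore_velocity_m_s": (float(speed[pore_cells].mean())
                                   if np.any(pore_cells) else 0.0),
        "n_recirculation_regions_sc": int(n_eddies),
    }
    if morph:
        out["vacuole_width_increase_pct"] = float(
            np.mean([m.width_change_pct for m in morph]))
        out["vacuole_length_increase_pct"] = float(
            np.mean([m.length_change_pct for m in morph]))
        out["vacuole_volume_change_um3"] = float(
            np.mean([m.volume_change_um3 for m in morph]))
    return out


def run_pipeline(config: dict | str | Path | None = None,
                 out_root: str | Path = "runs") -> RunManifest:
    """Execute all stages under a single config; cached stages are reused.

    Returns the manifest; on stage failure the manifest records the failed
    stage and the error, and the exception is re-raised by default via
    ``manifest.failed_stage`` inspection at the call site (the CLI exits
    non-zero).
    """
    if isinstance(config, (str, Path)):
        config = oio.read_config_yaml(config)
    cfg = _merged(config)
    h = config_hash(cfg)
    from . import __version__
    out_dir = Path(out_root) / h
    out_dir.mkdir(parents=True, exist_ok=True)
    man = RunManifest(config_hash=h, seed=int(cfg["seed"]),
                      package_version=__version__)
    seed = int(cfg["seed"])

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            man.failed_stage = name
            man.error = f"{type(exc).__name__}: {exc}"
            _write_manifest()
            raise
        man.stage_seconds[name] = round(time.perf_counter() - t0, 3)

    def _write_manifest():
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(man.to_dict(), fh, indent=1)

    store: dict = {}

    def gen():
        params = MicrostructureParams(**cfg["microstructure"], rng_seed=seed)
        img, truths = generate_microstructure(params)
        gray = render_grayscale(img, seed=seed + 1, **cfg["render"])
        store.update(img=img, truths=truths, gray=gray, params=params)
        oio.write_label_tiff(out_dir / "labels.tif", img)
        oio.write_gray_tiff(out_dir / "gray.tif", gray)
        oio.write_vacuole_truth_csv(out_dir / "vacuole_truth.csv", truths)
        oio.write_config_yaml(out_dir / "config.yaml", cfg)
        man.outputs["labels"] = str(out_dir / "labels.tif")
        man.outputs["gray"] = str(out_dir / "gray.tif")

    def seg():
        mask = remove_boundary_artifacts(
            binarize(store["gray"]), **cfg["segmentation"])
        truth = mask_from_labels(store["img"])
        store["mask"] = mask
        store["seg_mismatch"] = float(
            np.mean(mask.array != truth.array))
        oio.write_mask_tiff(out_dir / "mask.tif", mask)
        man.outputs["mask"] = str(out_dir / "mask.tif")

    def mesh_stage():
        img = store["img"]
        mesh = build_parent_mesh(img.extent_um,
                                 cfg["mesh"]["edge_length_um"])
        selector = None if int(cfg["mesh"]["model"]) == 1 else "deep_jct"
        assign_parts(mesh, img, selector)
        _, overlay = boundary_overlay_error(mesh, img)
        store.update(mesh=mesh, overlay=overlay)
        oio.write_mesh_vtk(out_dir / "mesh.vtk", mesh)
        oio.write_node_sets_json(out_dir / "node_sets.json", mesh)
        man.outputs["mesh"] = str(out_dir / "mesh.vtk")

    def solve():
        sc = standard_desk_config(**cfg["solver"])
        series = run_fsi(store["mesh"], config=sc)
        store["series"] = series
        oio.write_results_h5(out_dir / "results.h5", series)
        oio.write_state_vtk(out_dir / "final_state.vtk", series, -1)
        man.outputs["results"] = str(out_dir / "results.h5")
        man.outputs["final_state"] = str(out_dir / "final_state.vtk")

    def post():
        summary = summarize_run(store["series"], store["mesh"],
                                store["truths"], **cfg["post"])
        summary["segmentation_mismatch_fraction"] = store["seg_mismatch"]
        summary["boundary_overlay_mismatch"] = store["overlay"]
        store["summary"] = summary
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        with open(out_dir / "summary.csv", "w") as fh:
            fh.write("quantity,value\n")
            for k in sorted(summary):
                fh.write(f"{k},{summary[k]}\n")
        man.outputs["summary"] = str(out_dir / "summary.json")

    _stage("generate", gen)
    _stage("segment", seg)
    _stage("mesh", mesh_stage)
    _stage("run", solve)
    _stage("post", post)
    _write_manifest()
    man.outputs["manifest"] = str(out_dir / "manifest.json")
    man.summary = store.get("summary")  # type: ignore[attr-defined]
    return man
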