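"""Coupled explicit FSI driver.

Builds the Lagrangian solid (tissue + sclera elements) and the Eulerian fluid
grid from a part-labeled structured mesh, couples them with penalty springs
along the solid boundary, applies the inlet pressure ramp at the
anterior-chamber side and the non-reflecting outlet at the Schlemm's-canal
side, and advances both domains with a common CFL-limited step.

The fluid grid covers the whole domain and the tissue is immersed in it;
fluid trapped inside solid parts simply moves with them.  The FLUID_AC /
FLUID_ZERO split of the mesh is carried as an initial-condition tag (the ramp
starts from 0 gauge, so both begin unpressurized).  Stiff solid parts (the
scleral tether) are selectively mass-scaled so they do not control the global
time step; with the quasi-static ramp their inertia is immaterial.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..constitutive import ElasticMaterial, FluidMaterial, PRESETS
from ..mesh import FEMesh, Part
from .config import SolverConfig, pressure_ramp
from .coupling import PenaltyCoupling, SelfContact
from .fluid import EulerianFluid
from .solid import ExplicitSolid

UM = 1e-6


class InstabilityError(RuntimeError):
    def __init__(self, time, budget):
        super().__init__(
            f"energy growth beyond budget at t = {time:.3e} s: {budget}")
        self.budget = budget


@dataclass
class SimulationState:
    """One output snapshot of the coupled run (SI units)."""

    time: float
    inlet_pressure_pa: float
    solid_displacement: np.ndarray      # (ns, 2) m
    solid_velocity: np.ndarray          # (ns, 2) m/s
    solid_stress: np.ndarray            # (ne, 4): xx, yy, zz, xy [Pa]
    solid_strain: np.ndarray            # (ne, 4)
    fluid_rho: np.ndarray               # (ny, nx) kg/m^3
    fluid_u: np.ndarray                 # (ny, nx) cell-centred m/s
    fluid_v: np.ndarray
    fluid_energy: np.ndarray            # per initial volume [Pa]
    fluid_pressure: np.ndarray          # [Pa]
    fluid_volume_fraction: np.ndarray   # fluid fraction per cell (1 - solid)
    energy: dict | None = None          # solid energy budget at this time

    def stress_tensors(self) -> np.ndarray:
        return _to_tensors(self.solid_stress)

    def strain_tensors(self) -> np.ndarray:
        return _to_tensors(self.solid_strain)


def _to_tensors(cols: np.ndarray) -> np.ndarray:
    out = np.zeros((cols.shape[0], 3, 3))
    out[:, 0, 0], out[:, 1, 1], out[:, 2, 2] = cols[:, 0], cols[:, 1], cols[:, 2]
    out[:, 0, 1] = out[:, 1, 0] = cols[:, 3]
    return out


@dataclass
class ResultSeries:
    """Ordered snapshots plus the context needed to interpret them."""

    states: list
    config: SolverConfig
    mesh: FEMesh
    solid_node_ids: np.ndarray          # mesh node ids of solid nodes
    solid_element_ids: np.ndarray       # mesh element ids of solid elements
    solid_reference: np.ndarray         # (ns, 2) reference coords [m]
    dx: float                           # fluid cell size [m]
    c_eff: float                        # effective sound speed [m/s]
    dt: float
    energy_budget: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])

    def solid_positions(self, k: int) -> np.ndarray:
        return self.solid_reference + self.states[k].solid_displacement

    def solid_elements_local(self) -> np.ndarray:
        """Solid element connectivity in local solid-node indices."""
        els = self.mesh.elements[self.solid_element_ids]
        return np.searchsorted(self.solid_node_ids, els)


def _solid_fraction_grid(solid: ExplicitSolid, nx, ny, dx) -> np.ndarray:
    """Approximate solid area fraction per fluid cell (centroid deposit;
    elements and cells have comparable size)."""
    cent = solid.x[solid.elements].mean(axis=1)
    A = solid._areas(solid.x)
    j = np.clip((cent[:, 0] / dx).astype(int), 0, nx - 1)
    i = np.clip((cent[:, 1] / dx).astype(int), 0, ny - 1)
    dep = np.zeros((ny, nx))
    np.add.at(dep, (i, j), A)
    return np.clip(1.0 - dep / dx ** 2, 0.0, 1.0)


def build_solid(mesh: FEMesh, tissue: ElasticMaterial, sclera: ElasticMaterial,
                config: SolverConfig):
    """Assemble the Lagrangian solid from the TISSUE/SCLERA elements."""
    solid_mask = np.isin(mesh.part, (int(Part.TISSUE), int(Part.SCLERA)))
    el_ids = np.flatnonzero(solid_mask)
    if el_ids.size == 0:
        raise ValueError("mesh contains no solid elements")
    els = mesh.elements[el_ids]
    node_ids, inv = np.unique(els, return_inverse=True)
    elements = inv.reshape(els.shape)
    nodes = mesh.nodes[node_ids][:, :2] * UM

    is_scl = mesh.part[el_ids] == int(Part.SCLERA)
    lam = np.where(is_scl, sclera.lam, tissue.lam)
    G = np.where(is_scl, sclera.shear_modulus, tissue.shear_modulus)
    rho = np.where(is_scl, sclera.rho, tissue.rho)

    fixed_global = np.concatenate([
        mesh.node_sets.get("sclera_left", np.empty(0, int)),
        mesh.node_sets.get("sclera_right", np.empty(0, int))])
    remap = {g: l for l, g in enumerate(node_ids.tolist())}
    fixed = [remap[g] for g in fixed_global.tolist() if g in remap]

    solid = ExplicitSolid(nodes, elements, lam, G, rho, fixed=fixed,
                          hourglass_coefficient=config.hourglass_coefficient,
                          mass_damping=config.mass_damping)
    return solid, node_ids, el_ids


def run_fsi(mesh: FEMesh, materials: dict | None = None,
            config: SolverConfig | None = None) -> ResultSeries:
    """Run the coupled explicit FSI problem defined by a part-labeled mesh.

    ``materials`` maps {"tissue", "sclera", "fluid"} to constitutive objects
    (defaults: the named presets).  Deterministic: no random state anywhere.
    """
    if config is None:
        config = SolverConfig()
    materials = {**{"tissue": PRESETS["jct_high_flow"],
                    "sclera": PRESETS["sclera"],
                    "fluid": PRESETS["aqueous_humor"]}, **(materials or {})}
    if mesh.mode != "2d":
        raise ValueError("the coupled solver runs on the 2-D plane-strain "
                         "mesh (the slab mode maps to it by the symmetry "
                         "constraints on the slab faces)")
    for req in ("inlet", "outlet"):
        if req not in mesh.node_sets or len(mesh.node_sets[req]) == 0:
            raise ValueError(f"mesh is missing the {req} face node set")

    fluid_mat: FluidMaterial = materials["fluid"]
    c_eff = fluid_mat.C * config.sound_speed_scaling
    scaled = replace(fluid_mat, C=c_eff)
    nx, ny = mesh.shape[:2]
    dx = mesh.edge_length_um * UM
    fluid = EulerianFluid(nx, ny, dx, scaled,
                          bc_bottom=config.inlet_mode,
                          bc_top="nonreflecting",
                          bc_sides="slip",
                          bulk_viscosity_linear=config.bulk_viscosity_linear,
                          outlet_relax_time=config.outlet_relax_time_s)

    solid, node_ids, el_ids = build_solid(
        mesh, materials["tissue"], materials["sclera"], config)

    dt = config.CFL_factor * fluid.stable_dt()
    if config.mass_scaling:
        # keep stiff parts stable at the fluid step even at ~40% compression
        solid.mass_scale_for_dt(dt, cfl=0.6)
    else:
        dt = min(dt, config.CFL_factor * 0.7 * solid.stable_dt())

    segments = solid.boundary_segments()
    coupling = PenaltyCoupling(solid, fluid, segments, dt,
                               penalty_factor=config.penalty_factor)
    tissue_mask = mesh.part[el_ids] == int(Part.TISSUE)
    contact = SelfContact(solid, solid.boundary_segments(subset=tissue_mask),
                          thickness=config.contact_thickness_um * UM, dt=dt,
                          stiffness_scale=config.contact_stiffness_scale)

    t_total = config.ramp_duration_s * (1.0 + config.hold_fraction)
    out_times = np.linspace(0.0, t_total, config.n_output_steps)
    states: list[SimulationState] = []

    def snapshot():
        fluid.update_pressure()
        uc, vc = fluid.cell_velocity()
        states.append(SimulationState(
            time=solid.time,
            inlet_pressure_pa=fluid.inlet_pressure,
            solid_displacement=solid.displacement().astype(np.float32),
            solid_velocity=solid.v.astype(np.float32),
            solid_stress=solid.stress.astype(np.float32),
            solid_strain=solid.strain.astype(np.float32),
            fluid_rho=fluid.rho.astype(np.float32),
            fluid_u=uc.astype(np.float32), fluid_v=vc.astype(np.float32),
            fluid_energy=fluid.E.astype(np.float32),
            fluid_pressure=fluid.p.astype(np.float32),
            fluid_volume_fraction=_solid_fraction_grid(
                solid, nx, ny, dx).astype(np.float32),
            energy=dict(kinetic=solid.kinetic_energy(),
                        internal=solid.internal_energy,
                        hourglass=solid.hourglass_energy,
                        damping=solid.damping_dissipation,
                        external_work=solid.external_work)))

    def check_energy():
        ke = solid.kinetic_energy()
        budget = dict(kinetic=ke, internal=solid.internal_energy,
                      hourglass=solid.hourglass_energy,
                      damping=solid.damping_dissipation,
                      external_work=solid.external_work)
        floor = 1e-18
        if (not np.isfinite(ke)) or \
                ke + solid.internal_energy > 10.0 * max(
                    solid.external_work, 0.0) + floor:
            raise InstabilityError(solid.time, budget)
        return budget

    next_out = 0
    t = 0.0
    n_steps = int(np.ceil(t_total / dt))
    for istep in range(n_steps + 1):
        while next_out < len(out_times) and t >= out_times[next_out] - 0.5 * dt:
            snapshot()
            next_out += 1
        if next_out >= len(out_times):
            break
        if config.inlet_mode == "pressure":
            fluid.inlet_pressure = pressure_ramp(t, config)
        else:
            frac = min(t / config.ramp_duration_s, 1.0)
            fluid.inlet_velocity = frac * config.inlet_velocity_m_s
        f_ext = coupling.apply(dt)
        f_ext += contact.apply(dt)
        solid.step(dt, f_ext)
        fluid.step(dt)
        t += dt
        if istep % 2000 == 0:
            budget = check_energy()
    budget = check_energy()

    return ResultSeries(states=states, config=config, mesh=mesh,
                        solid_node_ids=node_ids, solid_element_ids=el_ids,
                        solid_reference=solid.X.copy(), dx=dx, c_eff=c_eff,
                        dt=dt, energy_budget=budget)
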