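"""Eulerian weakly-compressible viscous fluid on a fixed staggered grid.

Finite-volume marker-and-cell layout: density, internal energy (per initial
volume) and pressure live at cell centres; velocity components live on cell
faces.  Each step is an operator split in the hydrocode tradition: a
Lagrangian (acoustic + viscous + body/coupling force) velocity update with
pressure from the Mie-Gruneisen equation of state and a small linear bulk
artificial viscosity, followed by first-order monotone upwind transport of
mass, momentum and energy across the fixed grid.  Mass update is in flux
form, so closed domains conserve mass to round-off.

Domain boundaries: lateral walls (slip or no-slip), a prescribed-pressure
reservoir at the bottom (inlet) and an impedance-matched non-reflecting
outlet at the top.  The outlet impedance acts on the deviation of the face
velocity from its slow running mean, so acoustic transients are absorbed
while steady outflow sees the 0-gauge reference pressure.
"""

from __future__ import annotations

import numpy as np

from ..constitutive import FluidMaterial, gruneisen_pressure


class NegativeDensityError(RuntimeError):
    def __init__(self, cell, time):
        super().__init__(f"negative density in cell {cell} at t = {time:.3e} s")


class EulerianFluid:
    def __init__(self, nx: int, ny: int, dx: float, fluid: FluidMaterial,
                 bc_bottom: str = "pressure", bc_top: str = "nonreflecting",
                 bc_sides: str = "slip", bulk_viscosity_linear: float = 0.15,
                 outlet_relax_time: float = 2e-5, outlet_pressure: float = 0.0):
        if bc_bottom not in ("wall", "pressure", "velocity"):
            raise ValueError(bc_bottom)
        if bc_top not in ("wall", "nonreflecting"):
            raise ValueError(bc_top)
        if bc_sides not in ("slip", "noslip"):
            raise ValueError(bc_sides)
        self.nx, self.ny, self.dx = nx, ny, dx
        self.mat = fluid
        self.bc_bottom, self.bc_top, self.bc_sides = bc_bottom, bc_top, bc_sides
        self.cl = bulk_viscosity_linear
        self.tau_out = outlet_relax_time
        self.p_out = outlet_pressure

        self.rho = np.full((ny, nx), fluid.rho0)
        self.E = np.zeros((ny, nx))          # internal energy per initial volume
        self.u = np.zeros((ny, nx + 1))      # x-face velocities
        self.v = np.zeros((ny + 1, nx))      # y-face velocities
        self.p = np.zeros((ny, nx))
        self.fcx = np.zeros_like(self.u)     # coupling force per unit volume
        self.fcy = np.zeros_like(self.v)
        self.gx = 0.0                        # uniform body acceleration
        self.gy = 0.0
        self.inlet_pressure = 0.0
        self.inlet_velocity = 0.0            # prescribed v for bc "velocity"
        self.vbar_out = np.zeros(nx)         # outlet running-mean velocity
        self.time = 0.0

    # -- diagnostics ----------------------------------------------------------
    @property
    def c_eff(self) -> float:
        return self.mat.C

    def total_mass(self) -> float:
        return float(np.sum(self.rho)) * self.dx ** 2

    def stable_dt(self) -> float:
        umax = max(float(np.max(np.abs(self.u))), float(np.max(np.abs(self.v))))
        # 0.5: empirical 2-D bound of the donor-cell staggered acoustic update
        dt_ac = 0.5 * self.dx / (self.c_eff + umax)
        dt_visc = self.mat.rho0 * self.dx ** 2 / (4.0 * self.mat.mu_dyn)
        return float(min(dt_ac, dt_visc))

    def cell_velocity(self):
        """Cell-centred velocity components (ny, nx)."""
        uc = 0.5 * (self.u[:, :-1] + self.u[:, 1:])
        vc = 0.5 * (self.v[:-1, :] + self.v[1:, :])
        return uc, vc

    def update_pressure(self) -> None:
        mu_c = self.rho / self.mat.rho0 - 1.0
        self.p = gruneisen_pressure(mu_c, self.E, self.mat)

    # -- step -----------------------------------------------------------------
    def step(self, dt: float) -> None:
        dx, mu = self.dx, self.mat.mu_dyn
        rho0 = self.mat.rho0
        self.update_pressure()
        div = (np.diff(self.u, axis=1) + np.diff(self.v, axis=0)) / dx
        P = self.p - self.cl * rho0 * self.c_eff * dx * div

        # ghost pressures for the inlet / outlet rows
        if self.bc_bottom == "pressure":
            p_bot = np.full(self.nx, self.inlet_pressure)
        if self.bc_top == "nonreflecting":
            v_top = self.v[-1, :]
            self.vbar_out += (dt / self.tau_out) * (v_top - self.vbar_out)
            Z = rho0 * self.c_eff
            p_top = self.p_out + Z * (v_top - self.vbar_out)

        # --- x-momentum (interior faces) -------------------------------------
        u, v = self.u, self.v
        rho_fx = 0.5 * (self.rho[:, :-1] + self.rho[:, 1:])   # interior x-faces
        lap_u = self._laplacian_u(u)
        adv_u = self._advect_u(u, v)
        du = dt * (-(P[:, 1:] - P[:, :-1]) / dx
                   + mu * lap_u + self.fcx[:, 1:-1]) / rho_fx \
            + dt * (self.gx - adv_u)
        u[:, 1:-1] += du
        u[:, 0] = 0.0
        u[:, -1] = 0.0

        # --- y-momentum -------------------------------------------------------
        rho_fy = 0.5 * (self.rho[:-1, :] + self.rho[1:, :])
        lap_v = self._laplacian_v(v)
        adv_v = self._advect_v(u, v)
        dv = dt * (-(P[1:, :] - P[:-1, :]) / dx
                   + mu * lap_v + self.fcy[1:-1, :]) / rho_fy \
            + dt * (self.gy - adv_v)
        v[1:-1, :] += dv
        if self.bc_bottom == "pressure":
            v[0, :] += dt * (-(P[0, :] - p_bot) / dx + self.fcy[0, :]) / self.rho[0, :]
        elif self.bc_bottom == "velocity":
            v[0, :] = self.inlet_velocity
        else:
            v[0, :] = 0.0
        if self.bc_top == "nonreflecting":
            v[-1, :] += dt * (-(p_top - P[-1, :]) / dx + self.fcy[-1, :]) / self.rho[-1, :]
        else:
            v[-1, :] = 0.0

        # --- conservative mass transport --------------------------------------
        Fx = np.zeros((self.ny, self.nx + 1))
        rho_up_x = np.where(u[:, 1:-1] > 0, self.rho[:, :-1], self.rho[:, 1:])
        Fx[:, 1:-1] = u[:, 1:-1] * rho_up_x
        Fy = np.zeros((self.ny + 1, self.nx))
        rho_up_y = np.where(v[1:-1, :] > 0, self.rho[:-1, :], self.rho[1:, :])
        Fy[1:-1, :] = v[1:-1, :] * rho_up_y
        if self.bc_bottom == "pressure":
            rho_in = rho0 * (1.0 + self.inlet_pressure / self.mat.bulk_modulus)
            Fy[0, :] = v[0, :] * np.where(v[0, :] > 0, rho_in, self.rho[0, :])
        elif self.bc_bottom == "velocity":
            Fy[0, :] = v[0, :] * np.where(v[0, :] > 0, rho0, self.rho[0, :])
        if self.bc_top == "nonreflecting":
            Fy[-1, :] = v[-1, :] * np.where(v[-1, :] > 0, self.rho[-1, :], rho0)
        self.rho -= dt / dx * (np.diff(Fx, axis=1) + np.diff(Fy, axis=0))
        if np.any(self.rho <= 0):
            idx = np.unravel_index(int(np.argmin(self.rho)), self.rho.shape)
            raise NegativeDensityError(idx, self.time)

        # --- internal energy: pdV work + upwind transport ---------------------
        div_new = (np.diff(u, axis=1) + np.diff(v, axis=0)) / dx
        self.E += -self.p * div_new * dt
        self.E += -dt * self._upwind_cell(self.E) / dx

        self.fcx[:] = 0.0
        self.fcy[:] = 0.0
        self.time += dt

    # -- spatial operators -----------------------------------------------------
    def _laplacian_u(self, u):
        """Laplacian of u at interior x-faces (ny, nx-1), 1/dx^2 units."""
        dx2 = self.dx ** 2
        ui = u  # (ny, nx+1)
        # x-direction neighbours exist for interior faces
        d2x = (ui[:, 2:] - 2.0 * ui[:, 1:-1] + ui[:, :-2])
        # y-direction with ghosts
        top = ui[-1:, 1:-1]
        bot = ui[:1, 1:-1]
        up = np.vstack([ui[1:, 1:-1], top])        # zero-gradient at outlet
        dn = np.vstack([bot, ui[:-1, 1:-1]])       # zero-gradient at inlet
        if self.bc_top == "wall" and self.bc_sides == "noslip":
            up[-1, :] = -ui[-1, 1:-1]
        if self.bc_bottom == "wall" and self.bc_sides == "noslip":
            dn[0, :] = -ui[0, 1:-1]
        d2y = (up - 2.0 * ui[:, 1:-1] + dn)
        return (d2x + d2y) / dx2

    def _laplacian_v(self, v):
        dx2 = self.dx ** 2
        d2y = (v[2:, :] - 2.0 * v[1:-1, :] + v[:-2, :])
        if self.bc_sides == "noslip":
            left = -v[1:-1, :1]
            right = -v[1:-1, -1:]
        else:
            left = v[1:-1, :1]
            right = v[1:-1, -1:]
        vx = np.hstack([left, v[1:-1, :], right])
        d2x = (vx[:, 2:] - 2.0 * vx[:, 1:-1] + vx[:, :-2])
        return (d2x + d2y) / dx2

    def _advect_u(self, u, v):
        """Upwind u grad(u) at interior x-faces."""
        dx = self.dx
        ui = u[:, 1:-1]
        dudx_m = (u[:, 1:-1] - u[:, :-2]) / dx
        dudx_p = (u[:, 2:] - u[:, 1:-1]) / dx
        term_x = np.where(ui > 0, ui * dudx_m, ui * dudx_p)
        # v interpolated to interior x-faces
        vf = 0.25 * (v[:-1, :-1] + v[:-1, 1:] + v[1:, :-1] + v[1:, 1:])
        ue = np.vstack([ui[:1], ui, ui[-1:]])
        dudy_m = (ue[1:-1] - ue[:-2]) / dx
        dudy_p = (ue[2:] - ue[1:-1]) / dx
        term_y = np.where(vf > 0, vf * dudy_m, vf * dudy_p)
        return term_x + term_y

    def _advect_v(self, u, v):
        dx = self.dx
        vi = v[1:-1, :]
        dvdy_m = (v[1:-1, :] - v[:-2, :]) / dx
        dvdy_p = (v[2:, :] - v[1:-1, :]) / dx
        term_y = np.where(vi > 0, vi * dvdy_m, vi * dvdy_p)
        uf = 0.25 * (u[:-1, :-1] + u[:-1, 1:] + u[1:, :-1] + u[1:, 1:])
        ve = np.hstack([vi[:, :1], vi, vi[:, -1:]])
        dvdx_m = (ve[:, 1:-1] - ve[:, :-2]) / dx
        dvdx_p = (ve[:, 2:] - ve[:, 1:-1]) / dx
        term_x = np.where(uf > 0, uf * dvdx_m, uf * dvdx_p)
        return term_x + term_y

    def _upwind_cell(self, q):
        """Upwind u . grad(q) * dx for a cell-centred scalar."""
        uc, vc = self.cell_velocity()
        qe = np.pad(q, 1, mode="edge")
        dqx = np.where(uc > 0, q - qe[1:-1, :-2], qe[1:-1, 2:] - q)
        dqy = np.where(vc > 0, q - qe[:-2, 1:-1], qe[2:, 1:-1] - q)
        return uc * dqx + vc * dqy
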