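"""Explicit Lagrangian solid: one-point-integrated plane-strain quadrilaterals.

Updated-Lagrangian hypoelastic formulation: at every step the velocity
gradient is evaluated at the element centroid from the current geometry, the
Cauchy stress is advanced with a Jaumann (corotational) rate using the linear
isotropic tangent, and nodal motion follows a central-difference (leapfrog)
update with lumped mass.  Zero-energy (hourglass) modes of the one-point
quadrature are resisted by Flanagan-Belytschko stiffness-type hourglass
control.  All quantities are SI (m, s, Pa, kg); a unit out-of-plane depth is
assumed.
"""

from __future__ import annotations

import numpy as np


class ElementInversionError(RuntimeError):
    def __init__(self, element: int, time: float):
        super().__init__(f"element {element} inverted (non-positive area) "
                         f"at t = {time:.3e} s")
        self.element = element
        self.time = time


_HG = np.array([1.0, -1.0, 1.0, -1.0])


class ExplicitSolid:
    """Explicit-dynamics solid on 4-node quads (one-point integration).

    Parameters
    ----------
    nodes : (n, 2) reference coordinates [m]
    elements : (e, 4) connectivity, counter-clockwise
    lam, shear, rho : per-element Lame lambda, shear modulus [Pa], density
    fixed : node indices with all DOFs constrained (tether faces)
    hourglass_coefficient : stiffness-type hourglass control scale
    mass_damping : mass-proportional damping coefficient [1/s]
    """

    def __init__(self, nodes, elements, lam, shear, rho, fixed=(),
                 hourglass_coefficient: float = 0.1,
                 mass_damping: float = 0.0):
        self.X = np.asarray(nodes, dtype=float).copy()
        self.elements = np.asarray(elements, dtype=int)
        n_el = self.elements.shape[0]
        self.lam = np.broadcast_to(np.asarray(lam, float), (n_el,)).copy()
        self.G = np.broadcast_to(np.asarray(shear, float), (n_el,)).copy()
        self.rho = np.broadcast_to(np.asarray(rho, float), (n_el,)).copy()
        self.chg = hourglass_coefficient
        self.alpha = mass_damping

        self.x = self.X.copy()
        self.v = np.zeros_like(self.X)
        # plane-strain stress/strain: columns (xx, yy, zz, xy)
        self.stress = np.zeros((n_el, 4))
        self.strain = np.zeros((n_el, 4))
        self.hg_q = np.zeros((n_el, 2))       # accumulated hourglass resistance
        self.time = 0.0
        self.internal_energy = 0.0
        self.external_work = 0.0
        self.damping_dissipation = 0.0
        self.hourglass_energy = 0.0

        self.A0 = self._areas(self.X)
        if np.any(self.A0 <= 0):
            bad = int(np.argmin(self.A0))
            raise ValueError(f"element {bad} has non-positive reference area")
        self.mass = np.zeros(self.X.shape[0])
        np.add.at(self.mass, self.elements.ravel(),
                  np.repeat(self.rho * self.A0 / 4.0, 4))
        self.free = np.ones(self.X.shape[0], dtype=bool)
        self.free[np.asarray(list(fixed), dtype=int)] = False

    # -- geometry helpers ----------------------------------------------------
    def _areas(self, coords) -> np.ndarray:
        q = coords[self.elements]          # (e, 4, 2)
        x, y = q[..., 0], q[..., 1]
        return 0.5 * ((x[:, 2] - x[:, 0]) * (y[:, 3] - y[:, 1])
                      + (x[:, 1] - x[:, 3]) * (y[:, 2] - y[:, 0]))

    def _b_matrices(self, coords):
        """One-point gradient operators b_x, b_y (e, 4) and areas (e,)."""
        q = coords[self.elements]
        x, y = q[..., 0], q[..., 1]
        A = 0.5 * ((x[:, 2] - x[:, 0]) * (y[:, 3] - y[:, 1])
                   + (x[:, 1] - x[:, 3]) * (y[:, 2] - y[:, 0]))
        bx = np.stack([y[:, 1] - y[:, 3], y[:, 2] - y[:, 0],
                       y[:, 3] - y[:, 1], y[:, 0] - y[:, 2]], axis=1)
        by = np.stack([x[:, 3] - x[:, 1], x[:, 0] - x[:, 2],
                       x[:, 1] - x[:, 3], x[:, 2] - x[:, 0]], axis=1)
        inv2A = 1.0 / (2.0 * A)
        return bx * inv2A[:, None], by * inv2A[:, None], A

    def stable_dt(self) -> float:
        """Acoustic stability limit over elements (current geometry)."""
        A = self._areas(self.x)
        le = A / self._max_edge(self.x)    # characteristic length
        c = np.sqrt((self.lam + 2.0 * self.G) / self.rho)
        return float(np.min(le / c))

    def _max_edge(self, coords) -> np.ndarray:
        q = coords[self.elements]
        e = np.stack([np.linalg.norm(q[:, (i + 1) % 4] - q[:, i], axis=1)
                      for i in range(4)], axis=1)
        return e.max(axis=1)

    def mass_scale_for_dt(self, dt_target: float, cfl: float = 0.9) -> float:
        """Scale element densities up so ``dt_target`` is stable (selective
        mass scaling of stiff parts, standard quasi-static explicit practice).
        Returns the added mass fraction."""
        A = self._areas(self.X)
        le = A / self._max_edge(self.X)
        rho_needed = (self.lam + 2.0 * self.G) * (dt_target / (cfl * le)) ** 2
        m0 = float(np.sum(self.rho * self.A0))
        self.rho = np.maximum(self.rho, rho_needed)
        self.mass[:] = 0.0
        np.add.at(self.mass, self.elements.ravel(),
                  np.repeat(self.rho * self.A0 / 4.0, 4))
        m1 = float(np.sum(self.rho * self.A0))
        return m1 / m0 - 1.0

    # -- time stepping -------------------------------------------------------
    def internal_forces(self, dt: float):
        """Advance stress/strain with the current velocity field and return
        nodal internal + hourglass forces.  Mutates element state."""
        el = self.elements
        bx, by, A = self._b_matrices(self.x)
        if np.any(A <= 0):
            raise ElementInversionError(int(np.argmin(A)), self.time)
        vq = self.v[el]                    # (e, 4, 2)
        vx, vy = vq[..., 0], vq[..., 1]
        dvx_dx = np.einsum('ij,ij->i', bx, vx)
        dvx_dy = np.einsum('ij,ij->i', by, vx)
        dvy_dx = np.einsum('ij,ij->i', bx, vy)
        dvy_dy = np.einsum('ij,ij->i', by, vy)
        dxx, dyy = dvx_dx, dvy_dy
        dxy = 0.5 * (dvx_dy + dvy_dx)
        w = 0.5 * (dvx_dy - dvy_dx)        # in-plane spin

        s = self.stress
        tr = dxx + dyy
        # Jaumann rotation terms
        rot_xx = 2.0 * w * s[:, 3]
        rot_yy = -2.0 * w * s[:, 3]
        rot_xy = w * (s[:, 1] - s[:, 0])
        s_old = s.copy()
        s[:, 0] += dt * (self.lam * tr + 2.0 * self.G * dxx + rot_xx)
        s[:, 1] += dt * (self.lam * tr + 2.0 * self.G * dyy + rot_yy)
        s[:, 2] += dt * (self.lam * tr)                      # out-of-plane
        s[:, 3] += dt * (2.0 * self.G * dxy + rot_xy)
        s_mid = 0.5 * (s + s_old)          # midpoint stress for energy only

        e = self.strain
        e_rot_xx = 2.0 * w * e[:, 3]
        e_rot_yy = -2.0 * w * e[:, 3]
        e_rot_xy = w * (e[:, 1] - e[:, 0])
        e[:, 0] += dt * (dxx + e_rot_xx)
        e[:, 1] += dt * (dyy + e_rot_yy)
        e[:, 3] += dt * (dxy + e_rot_xy)

        # internal nodal forces f_i = -A * sigma . b_i (end-of-step stress)
        fx = -A[:, None] * (s[:, 0:1] * bx + s[:, 3:4] * by)
        fy = -A[:, None] * (s[:, 3:4] * bx + s[:, 1:2] * by)

        # Flanagan-Belytschko stiffness hourglass control
        xq = self.x[el]
        hx = xq[:, 0, 0] - xq[:, 1, 0] + xq[:, 2, 0] - xq[:, 3, 0]
        hy = xq[:, 0, 1] - xq[:, 1, 1] + xq[:, 2, 1] - xq[:, 3, 1]
        gam = _HG[None, :] - hx[:, None] * bx - hy[:, None] * by
        qdot_x = np.einsum('ij,ij->i', gam, vx)
        qdot_y = np.einsum('ij,ij->i', gam, vy)
        k_hg = self.chg * A * self.G * np.einsum(
            'ij,ij->i', bx, bx) + self.chg * A * self.G * np.einsum(
            'ij,ij->i', by, by)
        self.hg_q[:, 0] += dt * k_hg * qdot_x
        self.hg_q[:, 1] += dt * k_hg * qdot_y
        fx -= self.hg_q[:, 0:1] * gam
        fy -= self.hg_q[:, 1:2] * gam

        self.internal_energy += float(np.sum(
            A * dt * (s_mid[:, 0] * dxx + s_mid[:, 1] * dyy
                      + 2.0 * s_mid[:, 3] * dxy)))
        self.hourglass_energy += float(np.sum(
            dt * (self.hg_q[:, 0] * qdot_x + self.hg_q[:, 1] * qdot_y)))

        n = self.X.shape[0]
        f = np.empty_like(self.x)
        f[:, 0] = np.bincount(el.ravel(), weights=fx.ravel(), minlength=n)
        f[:, 1] = np.bincount(el.ravel(), weights=fy.ravel(), minlength=n)
        return f

    def step(self, dt: float, f_ext=None) -> None:
        """One central-difference step with external nodal forces ``f_ext``."""
        f = self.internal_forces(dt)
        if f_ext is not None:
            f = f + f_ext
        a = f / self.mass[:, None]
        v_old = self.v
        v_new = (v_old + dt * a) / (1.0 + self.alpha * dt)
        v_new[~self.free] = 0.0
        v_mid = 0.5 * (v_old + v_new)
        if f_ext is not None:
            self.external_work += float(
                np.sum(f_ext[self.free] * v_mid[self.free]) * dt)
        self.damping_dissipation += float(
            np.sum(self.mass[:, None] * self.alpha * v_new * v_mid) * dt)
        self.v = v_new
        self.x = self.x + dt * self.v
        self.time += dt

    # -- diagnostics ----------------------------------------------------------
    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self.mass[:, None] * self.v ** 2))

    def displacement(self) -> np.ndarray:
        return self.x - self.X

    def stress_tensors(self) -> np.ndarray:
        """(e, 3, 3) Cauchy stress tensors (plane strain)."""
        s = self.stress
        out = np.zeros((s.shape[0], 3, 3))
        out[:, 0, 0], out[:, 1, 1], out[:, 2, 2] = s[:, 0], s[:, 1], s[:, 2]
        out[:, 0, 1] = out[:, 1, 0] = s[:, 3]
        return out

    def strain_tensors(self) -> np.ndarray:
        e = self.strain
        out = np.zeros((e.shape[0], 3, 3))
        out[:, 0, 0], out[:, 1, 1], out[:, 2, 2] = e[:, 0], e[:, 1], e[:, 2]
        out[:, 0, 1] = out[:, 1, 0] = e[:, 3]
        return out

    def boundary_segments(self, subset=None) -> np.ndarray:
        """(m, 2) node pairs of element edges used exactly once, oriented so
        the solid lies to the left (outward normal = edge direction rotated
        -90 deg).  ``subset``: optional element mask."""
        el = self.elements if subset is None else self.elements[subset]
        edges = np.concatenate([el[:, [0, 1]], el[:, [1, 2]],
                                el[:, [2, 3]], el[:, [3, 0]]], axis=0)
        key = np.sort(edges, axis=1)
        _, idx, cnt = np.unique(key, axis=0, return_index=True,
                                return_counts=True)
        return edges[idx[cnt == 1]]
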