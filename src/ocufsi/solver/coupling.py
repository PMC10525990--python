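"""Penalty coupling between the Lagrangian solid boundary and the Eulerian
fluid grid, plus tissue self-contact.

Coupling points are distributed along the solid boundary segments (spacing
about half a fluid cell).  Each point carries a spring-dashpot acting on the
accumulated relative displacement between the local fluid velocity
(interpolated from the staggered grid) and the solid surface velocity, in
both the normal and tangential directions ("tension and compression"
coupling: the fluid sticks to the wall, which is the no-slip condition for a
viscous fluid).  Equal and opposite forces are applied to the fluid faces
(bilinear spreading, the adjoint of interpolation) and the solid nodes, so
the pair adds zero net momentum to machine precision.

The spring stiffness is the penalty-factor-scaled interface stiffness
estimated from the fluid bulk modulus and face geometry, capped by the
explicit stability limit of the lighter of the two coupled masses.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .fluid import EulerianFluid
from .solid import ExplicitSolid

try:  # optional acceleration of the per-point coupling loop
    from numba import njit
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap


@njit(cache=True)
def _couple_kernel(x, vel, idx, wgt, kappa, eta, q, ugrid, vgrid,
                   fcx, fcy, f_solid, dx, dt):
    ny, nxp1 = ugrid.shape
    nyp1, nx = vgrid.shape
    inv_vol = 1.0 / (dx * dx)
    work = 0.0
    n_pts = idx.shape[0]
    for p in range(n_pts):
        xp0 = 0.0; xp1 = 0.0; us0 = 0.0; us1 = 0.0
        for k in range(4):
            n = idx[p, k]
            w = wgt[p, k]
            xp0 += w * x[n, 0]; xp1 += w * x[n, 1]
            us0 += w * vel[n, 0]; us1 += w * vel[n, 1]
        # --- sample u (x-faces at (j*dx, (i+0.5)*dx)) ---
        gx = xp0 / dx; gy = xp1 / dx - 0.5
        ju = int(gx)
        if ju < 0: ju = 0
        if ju > nxp1 - 2: ju = nxp1 - 2
        iu = int(gy)
        if iu < 0: iu = 0
        if iu > ny - 2: iu = ny - 2
        fxu = gx - ju
        if fxu < 0.0: fxu = 0.0
        if fxu > 1.0: fxu = 1.0
        fyu = gy - iu
        if fyu < 0.0: fyu = 0.0
        if fyu > 1.0: fyu = 1.0
        uf0 = (ugrid[iu, ju] * (1 - fxu) * (1 - fyu)
               + ugrid[iu, ju + 1] * fxu * (1 - fyu)
               + ugrid[iu + 1, ju] * (1 - fxu) * fyu
               + ugrid[iu + 1, ju + 1] * fxu * fyu)
        # --- sample v (y-faces at ((j+0.5)*dx, i*dx)) ---
        gx = xp0 / dx - 0.5; gy = xp1 / dx
        jv = int(gx)
        if jv < 0: jv = 0
        if jv > nx - 2: jv = nx - 2
        iv = int(gy)
        if iv < 0: iv = 0
        if iv > nyp1 - 2: iv = nyp1 - 2
        fxv = gx - jv
        if fxv < 0.0: fxv = 0.0
        if fxv > 1.0: fxv = 1.0
        fyv = gy - iv
        if fyv < 0.0: fyv = 0.0
        if fyv > 1.0: fyv = 1.0
        uf1 = (vgrid[iv, jv] * (1 - fxv) * (1 - fyv)
               + vgrid[iv, jv + 1] * fxv * (1 - fyv)
               + vgrid[iv + 1, jv] * (1 - fxv) * fyv
               + vgrid[iv + 1, jv + 1] * fxv * fyv)
        ur0 = uf0 - us0; ur1 = uf1 - us1
        q[p, 0] += ur0 * dt; q[p, 1] += ur1 * dt
        Ff0 = -(kappa[p] * q[p, 0] + eta[p] * ur0)
        Ff1 = -(kappa[p] * q[p, 1] + eta[p] * ur1)
        g = Ff0 * inv_vol
        fcx[iu, ju] += g * (1 - fxu) * (1 - fyu)
        fcx[iu, ju + 1] += g * fxu * (1 - fyu)
        fcx[iu + 1, ju] += g * (1 - fxu) * fyu
        fcx[iu + 1, ju + 1] += g * fxu * fyu
        g = Ff1 * inv_vol
        fcy[iv, jv] += g * (1 - fxv) * (1 - fyv)
        fcy[iv, jv + 1] += g * fxv * (1 - fyv)
        fcy[iv + 1, jv] += g * (1 - fxv) * fyv
        fcy[iv + 1, jv + 1] += g * fxv * fyv
        for k in range(4):
            n = idx[p, k]
            w = wgt[p, k]
            f_solid[n, 0] -= w * Ff0
            f_solid[n, 1] -= w * Ff1
        work += (-Ff0 * us0 - Ff1 * us1) * dt
    return work


def _interp_weights(gx, gy, n_col, n_row):
    """Bilinear gather/scatter stencil on a (n_row, n_col) grid in grid
    units; returns (i0, j0, fx, fy) clipped to the valid interior."""
    j0 = np.clip(np.floor(gx).astype(int), 0, n_col - 2)
    i0 = np.clip(np.floor(gy).astype(int), 0, n_row - 2)
    fx = np.clip(gx - j0, 0.0, 1.0)
    fy = np.clip(gy - i0, 0.0, 1.0)
    return i0, j0, fx, fy


class PenaltyCoupling:
    """Coupling points on the solid boundary (sub-sampled segments) plus one
    interior point per solid element, so that fluid trapped inside the solid
    is carried with it (otherwise the solid interior would act as a porous
    bypass for the pressure gradient)."""

    def __init__(self, solid: ExplicitSolid, fluid: EulerianFluid,
                 segments: np.ndarray, dt: float,
                 penalty_factor: float = 0.1,
                 spacing_factor: float = 0.5,
                 stability_fraction: float = 0.04,
                 interior_points: bool = True):
        self.solid = solid
        self.fluid = fluid
        self.segments = np.asarray(segments, dtype=int)
        dx = fluid.dx
        ref = solid.X
        a, b = ref[self.segments[:, 0]], ref[self.segments[:, 1]]
        seg_len = np.linalg.norm(b - a, axis=1)
        n_sub = np.maximum(1, np.ceil(seg_len / (spacing_factor * dx)).astype(int))

        idx, wgt, wlen = [], [], []
        for s, (n0, n1) in enumerate(self.segments):
            k = n_sub[s]
            t = (np.arange(k) + 0.5) / k
            idx.append(np.column_stack([np.full(k, n0), np.full(k, n1),
                                        np.zeros(k, int), np.zeros(k, int)]))
            wgt.append(np.column_stack([1.0 - t, t, np.zeros(k),
                                        np.zeros(k)]))
            wlen.append(np.full(k, seg_len[s] / k))
        if interior_points:
            # 2x2 interior points per element so trapped fluid stays pinned
            # even when elements stretch to about twice the cell size
            el = solid.elements
            A0 = solid.A0
            for xi, eta in ((0.25, 0.25), (0.75, 0.25),
                            (0.75, 0.75), (0.25, 0.75)):
                idx.append(el)
                wgt.append(np.tile(np.array([(1 - xi) * (1 - eta),
                                             xi * (1 - eta), xi * eta,
                                             (1 - xi) * eta]), (len(el), 1)))
                wlen.append(A0 / dx / 4.0)  # area-equivalent length share
        self.idx = np.concatenate(idx).astype(np.int64)  # (n_pts, 4) nodes
        self.wgt = np.concatenate(wgt).astype(float)     # shape weights
        self.wlen = np.concatenate(wlen)
        n_pts = self.idx.shape[0]

        # per-point effective masses (unit depth)
        pts_per_node = np.zeros(solid.X.shape[0])
        np.add.at(pts_per_node, self.idx.ravel(), self.wgt.ravel())
        m_node = solid.mass / np.maximum(pts_per_node, 1.0)
        m_solid_pt = np.min(np.where(self.wgt > 0, m_node[self.idx], np.inf),
                            axis=1)
        m_fluid_pt = fluid.mat.rho0 * dx * self.wlen
        m_min = np.minimum(m_solid_pt, m_fluid_pt)

        # interface stiffness estimate from the fluid bulk modulus and the
        # coupled face geometry, scaled by the penalty factor, then capped
        # by the explicit stability limit of the lighter coupled mass
        k_est = fluid.mat.bulk_modulus * self.wlen / dx
        k_cap = stability_fraction * m_min / dt ** 2
        self.kappa = np.minimum(penalty_factor / 0.1 * k_est, k_cap)
        self.eta = 2.0 * np.sqrt(self.kappa * m_min)
        self.q = np.zeros((n_pts, 2))      # accumulated relative displacement
        self.work_on_solid = 0.0
        self.n_points = n_pts

    # -- staggered-grid sampling ----------------------------------------------
    def _fluid_velocity_at(self, xp):
        fl = self.fluid
        dx = fl.dx
        # u lives at (j*dx, (i+0.5)*dx) on an (ny, nx+1) grid
        i0, j0, fx, fy = _interp_weights(xp[:, 0] / dx, xp[:, 1] / dx - 0.5,
                                         fl.nx + 1, fl.ny)
        u = (fl.u[i0, j0] * (1 - fx) * (1 - fy) + fl.u[i0, j0 + 1] * fx * (1 - fy)
             + fl.u[i0 + 1, j0] * (1 - fx) * fy + fl.u[i0 + 1, j0 + 1] * fx * fy)
        self._u_stencil = (i0, j0, fx, fy)
        # v lives at ((j+0.5)*dx, i*dx) on an (ny+1, nx) grid
        i0, j0, fx, fy = _interp_weights(xp[:, 0] / dx - 0.5, xp[:, 1] / dx,
                                         fl.nx, fl.ny + 1)
        v = (fl.v[i0, j0] * (1 - fx) * (1 - fy) + fl.v[i0, j0 + 1] * fx * (1 - fy)
             + fl.v[i0 + 1, j0] * (1 - fx) * fy + fl.v[i0 + 1, j0 + 1] * fx * fy)
        self._v_stencil = (i0, j0, fx, fy)
        return np.column_stack([u, v])

    @staticmethod
    def _scatter(grid, stencil, vals):
        i0, j0, fx, fy = stencil
        ncol = grid.shape[1]
        base = i0 * ncol + j0
        idx = np.concatenate([base, base + 1, base + ncol, base + ncol + 1])
        w = np.concatenate([vals * (1 - fx) * (1 - fy), vals * fx * (1 - fy),
                            vals * (1 - fx) * fy, vals * fx * fy])
        grid.ravel()[:] += np.bincount(idx, weights=w, minlength=grid.size)

    def _spread_force_to_fluid(self, F):
        """Adjoint bilinear scatter of point forces onto the face grids as
        force per unit volume."""
        fl = self.fluid
        vol = fl.dx ** 2
        self._scatter(fl.fcx, self._u_stencil, F[:, 0] / vol)
        self._scatter(fl.fcy, self._v_stencil, F[:, 1] / vol)

    def apply(self, dt: float) -> np.ndarray:
        """Advance the penetration springs one step.  Loads the fluid force
        fields and returns the nodal force array for the solid."""
        s = self.solid
        if _HAVE_NUMBA:
            f_solid = np.zeros_like(s.x)
            work = _couple_kernel(s.x, s.v, self.idx, self.wgt, self.kappa,
                                  self.eta, self.q, self.fluid.u,
                                  self.fluid.v, self.fluid.fcx,
                                  self.fluid.fcy, f_solid, self.fluid.dx, dt)
            self.work_on_solid += float(work)
            return f_solid
        xp = np.einsum('pk,pkd->pd', self.wgt, s.x[self.idx])
        us = np.einsum('pk,pkd->pd', self.wgt, s.v[self.idx])
        uf = self._fluid_velocity_at(xp)
        urel = uf - us
        self.q += urel * dt
        F_fluid = -(self.kappa[:, None] * self.q + self.eta[:, None] * urel)
        self._spread_force_to_fluid(F_fluid)
        F_solid = -F_fluid
        n = s.x.shape[0]
        flat = self.idx.ravel()
        f_solid = np.empty_like(s.x)
        f_solid[:, 0] = np.bincount(
            flat, weights=(self.wgt * F_solid[:, 0:1]).ravel(), minlength=n)
        f_solid[:, 1] = np.bincount(
            flat, weights=(self.wgt * F_solid[:, 1:2]).ravel(), minlength=n)
        self.work_on_solid += float(np.sum(F_solid * us) * dt)
        return f_solid


class SelfContact:
    """Penalty repulsion between non-adjacent tissue boundary segments.

    Node-versus-segment: boundary nodes closer than ``thickness`` to a
    non-adjacent segment receive a normal penalty force, with the opposite
    force split between the segment nodes (action-reaction).  Candidate
    pairs are refreshed from a k-d tree every ``check_every`` steps.
    """

    def __init__(self, solid: ExplicitSolid, segments: np.ndarray,
                 thickness: float, dt: float,
                 stiffness_scale: float = 0.1, check_every: int = 100,
                 stability_fraction: float = 0.04):
        self.solid = solid
        self.segments = np.asarray(segments, dtype=int)
        self.nodes = np.unique(self.segments)
        self.thickness = thickness
        self.check_every = check_every
        # bound on how far surfaces can approach between rebuilds
        self._approach_margin = 2.0 * thickness
        self._step = 0
        self._pairs = (np.empty(0, int), np.empty(0, int))
        m_min = solid.mass[self.nodes].min() if self.nodes.size else 1.0
        self.k = stiffness_scale * stability_fraction * m_min / dt ** 2
        # reference proximity: permanently close pairs are not contacts
        ref = solid.X
        a, b = ref[self.segments[:, 0]], ref[self.segments[:, 1]]
        self._ref_mid = 0.5 * (a + b)
        self._ref_node_pos = ref[self.nodes]

    def _rebuild(self):
        s = self.solid
        if self.segments.size == 0:
            return
        mids = 0.5 * (s.x[self.segments[:, 0]] + s.x[self.segments[:, 1]])
        seg_len = np.linalg.norm(
            s.x[self.segments[:, 1]] - s.x[self.segments[:, 0]], axis=1)
        r = 2.0 * self.thickness + seg_len.max()
        tree = cKDTree(mids)
        pos = s.x[self.nodes]
        groups = tree.query_ball_point(pos, r)
        lens = np.fromiter((len(g) for g in groups), int, len(groups))
        if lens.sum() == 0:
            self._pairs = (np.empty(0, int), np.empty(0, int))
            return
        ki = np.repeat(np.arange(len(self.nodes)), lens)
        si = np.concatenate([g for g in groups if g]).astype(int)
        ni = self.nodes[ki]
        keep = (ni != self.segments[si, 0]) & (ni != self.segments[si, 1])
        # exclude pairs already close in the reference configuration
        # (adjacent boundary, bonded interfaces)
        dref = np.linalg.norm(self._ref_node_pos[ki] - self._ref_mid[si],
                              axis=1)
        keep &= dref >= 3.0 * self.thickness
        ni, si = ni[keep], si[keep]
        # keep only pairs currently near contact; the others cannot close
        # the gap before the next rebuild
        if ni.size:
            P = s.x[ni]
            A = s.x[self.segments[si, 0]]
            B = s.x[self.segments[si, 1]]
            AB = B - A
            L2 = np.maximum(np.sum(AB ** 2, axis=1), 1e-30)
            tt = np.clip(np.sum((P - A) * AB, axis=1) / L2, 0.0, 1.0)
            dist = np.linalg.norm(P - (A + tt[:, None] * AB), axis=1)
            near = dist < self.thickness + self._approach_margin
            ni, si = ni[near], si[near]
        self._pairs = (ni, si)

    def apply(self, dt: float) -> np.ndarray:
        s = self.solid
        if self._step % self.check_every == 0:
            self._rebuild()
        self._step += 1
        f = np.zeros_like(s.x)
        ni, si = self._pairs
        if ni.size == 0:
            return f
        P = s.x[ni]
        A = s.x[self.segments[si, 0]]
        B = s.x[self.segments[si, 1]]
        AB = B - A
        L2 = np.sum(AB ** 2, axis=1)
        t = np.clip(np.sum((P - A) * AB, axis=1) / np.maximum(L2, 1e-30), 0, 1)
        C = A + t[:, None] * AB
        d = P - C
        dist = np.linalg.norm(d, axis=1)
        pen = self.thickness - dist
        hit = pen > 0
        if not np.any(hit):
            return f
        n = d[hit] / np.maximum(dist[hit], 1e-12 * self.thickness)[:, None]
        Fn = self.k * pen[hit]
        Fv = Fn[:, None] * n
        np.add.at(f[:, 0], ni[hit], Fv[:, 0])
        np.add.at(f[:, 1], ni[hit], Fv[:, 1])
        th = t[hit]
        np.add.at(f[:, 0], self.segments[si[hit], 0], -(1 - th) * Fv[:, 0])
        np.add.at(f[:, 1], self.segments[si[hit], 0], -(1 - th) * Fv[:, 1])
        np.add.at(f[:, 0], self.segments[si[hit], 1], -th * Fv[:, 0])
        np.add.at(f[:, 1], self.segments[si[hit], 1], -th * Fv[:, 1])
        return f
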