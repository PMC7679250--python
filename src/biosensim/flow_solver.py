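"""Implicit coupled solver for 2D incompressible laminar channel flow.

Momentum and continuity are discretized on the dual control volumes and
solved simultaneously for the nodal (u, v, p).  Two different
integration-point velocity closures are used, both algebraic
reconstructions of the momentum balance at the point:

* continuity uses pressure-aware "hat" velocities
  ``u_hat = u_BL - (1/beta) * (-rho*(u dv/dy - v du/dy) + dp/dx)``
  (and the analogous ``v_hat``) so that the collocated arrangement sees
  the pressure field;
* momentum convection uses the physical-influence (streamline upwind)
  velocity, a beta-weighted blend of the upwind value, the bilinear
  value and the pressure gradient whose two velocity weights sum to 1.

``beta = rho*|V_elem|/A_elem + mu/L_ref**2`` per element; the printed
form of this coefficient is ambiguous in its grouping and this is the
only reading that is dimensionally self-consistent with weights summing
to one.  ``L_ref`` defaults to the channel height.  The nonlinear
convection terms are Picard-linearized (mass fluxes and the hat-velocity
cross terms frozen at the previous iterate) and each linear system is
solved by a sparse direct factorization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import cvfem_core as cv
from .mesh import FACE_FROM, FACE_TO, Mesh

__all__ = [
    "FluidProperties",
    "FlowState",
    "FlowBC",
    "FlowSolver",
    "compute_beta",
    "ks_hat_velocity",
    "pis_momentum_velocity",
    "solve_flow_step",
    "steady_flow",
    "uniform_inlet",
    "parabolic_inlet",
]


class FlowConvergenceError(RuntimeError):
    """Raised when the Picard loop or the pseudo-time march stalls."""


@dataclass(frozen=True)
class FluidProperties:
    rho: float  # kg m^-3
    mu: float  # Pa s

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass
class FlowState:
    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    t: float = 0.0

    def copy(self) -> "FlowState":
        return FlowState(self.u.copy(), self.v.copy(), self.p.copy(), self.t)


@dataclass(frozen=True)
class FlowBC:
    """Inlet velocity per inlet node (same order as the inlet tag array).

    Walls are no-slip, the outlet is "straight out" (zero streamwise
    gradient for u, v = 0) with the pressure pinned to zero there.
    """

    u_inlet: np.ndarray


def uniform_inlet(mesh: Mesh, u0: float) -> FlowBC:
    return FlowBC(u_inlet=np.full(mesh.boundary_tags["inlet"].size, float(u0)))


def parabolic_inlet(mesh: Mesh, u_mean: float) -> FlowBC:
    y = mesh.node_y[mesh.boundary_tags["inlet"]]
    H = mesh.geometry.H
    return FlowBC(u_inlet=6.0 * u_mean * (y / H) * (1.0 - y / H))


def compute_beta(v_bar: float, area: float, props: FluidProperties, L_ref: float) -> float:
    """Element coupling coefficient ``rho*|V|/A + mu/L_ref**2`` (always > 0)."""
    if area <= 0:
        raise ValueError("element area must be positive")
    return props.rho * abs(v_bar) / area + props.mu / L_ref**2


def ks_hat_velocity(
    u_bl: float,
    v_bl: float,
    beta: float,
    rho: float,
    dpdx: float,
    dpdy: float,
    u_ip: float,
    v_ip: float,
    dudx: float,
    dudy: float,
    dvdx: float,
    dvdy: float,
) -> tuple[float, float]:
    """Pressure-aware integration-point velocities used in continuity."""
    u_hat = u_bl - (1.0 / beta) * (-rho * (u_ip * dvdy - v_ip * dudy) + dpdx)
    v_hat = v_bl - (1.0 / beta) * (-rho * (v_ip * dudx - u_ip * dvdx) + dpdy)
    return u_hat, v_hat


def pis_momentum_velocity(
    u_up: float,
    u_bl: float,
    beta: float,
    conv_coeff: float,
    diff_coeff: float,
    dpd: float,
) -> float:
    """Convected velocity: ``(conv*u_up + diff*u_bl - dpd) / beta`` with
    ``conv_coeff = rho*|V|/A``, ``diff_coeff = mu/L_ref**2`` (their sum
    is beta, so the two velocity weights sum to one)."""
    return (conv_coeff * u_up + diff_coeff * u_bl - dpd) / beta


class FlowSolver:
    """Assembles and solves the coupled (u, v, p) system on a mesh."""

    def __init__(
        self,
        mesh: Mesh,
        props: FluidProperties,
        bc: FlowBC,
        L_ref: float | None = None,
        picard_tol: float = 1e-6,
        picard_max: int = 30,
    ):
        self.mesh = mesh
        self.props = props
        self.bc = bc
        self.L_ref = mesh.geometry.H if L_ref is None else L_ref
        self.picard_tol = picard_tol
        self.picard_max = picard_max
        self.pre = cv.precompute(mesh)
        self.n = mesh.n_nodes
        self._setup_bc_rows()

    # ------------------------------------------------------------------
    def _setup_bc_rows(self) -> None:
        mesh = self.mesh
        n = self.n
        inlet = mesh.boundary_tags["inlet"]
        outlet = mesh.boundary_tags["outlet"]
        wall = mesh.boundary_tags["wall"]

        constrained = np.zeros(3 * n, dtype=bool)
        constrained[inlet] = True
        constrained[wall] = True
        constrained[outlet] = True  # u: extrapolation rows
        constrained[n + inlet] = True
        constrained[n + wall] = True
        constrained[n + outlet] = True
        constrained[2 * n + outlet] = True  # p pinned at outlet
        self._constrained = constrained

        rows = []
        cols = []
        vals = []
        rhs_rows = []
        rhs_vals = []

        # Dirichlet u at inlet and walls, v = 0 on all of them
        rows += [inlet, wall, n + inlet, n + wall, n + outlet]
        cols += [inlet, wall, n + inlet, n + wall, n + outlet]
        vals += [np.ones(inlet.size), np.ones(wall.size), np.ones(inlet.size),
                 np.ones(wall.size), np.ones(outlet.size)]
        rhs_rows += [inlet]
        rhs_vals += [self.bc.u_inlet]

        # outlet: du/dx = 0  ->  u[i] - u[i-1] = 0
        rows += [outlet, outlet]
        cols += [outlet, outlet - 1]
        vals += [np.ones(outlet.size), -np.ones(outlet.size)]

        # outlet pressure pin
        rows += [2 * n + outlet]
        cols += [2 * n + outlet]
        vals += [np.ones(outlet.size)]

        self._bc_rows = np.concatenate(rows)
        self._bc_cols = np.concatenate(cols)
        self._bc_vals = np.concatenate(vals)
        self._bc_rhs_rows = np.concatenate(rhs_rows)
        self._bc_rhs_vals = np.concatenate(rhs_vals)

        # inlet mass-flux closure for the continuity rows of inlet CVs
        self._inlet_len = mesh.boundary_segment_lengths(inlet, "y")
        self._inlet_nodes = inlet

    # ------------------------------------------------------------------
    def _ip_fields(self, u: np.ndarray, v: np.ndarray, p: np.ndarray):
        """Per-element integration-point quantities of a nodal state."""
        pre = self.pre
        en = self.mesh.elements
        Nw = pre.shape_ip  # (4 ip, 4 node)
        un, vn, pn = u[en], v[en], p[en]
        u_bl = un @ Nw.T
        v_bl = vn @ Nw.T
        dudx = np.einsum("efk,ek->ef", pre.dNdx, un)
        dudy = np.einsum("efk,ek->ef", pre.dNdy, un)
        dvdx = np.einsum("efk,ek->ef", pre.dNdx, vn)
        dvdy = np.einsum("efk,ek->ef", pre.dNdy, vn)
        dpdx = np.einsum("efk,ek->ef", pre.dNdx, pn)
        dpdy = np.einsum("efk,ek->ef", pre.dNdy, pn)
        v_bar = np.hypot(un.mean(axis=1), vn.mean(axis=1))
        beta = self.props.rho * v_bar / pre.area + self.props.mu / self.L_ref**2
        return u_bl, v_bl, dudx, dudy, dvdx, dvdy, dpdx, dpdy, v_bar, beta

    def hat_velocities(self, state: FlowState) -> tuple[np.ndarray, np.ndarray]:
        """Continuity-equation (pressure-aware) ip velocities, (Ne, 4) each."""
        rho = self.props.rho
        u_bl, v_bl, dudx, dudy, dvdx, dvdy, dpdx, dpdy, _, beta = self._ip_fields(
            state.u, state.v, state.p
        )
        b = beta[:, None]
        u_hat = u_bl - (-rho * (u_bl * dvdy - v_bl * dudy) + dpdx) / b
        v_hat = v_bl - (-rho * (v_bl * dudx - u_bl * dvdx) + dpdy) / b
        return u_hat, v_hat

    def _net_cv_flux(self, state: FlowState) -> np.ndarray:
        """Net volumetric hat flux out of every CV through interior faces."""
        mesh = self.mesh
        u_hat, v_hat = self.hat_velocities(state)
        ds = mesh.face_ds
        flux = u_hat * ds[:, :, 0] + v_hat * ds[:, :, 1]  # (Ne, 4)
        res = np.zeros(self.n)
        en = mesh.elements
        for f in range(4):
            np.add.at(res, en[:, FACE_FROM[f]], flux[:, f])
            np.add.at(res, en[:, FACE_TO[f]], -flux[:, f])
        return res

    def continuity_residual(self, state: FlowState) -> np.ndarray:
        """Net volumetric hat-velocity flux out of every control volume.

        Includes the inlet boundary closure; outlet CVs are reported as
        zero (their continuity is not enforced, pressure is pinned
        there).
        """
        res = self._net_cv_flux(state)
        res[self._inlet_nodes] -= self.bc.u_inlet * self._inlet_len
        res[self.mesh.boundary_tags["outlet"]] = 0.0
        return res

    def projected_face_fluxes(self, state: FlowState) -> tuple[np.ndarray, np.ndarray]:
        """Hat-velocity face fluxes corrected to exact discrete solenoidality.

        The Picard-converged hat fluxes balance every control volume only
        to the iteration tolerance; the residual acts as a spurious
        source for scalar transport and lets a uniform concentration
        drift off its boundary value.  A single graph-Laplacian solve
        distributes face corrections that cancel the per-CV imbalance at
        interior and wall nodes (inlet CVs are Dirichlet in transport,
        outlet CVs are balanced by their closure).  Returns the corrected
        volumetric face fluxes (Ne, 4) and the per-outlet-node closure
        fluxes.
        """
        mesh = self.mesh
        u_hat, v_hat = self.hat_velocities(state)
        ds = mesh.face_ds
        flux = u_hat * ds[:, :, 0] + v_hat * ds[:, :, 1]  # (Ne, 4)
        en = mesh.elements
        n = self.n

        net = np.zeros(n)
        for f in range(4):
            np.add.at(net, en[:, FACE_FROM[f]], flux[:, f])
            np.add.at(net, en[:, FACE_TO[f]], -flux[:, f])
        net[self._inlet_nodes] -= self.bc.u_inlet * self._inlet_len

        pinned = np.zeros(n, dtype=bool)
        pinned[self._inlet_nodes] = True
        pinned[mesh.boundary_tags["outlet"]] = True

        rows, cols, vals = [], [], []
        for f in range(4):
            a = en[:, FACE_FROM[f]]
            b = en[:, FACE_TO[f]]
            one = np.ones(a.size)
            rows += [a, a, b, b]
            cols += [a, b, b, a]
            vals += [one, -one, one, -one]
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        keep = ~pinned[rows]
        rows = np.concatenate([rows[keep], np.nonzero(pinned)[0]])
        cols = np.concatenate([cols[keep], np.nonzero(pinned)[0]])
        vals = np.concatenate([vals[keep], np.ones(int(pinned.sum()))])
        Lap = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
        rhs = np.where(pinned, 0.0, net)
        phi = spla.splu(Lap).solve(rhs)

        for f in range(4):
            flux[:, f] -= phi[en[:, FACE_FROM[f]]] - phi[en[:, FACE_TO[f]]]

        net2 = np.zeros(n)
        for f in range(4):
            np.add.at(net2, en[:, FACE_FROM[f]], flux[:, f])
            np.add.at(net2, en[:, FACE_TO[f]], -flux[:, f])
        outlet_flux = -net2[mesh.boundary_tags["outlet"]]
        return flux, outlet_flux

    def outlet_closure_flux(self, state: FlowState) -> np.ndarray:
        """Per-outlet-node boundary outflow that balances each outlet CV.

        Equal to the net hat influx through the CV's interior faces;
        sums to the inlet flux at convergence.  Used to close the
        transport operator so that a uniform concentration is an exact
        steady state.
        """
        net = self._net_cv_flux(state)
        return -net[self.mesh.boundary_tags["outlet"]]

    def section_fluxes(self, state: FlowState) -> np.ndarray:
        """Volumetric flux (per unit depth) through the dual surface
        between node columns i and i+1, for every element column.

        At convergence these are all equal to the inlet flux: the dual
        surface is made of the x-crossing internal faces of one element
        column and interior continuity telescopes across it.
        """
        u_hat, v_hat = self.hat_velocities(state)
        ds = self.mesh.face_ds
        flux = u_hat * ds[:, :, 0] + v_hat * ds[:, :, 1]  # (Ne, 4)
        nx, ny = self.mesh.shape
        per_elem = (flux[:, 0] - flux[:, 2]).reshape(ny - 1, nx - 1)
        return per_elem.sum(axis=0)

    # ------------------------------------------------------------------
    def _assemble(
        self,
        u: np.ndarray,
        v: np.ndarray,
        p: np.ndarray,
        dt: float | None,
        u_old: np.ndarray,
        v_old: np.ndarray,
    ) -> tuple[sp.csc_matrix, np.ndarray]:
        mesh, pre, props = self.mesh, self.pre, self.props
        rho, mu = props.rho, props.mu
        n = self.n
        en = mesh.elements
        ds = mesh.face_ds
        Nw = pre.shape_ip

        u_bl, v_bl, dudx, dudy, dvdx, dvdy, dpdx, dpdy, v_bar, beta = self._ip_fields(u, v, p)
        b1 = beta[:, None]
        conv_c = rho * v_bar / pre.area  # rho*|V|/A
        diff_c = mu / self.L_ref**2
        w_up = (conv_c / beta)[:, None]
        w_bl = (diff_c / beta) * np.ones_like(beta)
        w_bl = w_bl[:, None]

        # frozen mass fluxes from the previous iterate's hat velocities
        u_hat = u_bl - (-rho * (u_bl * dvdy - v_bl * dudy) + dpdx) / b1
        v_hat = v_bl - (-rho * (v_bl * dudx - u_bl * dvdx) + dpdy) / b1
        mdot = rho * (u_hat * ds[:, :, 0] + v_hat * ds[:, :, 1])  # (Ne, 4)

        v_ref = max(float(np.abs(self.bc.u_inlet).max()), float(np.hypot(u, v).max()), 1e-300)
        C = cv.element_upwind_matrices(pre.x4, pre.y4, mesh.face_ip, u_bl, v_bl, v_ref)

        rows, cols, vals = [], [], []
        rhs_rows, rhs_vals = [], []

        def face_term(row_off: int, col_off: int, f: int, coeff: np.ndarray) -> None:
            rf = en[:, FACE_FROM[f]] + row_off
            rt = en[:, FACE_TO[f]] + row_off
            cc = en + col_off
            rows.append(np.repeat(rf, 4))
            cols.append(cc.ravel())
            vals.append(coeff.ravel())
            rows.append(np.repeat(rt, 4))
            cols.append(cc.ravel())
            vals.append(-coeff.ravel())

        def face_rhs(row_off: int, f: int, val: np.ndarray) -> None:
            rhs_rows.append(en[:, FACE_FROM[f]] + row_off)
            rhs_vals.append(val)
            rhs_rows.append(en[:, FACE_TO[f]] + row_off)
            rhs_vals.append(-val)

        cross_u = (rho / beta)[:, None] * (u_bl * dvdy - v_bl * dudy)
        cross_v = (rho / beta)[:, None] * (v_bl * dudx - u_bl * dvdx)

        for f in range(4):
            m = mdot[:, f][:, None]
            nx = ds[:, f, 0][:, None]
            ny = ds[:, f, 1][:, None]
            dNx = pre.dNdx[:, f, :]
            dNy = pre.dNdy[:, f, :]
            shp = Nw[f][None, :]
            upw = w_up * C[:, f, :] + w_bl * shp

            # u momentum: convection (PIS velocity), diffusion, pressure
            face_term(0, 0, f, m * upw - mu * (dNx * nx + dNy * ny))
            face_term(0, 2 * n, f, -m / b1 * dNx + shp * nx)
            # v momentum
            face_term(n, n, f, m * upw - mu * (dNx * nx + dNy * ny))
            face_term(n, 2 * n, f, -m / b1 * dNy + shp * ny)
            # continuity with hat velocities
            face_term(2 * n, 0, f, rho * nx * shp)
            face_term(2 * n, n, f, rho * ny * shp)
            face_term(2 * n, 2 * n, f, -rho / b1 * (nx * dNx + ny * dNy))
            face_rhs(2 * n, f, -rho * (ds[:, f, 0] * cross_u[:, f] + ds[:, f, 1] * cross_v[:, f]))

        diag_rows = []
        diag_vals = []
        if dt is not None and np.isfinite(dt):
            a_t = rho * mesh.node_volumes / dt
            diag_rows.append(np.arange(n))
            diag_vals.append(a_t)
            diag_rows.append(n + np.arange(n))
            diag_vals.append(a_t)
            rhs_rows += [np.arange(n), n + np.arange(n)]
            rhs_vals += [a_t * u_old, a_t * v_old]

        # inlet boundary mass flux (outward normal -x): moves to the RHS
        rhs_rows.append(2 * n + self._inlet_nodes)
        rhs_vals.append(rho * self.bc.u_inlet * self._inlet_len)

        rows = np.concatenate(rows + diag_rows)
        cols = np.concatenate(cols + ([np.arange(n), n + np.arange(n)] if diag_vals else []))
        vals = np.concatenate(vals + diag_vals)

        keep = ~self._constrained[rows]
        rows = np.concatenate([rows[keep], self._bc_rows])
        cols = np.concatenate([cols[keep], self._bc_cols])
        vals = np.concatenate([vals[keep], self._bc_vals])

        rhs = np.zeros(3 * n)
        for r, vv in zip(rhs_rows, rhs_vals):
            np.add.at(rhs, r, vv)
        rhs[self._constrained] = 0.0
        np.add.at(rhs, self._bc_rhs_rows, self._bc_rhs_vals)

        A = sp.coo_matrix((vals, (rows, cols)), shape=(3 * n, 3 * n)).tocsc()
        return A, rhs

    # ------------------------------------------------------------------
    def solve_step(
        self, state: FlowState, dt: float | None, tol: float | None = None
    ) -> FlowState:
        """One implicit (backward-Euler) step; ``dt=None`` drops the
        transient terms and solves the steady equations directly.

        Picard-iterates the frozen coefficients until the relative
        velocity change falls below ``tol`` (default ``picard_tol``).
        """
        tol = self.picard_tol if tol is None else tol
        u, v, p = state.u.copy(), state.v.copy(), state.p.copy()
        u_ref = max(float(np.abs(self.bc.u_inlet).max()), 1e-300)
        last_rel = np.inf
        for it in range(self.picard_max):
            A, rhs = self._assemble(u, v, p, dt, state.u, state.v)
            try:
                lu = spla.splu(A)
            except RuntimeError as exc:  # pragma: no cover - singular pivot
                raise FlowConvergenceError(f"singular flow system: {exc}") from exc
            sol = lu.solve(rhs)
            if not np.all(np.isfinite(sol)):
                raise FlowConvergenceError("flow solve produced non-finite values")
            un, vn, pn = sol[: self.n], sol[self.n : 2 * self.n], sol[2 * self.n :]
            rel = max(np.abs(un - u).max(), np.abs(vn - v).max()) / u_ref
            u, v, p = un, vn, pn
            if rel < tol:
                break
            last_rel = rel
        else:
            raise FlowConvergenceError(
                f"Picard iteration did not converge: relative change {last_rel:.3e} "
                f"after {self.picard_max} iterations (tol {tol:.1e})"
            )
        return FlowState(u=u, v=v, p=p, t=state.t + (dt if dt and np.isfinite(dt) else 0.0))

    def steady(self, tol: float = 1e-8, max_outer: int = 50) -> FlowState:
        """March the steady equations (no transient term) to a fixed point."""
        state = FlowState(
            u=np.zeros(self.n), v=np.zeros(self.n), p=np.zeros(self.n), t=0.0
        )
        u_ref = max(float(np.abs(self.bc.u_inlet).max()), 1e-300)
        if u_ref <= 1e-299:  # zero inlet: trivial solution
            return state
        history: list[float] = []
        for _ in range(max_outer):
            new = self.solve_step(state, dt=None, tol=self.picard_tol)
            rel = max(np.abs(new.u - state.u).max(), np.abs(new.v - state.v).max()) / u_ref
            state = new
            history.append(rel)
            if rel < tol:
                return state
            if len(history) >= 4 and abs(history[-1] - history[-3]) < 1e-16:
                break  # residual plateau
        raise FlowConvergenceError(
            f"steady flow stalled: last relative changes {history[-3:]}"
        )


def solve_flow_step(
    mesh: Mesh,
    state: FlowState,
    dt: float,
    props: FluidProperties,
    bc: FlowBC,
    tol: float = 1e-6,
    **kwargs,
) -> FlowState:
    """Functional wrapper: one backward-Euler step of the coupled system."""
    if dt is not None and dt <= 0:
        raise ValueError("dt must be positive")
    solver = FlowSolver(mesh, props, bc, picard_tol=tol, **kwargs)
    return solver.solve_step(state, dt)


def steady_flow(
    mesh: Mesh,
    props: FluidProperties,
    bc: FlowBC,
    tol: float = 1e-8,
    picard_tol: float = 1e-6,
    picard_max: int = 30,
    L_ref: float | None = None,
) -> tuple[FlowState, FlowSolver]:
    """Converged steady flow field plus the solver (for ip velocities)."""
    solver = FlowSolver(
        mesh, props, bc, L_ref=L_ref, picard_tol=picard_tol, picard_max=picard_max
    )
    return solver.steady(tol=tol), solver
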