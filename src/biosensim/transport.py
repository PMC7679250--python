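"""Convection-diffusion of the analyte on a frozen velocity field.

The concentration equation  dc/dt + u.grad(c) = div(D grad c) + S  is
integrated with backward Euler on the dual control volumes.  Advective
face values come from the streamline upwind operator, diffusive fluxes
from Fick's law with bilinear shape-function gradients.  Boundary
conditions: Dirichlet c0 at the inlet, homogeneous Neumann on the walls,
zero diffusive flux with upwinded advective outflow at the outlet, and a
prescribed Neumann flux on the sensor strip equal to the surface uptake
rate db/dt (positive uptake removes analyte from the fluid).  The flux
(integral) form of the sensor condition is used so that species
conservation is exact at the discrete level.

Because the velocity field, the time step and the boundary layout are
all frozen during a run, the system matrix is factorized once and reused
for every step; only the right-hand side changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import cvfem_core as cv
from .mesh import FACE_FROM, FACE_TO, Mesh

__all__ = [
    "TransportParams",
    "ConcentrationField",
    "TransportSystem",
    "diffusive_flux",
    "assemble_transport",
    "apply_sensor_flux",
    "solve_transport_step",
]


@dataclass(frozen=True)
class TransportParams:
    D: float  # m^2 s^-1
    c0: float  # mol m^-3
    # S is passed per step as a nodal array (default zero); kept out of
    # the frozen parameter set because manufactured solutions need it
    # time dependent.

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("diffusion coefficient D must be positive")
        if self.c0 < 0:
            raise ValueError("inlet concentration c0 must be non-negative")


@dataclass
class ConcentrationField:
    c: np.ndarray
    t: float = 0.0


def diffusive_flux(mesh: Mesh, c: np.ndarray, D: float, pre: cv.ElementPrecomp | None = None):
    """Fick's-law flux vectors ``-D grad(c)`` at the integration faces.

    Returns an (Ne, 4, 2) array.  The same face value serves the two
    adjacent control volumes with opposite sign, so the flux exchange is
    antisymmetric by construction.
    """
    pre = pre or cv.precompute(mesh)
    cn = c[mesh.elements]
    fx = -D * np.einsum("efk,ek->ef", pre.dNdx, cn)
    fy = -D * np.einsum("efk,ek->ef", pre.dNdy, cn)
    return np.stack([fx, fy], axis=2)


def apply_sensor_flux(
    rhs: np.ndarray, sensor_nodes: np.ndarray, db_dt: np.ndarray, lengths: np.ndarray
) -> np.ndarray:
    """Add the sensor-uptake boundary integral to a system RHS.

    ``db_dt`` (mol m^-2 s^-1) per sensor node; the per-node boundary face
    length distributes the strip integral.  Positive db/dt is a sink.
    """
    if len(sensor_nodes) != len(db_dt):
        raise ValueError("sensor node list and db_dt length mismatch")
    rhs = rhs.copy()
    rhs[sensor_nodes] -= db_dt * lengths
    return rhs


class TransportSystem:
    """Pre-assembled, factorized transport operator on a frozen flow.

    Parameters
    ----------
    ip_u, ip_v : (Ne, 4) velocities at the integration faces (the
        continuity-consistent hat velocities when coming from the flow
        solver, or an analytic field evaluated at the face points).
    bc_mode : ``"channel"`` (inlet Dirichlet / wall Neumann / outlet
        advective outflow / sensor flux) or ``"dirichlet"`` (all
        boundary nodes pinned; used by manufactured solutions).
    dt : time step; ``None`` assembles the steady operator.
    """

    def __init__(
        self,
        mesh: Mesh,
        ip_u: np.ndarray,
        ip_v: np.ndarray,
        D: float,
        dt: float | None,
        bc_mode: str = "channel",
        u_inlet: np.ndarray | None = None,
        outlet_flux: np.ndarray | None = None,
        pre: cv.ElementPrecomp | None = None,
        mdot: np.ndarray | None = None,
    ):
        if dt is not None and dt <= 0:
            raise ValueError("dt must be positive")
        self.mesh = mesh
        self.pre = pre or cv.precompute(mesh)
        self.D = D
        self.dt = dt
        self.bc_mode = bc_mode
        n = mesh.n_nodes
        en = mesh.elements
        ds = mesh.face_ds

        v_ref = max(float(np.hypot(ip_u, ip_v).max()), 1e-300)
        C = cv.element_upwind_matrices(self.pre.x4, self.pre.y4, mesh.face_ip, ip_u, ip_v, v_ref)
        if mdot is None:
            mdot = ip_u * ds[:, :, 0] + ip_v * ds[:, :, 1]  # volumetric, per depth
        self.mdot = mdot

        rows, cols, vals = [], [], []
        for f in range(4):
            coeff = (
                self.mdot[:, f][:, None] * C[:, f, :]
                - D * (self.pre.dNdx[:, f, :] * ds[:, f, 0][:, None]
                       + self.pre.dNdy[:, f, :] * ds[:, f, 1][:, None])
            )
            rf = en[:, FACE_FROM[f]]
            rt = en[:, FACE_TO[f]]
            rows += [np.repeat(rf, 4), np.repeat(rt, 4)]
            cols += [en.ravel(), en.ravel()]
            vals += [coeff.ravel(), -coeff.ravel()]

        diag = np.zeros(n)
        if dt is not None:
            diag += mesh.node_volumes / dt

        tags = mesh.boundary_tags
        if bc_mode == "channel":
            if u_inlet is None or outlet_flux is None:
                raise ValueError("channel transport needs u_inlet and outlet_flux node values")
            self.inlet = tags["inlet"]
            self.outlet = tags["outlet"]
            self.inlet_len = mesh.boundary_segment_lengths(self.inlet, "y")
            self.u_inlet = np.asarray(u_inlet, dtype=float)
            # per-node advective outflow closure; clamped at zero so the
            # operator keeps its sign structure if a closure flux is
            # marginally negative
            self.outlet_flux = np.maximum(np.asarray(outlet_flux, dtype=float), 0.0)
            diag_extra = np.zeros(n)
            diag_extra[self.outlet] = self.outlet_flux
            diag += diag_extra
            self.dirichlet = self.inlet
        elif bc_mode == "dirichlet":
            self.dirichlet = np.unique(
                np.concatenate([tags["inlet"], tags["outlet"], tags["wall"]])
            )
        else:
            raise ValueError(f"unknown bc_mode {bc_mode!r}")

        sensor = tags["sensor"]
        self.sensor_nodes = sensor
        self.sensor_len = mesh.boundary_segment_lengths(sensor, "x")

        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)

        self.A_full = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

        is_dir = np.zeros(n, dtype=bool)
        is_dir[self.dirichlet] = True
        self._is_dir = is_dir
        keep = ~is_dir[rows]
        rows_d = np.concatenate([rows[keep], self.dirichlet])
        cols_d = np.concatenate([cols[keep], self.dirichlet])
        vals_d = np.concatenate([vals[keep], np.ones(self.dirichlet.size)])
        A = sp.coo_matrix((vals_d, (rows_d, cols_d)), shape=(n, n)).tocsc()
        self._lu = spla.splu(A)

    # ------------------------------------------------------------------
    def rhs(
        self,
        c_old: np.ndarray | None,
        *,
        inlet_value: float | None = None,
        db_dt: np.ndarray | None = None,
        S: np.ndarray | None = None,
        dirichlet_values: np.ndarray | None = None,
    ) -> np.ndarray:
        n = self.mesh.n_nodes
        rhs = np.zeros(n)
        if self.dt is not None:
            if c_old is None:
                raise ValueError("transient step needs c_old")
            rhs += self.mesh.node_volumes / self.dt * c_old
        if S is not None:
            rhs += S * self.mesh.node_volumes
        if db_dt is not None:
            rhs = apply_sensor_flux(rhs, self.sensor_nodes, db_dt, self.sensor_len)
        rhs[self.dirichlet] = 0.0
        if self.bc_mode == "channel":
            rhs[self.inlet] = 0.0 if inlet_value is None else inlet_value
        if dirichlet_values is not None:
            rhs[self.dirichlet] = dirichlet_values
        return rhs

    def step(
        self,
        c_old: np.ndarray | None,
        *,
        inlet_value: float | None = None,
        db_dt: np.ndarray | None = None,
        S: np.ndarray | None = None,
        dirichlet_values: np.ndarray | None = None,
    ) -> np.ndarray:
        """Solve for the new concentration field."""
        b = self.rhs(
            c_old, inlet_value=inlet_value, db_dt=db_dt, S=S, dirichlet_values=dirichlet_values
        )
        c = self._lu.solve(b)
        if not np.all(np.isfinite(c)):
            raise RuntimeError("transport solve produced non-finite values")
        return c

    # ------------------------------------------------------------------
    def species_balance(
        self,
        c_old: np.ndarray,
        c_new: np.ndarray,
        inlet_value: float,
        db_dt: np.ndarray | None = None,
        S: np.ndarray | None = None,
        scale: float | None = None,
    ) -> dict[str, float]:
        """Physical bookkeeping of one step: in - out - storage - uptake.

        All rates are per unit depth (mol s^-1 m^-1).  The relative
        residual is normalized by ``scale`` (default: the inlet influx).
        """
        V = self.mesh.node_volumes
        inflow = float(np.sum(self.u_inlet * self.inlet_len) * inlet_value)
        outflow = float(np.sum(self.outlet_flux * c_new[self.outlet]))
        acc = float(np.sum(V * (c_new - c_old)) / self.dt)
        surf = 0.0 if db_dt is None else float(np.sum(db_dt * self.sensor_len))
        src = 0.0 if S is None else float(np.sum(S * V))
        ref = scale if scale else max(abs(inflow), abs(outflow), abs(acc), 1e-300)
        resid = (inflow + src - outflow - acc - surf) / ref
        return {
            "inflow": inflow,
            "outflow": outflow,
            "accumulation": acc,
            "surface_uptake": surf,
            "source": src,
            "residual": resid,
        }


def assemble_transport(
    mesh: Mesh,
    ip_u: np.ndarray,
    ip_v: np.ndarray,
    params: TransportParams,
    dt: float | None,
    **kwargs,
) -> TransportSystem:
    """Build the factorized backward-Euler transport operator."""
    return TransportSystem(mesh, ip_u, ip_v, params.D, dt, **kwargs)


def solve_transport_step(
    system: TransportSystem, field: ConcentrationField, **kwargs
) -> ConcentrationField:
    """Advance the concentration one step on the pre-assembled system."""
    c = system.step(field.c, **kwargs)
    dt = system.dt or 0.0
    return ConcentrationField(c=c, t=field.t + dt)
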