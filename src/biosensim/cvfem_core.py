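"""Discretization kernel: shape functions, integration points, and the
streamline-based upwind operator.

Every element is a bilinear quad with four internal integration faces
(edge midpoint to centroid).  Convected quantities at an integration
point are taken at the point where the local streamline, traced
upstream, crosses the element boundary; the value there is a linear
interpolation between the two nodes of the crossed edge.  Collecting the
four integration points of an element gives a 4x4 matrix mapping nodal
values to upwind values, each row a convex combination of the nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .mesh import FACE_FROM, FACE_TO, Mesh

__all__ = [
    "IP_REF",
    "IntegrationPoint",
    "UpwindSplit",
    "ElementUpwindMatrix",
    "bilinear_shape",
    "bilinear_shape_gradients",
    "streamline_upwind_point",
    "upwind_value",
    "element_upwind_matrix",
    "element_upwind_matrices",
    "ElementPrecomp",
    "precompute",
    "assemble_global",
    "apply_dirichlet",
]

#: Reference-square (xi, eta) coordinates of the four face-midpoint
#: integration points (face f joins the midpoint of edge (f, f+1) to the
#: element centroid).
IP_REF = np.array([[0.0, -0.5], [0.5, 0.0], [0.0, 0.5], [-0.5, 0.0]])

_VEL_FLOOR = 1e-12  # |velocity| below floor*ref -> no upwind direction
_CORNER_TOL = 1e-12  # near-corner hits collapse onto the corner node


@dataclass(frozen=True)
class IntegrationPoint:
    x_ip: float
    y_ip: float
    element_id: int
    face: int  # local face id 0..3
    xi: float
    eta: float


@dataclass(frozen=True)
class UpwindSplit:
    """Result of intersecting the upstream streamline with an element edge.

    ``donor_nodes`` are the local ids of the two nodes bounding the
    crossed edge; ``a_frac``/``b_frac`` are the lengths of the two edge
    portions created by the intersection, with ``b_frac`` the portion
    adjacent to ``donor_nodes[0]``.
    """

    edge_id: int
    donor_nodes: tuple[int, int]
    a_frac: float
    b_frac: float


@dataclass(frozen=True)
class ElementUpwindMatrix:
    C: np.ndarray  # (4, 4); row f maps nodal values to the upwind value at ip f


def bilinear_shape(xi: float | np.ndarray, eta: float | np.ndarray) -> np.ndarray:
    """Standard bilinear weights on [-1, 1]^2, corner order BL, BR, TR, TL."""
    xi = np.asarray(xi, dtype=float)
    eta = np.asarray(eta, dtype=float)
    n = np.stack(
        [
            0.25 * (1 - xi) * (1 - eta),
            0.25 * (1 + xi) * (1 - eta),
            0.25 * (1 + xi) * (1 + eta),
            0.25 * (1 - xi) * (1 + eta),
        ],
        axis=-1,
    )
    return n


def _shape_ref_gradients(xi: float, eta: float) -> np.ndarray:
    """d(N)/d(xi, eta) at a reference point, shape (4, 2)."""
    return 0.25 * np.array(
        [
            [-(1 - eta), -(1 - xi)],
            [(1 - eta), -(1 + xi)],
            [(1 + eta), (1 + xi)],
            [-(1 + eta), (1 - xi)],
        ]
    )


def bilinear_shape_gradients(
    x4: np.ndarray, y4: np.ndarray, xi: float, eta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Physical gradients (dN/dx, dN/dy) of the 4 shape functions.

    ``x4, y4`` may be (4,) for one element or (Ne, 4); results match.
    """
    g = _shape_ref_gradients(xi, eta)  # (4,2)
    squeeze = x4.ndim == 1
    x4 = np.atleast_2d(x4)
    y4 = np.atleast_2d(y4)
    # Jacobian of the bilinear map
    dxdxi = x4 @ g[:, 0]
    dxdeta = x4 @ g[:, 1]
    dydxi = y4 @ g[:, 0]
    dydeta = y4 @ g[:, 1]
    det = dxdxi * dydeta - dxdeta * dydxi
    dNdx = (g[:, 0][None, :] * dydeta[:, None] - g[:, 1][None, :] * dydxi[:, None]) / det[:, None]
    dNdy = (-g[:, 0][None, :] * dxdeta[:, None] + g[:, 1][None, :] * dxdxi[:, None]) / det[:, None]
    if squeeze:
        return dNdx[0], dNdy[0]
    return dNdx, dNdy


def _edges(x4: np.ndarray, y4: np.ndarray):
    ax = x4
    ay = y4
    bx = np.roll(x4, -1, axis=-1)
    by = np.roll(y4, -1, axis=-1)
    return ax, ay, bx, by


def streamline_upwind_point(
    x4: np.ndarray,
    y4: np.ndarray,
    ip_xy: tuple[float, float],
    u_ip: float,
    v_ip: float,
    v_ref: float = 1.0,
) -> UpwindSplit:
    """Intersect the upstream streamline through an integration point
    with the element boundary.

    The streamline is the line through ``ip_xy`` with direction
    ``(u_ip, v_ip)``; "upstream" is the crossing at negative parameter
    along the velocity.  Raises ``ValueError`` when the velocity
    magnitude is below ``_VEL_FLOOR * v_ref`` (no upwind direction; the
    caller falls back to central interpolation).
    """
    speed = np.hypot(u_ip, v_ip)
    if speed <= _VEL_FLOOR * v_ref:
        raise ValueError("no upwind direction: velocity magnitude below threshold")
    px, py = ip_xy
    dx, dy = u_ip / speed, v_ip / speed
    best = None  # (t, edge, s, length)
    for k in range(4):
        kp = (k + 1) % 4
        ex = x4[kp] - x4[k]
        ey = y4[kp] - y4[k]
        det = dx * ey - ex * dy
        if det == 0.0:
            continue
        wx = x4[k] - px
        wy = y4[k] - py
        t = (ex * wy - ey * wx) / det
        s = (wx * dy - wy * dx) / det
        length = np.hypot(ex, ey)
        if t > 1e-14 * length and -_CORNER_TOL <= s <= 1 + _CORNER_TOL:
            if best is None or t < best[0]:
                best = (t, k, s, length)
    if best is None:
        raise ValueError("upstream ray does not cross the element boundary")
    _, k, s, length = best
    s = min(max(s, 0.0), 1.0)
    # near-corner tie-break: full weight to the corner node
    if s < _CORNER_TOL:
        s = 0.0
    elif s > 1 - _CORNER_TOL:
        s = 1.0
    kp = (k + 1) % 4
    return UpwindSplit(
        edge_id=k, donor_nodes=(k, kp), a_frac=(1.0 - s) * length, b_frac=s * length
    )


def upwind_value(split: UpwindSplit, phi: np.ndarray) -> float:
    """Linear interpolation along the crossed edge,
    ``(a*phi_n1 + b*phi_n2) / (a + b)``."""
    denom = split.a_frac + split.b_frac
    if denom <= 0:
        raise ValueError("degenerate edge: a_frac + b_frac == 0")
    n1, n2 = split.donor_nodes
    return (split.a_frac * phi[n1] + split.b_frac * phi[n2]) / denom


def element_upwind_matrix(
    x4: np.ndarray,
    y4: np.ndarray,
    ip_xy: np.ndarray,
    ip_uv: np.ndarray,
    v_ref: float = 1.0,
) -> ElementUpwindMatrix:
    """4x4 matrix mapping element nodal values to the 4 upwind values.

    Rows where the streamline construction fails (stagnant point) fall
    back to bilinear interpolation at the integration point itself.
    """
    C = np.zeros((4, 4))
    fallback = bilinear_shape(IP_REF[:, 0], IP_REF[:, 1])
    for f in range(4):
        try:
            split = streamline_upwind_point(
                x4, y4, (ip_xy[f, 0], ip_xy[f, 1]), ip_uv[f, 0], ip_uv[f, 1], v_ref
            )
        except ValueError:
            C[f] = fallback[f]
            continue
        denom = split.a_frac + split.b_frac
        n1, n2 = split.donor_nodes
        C[f, n1] = split.a_frac / denom
        C[f, n2] = split.b_frac / denom
    return ElementUpwindMatrix(C=C)


def element_upwind_matrices(
    x4: np.ndarray,
    y4: np.ndarray,
    ip_xy: np.ndarray,
    u_ip: np.ndarray,
    v_ip: np.ndarray,
    v_ref: float,
) -> np.ndarray:
    """Vectorized upwind matrices for all elements, shape (Ne, 4, 4).

    ``x4, y4``: (Ne, 4) element corners; ``ip_xy``: (Ne, 4, 2) face
    integration points; ``u_ip, v_ip``: (Ne, 4) velocities there.
    """
    ne = x4.shape[0]
    C = np.zeros((ne, 4, 4))
    speed = np.hypot(u_ip, v_ip)  # (Ne,4)
    ok = speed > _VEL_FLOOR * v_ref
    dx = np.where(ok, u_ip / np.where(ok, speed, 1.0), 0.0)
    dy = np.where(ok, v_ip / np.where(ok, speed, 1.0), 0.0)

    ax, ay, bx, by = _edges(x4, y4)  # (Ne,4) each, edge k = (node k, node k+1)
    ex = bx - ax
    ey = by - ay
    elen = np.hypot(ex, ey)

    # broadcast: (Ne, 4 ip, 4 edge)
    px = ip_xy[:, :, 0][:, :, None]
    py = ip_xy[:, :, 1][:, :, None]
    DX = dx[:, :, None]
    DY = dy[:, :, None]
    EX = ex[:, None, :]
    EY = ey[:, None, :]
    WX = ax[:, None, :] - px
    WY = ay[:, None, :] - py
    det = DX * EY - EX * DY
    safe = np.where(det == 0.0, 1.0, det)
    t = (EX * WY - EY * WX) / safe
    s = (WX * DY - WY * DX) / safe
    valid = (
        (det != 0.0)
        & (t > 1e-14 * elen[:, None, :])
        & (s >= -_CORNER_TOL)
        & (s <= 1 + _CORNER_TOL)
        & ok[:, :, None]
    )
    t_pick = np.where(valid, t, np.inf)
    edge = np.argmin(t_pick, axis=2)  # (Ne,4)
    has_edge = np.isfinite(np.min(t_pick, axis=2)) & ok

    ii = np.arange(ne)[:, None]
    ff = np.arange(4)[None, :]
    s_hit = np.clip(s[ii, ff, edge], 0.0, 1.0)
    s_hit = np.where(s_hit < _CORNER_TOL, 0.0, s_hit)
    s_hit = np.where(s_hit > 1 - _CORNER_TOL, 1.0, s_hit)

    n1 = edge
    n2 = (edge + 1) % 4
    w1 = np.where(has_edge, 1.0 - s_hit, 0.0)
    w2 = np.where(has_edge, s_hit, 0.0)

    C[ii, ff, n1] += w1
    C[ii, ff, n2] += w2

    fallback = bilinear_shape(IP_REF[:, 0], IP_REF[:, 1])  # (4,4)
    fb = ~has_edge
    if np.any(fb):
        fi, fj = np.nonzero(fb)
        C[fi, fj, :] = fallback[fj]
    return C


@dataclass
class ElementPrecomp:
    """Geometry-dependent element quantities shared by the solvers."""

    shape_ip: np.ndarray  # (4 ip, 4 node) bilinear weights at the integration points
    dNdx: np.ndarray  # (Ne, 4 ip, 4 node)
    dNdy: np.ndarray  # (Ne, 4 ip, 4 node)
    area: np.ndarray  # (Ne,) element areas
    x4: np.ndarray  # (Ne, 4)
    y4: np.ndarray  # (Ne, 4)


def precompute(mesh: Mesh) -> ElementPrecomp:
    x4, y4 = mesh.element_coords()
    ne = mesh.n_elements
    dNdx = np.empty((ne, 4, 4))
    dNdy = np.empty((ne, 4, 4))
    for f in range(4):
        gx, gy = bilinear_shape_gradients(x4, y4, IP_REF[f, 0], IP_REF[f, 1])
        dNdx[:, f, :] = gx
        dNdy[:, f, :] = gy
    return ElementPrecomp(
        shape_ip=bilinear_shape(IP_REF[:, 0], IP_REF[:, 1]),
        dNdx=dNdx,
        dNdy=dNdy,
        area=mesh.sub_areas.sum(axis=1),
        x4=x4,
        y4=y4,
    )


def assemble_global(
    n_unknowns: int,
    entries: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    rhs_entries: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Scatter-add COO triplets into a global sparse matrix and RHS."""
    rows = np.concatenate([np.asarray(r).ravel() for r, _, _ in entries])
    cols = np.concatenate([np.asarray(c).ravel() for _, c, _ in entries])
    vals = np.concatenate([np.asarray(v).ravel() for _, _, v in entries])
    if rows.size != cols.size or rows.size != vals.size:
        raise ValueError("assembly dimension mismatch between rows, cols and values")
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n_unknowns, n_unknowns)).tocsr()
    b = np.zeros(n_unknowns)
    if rhs_entries:
        for r, v in rhs_entries:
            np.add.at(b, np.asarray(r).ravel(), np.asarray(v).ravel())
    return A, b


def apply_dirichlet(
    A: sp.csr_matrix, b: np.ndarray, rows: np.ndarray, values: np.ndarray
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Replace the given rows by identity rows with prescribed values."""
    A = A.tolil()
    A[rows, :] = 0.0
    A[rows, rows] = 1.0
    b = b.copy()
    b[rows] = values
    return A.tocsr(), b
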