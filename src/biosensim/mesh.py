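"""Structured quad mesh of the channel with dual control volumes.

The channel is meshed with a tensor-product grid of bilinear quad
elements.  Around every node a dual control volume is carved out of the
adjacent elements: each element is cut into four sub-volumes by the
segments joining its edge midpoints to its centroid, and every node owns
the quadrant touching it.  The four cutting segments are the internal
integration faces through which all fluxes are evaluated.

Node numbering is 0-based and row-major: node ``n = j*Nx + i`` sits at
``(x[i], y[j])`` with ``i`` streamwise and ``j`` cross-channel.  Element
``e = j*(Nx-1) + i`` lists its corner nodes counter-clockwise starting
from the bottom-left one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryConfig",
    "Mesh",
    "build_channel_mesh",
    "subcontrol_areas",
    "locate_sensor_nodes",
]

# Local corner order of an element: BL, BR, TR, TL (counter-clockwise).
# Internal face f runs from the midpoint of edge (f, f+1) to the element
# centroid; its normal points from sub-volume f into sub-volume f+1.
FACE_FROM = np.array([0, 1, 2, 3])
FACE_TO = np.array([1, 2, 3, 0])


@dataclass(frozen=True)
class GeometryConfig:
    """Channel and sensor geometry plus structured-mesh resolution.

    All lengths are SI metres.  ``grading_ratio`` is the geometric ratio
    of successive cell heights in y moving away from the bottom (sensor)
    wall; 1 gives a uniform mesh.
    """

    L: float
    H: float
    Ls: float
    Nx: int
    Ny: int
    Ns: int
    sensor_offset: float = 0.0
    grading_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not (self.L > 0 and self.H > 0):
            raise ValueError("channel dimensions L, H must be positive")
        if not (0 < self.Ls <= self.L):
            raise ValueError("sensor length Ls must satisfy 0 < Ls <= L")
        if self.sensor_offset < 0 or self.sensor_offset + self.Ls > self.L * (1 + 1e-12):
            raise ValueError("sensor [offset, offset+Ls] must lie inside [0, L]")
        if self.Nx < 3 or self.Ny < 3:
            raise ValueError("Nx and Ny must both be >= 3")
        if not (2 <= self.Ns <= self.Nx):
            raise ValueError("Ns must satisfy 2 <= Ns <= Nx")
        if not self.grading_ratio > 0:
            raise ValueError("grading_ratio must be positive")


@dataclass
class Mesh:
    """Structured channel mesh with dual-control-volume geometry.

    Attributes
    ----------
    node_x, node_y : (N,) nodal coordinates.
    elements : (Ne, 4) corner node indices, counter-clockwise.
    face_ds : (Ne, 4, 2) signed area components (per unit depth) of the
        four internal integration faces of each element; the normal of
        face ``f`` points from sub-volume ``FACE_FROM[f]`` into
        ``FACE_TO[f]``.
    face_ip : (Ne, 4, 2) physical coordinates of the face-midpoint
        integration points.
    sub_areas : (Ne, 4) area of each sub-control volume.
    node_volumes : (N,) dual control-volume area of every node.
    boundary_tags : node-index arrays for inlet, outlet, wall, sensor.
        ``wall`` holds every no-slip node (sensor nodes included);
        ``sensor`` is the contiguous bottom-wall run under the strip.
    """

    geometry: GeometryConfig
    node_x: np.ndarray
    node_y: np.ndarray
    elements: np.ndarray
    face_ds: np.ndarray
    face_ip: np.ndarray
    sub_areas: np.ndarray
    node_volumes: np.ndarray
    boundary_tags: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.node_x.size

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.geometry.Nx, self.geometry.Ny)

    def node_index(self, i: int, j: int) -> int:
        return j * self.geometry.Nx + i

    def element_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Corner coordinates of every element as (Ne, 4) arrays."""
        return self.node_x[self.elements], self.node_y[self.elements]

    def interior_nodes(self) -> np.ndarray:
        tagged = np.concatenate(
            [self.boundary_tags["inlet"], self.boundary_tags["outlet"], self.boundary_tags["wall"]]
        )
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[tagged] = False
        return np.nonzero(mask)[0]

    def boundary_segment_lengths(self, nodes: np.ndarray, axis: str) -> np.ndarray:
        """Length of boundary owned by each of the given boundary nodes.

        ``axis='y'`` for inlet/outlet columns (lengths along y),
        ``axis='x'`` for wall rows (lengths along x).  Each node owns the
        half-segments on either side of it.
        """
        coord = self.node_y if axis == "y" else self.node_x
        c = np.sort(coord[nodes])
        ln = np.empty_like(c)
        ln[1:-1] = 0.5 * (c[2:] - c[:-2])
        ln[0] = 0.5 * (c[1] - c[0])
        ln[-1] = 0.5 * (c[-1] - c[-2])
        order = np.argsort(coord[nodes])
        out = np.empty_like(ln)
        out[order] = ln
        return out

    def export_vtk(self, path, point_data: dict[str, np.ndarray] | None = None) -> None:
        from .vtkio import write_structured_vtk

        write_structured_vtk(path, self, point_data or {})


def _graded_coords(start: float, length: float, n: int, ratio: float) -> np.ndarray:
    """n coordinates over [start, start+length]; successive spacings grow by `ratio`."""
    if abs(ratio - 1.0) < 1e-14:
        return start + np.linspace(0.0, length, n)
    w = ratio ** np.arange(n - 1)
    steps = length * w / w.sum()
    return start + np.concatenate([[0.0], np.cumsum(steps)])


def _quad_subareas(x4: np.ndarray, y4: np.ndarray) -> np.ndarray:
    """Areas of the 4 corner sub-volumes of each element, (Ne, 4).

    Sub-volume k is the quad (node_k, mid(k,k+1), centroid, mid(k-1,k)).
    """
    ox = x4.mean(axis=1)
    oy = y4.mean(axis=1)
    areas = np.empty_like(x4)
    for k in range(4):
        kp = (k + 1) % 4
        km = (k - 1) % 4
        px = np.stack(
            [x4[:, k], 0.5 * (x4[:, k] + x4[:, kp]), ox, 0.5 * (x4[:, km] + x4[:, k])], axis=1
        )
        py = np.stack(
            [y4[:, k], 0.5 * (y4[:, k] + y4[:, kp]), oy, 0.5 * (y4[:, km] + y4[:, k])], axis=1
        )
        # shoelace
        s = np.zeros(x4.shape[0])
        for m in range(4):
            mp = (m + 1) % 4
            s += px[:, m] * py[:, mp] - px[:, mp] * py[:, m]
        areas[:, k] = 0.5 * s
    return areas


def subcontrol_areas(x4: np.ndarray, y4: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Signed area components and midpoints of the internal faces.

    Parameters are the element corner coordinates, shape (Ne, 4) (a
    single element may be passed as shape (4,)).  Returns ``(ds, ip)``
    with shapes (Ne, 4, 2): face ``f`` runs from the midpoint of edge
    (f, f+1) to the element centroid and ``ds[:, f] = (dy, -dx)`` along
    that segment, i.e. the outward normal of sub-volume ``f`` times the
    face length.  Degenerate (non-positive area) elements are rejected.
    """
    squeeze = x4.ndim == 1
    x4 = np.atleast_2d(x4)
    y4 = np.atleast_2d(y4)
    area = 0.5 * np.abs(
        sum(x4[:, m] * y4[:, (m + 1) % 4] - x4[:, (m + 1) % 4] * y4[:, m] for m in range(4))
    )
    bad = np.nonzero(area <= 0)[0]
    if bad.size:
        raise ValueError(f"degenerate element(s) with zero area: indices {bad.tolist()}")
    ox = x4.mean(axis=1)
    oy = y4.mean(axis=1)
    ds = np.empty((x4.shape[0], 4, 2))
    ip = np.empty((x4.shape[0], 4, 2))
    for f in range(4):
        fp = (f + 1) % 4
        mx = 0.5 * (x4[:, f] + x4[:, fp])
        my = 0.5 * (y4[:, f] + y4[:, fp])
        dx = ox - mx
        dy = oy - my
        ds[:, f, 0] = dy
        ds[:, f, 1] = -dx
        ip[:, f, 0] = 0.5 * (mx + ox)
        ip[:, f, 1] = 0.5 * (my + oy)
    if squeeze:
        return ds[0], ip[0]
    return ds, ip


def _snap_sensor_run(x: np.ndarray, geom: GeometryConfig) -> np.ndarray:
    """Bottom-row i-indices of the sensor strip, snapped to nearest nodes."""
    x0 = geom.sensor_offset
    x1 = geom.sensor_offset + geom.Ls
    i0 = int(np.argmin(np.abs(x - x0)))
    i1 = int(np.argmin(np.abs(x - x1)))
    # half-cell snapping tolerance at each end
    for i_end, target in ((i0, x0), (i1, x1)):
        lo = x[max(i_end - 1, 0)]
        hi = x[min(i_end + 1, x.size - 1)]
        half = 0.5 * max(x[min(i_end + 1, x.size - 1)] - x[i_end], x[i_end] - x[max(i_end - 1, 0)])
        if abs(x[i_end] - target) > half * (1 + 1e-9):
            raise ValueError(
                f"sensor edge at x={target:g} m falls more than half a cell from the "
                f"nearest node (x={x[i_end]:g} m, neighbours {lo:g}, {hi:g})"
            )
    count = i1 - i0 + 1
    if count != geom.Ns:
        raise ValueError(
            f"Ns={geom.Ns} is incompatible with the mesh: the snapped sensor run "
            f"[{x[i0]:g}, {x[i1]:g}] m contains {count} bottom-wall nodes"
        )
    return np.arange(i0, i1 + 1)


def build_channel_mesh(geom: GeometryConfig) -> Mesh:
    """Build the structured channel mesh with boundary tags.

    The origin sits at the inlet/bottom corner, x streamwise, y
    cross-channel.  Inlet/outlet are the x=0 / x=L node columns and take
    precedence over the walls at the corners.  The sensor run is snapped
    to the nearest bottom-wall nodes (within half a cell at each edge)
    and must contain exactly ``Ns`` nodes.
    """
    nx, ny = geom.Nx, geom.Ny
    x = np.linspace(0.0, geom.L, nx)
    y = _graded_coords(0.0, geom.H, ny, geom.grading_ratio)

    node_x = np.tile(x, ny)
    node_y = np.repeat(y, nx)

    i = np.arange(nx - 1)
    j = np.arange(ny - 1)
    ii, jj = np.meshgrid(i, j, indexing="xy")
    n0 = (jj * nx + ii).ravel()
    elements = np.stack([n0, n0 + 1, n0 + nx + 1, n0 + nx], axis=1)

    x4 = node_x[elements]
    y4 = node_y[elements]
    face_ds, face_ip = subcontrol_areas(x4, y4)
    sub_areas = _quad_subareas(x4, y4)

    node_volumes = np.zeros(nx * ny)
    np.add.at(node_volumes, elements.ravel(), sub_areas.ravel())

    inlet = np.arange(ny) * nx
    outlet = np.arange(ny) * nx + (nx - 1)
    bottom = np.arange(nx)
    top = (ny - 1) * nx + np.arange(nx)
    wall = np.setdiff1d(np.concatenate([bottom, top]), np.concatenate([inlet, outlet]))

    sensor_i = _snap_sensor_run(x, geom)
    sensor = sensor_i.copy()  # bottom row -> node index == i

    mesh = Mesh(
        geometry=geom,
        node_x=node_x,
        node_y=node_y,
        elements=elements,
        face_ds=face_ds,
        face_ip=face_ip,
        sub_areas=sub_areas,
        node_volumes=node_volumes,
        boundary_tags={
            "inlet": inlet,
            "outlet": outlet,
            "wall": wall,
            "sensor": sensor,
        },
    )
    return mesh


def locate_sensor_nodes(mesh: Mesh) -> np.ndarray:
    """Sensor-strip node indices on the bottom wall, ordered by x."""
    s = mesh.boundary_tags["sensor"]
    return s[np.argsort(mesh.node_x[s], kind="stable")]
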