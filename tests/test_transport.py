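import numpy as np
import pytest

from biosensim.mesh import GeometryConfig, build_channel_mesh
from biosensim.transport import (
    ConcentrationField,
    TransportParams,
    TransportSystem,
    apply_sensor_flux,
    assemble_transport,
    diffusive_flux,
    solve_transport_step,
)


def box_mesh(nx=6, ny=5, L=1.0, H=1.0):
    g = GeometryConfig(L=L, H=H, Ls=L, Nx=nx, Ny=ny, Ns=nx)
    return build_channel_mesh(g)


class TestParams:
    def test_invariants(self):
        with pytest.raises(ValueError):
            TransportParams(D=0.0, c0=1.0)
        with pytest.raises(ValueError):
            TransportParams(D=1.0, c0=-1.0)


class TestDiffusiveFlux:
    def test_uniform_field_zero_flux(self):
        m = box_mesh()
        F = diffusive_flux(m, np.full(m.n_nodes, 3.7), D=1.0)
        assert np.abs(F).max() < 1e-14

    def test_linear_field_exact_gradient(self):
        m = box_mesh()
        F = diffusive_flux(m, m.node_x.copy(), D=2.0)
        assert np.allclose(F[:, :, 0], -2.0, atol=1e-13)
        assert np.abs(F[:, :, 1]).max() < 1e-13

    def test_antisymmetric_exchange(self):
        # a single face value serves both adjacent CVs; reconstructing
        # per-node net fluxes from faces must sum to zero globally
        m = box_mesh(4, 4)
        rng = np.random.default_rng(1)
        c = rng.normal(size=m.n_nodes)
        F = diffusive_flux(m, c, D=0.5)
        from biosensim.mesh import FACE_FROM, FACE_TO

        net = np.zeros(m.n_nodes)
        for f in range(4):
            fl = F[:, f, 0] * m.face_ds[:, f, 0] + F[:, f, 1] * m.face_ds[:, f, 1]
            np.add.at(net, m.elements[:, FACE_FROM[f]], fl)
            np.add.at(net, m.elements[:, FACE_TO[f]], -fl)
        assert abs(net.sum()) < 1e-14


class TestChannelTransport:
    def _quiescent(self, m, dt=1.0, D=1e-3):
        ne = m.n_elements
        n_in = m.boundary_tags["inlet"].size
        n_out = m.boundary_tags["outlet"].size
        return TransportSystem(
            m,
            np.zeros((ne, 4)),
            np.zeros((ne, 4)),
            D,
            dt,
            bc_mode="channel",
            u_inlet=np.zeros(n_in),
            outlet_flux=np.zeros(n_out),
        )

    def test_equilibrium_uniform_field(self):
        m = box_mesh()
        ts = self._quiescent(m)
        c = np.full(m.n_nodes, 2.0)
        for _ in range(5):
            c = ts.step(c, inlet_value=2.0)
        assert np.allclose(c, 2.0, atol=1e-12)

    def test_zero_solution_stays_zero(self):
        m = box_mesh()
        ts = self._quiescent(m)
        c = np.zeros(m.n_nodes)
        for _ in range(3):
            c = ts.step(c, inlet_value=0.0)
        assert np.abs(c).max() == 0.0

    def test_plug_flow_front_speed(self):
        # method-of-characteristics oracle: an advected inlet step sits
        # at x = u*t to within one cell
        L, u0, D = 1.0, 1.0e-2, 1e-9
        m = box_mesh(nx=51, ny=4, L=L, H=0.05)
        ne = m.n_elements
        ipu = np.full((ne, 4), u0)
        n_in = m.boundary_tags["inlet"].size
        out_len = m.boundary_segment_lengths(m.boundary_tags["outlet"], "y")
        dt = 0.5
        ts = TransportSystem(
            m,
            ipu,
            np.zeros((ne, 4)),
            D,
            dt,
            bc_mode="channel",
            u_inlet=np.full(n_in, u0),
            outlet_flux=u0 * out_len,
        )
        c = np.zeros(m.n_nodes)
        t_end = 50.0
        for _ in range(int(t_end / dt)):
            c = ts.step(c, inlet_value=1.0)
        bottom = c[: m.geometry.Nx]
        x = m.node_x[: m.geometry.Nx]
        front = x[np.argmin(np.abs(bottom - 0.5))]
        dx = L / (m.geometry.Nx - 1)
        assert abs(front - u0 * t_end) <= dx + 1e-12

    def test_missing_boundary_assignment_raises(self):
        m = box_mesh()
        ne = m.n_elements
        with pytest.raises(ValueError, match="u_inlet|outlet_flux"):
            TransportSystem(
                m, np.zeros((ne, 4)), np.zeros((ne, 4)), 1e-3, 1.0, bc_mode="channel"
            )

    def test_unknown_bc_mode_raises(self):
        m = box_mesh()
        ne = m.n_elements
        with pytest.raises(ValueError, match="bc_mode"):
            TransportSystem(
                m, np.zeros((ne, 4)), np.zeros((ne, 4)), 1e-3, 1.0, bc_mode="periodic"
            )


class TestSensorFlux:
    def test_zero_uptake_identical_to_wall(self):
        m = box_mesh()
        sensor = m.boundary_tags["sensor"]
        rhs = np.ones(m.n_nodes)
        lengths = m.boundary_segment_lengths(sensor, "x")
        out = apply_sensor_flux(rhs, sensor, np.zeros(sensor.size), lengths)
        assert np.array_equal(out, rhs)

    def test_uniform_uptake_total_sink(self):
        # total sink over a strip of length Ls equals r*Ls per unit depth
        m = box_mesh(nx=11, ny=4, L=2.0)
        sensor = m.boundary_tags["sensor"]
        lengths = m.boundary_segment_lengths(sensor, "x")
        r = 3.0e-7
        rhs = apply_sensor_flux(np.zeros(m.n_nodes), sensor, np.full(sensor.size, r), lengths)
        assert rhs.sum() == pytest.approx(-r * 2.0, rel=1e-12)

    def test_length_mismatch_raises(self):
        m = box_mesh()
        sensor = m.boundary_tags["sensor"]
        with pytest.raises(ValueError, match="mismatch"):
            apply_sensor_flux(np.zeros(m.n_nodes), sensor, np.zeros(2), np.zeros(2))

    def test_steady_constant_sink_global_balance(self):
        # inlet influx - outlet efflux = r*Ls at steady state
        # advection-dominated so the (unaudited) inlet diffusive flux is
        # negligible against the advective influx
        L, H, u0, D = 1e-2, 1e-3, 1e-5, 1e-10
        g = GeometryConfig(L=L, H=H, Ls=L, Nx=41, Ny=9, Ns=41)
        m = build_channel_mesh(g)
        ne = m.n_elements
        n_in = m.boundary_tags["inlet"].size
        out_len = m.boundary_segment_lengths(m.boundary_tags["outlet"], "y")
        ts = TransportSystem(
            m,
            np.full((ne, 4), u0),
            np.zeros((ne, 4)),
            D,
            dt=None,
            bc_mode="channel",
            u_inlet=np.full(n_in, u0),
            outlet_flux=u0 * out_len,
        )
        c0 = 1.0
        # sink small enough not to drive c negative
        r = 0.2 * u0 * H * c0 / L
        c = ts.step(None, inlet_value=c0, db_dt=np.full(ts.sensor_nodes.size, r))
        inflow = u0 * H * c0
        outflow = float(np.sum(ts.outlet_flux * c[ts.outlet]))
        # the sensor's inlet-corner node is Dirichlet (inlet wins at
        # corners), so its share of the sink is not applied
        applied = ~np.isin(ts.sensor_nodes, m.boundary_tags["inlet"])
        sink = r * float(ts.sensor_len[applied].sum())
        assert abs(inflow - outflow - sink) / inflow < 1e-3


class TestStepWrapper:
    def test_solve_transport_step_advances_time(self):
        m = box_mesh()
        ne = m.n_elements
        ts = TransportSystem(
            m,
            np.zeros((ne, 4)),
            np.zeros((ne, 4)),
            1e-3,
            2.0,
            bc_mode="channel",
            u_inlet=np.zeros(m.boundary_tags["inlet"].size),
            outlet_flux=np.zeros(m.boundary_tags["outlet"].size),
        )
        f0 = ConcentrationField(c=np.zeros(m.n_nodes), t=10.0)
        f1 = solve_transport_step(ts, f0, inlet_value=0.0)
        assert f1.t == 12.0

    def test_assemble_transport_wrapper(self):
        m = box_mesh()
        ne = m.n_elements
        ts = assemble_transport(
            m,
            np.zeros((ne, 4)),
            np.zeros((ne, 4)),
            TransportParams(D=1e-3, c0=1.0),
            dt=1.0,
            bc_mode="dirichlet",
        )
        assert ts.dt == 1.0

    def test_temporal_richardson_first_order(self):
        # halving dt changes c(T) by O(dt)
        from biosensim.driver_io import run_mms_temporal

        e1 = run_mms_temporal(0.1, n_nodes=17, t_end=0.4)
        e2 = run_mms_temporal(0.05, n_nodes=17, t_end=0.4)
        ratio = e1 / e2
        assert 1.6 < ratio < 2.6
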