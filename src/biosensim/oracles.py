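"""Closed-form references and manufactured solutions for verification.

Everything here is evaluable without running the simulator: the
fully developed channel profile, the well-mixed binding ODE (closed form
plus an adaptive-integration cross-check), manufactured
convection-diffusion solutions with symbolically derived source terms,
and the packaged validation-case configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .kinetics import SurfaceKineticsParams
from .mesh import GeometryConfig

__all__ = [
    "poiseuille_profile",
    "well_mixed_langmuir",
    "langmuir_ode_reference",
    "MMSCase",
    "mms_case",
    "validation_fixture",
]


def poiseuille_profile(Q: float, H: float, W: float, y: np.ndarray | float) -> np.ndarray | float:
    """Fully developed laminar profile ``u(y) = 6*u_mean*(y/H)*(1 - y/H)``."""
    u_mean = Q / (H * W)
    yy = np.asarray(y, dtype=float)
    return 6.0 * u_mean * (yy / H) * (1.0 - yy / H)


def well_mixed_langmuir(
    t: np.ndarray | float, c: float, params: SurfaceKineticsParams, b0: float = 0.0
) -> np.ndarray | float:
    """Closed-form b(t) for constant wall concentration c.

    ``b(t) = b_eq*(1 - exp(-k t)) + b0*exp(-k t)`` with
    ``k = kon*c + koff`` and ``b_eq = bmax*kon*c/k``.
    """
    k = params.kon * c + params.koff
    tt = np.asarray(t, dtype=float)
    if k == 0:
        return np.full_like(tt, b0, dtype=float)
    b_eq = params.bmax * params.kon * c / k
    return b_eq * (1.0 - np.exp(-k * tt)) + b0 * np.exp(-k * tt)


def langmuir_ode_reference(
    t_eval: np.ndarray, c: float, params: SurfaceKineticsParams, b0: float = 0.0
) -> np.ndarray:
    """High-accuracy adaptive integration of the binding ODE.

    Independent cross-check of :func:`well_mixed_langmuir`.
    """
    from scipy.integrate import solve_ivp

    t_eval = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(
        lambda _t, b: params.kon * c * (params.bmax - b) - params.koff * b,
        (0.0, float(t_eval.max())),
        [b0],
        t_eval=t_eval,
        method="LSODA",
        rtol=1e-12,
        atol=1e-30,
    )
    if not sol.success:
        raise RuntimeError(f"ODE reference integration failed: {sol.message}")
    return sol.y[0]


@dataclass
class MMSCase:
    """A manufactured convection-diffusion solution on the unit-ish box.

    ``c_star(x, y, t)`` solves dc/dt + u.grad(c) = div(D grad c) + S
    exactly for the prescribed divergence-free velocity, with ``S``
    derived by symbolic differentiation.
    """

    geometry: GeometryConfig
    D: float
    u: Callable
    v: Callable
    c_star: Callable
    source: Callable
    level: int
    regime: str


def mms_case(level: int, regime: str = "diffusion", base: int = 8, omega: float = 0.0) -> MMSCase:
    """Manufactured case at mesh density ``base * 2**level + 1`` nodes/side.

    ``regime='diffusion'`` uses a slow recirculating velocity (cell
    Peclet < 1 on all levels); ``'advection'`` scales the velocity so
    convection dominates the transport balance.  ``omega`` adds a
    ``cos(omega t)`` modulation for temporal-order studies.
    """
    import sympy as sy

    if level < 0:
        raise ValueError("level must be >= 0")
    L = H = 1.0
    D = 1.0e-2
    if regime == "diffusion":
        U0 = 5.0e-3
    elif regime == "advection":
        U0 = 10.0  # global Peclet 1e3: clean first-order upwind asymptotics
    else:
        raise ValueError("regime must be 'diffusion' or 'advection'")

    x, y, t = sy.symbols("x y t", real=True)
    u_sym = U0 * sy.sin(sy.pi * x / L) * sy.cos(sy.pi * y / H)
    v_sym = -U0 * (H / L) * sy.cos(sy.pi * x / L) * sy.sin(sy.pi * y / H)
    c_sym = (1 + sy.Rational(1, 2) * sy.sin(2 * sy.pi * x / L) * sy.sin(2 * sy.pi * y / H)) * (
        1 + sy.Rational(1, 2) * sy.cos(omega * t)
    )
    s_sym = (
        sy.diff(c_sym, t)
        + u_sym * sy.diff(c_sym, x)
        + v_sym * sy.diff(c_sym, y)
        - D * (sy.diff(c_sym, x, 2) + sy.diff(c_sym, y, 2))
    )
    u_f = sy.lambdify((x, y), u_sym, "numpy")
    v_f = sy.lambdify((x, y), v_sym, "numpy")
    c_f = sy.lambdify((x, y, t), c_sym, "numpy")
    s_f = sy.lambdify((x, y, t), sy.simplify(s_sym), "numpy")

    n = base * 2**level + 1
    geom = GeometryConfig(L=L, H=H, Ls=L, Nx=n, Ny=n, Ns=n)

    def u_fn(xx, yy):
        return np.broadcast_to(np.asarray(u_f(xx, yy), dtype=float), np.shape(xx)).copy()

    def v_fn(xx, yy):
        return np.broadcast_to(np.asarray(v_f(xx, yy), dtype=float), np.shape(xx)).copy()

    def c_fn(xx, yy, tt=0.0):
        return np.broadcast_to(np.asarray(c_f(xx, yy, tt), dtype=float), np.shape(xx)).copy()

    def s_fn(xx, yy, tt=0.0):
        return np.broadcast_to(np.asarray(s_f(xx, yy, tt), dtype=float), np.shape(xx)).copy()

    return MMSCase(
        geometry=geom, D=D, u=u_fn, v=v_fn, c_star=c_fn, source=s_fn, level=level, regime=regime
    )


def validation_fixture():
    """The packaged validation-case configuration.

    Returns the :class:`~biosensim.driver_io.SimulationConfig` read from
    the configuration file shipped with the package.  Printed values:
    Q = 7e-11 m^3/s, c0 = 2.5e-6 mol/m^3, L x H = 1e-2 x 1e-3 m,
    bmax = 1.668e-8 mol/m^2, kon = 75, koff = 1e-2, run time 1e5 s.
    The diffusion coefficient, chamber depth and sensor placement are
    not printed anywhere and are documented assumptions: D = 1e-10
    m^2/s (short DNA strands), depth 1 cm, sensor covering the whole
    bottom wall.
    """
    from importlib.resources import files

    from .driver_io import read_config_text

    text = files("biosensim.data").joinpath("validation_case.cfg").read_text()
    return read_config_text(text)
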