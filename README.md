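# biosensim

Control-volume finite-element (CVFEM) simulation of bio-species
transport and capture in microfluidic biosensor channels.

A run solves, in sequence:

1. **Steady laminar flow** — the 2D incompressible Navier–Stokes
   equations, discretized on the dual control volumes of a structured
   quad mesh and solved implicitly for the coupled nodal `(u, v, p)`.
   The continuity equation uses pressure-aware ("hat") integration-point
   velocities (an algebraic momentum-interpolation closure for the
   collocated arrangement); momentum convection uses the physical
   influence scheme (PIS), which evaluates convected quantities at the
   upstream intersection of the local streamline with the element
   boundary.
2. **Analyte transport** — backward-Euler convection–diffusion of the
   dilute analyte on the frozen flow field, advective face values from
   the same streamline upwind operator, diffusive fluxes from Fick's law
   with bilinear shape-function gradients.
3. **Surface kinetics** — reversible first-order (Langmuir-type) binding
   `db/dt = kon*c*(bmax - b) - koff*b` per sensor node, advanced by its
   exact exponential update and coupled to the bulk through a
   conservative Neumann flux on the sensor strip.

The observable is the sensorgram: the length-weighted mean surface
coverage normalized by the binding-site density, written as CSV, with
optional VTK field snapshots.

## Layout

| module | contents |
| --- | --- |
| `biosensim.mesh` | structured channel mesh, dual control volumes, boundary tagging, sensor placement |
| `biosensim.cvfem_core` | shape functions, integration points, streamline upwind operator, assembly helpers |
| `biosensim.flow_solver` | coupled implicit Navier–Stokes solver with the momentum-interpolation closure |
| `biosensim.transport` | backward-Euler convection–diffusion operator with the sensor flux coupling |
| `biosensim.kinetics` | surface binding ODE, coupling fluxes, coverage observable |
| `biosensim.driver_io` | configuration files, binding-cycle orchestration, outputs, CLI |
| `biosensim.oracles` | closed-form references and manufactured solutions used for verification |

## CLI

```bash
# run a binding cycle from a config file
biosensim run --config case.cfg --out outdir [--washout-time T] [--snapshot-every N]

# run the packaged validation configuration (1e5 s window)
biosensim validate-case [--out outdir] [--t-end T]

# manufactured-solution convergence suite
biosensim mms --level 3
```

Exit codes: 0 success, 2 configuration error, 3 solver failure.

Configuration files are flat `key = value` text using the physical
symbols as keys, all in SI units — see
`src/biosensim/data/validation_case.cfg` for a complete example:

```
H = 1e-3        # channel height (m)
L = 1e-2        # channel length (m)
Ls = 1e-2       # sensor length (m)
Q = 7e-11       # flow rate (m^3/s)
c0 = 2.5e-6     # inlet concentration (mol/m^3)
D = 1e-10       # diffusion coefficient (m^2/s)
bmax = 1.668e-8 # binding-site density (mol/m^2)
kon = 75.0      # adsorption rate (m^3/mol/s)
koff = 1e-2     # dissociation rate (1/s)
Nx = 101
Ny = 21
Ns = 101
dt = 10.0
t_end = 1e5
```

Outputs: `sensorgram.csv` (`t_seconds, b_bar, b_min, b_max_node,
mass_balance_residual`), `run.log` (tolerances and every documented
interpretation), and `snap_<step>.vtk` legacy-ASCII structured-grid
snapshots of `u, v, p, c`.

## Documented interpretations

These choices are ambiguous in the source material, logged at run start
in `run.log`:

- the coupling coefficient is read as
  `beta = rho*|V_elem|/A_elem + mu/L_ref^2` with `L_ref = H` — the only
  grouping whose two velocity weights sum to one;
- the surface rate equation uses the **local wall concentration** by
  default (`concentration_source = local`); the literal printed rate law
  uses the inlet concentration and is available as
  `concentration_source = inlet`, but only the local form is consistent
  with the sensor's Neumann coupling;
- `bmax` is a surface site density in mol/m²;
- the mean inlet velocity is `Q/(H*W)` with the out-of-plane depth `W`
  (`depth_W`) defaulting to 1 m and set to 1 cm in the packaged
  validation configuration;
- the validation case's diffusion coefficient and sensor placement are
  not printed anywhere: the packaged config assumes `D = 1e-10 m²/s`
  (short DNA strands) and a sensor covering the whole bottom wall.
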