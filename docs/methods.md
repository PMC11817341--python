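# Methods

## Model

`shrimpdry` simulates convective hot-air drying of a small food body
(peeled shrimp) as coupled transient mass and heat transfer in a
non-deformable, isotropic medium:

- moisture: `∂c_w/∂t = ∇·(D ∇c_w)` with a constant effective
  diffusivity D (m²/s) and water concentration c_w (kg/m³);
- heat: `ρ_sh c_p,sh ∂T/∂t = ∇·(k_sh ∇T)` with composition- and
  temperature-dependent tissue properties.

The two fields couple only at the surface, where water evaporates into
the air stream:

```
-D ∂c_w/∂n = J = h_m M_w [ a_w(X_s) Psat(T_s)/(R T_s) - (RH/100) Psat(T_air)/(R T_air) ]
-k  ∂T/∂n  = h_T (T_s - T_air) + ΔH_evap(T_s) · J
```

`a_w` is the water activity of the surface given by the sorption
isotherm evaluated at the *local* surface moisture `X_s = c_w,s/c_s`;
`c_s` is the solids concentration, constant in time because the medium
is assumed not to shrink. Radiation and tray conduction are neglected
(the tray's conductive resistance, ~2.2·10⁻⁶ m²K/W, is four orders of
magnitude below the convective resistance ~0.018 m²K/W). Evaporation
occurs only at the surface; there is no internal vapor phase.

Drying then shows the classic three stages: a short warm-up, a
constant-rate period in which the wet surface sits near the wet-bulb-like
temperature where `h_T (T_air − T*) = ΔH_evap · J(T*)` (computed
independently by `pseudo_steady_surface_temperature`), and a falling-rate
period limited by internal diffusion, during which the body heats toward
the air temperature.

## Property sub-models

Tissue is a two-component (water/protein) mixture. Component densities,
heat capacities and conductivities are quadratic polynomials in T (°C);
mixture density uses mass-fraction-weighted reciprocal (harmonic) mixing,
heat capacity linear mixing, and conductivity the mean of the
volume-fraction parallel and series bounds.

Saturation vapor pressure uses an Antoine correlation
`Psat = 10³·exp(16.3872 − 3885.70/(T/K − 42.98))` Pa. The correlation as
printed in the source literature carries a "+42.83" denominator which
reproduces no physical vapor pressure in either °C or K; the form above
(a sign typo away) matches steam tables within 0.6 % at 25 °C and 0.1 %
at 100 °C, verified in the test suite. The latent heat of vaporization,
for which the source gives no correlation, is the linear steam-table fit
`ΔH(T/°C) = 2.501·10⁶ − 2.36·10³ T` J/kg, evaluated at the local surface
temperature (within 1 % of tabulated values over 0–100 °C). Because the
drying literature rarely states its ΔH convention, plateau-temperature
comparisons carry a ±2 °C tolerance.

### Sorption isotherm

The fitted sigmoid correlation `a_w(X_db)` is typeset ambiguously in the
source; two readings are implemented:

- **`power-outside` (default):** `a_w = exp(−A·exp(−B·X)·X^C)`. This is
  the literal reading and, decisively, the one that reproduces the
  published curve-level results at both drying temperatures (final
  moisture 0.70 vs 0.69 kg/kg at 60 °C, 0.38 vs 0.40 at 70 °C; time to
  1 kg/kg 131 vs 133 min). Its flaw: below the stationary point
  `X* = C/B` the raw expression *rises* again toward a_w = 1 as the
  material dries out, which is unphysical. We therefore evaluate it at
  `max(X, X*)` — a monotone floor that leaves the fitted range
  (a_w between roughly 0.1 and 0.85) untouched. With the 70 °C parameter
  set the floor value is a_w(X*) ≈ 0.48; with the 60 °C set ≈ 0.03.
- **`exp-inside` (alternative):** `a_w = exp(−A·exp(−B·X^C))`, a clean
  monotone sigmoid from `exp(−A)` to 1. Better behaved analytically and
  better conditioned for fitting, but it misses the published drying
  curves by ~±14 % at 180 min, so it serves as the verification and
  identifiability variant, not the default.

Parameters: A₆₀ = 6.03, B₆₀ = 11.00, C₆₀ = 0.0980;
A₇₀ = 11.09, B₇₀ = 11.54, C₇₀ = 0.7195.

### Dry-surface flux limiter

With the floored default isotherm the evaporative flux would persist at
a completely dry surface (the floor exceeds typical air-side activity),
driving surface concentrations negative. The boundary flux is therefore
multiplied by `clamp(X_s / X_cut, 0, 1)` with `X_cut = 0.01` kg/kg
(`SimulationConfig.dry_surface_cutoff`): evaporation cannot remove water
that is not there, while condensation is never limited. The solver also
retains a clip-to-zero safety net with a warning counter; with the
limiter active it normally never fires. Setting `dry_surface_cutoff = 0`
disables the limiter (used for the Dirichlet-limit slab verification).

## Geometry

The irregular domain is a parametric swept-ellipse surrogate: elliptical
cross sections carried orthogonally along a planar quadratic-Bézier
spine (arc length 51.6 mm), with a shape-preserving monotone taper
toward the tail and the thickest section matching the measured 11.02 mm
first-segment diameter. Because section centroids lie on the spine, the
solid volume equals the arc-length integral of the section area exactly,
and the semi-axes are calibrated jointly so the volume equals the
measured 3.92 cm³. The published CAD shape is not reproducible exactly,
so field-level comparisons are qualitative while curve-level quantities
carry ±10 % tolerances. The thermocouple probe sits on the spine 25 % of
the arc length from the head (between the first and second abdominal
segments); the cylinder probe is on the axis at mid-length. The
comparison cylinder is 11 mm × 42 mm (equal volume within 2 %).

## Discretization and numerics

- **Mesh:** deterministic mapped meshing. A spiderweb triangulation of
  the unit disk (center node plus rings of 6k nodes, Delaunay) is scaled
  by the local semi-axes and extruded into triangular prisms along the
  spine; each prism splits into three tetrahedra by the diagonal through
  each quad face's smallest global vertex index — a face-local rule, so
  the mesh is conforming. Axial layer spacing is variable: thin tail
  sections admit longer axial steps within the edge budget
  `sqrt(axial² + cross²) ≤ h`. The resolution is refined until **no
  element edge exceeds** the requested maximum size `h`. Enforcing a
  strict edge bound on an extruded topology costs roughly 2× the element
  count of a quality-driven unstructured mesher at the same nominal
  size (≈150k vs ≈67k tetrahedra at 1 mm); the mesh-independence study
  (below) shows the solution is converged at these resolutions.
  Slab verification meshes use a structured hex grid with a
  checkerboard five-tet split and flux restricted to the two
  thickness-normal faces.
- **Space:** lumped-mass P1 tetrahedra; boundary integrals by lumped
  (one-point-per-vertex) facet quadrature. Mass lumping preserves the
  discrete maximum principle at the steep surface moisture front.
- **Time:** fixed-step BDF2 (BDF1 startup), step capped at 10 s by
  default. On a nonlinear failure the step is retried as two implicit-
  Euler half steps and the multistep history restarts.
- **Nonlinearity:** a Picard loop per step re-evaluates the
  temperature/composition-dependent properties and the boundary terms;
  the evaporative flux is linearized in its own surface unknown
  (Newton-type Robin term, non-negative by monotonicity of the isotherm
  and of Psat/T, hence unconditionally stabilizing). Convergence at
  max relative change < 10⁻⁶, cap 25 iterations, with 0.5 damping from
  the fifth iteration to suppress limiter chattering.
- **Linear algebra:** both systems are symmetric positive definite and
  Jacobi-scaled before solution (mass, stiffness and Robin entries span
  several decades). They are solved by conjugate gradients warm-started
  from the current iterate and preconditioned with a cached
  factorization refreshed only when CG stalls: incomplete LU for the
  moisture system (whose matrix drifts only through the boundary
  diagonal), exact LU for the stiffness-dominated heat system, with an
  automatic permanent fallback to exact factorizations if an incomplete
  one proves inadequate.
- **Conservation:** the scheme is discretely conservative; the solver
  reports a mass-balance audit (time-integrated applied boundary flux vs
  water inventory change), typically ~10⁻⁴ relative, asserted ≤ 0.5 %.

## Parameter estimation

- `fit_heat_transfer_coefficient`: nonlinear least squares of the
  lumped-capacitance heating curve `T(t) = T_air + (T0 − T_air)·
  exp(−h_T A/(m c_p) t)` of an aluminum surrogate body (m = 11.1214 g,
  A = 17.893 cm², V = 4.15 cm³, c_p = 900 J/kgK, k = 229 W/mK). Only the
  group `h_T A/(m c_p)` is identified; h_T is reported with the known
  A, m, c_p. Validity: Bi = h_T (V/A)/k ≈ 6·10⁻⁴ ≪ 0.1.
- `grid_search_D_hm`: exhaustive search over the screening grid
  h_m ∈ {0.005…0.01} m/s step 0.001 and D ∈ {5…10}·10⁻¹⁰ m²/s step
  0.5·10⁻¹⁰ (66 pairs), one full simulation per candidate. The source's
  wording implies a temperature-only RMSE objective while estimating two
  parameters; the default objective sums the min-max-normalized RMSEs of
  moisture **and** temperature (both observables are needed to identify
  two parameters), with `mode="temperature"` matching the stated wording.
  Ties break toward smaller D, then smaller h_m. Failed candidates score
  +∞ rather than aborting the search.
- `fit_isotherm`: bounded least squares with a 3-start multistart.
- `goodness_of_fit`: R² (may be negative) and RMSE exactly as defined;
  zero observation variance flags R² as undefined.

## Synthetic experiments

`synthetic` emulates the measurement structure so the estimation chain
is testable end to end: moisture sampled at 15/30/45/60/90/120/150/180
min, probe temperature every 30 s, three replicates, additive Gaussian
noise with σ_X = 0.1 kg/kg and σ_T = 0.5 K by default (the order of the
published validation RMSEs, 0.16–0.22 kg/kg and 0.5–1.1 °C), air
humidity as a smooth bounded random walk inside the logged band
(16–23 % at 60 °C, 11–19 % at 70 °C). One seeded generator per
experiment; replicate streams are spawned deterministically, so fixed
seeds are bit-reproducible. What the generator does *not* emulate:
thermocouple lag, tray thermal mass, shrinkage, sample-to-sample
geometry variation, or structured (non-Gaussian) measurement error —
passing recovery tests therefore demonstrate estimator correctness
under the stated noise model, not robustness to every real-world
artifact.

## Problem sizes used by the shipped checks

Chosen as the package's own verification scale: the acceptance script
runs the two baselines on the shrimp mesh at 1.2 mm (≈17k nodes); the
test suite uses 1.5 mm (≈9k nodes) for the baseline comparisons, a
4 mm cylinder for estimation-recovery tests (truth and candidates share
one discretization, so grid recovery is exact by construction), the
1.0 mm vs 0.8 mm cylinder pair with 30 s steps for mesh independence
(identical time discretization on both meshes isolates the spatial
error), and a 96-layer slab with 0.5 s steps for the series-solution
check. At 1.5 mm vs 2 mm the 180-min average moisture changes by
< 0.5 %, consistent with the mesh-independence study.

## Known limitations

- No shrinkage or deformation: late-stage geometry (hence area-to-volume
  ratio) is overestimated, one reason curve-level tolerances are ±10 %.
- Constant-in-time transfer coefficients and (by default) constant air
  state; logged humidity fluctuations can be supplied as series inputs.
- The isotherm's low-moisture branch is an extrapolation stabilized by
  the monotone floor and the flux limiter; surface moisture below
  ~0.01 kg/kg is not quantitatively meaningful.
- Internal evaporation, case hardening and quality attributes are out of
  scope.
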