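# Methods

## The physical model

`implantflow` simulates the first three seconds of blood flow in the
gap between an alveolar-bone wall and a threaded implant surface, and
measures how the implant's wettability controls the delivery of
fibrinogen — the clotting protein whose early adsorption is believed to
seed osseointegration — into the thread region.

Whole blood is a two-phase continuum: blood plasma (primary phase,
carrying dissolved fibrinogen) and red blood cells (secondary phase).
Both are Newtonian here; RBCs are not resolved as particles (their
~7 um diameter is far below the 1.5 mm channel width).  The phases are
tracked with a volume-of-fluid (VOF) field `alpha_p`, the plasma volume
fraction per cell.  Surface tension between the phases
(sigma = 0.021 N/m) acts through the continuum-surface-force (CSF)
model, `f = sigma * kappa * grad(alpha_p)`, and the implant's
wettability enters as the contact angle theta imposed where the
interface meets the implant surface: the interface normal at
wall-adjacent cells is rotated to `n_wall cos(theta) + t_wall
sin(theta)` before the curvature is evaluated (theta measured through
the plasma).  theta is the study's control variable: 5 deg
(superhydrophilic, e.g. UV-photofunctionalised titanium) to 100 deg
(hydrorepellent).

Fibrinogen is a dissolved species in the plasma phase with mass
fraction `Y0` (plasma itself is `Y1 = 1 - Y0`).  It obeys an
advection-diffusion equation in conservative form; the conserved cell
quantity is the partial density `f = alpha_p * rho_m(Y0) * Y0`, which
confines the species to the plasma phase by construction.  The
plasma-fibrinogen mixture density follows the volume-weighted
(harmonic-in-mass-fraction) law

    rho_m = 1 / (Y0/1400 + (1 - Y0)/1025)   [kg/m^3],

and the plasma viscosity is a piecewise fit in the fibrinogen
concentration C (g/100 mL):

    mu_m [mPa.s] = 1.16 C + 0.53        (0 <= C < 0.40)
                   0.37 C + 0.85        (0.40 <= C < 1.00)
                   0.19 C^2 + 1.03      (C >= 1.00)

The fit has a 0.4% upward step at C = 0.40 (0.994 vs 0.998 mPa.s); it
is kept as published rather than smoothed.  Fick diffusion uses the
fibrinogen-in-water coefficient D = 0.23e-10 m^2/s (no measurement in
plasma exists; over 3 s this spreads a front by ~12 um, far less than
one cell, so transport is advection-dominated — a property the test
suite asserts).  Cell properties blend the two phases arithmetically by
`alpha_p` (the standard VOF mixture rule): RBC phase density
1125 kg/m^3 and viscosity 5.0 mPa.s.

## Geometry, zones, and reported masses

The domain is a 2D vertical channel, 10.0 mm tall and 1.5 mm wide, with
the implant on the right wall carrying ten threads of 1.0 mm height and
0.5 mm depth.  The thread cross-section is not fully constrained by the
source geometry (only its bounding box); we use an isosceles triangular
profile, which makes the interfacial fluid area exactly 2.5 mm^2 and
reproduces the reported plasma-infiltration plateau (~2400 mg at full
wetting under the per-metre-depth convention).  Rectangular and
trapezoidal profiles are selectable for sensitivity runs.

A vertical line through the thread peaks (x = 1.0 mm) splits the fluid
into the *interfacial zone* (threads side; the osseointegration-relevant
region) and the *outer zone*.  *Infiltration* is the mass of fibrinogen
or plasma in the interfacial zone at a sample time; the *infiltration
rate* divides it by the total mass of that component in the fluid zone
(percent).  All 2D masses are reported per 1 m of out-of-plane depth,
which reproduces the mg scale of the reference tables.

Boundary placement (the source figure is not machine-readable): blood
inlet = bottom edge, alveolar bone = left edge — both velocity inlets at
0.01 m/s — and blood outlet = top edge (zero gauge pressure, zero normal
gradients, inflow clamped to the inlet composition).  Inlet composition:
45% hematocrit (alpha_p = 0.55) and fibrinogen mass fraction
0.0029 = (300 mg/dL = 3 kg/m^3) / (1024 kg/m^3 serum), rounded to two
significant figures.  With the inlet-blend density (1070 kg/m^3) and
viscosity (2.73 mPa.s) and the 1.5 mm width, the inlet Reynolds number
is 5.9 — printed as 6 — versus a ~2800 turbulence threshold: the flow is
laminar and no turbulence model is used.

**Dispersed-inlet representation.**  VOF represents *resolved* phases: a
cell that carries alpha_p = 0.55 forever is a premixed state the model
cannot act on — it has no interface, so neither surface tension nor the
wall contact angle can influence it, and the contact angle would become
a no-op (we verified this: a premixed-inlet run shows no angle
dependence at all).  Whole blood at 45% hematocrit therefore enters as a
resolved dispersion: a deterministic travelling square-wave train of
plasma and RBC slugs (spatial period 0.5 mm along each inlet, temporal
period 0.05 s, duty cycle = plasma fraction 0.55), so the time-averaged
inflow composition is exactly the prescribed 45/55 while sharp
interfaces exist throughout the flow.  The slug scale (~1/3 of the
channel width, ~20 slugs/s) is a modeling choice of this package — the
sub-grid arrangement of a suspension is not specified by a volume
fraction alone; results at the coarse preset are reported under this
representation.  Setting ``slug_period = 0`` recovers the premixed
inlet.

**Initial condition** (not stated by the source): the peri-implant space
is full of resting, fibrinogen-free whole blood — the same dispersed
bands at the mean 55% plasma fraction (a freshly placed implant sits in
a socket already filled with blood).  An all-plasma start was
implemented first and rejected: it coats the implant with a film whose
interface never touches the wall, so a contact line never forms and the
hydrorepellent case cannot dewet, contradicting the reference's
hydrophobic collapse already within the first second.  With the
dispersed start, interfaces exist at the thread walls from t = 0 and
wettability selects the groove occupancy immediately: at 5 deg the
threads re-wet toward the ~2500 mg full-wetting plasma capacity, at
100 deg the RBC phase displaces plasma from the grooves.  Fibrinogen
starts at zero everywhere and enters with the inlet plasma.

## Numerical scheme

Uniform structured quadrilateral (MAC-staggered) grid; cells whose
centres fall inside a thread polygon are solid.  The production
("full") preset uses 0.025 mm cells, the scaled-down ("coarse") preset
0.05 mm; the source's unstructured 14,610-cell mesh is deliberately not
reproduced — resolution is a parameter and the acceptance statistics are
computed on the coarse preset.

Each outer step (dt = 1e-4 s, horizon 3 s) is advanced in sub-steps
limited by the advective CFL (safety 0.4), the explicit viscous and
diffusive limits (0.25 dx^2/nu), and the Brackbill capillary limit
`sqrt((rho1+rho2) dx^3 / (4 pi sigma))`.  The capillary safety factor
is 1.8 — above the nominal sharp-interface limit — which is empirically
stable here because the curvature driving the CSF force is evaluated
from the smoothed alpha field and clamped to 1/dx (both relax the
capillary stiffness), and a mid-step CFL guard redoes any step whose
velocities outgrow the estimate.  On the coarse preset this gives 2
sub-steps per outer step.  A sub-step performs:

1. **CSF force** from the twice-smoothed (3x3 binomial) alpha field;
   solid cells are first filled from fluid neighbours; curvature
   `kappa = -div(n_hat)` is evaluated only where the sharp |grad alpha|
   exceeds 1e-3 of its maximum (suppressing spurious currents), clamped
   to the grid-resolvable `1/dx` (sub-cell structures would otherwise
   inject unphysical capillary kicks), and the wall-adhesion rotation is
   applied at implant-adjacent cells.
2. **Momentum predictor**: explicit, conservative advection with
   van-Leer-limited second-order upwind reconstruction, plus the CSF
   force.  The viscous term uses the conservative flux form
   `div(mu grad u)` with face/corner-interpolated viscosity and mirror
   ghosts at no-slip boundaries: with sharp interfaces the viscosity
   varies 10x cell-to-cell and only the symmetric (dissipative) form is
   robust there.  No gravity (not part of the model).
3. **Pressure projection**: variable-coefficient Poisson problem
   `div(grad(p)/rho) = div(u*)/dt` with Neumann faces at walls/inlets
   and a ghost-Dirichlet outlet, solved by defect correction to a 1e-6
   relative residual, warm-started by linear extrapolation of the two
   previous solutions.  The preconditioner is a single banded Cholesky
   factorisation (bandwidth = nx in column-major ordering) of the
   mean-coefficient operator, stored in single precision: the
   plasma/RBC density contrast is only ~10%, so the constant-coefficient
   factor contracts the residual by ~20x per iteration and never needs
   refreshing as the interface moves (an exact-coefficient refactor is
   kept as a stall fallback for exotic property sets).  Closed-box
   (all-Neumann) problems pin one cell's gauge and project the
   right-hand side's mean.
4. **VOF transport**: conservative flux update of alpha_p with
   superbee-limited (compressive) reconstruction, followed by an
   interface-compression pass (counter-gradient transfer
   `c_alpha |u_f| n_hat alpha(1-alpha)`, c_alpha = 1, the interFoam
   convention) that counteracts numerical diffusion of the slug
   interfaces.  Compression is gated on the twice-smoothed gradient
   (> 0.03 per cell) so only coherent interfaces are sharpened, and is
   implemented as bounded sequential transfers — exactly conservative,
   no clipping needed, resting fluid untouched.
5. **Species transport**: the fibrinogen partial density rides the
   *actual* plasma face fluxes (advective and compressive alike) with
   superbee-reconstructed `rho_m Y0` face values upwinded by the flux
   sign, plus alpha-weighted Fickian diffusion; Y0 is recovered by
   inverting the harmonic mixing law in closed form.  Riding the alpha
   fluxes makes the two fields exactly consistent: a cell that loses
   plasma loses its dissolved fibrinogen at the same rate and a uniform
   Y0 is transported unchanged, which keeps Y0 bounded by its sources
   (decoupled schemes let Y0 = f/alpha blow up in nearly-emptied cells,
   where the unbounded quadratic branch of the viscosity law then
   destabilises the momentum equation).  Cells with alpha_p < 1e-6
   carry no dissolved fibrinogen.

If the velocity grows mid-step beyond the estimate used to pick the
sub-step count, the step is redone with twice the sub-divisions (up to
four doublings) before a CFL error is raised.

The source monitored convergence as "change in fibrinogen mass per time
step below 1e-9 kg", which we read as the inner criterion of its
iterative coupled solver.  Our explicit sub-stepped scheme has no
lagged coupling to iterate, so the default is a single sweep per step;
an optional Picard loop (`max_inner_iterations > 1`) re-sweeps the step
with properties evaluated midway to the previous iterate and stops on
the same 1e-9 kg fibrinogen-mass monitor (it converges in <= 2 sweeps
in the tests).  The per-step mass change is also what the progress log
reports.

All inner loops are numba-compiled; the code draws no random numbers
anywhere, so identical configurations give bit-identical outputs.

## Verification benchmarks (the synthetic data of this study)

Because the study consumes no external data, the "data generator" is a
set of closed-form-checkable cases whose references are computed
analytically, never from the solver:

* **Plane Poiseuille flow** (momentum + projection): thread-free
  channel, fixed flow rate; max/mean = 1.5, pressure gradient
  `12 mu U / W^2`, and second-order L2 convergence of the profile.
* **Diffusing Gaussian spot** (species): zero flow, closed box;
  variance grows by exactly 2 D t; total fibrinogen conserved to 1e-12.
* **Static/sessile droplet** (CSF + wall adhesion): Young-Laplace jump
  sigma/R within 10%; apparent contact angle (measured by fitting the
  alpha = 0.5 contour over the 3 near-wall columns — the measurement
  method shifts the value by a few degrees, so it is fixed and used
  consistently) within 5 deg at theta = 90, and monotone in the imposed
  angle across {5, 30, 50, 70, 100} deg.

Benchmark fluids use raised viscosities (0.05 Pa.s) so the analytic
steady states are reached in sub-second runs; this verifies the
numerics, not blood.  What these cases do *not* establish: fidelity of
real RBC rheology (shear thinning is out of scope), 3D/helical thread
effects, coagulation-driven property changes, or protein-surface
electrochemistry — the simulator isolates the purely hydrodynamic
wetting mechanism.

## Problem sizes and tolerances

The acceptance statistics (3 s means, ratios, rates, correlations) are
computed on the coarse preset: 30 x 200 cells (0.05 mm), dt = 1e-4 s,
30,000 steps sampled every step.  This is the package's standard
desk-scale configuration; the full preset (0.025 mm) doubles resolution
for production use.  Stage averages are trapezoidal time averages over
[0,1), [1,2), [2,3] s; reported ratios are rounded to 2 decimals and
CSV output uses 6 significant digits, making repeated runs
byte-identical.  Correlations use every 1e-4 s sample (n = 30,001),
where any |R| above ~0.02 is significant at p < 0.001 — matching the
uniformly significant reference report.

## Known limitations

* **Fibrinogen saturates quickly under the stated inflow.**  The two
  velocity inlets at 0.01 m/s carry ~190 mg/s of dissolved fibrinogen
  into a fluid zone whose saturated content (every plasma cell at the
  inlet mass fraction) is only ~23 mg, so Y0 reaches its inlet value
  throughout the domain within about a second of simulated time.  The
  interfacial fibrinogen mass therefore tracks the plasma occupancy
  ceiling (~6-7 mg at wetting angles) rather than rising slowly over
  the whole 3 s, and once saturated the fibrinogen and plasma
  infiltration rates co-move, which raises their correlation at the
  hydrophobic angles.  Slower, still-rising fibrinogen dynamics would
  require a much smaller effective fibrinogen delivery than these
  boundary conditions produce.
* 2D: recirculation in V-grooves is more confining than in a 3D helical
  thread; absolute infiltration masses inherit the per-depth convention.
* The coarse preset resolves each thread with ~10 x 20 cells; interface
  positions within a thread are accurate to a cell or two — the
  hydrorepellent case empties the grooves to a mean plasma fraction of
  ~0.44 rather than fully, so hydrophilic/hydrorepellent infiltration
  ratios come out nearer 2 than 3.  This is why the built-in comparisons
  are ratio- and average-based.
* The momentum viscous term omits the transposed-gradient part of the
  stress divergence; at viscosity ratios of ~10 and Re ~ 6 the effect is
  below the discretisation error.
* Fixed contact angle (no hysteresis or dynamic-angle model); the
  apparent angle below ~30 deg is limited by the film thickness
  reaching the cell size.
* No coagulation kinetics or time-varying viscosity: the 3 s window is
  before clotting changes the rheology.
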