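# Methods

## Model

The package solves steady-state current conservation,
`-∇·(σ∇φ) = 0`, for the electric potential φ in a tissue domain, with the
applied pulse amplitude entering as Dirichlet data on the electrode–tissue
contact surfaces (anode at U, cathode at 0; the electrode bodies are not
meshed) and a homogeneous Neumann condition `J·n = 0` on every other
boundary.  Capacitive transients and the intra-pulse time course are
neglected: the solution represents the quasi-static state at the end of a
pulse, which is when currents are compared with measurements.

Electroporation enters through the constitutive law: the bulk conductivity
of each tissue is a non-decreasing function of the local field magnitude
`E = |∇φ|`.  Five families are implemented (constant; linear; exponential;
smoothed Heaviside; sigmoid — see `epfem.conductivity`).  The step families
rise from the baseline σ₀ below `E_rev` to `factor·σ₀` above `E_irrev`.
Threshold units are V/cm everywhere at the user surface; SI internally, with
the single conversion constant in `epfem.units`.

Two realizations of the step were open choices:

* the smoothed Heaviside uses the quintic smoothstep
  `S(t) = 6t⁵ − 15t⁴ + 10t³` on `t = (E − E_rev)/(E_irrev − E_rev)`, which
  has vanishing first and second derivatives at both ends (C² as required
  for a Newton solver with a consistent tangent);
* the sigmoid is logistic with midpoint `(E_rev + E_irrev)/2` and width
  `(E_irrev − E_rev)/12`, placing the curve within ~0.25 % of its
  asymptotes at the thresholds; both are overridable per model.

Anisotropic tissue (muscle) carries one σ(E) model per principal axis in an
orthonormal fiber frame; each axis model is evaluated on the field
*magnitude* (the degree of permeabilization is set by |E|, not by a field
component), and the lab-frame tensor is `Fᵀ diag(σᵢ(|E|)) F`.  Whether the
per-axis laws should share a single multiplier was open; each axis carries
its own full model with a shared increase factor of 2.5.

## Discretization and linear solves

Galerkin P1 (linear) tetrahedra: the element field is constant, which is
the natural resolution for a per-element σ(E).  Element matrices
`∫ ∇N·σ·∇Nᵀ dV` are assembled vectorized; Dirichlet rows are eliminated
symmetrically (reduced SPD system) and solved with SuperLU.  Electrode
currents are the sums of the unconstrained residual over the Dirichlet
nodes of a contact ("reaction" flux) — variationally consistent and far
more mesh-robust than direct surface quadrature of `J·n`, which is retained
only as a cross-check oracle.  On uniform-field plate blocks the two agree
to 1e-9; at needle-bore walls, where the field is near-singular at the
insertion rim, the quadrature converges only slowly toward the reaction
value under refinement (ratio 0.34 → 0.59 over three refinements), which is
the expected behaviour of one-sided element-constant fluxes, not a defect
of the reaction current.  Because Dirichlet P1 solutions over-estimate the
Dirichlet energy (= U·I), computed currents decrease monotonically toward
the mesh limit under refinement.

A 0.5 %-change mesh-convergence protocol (`mesh_convergence_study`) refines
until a chosen scalar output stabilizes and reports the full sequence;
non-convergence is reported, not raised.

## Nonlinear solvers

**NPA (parametric continuation + damped Newton).**  The applied voltage is
raised from 0 in adaptive steps (initial step U/20, ×1.5 after fast
convergence, ×0.5 on failure), each converged potential seeding the next
step.  At fixed U the nonlinear residual `R(φ) = K(σ(φ))φ` is driven to a
relative tolerance of 1e-8 (free-node residual norm over the reaction-force
norm) by damped Newton with the consistent tangent
`K + Σₑ (Vₑ/|E|) (G(σ′E))(GE)ᵀ`, where σ′ is the per-axis slope tensor;
the step is halved while the residual grows (λ_min = 2⁻¹⁰).  A lagged-
conductivity Picard scheme is available, but on steep step laws (factor
10–100) its contraction is so poor (thousands of iterations where Newton
needs ten) that Newton is the default; both land on the same fixed point
and are tested for agreement on a mild law.

**SA (sequential analysis).**  The intra-pulse conductivity rise is
modelled as `k` static solves, step j using per-element
`σ = f(|E|_{j−1})` with σ(E) quantized onto `levels` equal conductivity
steps (the classic coarse discretization uses 5 steps; 64 makes a fine
one).  The raw lagged update is a fixed-point iteration that is period-2
unstable on steep step laws in near-uniform regions (a whole layer flips
between unpermeabilized and saturated); the implementation therefore halves
the update weight whenever successive global updates reverse direction,
which restores convergence to the same self-consistent state without
changing it.  An optional ratchet (σ never decreases across the sequence)
models within-pulse irreversibility but systematically overshoots the
fixed point when the converged state is mid-transition, so it is off by
default.  With k = 15 and 64 levels SA agrees with the 1-D slab oracle
within ~1.2 %; with k = 5 and 5 levels within a few percent except
mid-transition, mirroring the coarseness of the original scheme.

**1-D oracle.**  For slabs in series the problem reduces to scalars: the
current density J is common, per-layer fields solve `σ(E)E = J` (strictly
monotone, bisection/Brent to 1e-15) and J solves `Σ Eᵢtᵢ = U`.  This
`slab_current` oracle is exact to ~1e-10·U and validates both solvers.

## Inverse analysis

Parameters θ of the linear (σ₀, k_σ) or exponential (σ₀, c₁, c₂) law are
identified by minimizing `f(θ) = Σⱼ (I_FEM(Uⱼ;θ) − Iⱼ)²` with
trust-region-reflective least squares under positivity bounds and
deterministic multistart (default 5 starts; the initial σ₀ is the
lowest-voltage secant I/U divided by the geometry cell factor computed with
σ = 1).  Sensitivities `dI/dθ` use direct differentiation of the discrete
residual: at each converged state one extra linear solve with the assembled
consistent tangent produces adjoint weights, after which each parameter
costs a matrix-free product; central finite differences are kept as a
validation oracle (agreement ~1e-4 relative or better in the tests).
Replicate measurements at one voltage are separate residuals but share one
forward solve.  `identifiability_report` flags parameters whose scaled
sensitivity column is < 1e-4 of the data norm (e.g. a slope fitted to ~0 on
constant-conductivity data) or whose sensitivity columns correlate beyond
0.99 (e.g. c₁/c₂ of an exponential fitted to linear-truth data).

## Study geometries

All meshes are generated deterministically in-package.

* **Plate block** (`plate_single`): box with the inter-electrode axis x;
  structured grid, 6-tet Kuhn subdivision; full-face or windowed contacts;
  optional layered stacks along x for the slab validations.  The liver
  block dimensions are not fixed by published data, so they are free
  parameters (defaults 4 × 20 × 10 mm).
* **Needle block** (`needle_single`): Delaunay triangulation of the
  cross-section with nodes placed exactly on the two bore circles, extruded
  into prisms and split into tetrahedra by the index-ordering rule of
  Dompierre et al. (shared faces conform); bores are open over the
  insertion depth (default 7 mm, diameter 1.1 mm, spacing 8 mm) and the
  lateral bore walls are the contacts (the flat tip disc is insulated — the
  lateral wall dominates the contact area; the polygonal wall area matches
  π·D·depth within 1 %).
* **Subcutaneous tumor fold** (`tumor_composite`): the tissue fold pinched
  between two plates d = 5.2 mm apart.  Skin — stratum corneum + epidermis
  (σ 0.008 S/m) outside, dermis + fat (0.25 S/m) beneath — covers the two
  lateral faces and the top; the subcutis fills the fold; the tumor sphere
  (default ⌀ 2.5 mm) sits in the subcutis 0.5 mm under the skin; an
  anisotropic muscle slab (fibers along x) forms the 1 mm base.  Electrode
  contacts are 3 × 3 mm patches at the top of the lateral faces.  The mesh
  is made boundary-conforming at the tumor surface by radially projecting
  nearby nodes onto the sphere (snaps that would flatten an element are
  reverted): elements straddling the conductivity jump otherwise average
  the interface field and corrupt minimum-field and coverage statistics at
  the tumor poles.

The fold's layer thicknesses, tumor placement and contact size are not
published as numbers; they were fixed, once, by requiring the composite
model to reproduce the published constant-conductivity behaviour (zero
tumor coverage above E_rev up to 800 V, with the very high field confined
to the stratum corneum) and the published σ(E) coverage ordering — more
conductive target tumors need higher voltage for full coverage.  Three
rejected layouts are instructive: with the tumor deep in muscle, or
touching the dermis underside over a muscle bulk, the anisotropic muscle
shunt creates low-field pockets at the tumor poles whose σ(E) feedback
inverts the T1/T2/T3 ordering; with full-face contacts every coverage
voltage lands ~30 % low because the rectangular fold then sees the full
U/d everywhere, whereas contact patches let the current spread and reduce
the interior field, as the dome-shaped experimental fold does.

## Evaluation metrics

R² follows the standard decomposition `1 − SS_err/SS_tot` (negative values
allowed; identical measurements are rejected).  Conductance curves are
pointwise I/U with a warning on non-monotonicity under σ(E).  Coverage is
element-based — the volume fraction of a region's elements with
`|E| ≥ threshold` — consistent with P1 constant-per-element fields; this
produces small staircase steps in coverage curves, and "minimum voltage for
100 % coverage" is resolved to the sweep grid (20 V steps from 20 to
800 V by default).

## Synthetic data

`generate_iv_dataset` draws `Iⱼ = I_FEM(Uⱼ; truth)(1 + ε zⱼ)` with
standard-normal zⱼ from a fixed seed, resampling non-positive draws.
Defaults: 10 geometrically spaced amplitudes (20–600 V on the 4 mm plate
block, i.e. fields ~50–1500 V/cm from the sub-threshold into the saturated
regime), 3 replicates per amplitude (in vivo currents are measured in
several animals per amplitude), ε = 3 % — the standard instrumentation
assumption for a current monitor.  The ground truth, design and seed are
embedded in a JSON sidecar that scoring code may read but fitting code
never does.  The generator emulates end-of-pulse currents only: pulse-train
memory between the eight pulses of a clinical burst, electrode polarization
and thermal drift are outside the model, so recovery results bound what the
method can do under ideal sampling, not under every in vivo artifact.

Default recovery-study truth: σ₀ = 0.088145 S/m (a published liver
baseline) and k_σ = σ₀/1500 per (V/cm), i.e. conductivity doubling at the
top of the sampled field range, consistent with the ×2–3 end-of-pulse
conductivity increases reported experimentally.  Under these conditions the
study (20 seeds) recovers σ₀ with ~3 % and k_σ with ~4–5 % median error; a
closed-form Monte-Carlo analysis shows that with single measurements per
amplitude the absolute-current objective leaves σ₀ near-unidentifiable at
the 5 % level (the low-voltage points carry almost no weight), which is why
replication is part of the default design.

## Problem sizes and tolerances

Defaults used by the tests and `scripts/acceptance.py`: plate validations
on 10 mm blocks at 2.5 mm resolution (750 tets — uniform fields are exact
at any resolution); slab validations at 1 mm (3 000 tets); recovery fits on
a 4 mm block at 2 mm (192 tets, again exact for uniform fields); the tumor
fold at 0.5 mm (11 232 tets), at which the 800 V current is within 2 % of
the next refinement while the discrete full-coverage voltages move by at
most one or two 20 V grid steps between refinement levels.  Newton
tolerance 1e-8 relative; slab oracle 1e-15 relative; optimizer ftol/xtol
1e-12.

## Known limitations

No time-domain dynamics within or between pulses; no thermal or
electrochemical effects; no contact impedance; linear elements only; the
composite-fold geometry is a calibrated idealization (rectangular fold,
spherical tumor), so its coverage voltages carry geometric uncertainty of
order one grid step beyond the mesh effects quantified above; SA's
adaptive damping is a numerical stabilization of the sequential
permeabilization picture, not a model of pore kinetics.
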