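# Methods

`menptherm` models the extremely localized heating produced by
magnetoelectric core–shell nanoparticles (MENPs) in a biological medium and
the resulting thermal denaturation of tissue and of an antibody-bound
cytokine. This note documents the model, its assumptions, the numerical
choices, and the package's own design decisions where the problem left the
design open.

## The physical model

A MENP couples a magnetostrictive cobalt-ferrite core to a piezoelectric
barium-titanate shell. Under a static magnetic field along z the strained
shell presents a dipolar electric surface potential; the model injects this
as a Dirichlet boundary condition

> V = V0 cos θ on the shell outer surface (radius a),

with θ the polar angle from the field axis of each particle. The
magnetoelectric constitutive chain that would fix V0 in absolute terms is
*not* part of the model (see "Source amplitude" below).

The surrounding conductive media (extracellular fluid, and optionally the
microvesicle-membrane coating and the antibody–cytokine complex) then carry
a steady current:

* E = −∇V,  J = σE,  with ∇·(σ∇V) = 0 in the conduction domain,
* Joule power density q = σ|E|²,
* heat conduction ρ Cp ∂T/∂t − ∇·(k∇T) = q, uniform initial and far-field
  temperature 37 °C, no perfusion or metabolic terms,
* Arrhenius damage dα/dt = A·exp(−E/(R·T)), α capped at 1.

Material constants (σ, ε_r, ρ, k, Cp and the kinetic pairs E, A) for the
three biological domains are the published values; the particle interior
(core, shell) enters only the heat solve through literature-typical
stand-ins (k = 4.5 W/m·K, i.e. an order of magnitude above water). The
interior holds no source, so it floats to its surface temperature and the
exterior fields are insensitive to the stand-in values; they exist so that
"particle surface temperature" is well defined. ε_r is carried for
completeness but unused: a DC conduction problem is governed by σ alone.

### Source amplitude: calibrated and field-scaled modes

The literature values for this system are mutually inconsistent under the
printed equations: surface fields of ~1e5 V/m at a ~100 nm source deposit
(8π/3)σV0²a ≈ 1e-13 W and produce micro-kelvin rises, while the reported
temperatures are tens of kelvin above body temperature (requiring V0 of a
few volts). The package therefore never guesses an absolute amplitude:

* **calibrated mode (default).** V0 is fixed so that the steady peak
  temperature at a stated anchor location matches a printed anchor value
  (56 °C surface maximum for the bare 100 nm particle; 65 °C extracellular
  maximum for the MV-coated 120 nm particle). Because the chain is linear
  in q and q ∝ V0², the rise scales exactly as V0², and one trial solve
  calibrates: V0 = V0_trial·sqrt(ΔT_target/ΔT_trial). Cluster scenarios
  inherit the amplitude calibrated on a *single* particle of the same
  build, solved axisymmetrically — the convention in which the anchors are
  stated.
* **field-scaled mode.** V0 = V0_ref·s(H) with s a monotone magnetostrictive
  saturation curve, s(1 T) = 1. The default s is a normalized Langevin
  shape with steepness 5, chosen so that a 50 mT field produces negligible
  heating (s² < 1%), a 300 mT field partial output, and 1 T saturation —
  the qualitative progression of the modelled stimulation protocol. This
  mode supports direction-of-effect sweeps (e.g. larger cores heat more
  when V0_ref is scaled by core volume fraction); it is not used for any
  quantitative result.

### The MV coating: thermal damping, not electrical screening

The 30 nm microvesicle coating has both electrical (σ = 0.3 S/m) and
thermal (k = 0.547 W/m·K) constants. Including it in the *conduction* solve
collapses the deposited power (the fluid-side dipole coefficient drops to
0.26·V0a², power to ~22%), and the coated fluid maximum would fall to
~40 °C from a 56 °C bare anchor — a far stronger damping than the reported
behaviour, which attributes the modest coated-particle temperature drop to
the layer's *heat*-dissipating action. The electrical model of the source
is also stated over core/shell/fluid subdomains only. The package default
therefore treats the coating as electrically transparent — the Joule source
is the bare particle's — while the coating participates fully in the heat
solve (`Scenario.coating_in_conduction = False`). The full electro-thermal
coating model remains available behind that flag and is validated against a
closed-form two-layer solution (`two_layer_dipole_analytic`). With the
default, the calibrated 56 °C bare particle yields a coated extracellular
maximum of ≈ 52 °C: the model's damping ratio across the MV layer is
ΔT(b)/ΔT(a) ≈ 0.80, confirmed independently by a spherical-harmonic radial
oracle.

### Quasi-steady damage integration

The thermal diffusion time a²ρCp/k is ~1e-7 s at these scales, nine orders
below the 1–10 minute stimulation, so damage is integrated on the *steady*
temperature field, where the Arrhenius integral is closed-form per node:
α = min(1, k(T)·t). The transient solver (implicit Euler; the explicit
stability limit at nanometre grids is ~1e-11 s) exists to verify this —
the field reaches steady state to within 0.1% by 1 ms — and to support
future time-varying sources, for which a trapezoidal quadrature over the
temperature series is provided.

The damage law is implemented exactly as stated: zeroth order in α (the
rate does not slow as material is consumed), capped at 1; "complete"
damage means α ≥ 0.999. A conventional first-order variant
(α = 1 − exp(−kt)) sits behind a `first_order` flag for sensitivity
analysis; the two coincide to first order in kt. Note one consequence of
the published kinetics: the antibody–cytokine pair (E = 178 kJ/mol,
A = 1.42e26 1/s) accrues ~9% damage in 10 minutes *at body temperature*;
the extracellular pair accrues ~0.8%.

## Geometry

* Single particle: core Ø 60 or 80 nm, shell 20 nm, optional 30 nm
  coating; axisymmetric r–z model, z the field axis, origin at the centre.
* Clusters: three MV-coated 120 nm particles (outer radius
  40 + 20 + 30 = 90 nm) with 30 nm coating-to-coating gaps, i.e. 210 nm
  centre spacing. The layouts are the two qualitatively distinct
  three-particle arrangements: `config-1` collinear along x, `config-2` an
  equilateral triangle in the x–y plane (centroid at the origin). Only the
  gap is constrained by the study; the layouts are this package's choice
  and are meant to differ in damage *distribution* while destroying
  comparable section areas.
* Antibody–cytokine complex: a 10×5 nm ellipsoid (major axis radial,
  touching the coating) plus a tangent 5 nm sphere, so the cytokine centre
  sits outer radius + 12.5 nm from its particle centre and the whole
  complex within 15 nm of the coating. Linking site A faces the cluster
  centroid (the hot inter-particle pocket); site B faces outward on a
  different particle. The two bracket the local temperature range a
  randomly placed complex would see. At 3D grid resolution the complex is
  sub-grid and is treated as a passive probe for damage evaluation (its
  nodes are labelled, but its thermal footprint is negligible); cytokine
  damage is the closed-form integral at the sampled cytokine-centre
  temperature.

## Numerics

* **Discretisation.** Node-centred finite volumes on structured grids;
  axisymmetric cells carry full 2π r ring volumes and face areas, so
  integrated powers and fluxes are physical. Face coefficients use
  harmonic means; cells cut by a spherical material interface get a
  series-resistance effective coefficient, placing the interface at its
  exact radius in the radial fluxes.
* **Dipole surface.** Links from a fluid node into the particle-interior
  Dirichlet region are shortened Shortley–Weller style to the exact
  distance to the sphere, with the boundary value V0 cos θ evaluated at the
  intersection point; this removes most of the staircase error (the
  numeric potential matches the closed forms to ≲1% at 1.5–2 radii).
* **Joule density.** The q map is the flux-consistent per-cell share of
  the discrete link dissipation: it integrates to the exact discrete total
  power (which matches (8π/3)σV0²a to <1% at the default axisymmetric
  spacing) and makes the steady heat balance an identity (boundary flux =
  total power to solver tolerance). E and J maps use central differences
  and are for export/probing.
* **Boundaries.** Far boundary: V = 0 and T = 37 °C (Dirichlet) at least
  six outer radii from every particle; r = 0 is a symmetry line. The
  truncation suppresses the rise by O(r_surf/R); fixed-V0 comparisons
  (coated vs bare) calibrate and re-solve in equal domains so the
  truncation largely cancels. Grid axes are built bitwise mirror-symmetric
  so symmetric geometries discretise symmetrically.
* **Solvers.** Sparse LU (cached factorisation for the time stepper) up to
  4e5 unknowns, Jacobi-preconditioned conjugate gradients above, relative
  tolerance 1e-9 and hard failure with the reached residual on
  non-convergence.
* **Spacings and sizes.** Defaults: 2 nm axisymmetric, 6 nm 3D (both
  configurable; `build_grid` refuses anything coarser than a third of the
  20 nm shell). The calibrated axisymmetric runs use ~1e5 nodes; the
  cluster runs ~6.6e6 nodes, the package's desk-scale choice for a
  converged interior field (halving the axisymmetric spacing moves total
  power by <1% and the peak rise by <3%).
* **Probing.** Field values are linearly interpolated. Profile samples are
  clamped two cells off a particle surface, because node values within a
  cell of an interface blend regions (inside the particle α is undefined);
  for the same reason oracle comparisons probe clear of the σ-kink at the
  coating interface, where pointwise linear interpolation across the
  gradient jump is ill-defined.

## Analysis windows and summaries

The damaged-area percentage of a cluster section is the fraction of a
planar window (particle interiors excluded) with α ≥ 0.999, computed on the
plane through the particle centres. The study does not state its window;
the package default is the bounding box of the particle centres padded by
300 nm, and the layout-comparability check applies one *common* window to
both configurations — only the comparability, never the absolute
percentage, is meaningful. Damage-vs-distance profiles report min/mean/max
of α over ray directions at each distance (0–100 nm) from each particle's
outer surface.

## What the scenarios do and do not emulate

The scenario builder generates the study conditions themselves (particle
sizes, coating, cluster gap, stimulation anchors, 37 °C environment); there
is no external data. Passing tests therefore demonstrate internal
consistency of the implemented physics and agreement with its closed-form
limits — not fidelity to living tissue. Deliberately not modelled:
blood perfusion and metabolic heat, advection, temperature-dependent
material properties, AC stimulation, particle polydispersity or motion,
receptor-level binding chemistry, and the magnetostriction–piezoelectric
constitutive chain that sets the absolute source amplitude.

## Known limitations

* The two printed anchors are not perfectly reconcilable under the printed
  equations: with the bare 100 nm particle anchored at 56 °C, the model's
  coated maximum is ≈52.1 °C, at the edge of the reported "around 50 °C"
  (the model's MV damping ratio is 0.80 where the report implies ≈0.68; the
  electrically active coating variant overshoots in the other direction,
  ≈40.5 °C).
* Voxelised spheres at 6 nm 3D spacing leave O(h) geometric error at the
  coating surfaces; quantities within ~2 cells of an interface should be
  read through the provided probing helpers, not raw node values.
* The far-boundary Dirichlet condition under-reports absolute rises by a
  few percent at the default domain sizes; calibrated comparisons cancel
  most of this, but absolute uncalibrated runs should enlarge the domain.
* The damaged-area percentage depends entirely on the window convention.
  Moreover, the two bundled layouts are genuinely less alike than "two
  cluster variants" might suggest: at the calibrated source the collinear
  layout destroys ~11% more section area than the triangle (26.5% vs 23.7%
  of the default joint window after 5 minutes), so their percentages differ
  by ~2.8 points rather than the fraction of a point seen between two more
  similar arrangements.
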