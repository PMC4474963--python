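# Methods

This package simulates a rigid, pseudopod-bearing neutrophil interacting
with a P-selectin-coated plane wall under linear shear flow, coupling
zero-Reynolds-number hydrodynamics to stochastic receptor–ligand bond
kinetics. This note records the model, its numerical realisation, the
open design choices we made, and what the synthetic study conditions do
and do not show about real cells.

## Cell geometry

The cell is a star-shaped rigid surface: a sphere carrying a single
Gaussian-shaped protrusion along the body-frame +x axis,

    r(θ) = a_body · (1 + Λ · exp(−θ² / (2w²))),

with θ the polar angle from the pseudopod axis. Λ is the dimensionless
protrusion (tip height above the body surface over the body radius;
default 1.9) and w the angular width of the bump (default 0.45 rad,
chosen so the silhouette shows a long slender pseudopod on a round body
while the surface remains star-shaped and meshable at the default
resolution). After meshing, `a_body` is rescaled so the enclosed volume
equals that of the 4-µm-radius sphere — the pseudopod redistributes
cytoplasm, it does not add volume.

The surface is discretised with 9-node biquadratic quadrilaterals on a
cubed-sphere layout (6 logical faces × n² elements; n = 8 gives the
default 384 elements). Areas, outward normals and the enclosed volume
are evaluated with a 3×3 Gauss rule per element; the volume uses the
divergence theorem, so the equal-volume normalisation is exact with
respect to the mesh's own quadrature (the acceptance check asks for 1%).

PSGL-1 receptors (default 25,100, ≈125 µm⁻² on the equal-volume sphere)
are apportioned to elements proportionally to area with largest-remainder
rounding (the configured total is met exactly) and placed at Halton
points inside each element. Placement is deterministic and seed-free by
design: all run-to-run stochasticity lives in the Monte-Carlo kinetics.

## Hydrodynamics

The ambient flow is u = γ̇ z x̂ over a no-slip wall at z = 0 (default
γ̇ = 1000 s⁻¹, plasma viscosity 1 cP). The quasi-static mobility problem
— find (U, Ω) such that hydrodynamic drag balances the applied bond and
steric loads — is solved with a first-kind single-layer boundary-integral
method: constant density per element, collocation at element centres, and
the wall condition built into the kernel through the classical image
system for a point force above a plane wall (Stokeslet, image Stokeslet,
potential dipole, Stokeslet doublet). The free-space Stokeslet pair is
regularised with a blob parameter ε = 0.15·√(element area); the image
terms are exact since their singularities lie below the wall. The
regularisation constant was fixed once by benchmarking the translational
drag of the meshed sphere against 6πµa (0.04% error at 384 elements,
0.5% at 96) and is not a per-run tuning knob.

Solving the collocation system for the six unit rigid modes and the
ambient flow yields a 6×6 resistance matrix and a shear forcing vector;
the mobility solve is a 6×6 linear system per time step. Verified
properties: exact no-slip of the Green's function on the wall, Lorentz
reciprocity, free-space Oseen limit, Stokes drag and freestream shear
advection within 2%, monotone wall retardation of a translating and of a
force-free sheared sphere, and symmetry/positive-definiteness of the
grand mobility matrix within 1%.

Two deliberate numerical approximations:

- **Operator reuse.** The collocation operator is exactly invariant
  under wall-parallel translation, so its LU factors are reused until the
  height changes by >0.01 µm or the orientation by >0.002 rad. This
  roughly halves the cost of bound phases without changing the physics
  beyond a sub-element-scale geometric perturbation.
- **No lubrication resolution.** Rigid-body collocation cannot resolve
  contact singularities; below gaps of order the steric layers the
  exponential steric repulsion dominates, and a per-step guard shrinks
  any advance that would carry a node through the wall plane (floor
  0.02 µm). Near-contact hydrodynamics is therefore approximate.

## Bond kinetics

Bonds are linear springs (stiffness σ = 250,000 fN/µm, natural length
l_b = 0.08 µm) anchored on the wall steric surface. Formation follows
the Bell form for 2-D bridging,

    k_f = k_f⁰ · exp( σ|x_b − l_b| (γ − ½|x_b − l_b|) / k_BT ),

so an unstressed encounter forms at k_f⁰ (default 10 s⁻¹) and the rate
collapses over a Gaussian window of width √(2k_BT/σ) ≈ 6 nm. The slip
velocity between receptor and wall can optionally attenuate formation
(`slip_velocity_scale`); the default leaves formation purely
length-dependent, since the published expression does not fix how the
velocity enters dimensionally.

Dissociation follows the two-pathway catch–slip model: a force-
independent native pathway (k_N = 9 s⁻¹), a Bell slip pathway
k_I = 0.33·exp(y_I f / k_BT) s⁻¹ (y_I = 2.4×10⁻⁴ µm), blended by the
population ratio Φ(f) = 90.01·exp(γ′ f / k_BT) with γ′ = 8.16×10⁻⁴ nm:

    k_r(f) = k_N/(1+Φ) + Φ·k_I(f)/(1+Φ).

**A caveat we report rather than repair:** with these constants the
blended rate is *monotonically increasing* in force — no catch–slip
minimum exists. The condition for an interior minimum,
(k_N − k_I⁰)·γ′/(1+Φ₀) > k_I⁰·y_I, is independent of temperature and
fails by three orders of magnitude at γ′ = 8.16×10⁻⁴ nm (and still
marginally fails if that value is read in µm). The machinery produces a
genuine catch–slip minimum for parameter sets that satisfy the
inequality (covered by a unit test); with the tabulated defaults the
model behaves as an effective slip bond with a low unstressed off-rate
k_r(0) ≈ 0.425 s⁻¹. γ′ is configurable.

Per step, every eligible free receptor forms with probability
1 − exp(−k_f Δt) and every bond breaks with 1 − exp(−k_r Δt); draws are
independent, and sub-stepping keeps k·Δt below 0.1. Thermal energy uses
body temperature (310 K) — the source material does not state a
temperature, and k_BT only rescales the tabulated compliances.

**Anchor placement and the formation deviation.** Wall P-selectin is
dense and not explicitly resolved, so a new bond is taken to attach at
the *deviation-minimising* point of the wall steric plane: vertically
beneath the receptor tip when the tip is more than l_b above the plane
(deviation z_tip − l_b), and laterally offset by √(l_b² − z_tip²) (random
azimuth) when the tip is closer than l_b, giving an unstretched, angled
bond. Treating near-wall receptors as compressed vertical springs
instead would suppress binding essentially completely at σ =
250,000 fN/µm and contradicts the observed prevalence of binding at
every condition; a tip pressed toward a ligand-dense surface always has
an unstressed partner within reach. Receptor tips protrude through the
cell's steric layer (tip = surface point + 0.175 µm along the outward
normal), so the natural bond geometry spans bond + both steric layers ≈
0.605 µm of surface-to-wall separation, consistent with the stated
reactive distance (0.58 µm, kept configurable and applied from the wall
steric surface).

## Contact, steric repulsion and stopping rules

A node is "in contact" when it lies within the reactive distance of the
wall steric surface; instantaneous contact area sums the areas of
elements with any node in contact, and per-node contact times accumulate
each step (the basis of the orientation-grid contact maps). Steric
overlap (gap < 0 between the two steric surfaces) produces a wall-normal
repulsion F₀·e^(−gap/λ) per overlapping node (F₀ = 10⁴ fN, λ = 0.01 µm)
— an invented but standard short-range regularisation; the source
describes steric layers without a repulsion law.

A run stops when the centroid passes x_stop (150 µm), when the cell is
firmly adhered, or at the step budget (reported as censored). "Firm" is
operationalised as: bond count at the cap, or at least half the cap
while the centroid speed stays below 1% of γ̇·R_eq for 10 ms. The cap
(200 at full scale) exists only to bound the bookkeeping, not to limit
spontaneous formation.

## Time stepping

Explicit quasi-static stepping: centroid advanced by UΔt, orientation by
the quaternion exponential of ΩΔt with renormalisation. The bond springs
set the stiffness scale: the spring relaxation time 1/(Mσ) with M the
near-wall mobility is ≈3×10⁻⁴ s, so Δt = 10⁻⁶ s (full profile) resolves
it comfortably and Δt = 5×10⁻⁶ s (reduced profile) remains stable while
resolving bond-force ramps to a few thousand fN per step. Halving Δt
changes adhesion-free trajectories by <1%. Bound trajectories are
individually chaotic (bond events are discrete), so convergence is
judged at the level of ensemble behaviour fractions: these shift
between Δt = 10⁻⁵ and 5×10⁻⁶ s — coarse steps under-sample the passage
of receptors through the ~10-nm formation window — and are stable
between 5×10⁻⁶ and 2×10⁻⁶ s, fixing the reduced-profile step at
5×10⁻⁶ s. Bond-free flight with a steric gap above 0.5 µm (far outside
the 0.4-µm contact range) integrates at 4× the base step; bonded and
near-wall phases always use the fine step, so kinetics sampling is
untouched.

## Study conditions and the reduced profile

The full study conditions are: 384-element mesh, 25,100 receptors,
Δt = 1 µs, start at a 0.5-µm steric gap with the pseudopod pointing
downstream and the long axis wall-parallel, stop at x = 150 µm, cap 200
bonds. Sweeps follow the published conditions: shear 100–2000 s⁻¹,
formation rate 1–20 s⁻¹, receptor count 25–300%, ten independently
seeded runs per condition; the orientation grid spans z-y-z angles
0…π at π/4 steps (125 poses) at a fixed centroid height chosen so the
default pose has a 1-µm gap, excluding poses that start in steric
overlap.

Tests and the acceptance script use a *reduced profile* whose physical
constants — including the 150-µm stop line — are identical but whose
numerics are scaled down: 96-element mesh, Δt = 5×10⁻⁶ s, bond cap 40
(chosen, like the original 200, to stay above the largest spontaneous
tether cluster — max ≈ 16 concurrent bonds at baseline — while keeping
arrested runs short). At this scale the package reproduces the regime
structure of the full model: unanimous firm arrest on first contact at
low shear (100 s⁻¹, 10/10 seeds) and at high on-rate (20 s⁻¹ at
500 s⁻¹, 10/10), near-unanimous tether-without-arrest at k_f⁰ = 1 s⁻¹
(9/10), the body's perpendicular (y) swing while the pseudopod is
tethered (excursions up to ≈3.9 µm), and arrest positions/times
(x ≈ 14–28 µm at t ≈ 13–22 ms for firm first contact at 500 s⁻¹) on the
scale the full-size model reports.

## What the synthetic conditions do not show

The cell is rigid: no pseudopod bending, membrane tether extrusion,
microvillus compliance, or deformation-induced drag reduction, all of
which matter for real neutrophils. Receptors are uniformly distributed
rather than clustered on microvilli, and wall ligand is treated as a
continuum (anchor azimuths are randomised rather than resolved to
discrete P-selectin sites). Brownian motion is omitted. Near-contact
lubrication is replaced by the steric repulsion, so absolute arrest
positions and contact areas carry discretisation-scale uncertainty —
coarse meshes overestimate instantaneous contact area because whole
elements count as soon as one node is in range. Quantitative
trajectory-level agreement with any particular prior implementation is
not expected; the reproducible content is the kinetics arithmetic, the
hydrodynamic benchmarks, and the regime structure of the behaviour
taxonomy.
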