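# Model and methods

`fibernet` simulates mechanical homeostasis in soft-tissue analogues
bottom-up: a periodic representative volume element (RVE) of a
collagen-like fiber network, quasi-static beam mechanics, stochastic
fiber–fiber cross-linking, and contractile cell agents coupled to the
network through molecular-clutch focal adhesions.  All internal units
are μm, s, pN; stress is reported in Pa (1 pN/μm² = 1 Pa).

## Network generation

Networks are periodic graphs of straight free-fiber segments between
junction nodes.  A periodic Voronoi tessellation of `n` uniform random
seed points supplies the initial graph: its vertices are generically
tetravalent and the graph is fully connected.  The seed count is sized
from the requested collagen concentration through the Poisson–Voronoi
edge-length density (5.832·λ^{2/3} per unit volume) and the
concentration relation

    rho_c = L_tot · D_f² · π / (V_RVE · v_c),

with `L_tot` the summed fiber length, `D_f = 0.18 μm` the fiber
diameter, `v_c = 0.73 ml/g` the specific volume of collagen.  The
relation is implemented exactly in this conventional form (the circular
cross-section area would carry an extra 1/4); a `use_quarter_factor`
switch provides the alternative.  Realized concentrations of generated
networks match the request to a few percent.

Three descriptors characterize the microstructure: node valency, the
free-fiber length, and the inter-fiber cosine of every unordered pair of
segments meeting at a node (both tangents pointing away from the node).
Simulated annealing displaces single nodes with Metropolis acceptance
against the energy

    E = Σ_d w_d Σ_b (p_db − t_db)²  +  w_L (L_tot/L_ref − 1)²,

a weighted squared bin-wise mismatch of the three descriptor histograms
(valency bins 1–10, length bins 0.5 μm, cosine bins 0.1) plus a
total-length conservation term.  The conservation term is load-bearing:
histograms alone underdetermine the geometry, and unconstrained node
shuffling accumulates slack fiber length (~15 % in our experiments),
which both drifts the concentration and softens the network by orders of
magnitude, in contradiction with the experimentally validated stiffness
of descriptor-matched collagen networks.  Temperature cools
geometrically (factor 0.97/sweep from 0.002·E₀) while the proposal
amplitude shrinks from 2 μm to 0.03 μm; moves creating segments shorter
than 0.2 μm are rejected.  Topology never changes, so the valency
distribution is fixed by the seed tessellation; the default valency
target is accordingly degenerate at 4.  Default length targets are
lognormal (right-skewed, CV 0.45) with the mean set by the seed density,
and the default cosine target is broad with excess mass near −1 (fibers
tending to continue straight through junctions).  User-supplied target
histograms (CSV) replace all defaults.  The annealing inner loop is
JIT-compiled (numba) with a pure-Python reference implementation kept
for cross-checking; both maintain the histograms incrementally and
deterministically per seed.

## Beam mechanics

Each free-fiber segment is subdivided into 2-node beam elements (default
two per segment).  A mesh node carries a translation and an orientation
triad; fibers sharing a junction node are rigidly coupled in both, which
models native covalent junctions as rigid joints.  Element strain
measures are one-point Cosserat quantities built from the nodal triads
`R_i, R_j`, the relative rotation `φ = log(R_iᵀR_j)` and the mid-triad
`R_m = R_i exp(φ/2)`:

    Γ = R_mᵀ d / L₀          (axial + transverse),
    κ = (φ − φ₀) / L₀        (torsion + bending),

with quadratic energy resolved along the element's reference tangent
(moduli EA, GAs, GJ, EI of a circular section, E_f = 1.1 MPa).  Shear
compliance is retained as a small Timoshenko-style term with the
MacNeal residual-bending-flexibility correction
`GAs_eff = 1/(1/GAs + L₀²/(12 EI))`, which makes the element nodally
exact for linear bending at any mesh density; for the slender fibers
here (L/D ≫ 10) physical shear deflection is negligible.  Internal
forces are the exact left-trivialized gradient of the stored energy,
derived with the SO(3) left Jacobian; the tangent is a finite difference
of that analytic gradient.  Verified oracles: axial bar and torsion
match closed forms to ~1e-6 relative, cantilever bending matches the
Timoshenko closed form to 1e-4 and Euler–Bernoulli within 1 %.

The box is periodic in all directions.  Segments crossing a boundary
store an integer shift triple; the element vector includes the
translation `shift · λ·L`, so prescribing the box stretch λ loads every
boundary-crossing element directly (fully periodic Dirichlet loading,
no boundary nodes).  An affine displacement predictor precedes each
equilibrium solve; relaxation is non-affine.  Equilibria are computed by
a Levenberg–Marquardt descent on the total potential: with μ = 0 the
step is plain Newton (quadratic near minima); on indefinite tangents
(post-buckling fibers) μ grows until the step descends.  Rotational
updates are multiplicative (`R ← exp(δw) R`) and capped at 0.5 rad per
step.  The only kinematic constraint is pinning one node's translation
(the global-translation null space of the periodic cell).  The sparse
symmetric system is factorized with SuperLU in symmetric mode.
Load stepping: the uniaxial protocol stretches in 0.2 % strain
increments; chemistry steps keep the cell-seeded solves warm.

Boundary stress is first Piola–Kirchhoff: for each axis the axial force
vectors of all elements (and stress-fiber springs) whose unwrapped span
crosses a periodic cut are summed with crossing orientation as sign and
divided by the reference face area.  Two distinct cuts per axis (at 0.31
and 0.79 of the edge) are evaluated; their agreement is an equilibrium
diagnostic.

## Fiber–fiber cross-linking

Binding spots sit on interior beam-mesh nodes, so a new bond can anchor
to existing degrees of freedom without remeshing.  When two unoccupied
spots on distinct fibers are within the capture interval (default
0.05–0.75 μm, matched to the node spacing rather than a molecular
capture radius), a bond forms as a Poisson event, `p = 1 − exp(−k_on Δt)`
(default `k_on^{f-f} = 0.01 /s`; protocol runs use higher desk-scale
values so the process is observable over minutes).  A formed bond is a
beam element whose reference strains are recorded in the current
configuration — stress-free at birth, which is the entrenchment
mechanism behind residual matrix tension.  Transient bonds rupture as
Poisson events with the Bell slip-bond rate
`k_off(F) = k_off,0 · exp(F·Δx / k_B T)` evaluated at the tensile part
of the element's axial force (Δx = 0.4 nm, k_BT at 310 K); `k_off,0 = 0`
makes a bond covalent.  One bond per spot; candidate pairs come from a
periodic fixed-radius KD-tree search that agrees exactly with the
brute-force minimum-image scan.

## Cell agents and molecular clutches

Cells are point particles with radius `R = 15 μm` and shell half-width
`ΔR = 2 μm`.  Unoccupied integrin spots (beam-mesh nodes) within
`R ± ΔR` of a cell center nucleate focal adhesions as Poisson events
with `k_on^{c-f} = 0.5 /s`, capped at 65 adhesions per cell.  An
adhesion holds 50 integrin clusters of up to 20 integrins (1000 per
adhesion); each cluster is pulled by its own actin stress fiber — a
tension-only spring between the cell center and the adhesion anchor
whose rest length shortens at `ċ = 0.1 μm/s` and whose stiffness is
`k_SF = 25 pN/μm`, chosen so that contraction loads single integrins
into the tens-of-pN catch–slip regime over the minutes-scale build-up.
The per-integrin force is `F_i = F_SF / N_bonded`; integrins unbind with
the double-Gaussian catch–slip rate

    k_off(F) = a1·exp(−((F−b1)/c1)²) + a2·exp(−((F−b2)/c2)²),

with defaults a1 = 1.8 /s, b1 = −10 pN, c1 = 18 pN, a2 = 0.7 /s,
b2 = 90 pN, c2 = 35 pN, and forces below 5 pN evaluated at 5 pN (a
low-force lifetime clamp).  These constants are a single fit of the
double-Gaussian form to published single-integrin behavior anchored at
the stated stability optimum: bond lifetime peaks at ≈30 pN (≈20 s) and
single-bond turnover at low force is ~1 s.  A cluster whose bound count
reaches zero dissolves with its stress fiber and may re-form immediately
(configurable delay) on a fresh, uncontracted fiber; an adhesion whose
clusters are all dead at once is removed.  Cell centers are unknowns of
the equilibrium solve, so the cell–matrix coupling is two-way: the
network's resistance sets the stress-fiber forces and the cells' pull
deforms the network.  Cluster statistics were validated against an
exact 21-state absorbing Markov chain (mean lifetime within 5 % at 10⁴
replicates).

## Protocols

All cell-seeded protocols run the same quasi-static splitting per
chemistry step Δt (default 0.5 s, chosen so that k·Δt stays ≤ ~0.5 for
the fastest default kinetics; halving Δt changes desk-scale plateau
levels within run-to-run scatter): contract stress fibers → integrin
clutch events and adhesion formation → cross-link events (when enabled)
→ re-equilibrate mechanics → record boundary stress.  The box is held
at stretch 1 (fully constrained, periodic all around).

* **Uniaxial stiffness.**  Acellular networks stretched to 1 % strain in
  five increments; the Young's modulus is the least-squares slope of the
  stress–strain record.  The stiffness scan runs 0.8/1.5/2.5 mg/ml in
  72/64/60 μm boxes (three seeds each) and fits the power-law exponent
  against the realized concentrations.
* **Homeostasis.**  Cell counts follow `ceil(density · V)`.  Tension
  rises from zero in two phases and settles at a cell-density-dependent
  level within simulated minutes.  At desk scale (1–3 cells) the
  "plateau" is punctuated by rupture-cascade stick-slip events; smooth
  plateaus emerge only as ensemble means, which is how the tests assess
  them.
* **Residual matrix tension (RMT).**  At a chosen time all cell–ECM
  bonds are dissolved (`k_on^{c-f} = 0`).  Without runtime cross-links
  the tension drops to zero in one step (the model has no viscosity);
  covalent cross-links entrench a non-decaying residual; transient
  cross-links hold a residual that decays faster the higher their
  off-rate.  Desk-scale runs use off-rates of 1e-2–5e-2 /s so the decay
  is resolvable within a few simulated minutes.

## Scope of the synthetic conditions

The generator and protocols emulate the *statistical structure* of
collagen-gel experiments (descriptor distributions, concentrations, cell
densities, kinetic scales), not any specific gel: boxes are 44–72 μm
rather than 245 μm, cells per box are 1–15, and horizons are minutes.
Quantities that survive this scaling — conversion rules, kinetic optima,
scaling exponents, orderings between cross-link regimes, displacement
magnitudes — are asserted in the tests; absolute plateau stresses and
experimental time scales are not.  Other known limitations: no fiber
contact, no mass turnover, adhesion spots quantized to mesh nodes
(coarser than the 50 nm integrin spacing of real fibers), and a
catch–slip fit whose off-rate decays unphysically above ~150 pN (outside
the operating range).
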