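# Methods

## The model

`corralsim` studies how a linear fence along the line X = 0 retards the
lateral escape of PIP₂ from a membrane "corral" (the pool X < 0).  Each
PIP₂ molecule is a single sphere carrying the net headgroup charge
q = −4 e, with Lennard-Jones parameters ε = 0.5 kcal/mol and
r_min/2 = 5.4 Å and mass 1043 amu.  Spheres are confined near a
diffusion plane lying 5 Å above the lipid phosphate plane by a harmonic
restraint (k = 0.6 kcal/mol/Å², CHARMM convention U = kΔ² without the
½), and a rectangular box of one-sided harmonic walls
(k = 100 kcal/mol/Å²) closes the system.  The energy of sphere i is

    U(r_i) = Σ_j [ ε_ij ((r_min/r_ij)¹² − 2 (r_min/r_ij)⁶) + k_e q_i q_j/(80 r_ij) ]
             + U_CORE(r_i) + q_i φ_PHIX(r_i) + restraints,

with k_e = 332.0636 kcal·Å/(mol·e²).  The water-screened 1/(80 r)
Coulomb term acts between PIP₂ spheres; the fence enters only through
two precomputed grid fields, the steric exclusion map U_CORE and the
implicit-membrane electrostatic map φ_PHIX, both interpolated with
3rd-order (quadratic) B-splines so interpolated forces are exact
negative gradients of the interpolated energy.

Units are AKMA-like throughout: Å, kcal/mol, amu, elementary charges,
ps.  In these units k_BT/(mγ) at 300 K, 1043 amu and γ = 1 ps⁻¹ equals
0.239 Å²/ps = 2.4×10⁻⁵ cm²/s, the model's (deliberately fast) lateral
diffusion constant.

## Langevin dynamics

The propagator is the BAOAB splitting of the Langevin equation with
exact Ornstein-Uhlenbeck velocity updates; at γ = 0 it reduces to
velocity Verlet (energy drift < 10⁻⁴ relative over 10⁵ steps in the
tests).  BAOAB was chosen over the leapfrog Langevin discretizations of
older MD codes because it samples configurational averages with very
small timestep bias and is equally characterized by the same D =
k_BT/(mγ); all conclusions drawn from trajectories are ratios of
relaxation times, which are insensitive to the discretization.  The
reference protocol equilibrates 25 ns with a one-sided harmonic wall
holding all spheres in the corral, then runs 10 μs of production
without it, with 20 (rod fences) or 30 (protein fences) independent
replicas; replica seeds derive from one `SeedSequence`, and identical
seeds reproduce trajectories bitwise.

## Fences

* **Steric rods**: uncharged impenetrable spheres (radius 5.4 Å,
  contact spacing 10.8 Å) on the diffusion plane along Y at X = 0, with
  a single gap of length L_open centered at Y = 0.  The reference-scale rod
  (L = 1000 Å, L_open = 0) contains ⌈1000/10.8⌉ = 93 spheres.  Within
  each blocked segment the spacing is compressed marginally so segments
  are covered end to end; a centered gap was chosen because the source
  figures show one opening per fence (an off-center or multi-gap layout
  is a config option).
* **Electrostatic rods**: an unbroken row of charged spheres raised a
  height h ∈ {2, 5, 7, 10} Å above the diffusion plane with per-sphere
  charge q ∈ {±0.05, ±0.1, ±0.5, ±1} e.  Raising the row eliminates
  steric contact, so this fence class contributes no core map — at
  small h an augmented-radius core would still intersect the plane and
  would reintroduce the steric blocking the construction is designed to
  remove.
* **Protein filaments**: rigid atomic structures replicated helically
  along the fence axis (rotation and rise per subunit, e.g.
  166.4°/27.6 Å for actin-like filaments, pure 253.2 Å or 338.7 Å
  translations for septin-like ones) and buried so their lowest atom
  sits at Z_min relative to the phosphate plane.  PDB input goes
  through Biopython; formal charges are per-residue (ASP/GLU −1,
  LYS/ARG +1, HIS 0) on the first atom of the residue, radii are
  per-element.  These tables replace force-field-specific per-atom
  charges and are configurable.

## Grid potentials

U_CORE is an indicator map: 100 kcal/mol at nodes inside any fence atom
grown by 4.16 Å (the effective PIP₂ probe radius, treated as an opaque
constant), 0 elsewhere.  φ_PHIX solves the linearized Poisson-Boltzmann
equation

    ∇·(ε∇φ) − ε_s κ² λ(r) φ = −4π k_e ρ

on a 7-point finite-difference stencil with three dielectric regions: a
36 Å membrane slab of ε = 2 below the phosphate plane, solvent ε = 80
with 150 mM 1:1 salt (Debye length ≈ 8 Å; λ = 1 only there), and ε = 2
cavities for fence atoms.  Face dielectrics come from a midpoint region
test without harmonic smoothing; charges spread to nodes trilinearly;
the linear system (symmetric positive definite after eliminating
Dirichlet boundaries) is solved by Jacobi-preconditioned conjugate
gradients to 10⁻⁸ relative residual.  Outer Dirichlet values are sums
of screened single-charge potentials, and the solution is focused
through a schedule of finer grids (1.0 Å → 0.5 Å by default), each
taking boundary values from its parent.  Linearization is justified by
the modest fence charges; no Stern (ion-exclusion) shell is added
beyond the solute cavities and the membrane.  The solver is validated
against Coulomb (≤2%), Debye-Hückel (≤3%) and two-dielectric
image-charge (≤3%) closed forms in the tests.

Rod calculations exploit the rod's Y-periodicity: the solve region is a
short Y-section at full 0.5 Å resolution while the boundary condition
uses the full-length rod.  This is an approximation; its error decays
with the 8 Å screening length and is negligible at the section center.

### The rod interaction barrier

Two quantities describe "the interaction of one PIP₂ with the rod":

1. the **map value** q·φ_PHIX(X, 0, z_plane), which is exactly what the
   dynamics feels (`rod_interaction_profile`);
2. the **PB interaction energy** of the PIP₂ present as a charged ε = 2
   sphere (`pip_rod_binding_energy`), whose default "electrostatic"
   component is the rod-charging part

       ΔG_elec = G(complex) − G(complex with rod uncharged) − G(rod),

   computed from focused solves on identical grids so grid self-energies
   cancel exactly.

Near contact the two differ severalfold: with the PIP₂ cavity in place,
the ε = 2 rod, the ε = 2 membrane and the cavity itself confine the
field lines and exclude screening ions from the thin solvent slot, so
the rod's charges act on the PIP₂ far more strongly than the bare
solvent-screened map suggests.  ΔG_elec is the quantity that cleanly
separates blocking from non-blocking rods: the acceptance script
computes ≈ 15 kcal/mol at the weakest complete-blockade condition
(q = −1 e, h = 7 Å), well above the ~7.5 kcal/mol blockade threshold,
while raising the rod or reducing its charge drops ΔG_elec below the
threshold (it scales close to linearly with the rod charge and decays
steeply with height).  The "total" component additionally contains the
charge-independent desolvation of the PIP₂ by the rod cavity and is
also available.

## Analysis

Pool depletion C(t) counts spheres at X < 0 and converts to mol% of
lipids with an area per lipid of 65 Å² — the value that reproduces all
three reference initial counts (438, 197, 329) from the box dimensions
at 6%.  Mean curves over replicas are fit by the stretched exponential
C(t) = (C₀−C∞)exp[−(t/τ)^β] + C∞ with C₀ fixed, multi-start over
β₀ ∈ {0.4, 0.7, 1.0, 1.3}, τ seeded from the half-decay time, best
residual winning and ties broken toward the smallest β.  The mean
relaxation time is ⟨τ⟩ = (τ/β)Γ(1/β) and fence quality is
ξ = ⟨τ_free⟩/⟨τ⟩.  Non-decaying curves are reported as blockades
(ξ = 0, flagged) when the fit fails, when ⟨τ⟩ exceeds 100× the
simulated span, or when the fitted amplitude C₀−C∞ falls below 20% of
the free-diffusion amplitude — a flat curve leaves τ unidentifiable, so
the amplitude is the reliable signature.

The 1D potential of mean force is W(x) = −k_BT ln[C_eq(x)/C_ref] with
C_ref = 2%: depleted regions carry positive barriers.  (The opposite
sign convention would make barriers negative where concentration is
depleted, contradicting the physical picture; this package uses the
physically consistent sign.)  Bins default to 5 Å; empty bins are
capped at +10 kcal/mol and flagged.  Burial histograms count charged
residues whose charge-carrying atom lies below the hydrophobic
boundary — the phosphate plane minus a 5 Å headgroup allowance by
default, configurable because the boundary of "the hydrophobic region"
is a modeling choice — in 1 Å slabs.

## Synthetic data and the desk profile

The synthetic-data module generates every input at two scales.

*Reference scale* reproduces the study conditions: boxes of
1400×1000 Å² (steric), 1400×450 Å² (electrostatic) and 1400×750 Å²
(protein) with the corral at −475 < X < 0 Å, initial placements of 438,
197 and 329 spheres (6% in the corral, 2% spread over the box) by
uniform rejection sampling at ≥ r_min separation on the plane.

*Desk scale* shrinks the box about the corral boundary by 0.25,
lowers the friction to 0.1 ps⁻¹ (raising D tenfold), uses a 20 fs
timestep (safe for 1043 amu spheres: the stiffest restraint period is
~0.7 ps), 12 replicas, 0.5 ns constrained equilibration, 10 ns
production, and an energy-shifted 40 Å cutoff on pair and fence
interactions.  Gap lengths are kept in absolute Å (gap-to-particle size
is what matters).  Only ratios of relaxation times are interpreted at
this profile.  Two desk-scale caveats: the truncated PIP₂-PIP₂ Coulomb
repulsion slows dispersal somewhat relative to the untruncated model
(identically across scenarios, so ξ ordering is unaffected), and with
only ~12–27 spheres the collective "trapped-layer" mechanism by which
*positive* rods eventually block cannot develop, so the negative-vs-
positive comparison is run at the high-contrast condition |q| = 1 e,
h = 2 Å, where the negative rod's ~11 k_BT direct barrier produces a
genuine blockade and the positive rod does not.

Pseudo-filaments are bead-chain walls (synthetic stand-ins for real
filament structures; labeled as such): columns of 2 Å beads every 4 Å
along Y, stacked 40 Å high from a bottom profile that is flat
(septin-like continuous footprint) or arched (actin-like, rising
30 Å mid-subunit).  The arch height is chosen so that an under-filament
channel survives any burial down to Z_min = −15 Å, while the flat wall
seals the plane once buried; bead labels cycle through a fixed
charged/hydrophobic/neutral pattern so charge assignment, PB mapping
and burial counting are exercised end to end.  They mimic neither real
sequences nor secondary structure.

The free-diffusion oracle is the Fourier-cosine solution of the 1D
diffusion equation between reflecting walls with a step initial profile
filling the corral; terms are added until the truncated tail is below
tolerance, each mode conserves mass exactly, and the t = 0 value is the
exact window average of the step (the series converges only pointwise
there).  Uncharged LD tracers reproduce this curve within 3σ of replica
scatter in the tests — the desk-scale stand-in for the continuum
comparison of the depletion figures.

## Permeability phenomenology

A fence region of thickness d = 5 nm with bulk diffusion D = 1 μm²/s
has permeability P = kD/d = 200·k μm/s; with inside/outside areal
concentrations 10⁵ and 3×10⁴ μm⁻² the outward flux per unit length is
F = P(C_i−C_o) = 1.4×10⁷·k/(μm·s).  Balancing leakage through one side
of a 1 μm square corral against a production rate of 10⁴
molecules/(μm²·s) bounds the partition coefficient at
k* = 10⁴/1.4×10⁷ ≈ 7.1×10⁻⁴ — corral-forming fences must be almost
perfectly excluding.  Units are handled explicitly (nm vs μm).

## Numerical choices and limitations

* Pair interactions use no cutoff in the reference model; the shifted
  cutoff exists only for the desk profile and defaults off.
* Grid boundary policy: U_CORE clamps to the interior (walls keep
  particles inside; clamping matters only transiently), φ_PHIX raises.
* The PB dielectric surface is the union of atom spheres (no reentrant
  molecular surface); tolerance claims account for the staircase
  representation at 0.5 Å.
* Fence atoms carry PB radii equal to their LJ radii (5.4 Å for rod
  spheres); the "optimized PB radii" of the original force-field
  pipeline are not reproducible here and table radii are a documented
  approximation for proteins.
* Reference-size grids (2801×2001×61 at 0.5 Å) are supported by the data
  structures but all shipped computations use reduced lateral extents;
  the full-scale 10 μs / 438-particle / 20-replica depletion study is a
  cluster-scale computation and is represented at desk scale by the ξ
  trend suite.
* No nonlinear PB, no periodic electrostatics, no flexible proteins,
  no constant-pressure dynamics.
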