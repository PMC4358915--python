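# corralsim

Langevin dynamics of PIP₂-like charged spheres corralled by membrane
fences, with implicit-membrane Poisson–Boltzmann fence potentials and
the relaxation-time, free-energy and permeability analyses that
quantify how well a fence retains a lipid pool.

## The problem

PIP₂ (phosphatidylinositol 4,5-bisphosphate) is a strongly anionic
lipid (net charge −4 e) of the inner plasma-membrane leaflet that
concentrates into pools several hundred nanometers across — locally
~6% of lipids against a ~2% background.  The *protein-fence*
hypothesis holds that filamentous proteins at the pool perimeter
hinder lateral escape.  `corralsim` is a minimal-model platform for
asking what makes such a fence effective: each PIP₂ is a charged
Lennard-Jones sphere (q = −4 e, ε = 0.5 kcal/mol, r_min/2 = 5.4 Å,
m = 1043 amu) diffusing on a plane 5 Å above the lipid phosphates
under Langevin dynamics (γ = 1 ps⁻¹, T = 300 K, dt = 5 fs, giving
D = k_BT/mγ = 2.4×10⁻⁵ cm²/s), and the fence is either

* a **steric rod** — uncharged blocking spheres with a gap of length
  L_open,
* an **electrostatic rod** — charged spheres raised a height h above
  the plane, acting through an implicit-membrane Poisson–Boltzmann
  potential, or
* a **protein filament** — a rigid atomic structure replicated
  helically and buried to a depth Z_min below the phosphate plane,
  acting through steric (U^CORE) and electrostatic (φ^PHIX) grid maps.

The sphere energy is

U(rᵢ) = Σⱼ [ εᵢⱼ((r_min/rᵢⱼ)¹² − 2(r_min/rᵢⱼ)⁶) + k_e qᵢqⱼ/(80 rᵢⱼ) ]
        + U^CORE(rᵢ) + qᵢ φ^PHIX(rᵢ) + harmonic restraints.

Fence quality is measured by depleting a 6% pool through the fence and
fitting the pool concentration with the stretched exponential
C(t) = (C₀−C∞)exp[−(t/τ)^β] + C∞, whose mean relaxation time is
⟨τ⟩ = (τ/β)Γ(1/β); the figure of merit is ξ = ⟨τ_free⟩/⟨τ⟩ (1 = no
fence, 0 = complete blockade).  A Fick's-law treatment (P = kD/d,
F = P(C_i−C_o)) translates blockade into a bound on the partition
coefficient of PIP₂ into the fence region.

## Worked example

Desk-scale steric fences (box shrunk 4×, friction 0.1 ps⁻¹, 12
replicas — only relaxation-time *ratios* are meaningful here):

```python
import corralsim as cs
from corralsim.synthetic_data import desk_profile

prof = desk_profile()

def xi_for_gap(l_open, free_fit=None):
    fence = (cs.build_steric_rod(
                 cs.RodFenceSpec(fence_length=250.0, opening_length=l_open))
             if l_open < 250.0 else None)
    recipe = cs.SystemRecipe(scenario="steric_rod",
                             scale_factor=prof.scale_factor, seed=100)
    geo, n, pos = cs.make_system(
        recipe, exclusion_points=fence.coords if fence else None)
    params = cs.IntegratorParams(friction=prof.friction,
                                 timestep=prof.timestep, seed=100)
    protocol = cs.SimulationProtocol(
        equilibration_time=prof.equilibration_time,
        production_time=prof.production_time,
        n_replicas=prof.n_replicas,
        snapshot_interval=prof.snapshot_interval)
    trajs = cs.run_protocol(pos, cs.ParticleSpec(), geo, params, protocol,
                            fence=fence, pair_cutoff=prof.pair_cutoff)
    series = cs.depletion_series(trajs, geo)
    fit = cs.fit_stretched_exponential(series, c0=series.mean[0])
    if free_fit is None:
        return fit
    xi, blocked = cs.relaxation_ratio(fit, free_fit)
    return xi, blocked

free = xi_for_gap(250.0)
for l_open in (100.0, 40.0, 20.0, 0.0):
    xi, blocked = xi_for_gap(l_open, free)
    print(f"L_open = {l_open:5.0f} A   xi = {xi:.3f}   blockade = {blocked}")
```

prints (a few minutes on one CPU)

```
L_open =   100 A   xi = 0.521   blockade = False
L_open =    40 A   xi = 0.219   blockade = False
L_open =    20 A   xi = 0.077   blockade = False
L_open =     0 A   xi = 0.000   blockade = True
```

Even a 20 Å gap — less than twice the sphere diameter — lets the pool
drain at ~8% of the free rate rather than sealing it: purely steric
single-row fences need essentially contact-tight gaps.  Only the
unbroken rod registers as a complete blockade (flat curve, ξ = 0).

The permeability phenomenology is instant:

```python
from corralsim import (PermeabilityModel, permeability_coefficient,
                       outward_flux, critical_partition_coefficient)
m = PermeabilityModel()          # d = 5 nm, D = 1 um^2/s, C_i = 1e5, C_o = 3e4 um^-2
print(permeability_coefficient(m))   # 200.0   um/s per unit partition coefficient
print(outward_flux(m))               # 14000000.0  per (um s) per unit k
print(critical_partition_coefficient(m))  # 0.000714... : fences must exclude PIP2 almost completely
```

A command-line interface mirrors the library
(`corralsim run | build-fence | make-maps | analyze | permeability |
make-fixtures`); see `corralsim --help`.

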