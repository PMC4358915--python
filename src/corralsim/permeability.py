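"""Fick's-law phenomenology of corral permeability.

A fence region of thickness d acts as a permeable membrane with
permeability P = k*D/d, where k is the partition coefficient of the
lipid from the bulk membrane into the fence region and D the lateral
diffusion constant.  The steady-state outward flux per unit fence
length is F = P (C_i - C_o); the corral retains its pool only while the
total outward flux stays below the in-corral production rate, which
bounds k from above (the critical partition coefficient).

Units are explicit because the inputs mix nm and um: d is in nm, D in
um^2/s, concentrations in um^-2, and P comes out in um/s.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PermeabilityModel",
    "permeability_coefficient",
    "outward_flux",
    "critical_partition_coefficient",
    "NM_PER_UM",
]

NM_PER_UM = 1000.0


@dataclass(frozen=True)
class PermeabilityModel:
    """Inputs of the permeability estimate.

    partition_coefficient : dimensionless k (fence/bulk concentration ratio)
    bulk_diffusion : D in um^2/s
    fence_thickness : d in nm
    inside/outside_concentration : areal densities in um^-2
    production_rate : molecules/(um^2 s) produced inside the corral
    corral_side : um, side of the square corral
    leaky_sides : number of sides through which the flux escapes
    """

    partition_coefficient: float = 1.0
    bulk_diffusion: float = 1.0
    fence_thickness: float = 5.0
    inside_concentration: float = 1.0e5
    outside_concentration: float = 3.0e4
    production_rate: float = 1.0e4
    corral_side: float = 1.0
    leaky_sides: int = 1

    def __post_init__(self) -> None:
        if self.fence_thickness <= 0:
            raise ValueError("fence thickness must be positive")
        if self.bulk_diffusion <= 0 or self.corral_side <= 0:
            raise ValueError("diffusion constant and corral side must be positive")
        if self.leaky_sides < 1:
            raise ValueError("need at least one leaky side")
        if self.inside_concentration < self.outside_concentration:
            raise ValueError("outward flux needs C_i >= C_o")


def permeability_coefficient(model: PermeabilityModel) -> float:
    """P = k * D / d in um/s (d converted nm -> um)."""
    d_um = model.fence_thickness / NM_PER_UM
    return model.partition_coefficient * model.bulk_diffusion / d_um


def outward_flux(model: PermeabilityModel) -> float:
    """Fick flux per unit fence length, F = P (C_i - C_o), in 1/(um s)."""
    return permeability_coefficient(model) * (
        model.inside_concentration - model.outside_concentration
    )


def critical_partition_coefficient(model: PermeabilityModel) -> float:
    """Largest k for which the fence still retains the pool.

    Balances production over the corral area against leakage through
    the leaky perimeter: k* = (production * side^2) / (F_per_k * L_leaky),
    where F_per_k is the flux at k = 1.
    """
    unit_model = PermeabilityModel(
        partition_coefficient=1.0,
        bulk_diffusion=model.bulk_diffusion,
        fence_thickness=model.fence_thickness,
        inside_concentration=model.inside_concentration,
        outside_concentration=model.outside_concentration,
        production_rate=model.production_rate,
        corral_side=model.corral_side,
        leaky_sides=model.leaky_sides,
    )
    flux_per_k = outward_flux(unit_model)
    if flux_per_k == 0:
        raise ValueError("flux per unit partition coefficient is zero")
    leaky_length = model.leaky_sides * model.corral_side
    return model.production_rate * model.corral_side**2 / (flux_per_k * leaky_length)
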