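"""Chemical fate and transport inside one culture well.

Derives transport and partition coefficients from physicochemical
properties and provides the mass-balance derivative terms for the five
chemical pools of a well: dissolved in medium, headspace, sorbed to
plastic, inside cells, and the cumulative degradation sink.

Correlations used (all constants overridable via :class:`FateConfig`):

* gas-phase diffusivity from the Fuller-Schettler-Giddings correlation,
  ``D_air = 1e-3 T^1.75 sqrt(1/M_air + 1/M) / (P (Vd_air^(1/3) + Vd^(1/3))^2)``
  in cm^2/s with T in K and P in atm;
* aqueous diffusivity from the Hayduk-Laudie correlation,
  ``D_water = 13.26e-5 / (eta^1.14 Vm^0.589)`` in cm^2/s with the water
  viscosity ``eta`` in centipoise and the molar volume ``Vm`` in cm^3/mol;
* volatilization through a two-film air-water interface,
  ``1/k_vol = 1/k_w + 1/(k_a Kaw)`` with ``k_w = D_water/delta_w`` and
  ``k_a = D_air/delta_a``;
* cell-water partitioning on a wet-weight composition basis,
  ``K_cw = f_water + f_lipid Kow + f_protein beta Kow``;
* reversible sorption to well plastic with the equilibrium
  ``log10 K_plastic = a log Kow + b`` split into on/off rates.

The assay temperature is fixed at 37 C (310.15 K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .types import CellLineProperties, ChemicalProperties, PlateSpec

__all__ = ["FateConfig", "FateCoefficients", "derive_fate_coefficients",
           "fate_derivatives"]


class FateConfig(BaseModel):
    """Tunable constants of the fate model (one named section of the run
    configuration file; every constant overridable)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    delta_w: float = Field(default=0.01, gt=0, description="stagnant water film, cm")
    delta_a: float = Field(default=0.5, gt=0, description="stagnant air film, cm")
    beta: float = Field(default=0.05, ge=0,
                        description="protein/octanol sorption ratio")
    plastic_a: float = Field(default=0.97,
                             description="slope of log10 K_plastic vs log Kow")
    plastic_b: float = Field(default=-6.94,
                             description="intercept of log10 K_plastic (K in cm)")
    k_plastic_off: float = Field(default=0.1, ge=0, description="desorption rate, 1/h")
    k_up: float = Field(default=100.0, gt=0,
                        description="cell uptake rate constant, 1/h")
    equilibrium_uptake: bool = Field(
        default=False,
        description="treat medium and cells as instantaneously partitioned")
    sealed: bool = Field(default=False,
                         description="sealed plate: no headspace exchange")
    debris_sink: bool = Field(
        default=False,
        description="dead cells keep their burden in a debris sink instead of "
                    "releasing it to the medium")
    temperature: float = Field(default=310.15, gt=0, description="K")
    pressure_atm: float = Field(default=1.0, gt=0)
    air_mw: float = Field(default=28.97, gt=0, description="g/mol")
    air_diffusion_volume: float = Field(default=19.7, gt=0)
    water_viscosity_cp: float = Field(default=0.6913, gt=0,
                                      description="water viscosity at 37 C, cP")


@dataclass(frozen=True)
class FateCoefficients:
    """Derived transport/partition coefficients for one chemical in one
    well geometry."""

    kaw: float            # dimensionless air-water partition
    d_water: float        # cm^2/s
    d_air: float          # cm^2/s
    k_vol: float          # overall volatilization velocity, cm/h
    k_plastic_on: float   # sorption velocity onto plastic, cm/h
    k_plastic_off: float  # desorption rate, 1/h
    k_cell_water: float   # cell-water partition, wet-weight basis

    def __post_init__(self) -> None:
        for name in ("kaw", "d_water", "d_air", "k_vol",
                     "k_plastic_on", "k_plastic_off", "k_cell_water"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kaw == 0 and self.k_vol != 0:
            raise ValueError("k_vol must be 0 when kaw is 0")


def fuller_gas_diffusivity(mw: float, diffusion_volume: float,
                           config: FateConfig) -> float:
    """Binary gas diffusivity in air, cm^2/s."""
    t, p = config.temperature, config.pressure_atm
    num = 1e-3 * t**1.75 * np.sqrt(1.0 / config.air_mw + 1.0 / mw)
    den = p * (config.air_diffusion_volume ** (1 / 3)
               + diffusion_volume ** (1 / 3)) ** 2
    return num / den


def hayduk_laudie_aqueous_diffusivity(molar_volume: float,
                                      config: FateConfig) -> float:
    """Aqueous diffusivity, cm^2/s."""
    return 13.26e-5 / (config.water_viscosity_cp**1.14 * molar_volume**0.589)


def derive_fate_coefficients(
    chem: ChemicalProperties,
    cell: CellLineProperties,
    geometry: PlateSpec,
    config: FateConfig | None = None,
) -> FateCoefficients:
    """Compute every fate coefficient for one chemical/cell/plate triple.

    With ``henry_kaw == 0`` volatilization is disabled (``k_vol = 0``)
    rather than raising.
    """
    config = config or FateConfig()
    d_air = fuller_gas_diffusivity(chem.mw, chem.atomic_diffusion_volume, config)
    d_water = hayduk_laudie_aqueous_diffusivity(chem.molar_volume, config)

    kaw = chem.henry_kaw
    if kaw > 0:
        k_w = d_water / config.delta_w * 3600.0  # cm/h
        k_a = d_air / config.delta_a * 3600.0    # cm/h
        k_vol = 1.0 / (1.0 / k_w + 1.0 / (k_a * kaw))
    else:
        k_vol = 0.0

    kow = 10.0 ** chem.log_kow
    k_cell_water = cell.f_water + cell.f_lipid * kow + cell.f_protein * config.beta * kow

    k_plastic_eq = 10.0 ** (config.plastic_a * chem.log_kow + config.plastic_b)  # cm
    k_plastic_off = config.k_plastic_off
    k_plastic_on = k_plastic_eq * k_plastic_off  # cm/h

    return FateCoefficients(
        kaw=kaw, d_water=d_water, d_air=d_air, k_vol=k_vol,
        k_plastic_on=k_plastic_on, k_plastic_off=k_plastic_off,
        k_cell_water=k_cell_water,
    )


def fate_derivatives(
    a_dissolved: float,
    a_headspace: float,
    a_plastic: float,
    coeffs: FateCoefficients,
    chem: ChemicalProperties,
    geometry: PlateSpec,
    assay_volume: float,
    config: FateConfig | None = None,
) -> tuple[float, float, float, float]:
    """Time derivatives (mol/h) of (dissolved, headspace, plastic,
    degraded) from abiotic fate processes; cell uptake is handled by the
    cell-dynamics module and excluded here by contract, so the four
    returned derivatives always sum to zero.
    """
    config = config or FateConfig()
    if assay_volume <= 0 or assay_volume > geometry.well_total_volume:
        raise ValueError("assay volume must be in (0, well_total_volume]")
    v_head = geometry.headspace_volume

    c_d = a_dissolved / assay_volume
    dd = dh = dp = dg = 0.0

    if coeffs.k_vol > 0 and coeffs.kaw > 0 and not config.sealed:
        c_h = a_headspace / v_head
        flux = coeffs.k_vol * geometry.well_bottom_area * (c_d - c_h / coeffs.kaw)
        dd -= flux
        dh += flux

    a_wall = geometry.well_wall_area_per_volume * assay_volume
    sorb = coeffs.k_plastic_on * a_wall * c_d - coeffs.k_plastic_off * a_plastic
    dd -= sorb
    dp += sorb

    loss_w = chem.k_deg_water * a_dissolved
    loss_a = 0.0 if config.sealed else chem.k_deg_air * a_headspace
    dd -= loss_w
    dh -= loss_a
    dg += loss_w + loss_a

    if config.sealed:
        dh = 0.0
    return dd, dh, dp, dg
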