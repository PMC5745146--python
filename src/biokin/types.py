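"""Validated domain records shared across the toolkit.

All records are immutable pydantic models.  Units follow the in vitro
bench conventions used throughout the package: volumes in cm^3, masses in
g, amounts of chemical in mol, time in hours, intracellular concentration
in g chemical per g cell wet weight (g/g ww).
"""

from __future__ import annotations

from typing import Self

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ChemicalProperties",
    "CellLineProperties",
    "PlateSpec",
    "ToxicityParams",
    "ViabilityObservation",
]


class _Record(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class ChemicalProperties(_Record):
    """Physicochemical parameters of one test chemical.

    ``henry_kaw`` is the dimensionless air-water partition coefficient
    (C_air / C_water at equilibrium); a value of 0 disables volatilization.
    """

    name: str
    cas: str = ""
    log_kow: float
    molar_volume: float = Field(gt=0, description="LeBas molar volume, cm^3/mol")
    atomic_diffusion_volume: float = Field(gt=0, description="Fuller diffusion volume")
    mw: float = Field(gt=0, description="molecular weight, g/mol")
    k_deg_water: float = Field(ge=0, description="first-order loss in medium, 1/h")
    k_deg_air: float = Field(ge=0, description="first-order loss in headspace, 1/h")
    henry_kaw: float = Field(ge=0, description="dimensionless air-water partition")


class CellLineProperties(_Record):
    """Cell-line parameters for the four-stage cell-cycle population model."""

    name: str
    stage_duration: tuple[float, float, float, float] = Field(
        description="residence time per cycle stage, h"
    )
    stage_mortality: tuple[float, float, float, float] = Field(
        description="background death rate per stage, 1/h"
    )
    cell_mass: float = Field(gt=0, description="g wet weight per cell")
    cell_volume: float = Field(gt=0, description="cm^3 per cell")
    f_water: float = Field(ge=0, le=1)
    f_lipid: float = Field(ge=0, le=1)
    f_protein: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> Self:
        if any(d <= 0 for d in self.stage_duration):
            raise ValueError("stage durations must be > 0")
        if any(m < 0 for m in self.stage_mortality):
            raise ValueError("stage mortalities must be >= 0")
        total = self.f_water + self.f_lipid + self.f_protein
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"composition fractions must sum to 1 (got {total!r})"
            )
        return self

    @property
    def density(self) -> float:
        """Cell density, g wet weight per cm^3."""
        return self.cell_mass / self.cell_volume


class PlateSpec(_Record):
    """Geometry of one well of a tissue-culture plate format."""

    name: str
    well_total_volume: float = Field(gt=0, description="cm^3")
    well_bottom_area: float = Field(gt=0, description="cm^2")
    well_wall_area_per_volume: float = Field(
        gt=0, description="plastic contact area per cm^3 of medium, cm^2/cm^3"
    )
    headspace_volume: float = Field(gt=0, description="cm^3 at the assay volume")

    def with_assay_volume(self, assay_volume: float) -> "PlateSpec":
        """Return a copy with headspace derived from the assay volume."""
        if assay_volume <= 0:
            raise ValueError("assay volume must be > 0")
        if assay_volume >= self.well_total_volume:
            raise ValueError(
                f"assay volume {assay_volume} cm^3 exceeds well volume "
                f"{self.well_total_volume} cm^3"
            )
        return self.model_copy(
            update={"headspace_volume": self.well_total_volume - assay_volume}
        )


class ToxicityParams(_Record):
    """No-effect concentration and killing-rate constant for one
    chemical / cell-line pair.

    ``nec`` is an intracellular concentration in g chemical per g cell wet
    weight; ``kt`` scales the added death rate with the excess of the
    intracellular concentration above ``nec`` (units 1/((g/g ww) h)).
    """

    chemical: str
    cell_line: str
    nec: float = Field(ge=0)
    kt: float = Field(ge=0)

    @property
    def key(self) -> tuple[str, str]:
        return (self.chemical, self.cell_line)


class ViabilityObservation(_Record):
    """One experimental (nominal concentration, viability) pair."""

    concentration: float = Field(ge=0, description="nominal medium conc., mol/cm^3")
    viability_exp: float = Field(ge=0, le=1)
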