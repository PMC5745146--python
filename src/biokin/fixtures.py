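"""Deterministic generators for reference chemicals, cell lines, plates,
PBK specs and synthetic viability observations.

Everything here is synthetic: numeric defaults are chosen once for good
conditioning of the downstream tests and demos (dose-response curves
spanning roughly 0.05-0.95 viability over the default concentration
grids) and make no claim to describe any real chemical or cell line.
All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

from . import cells as cd
from .engine import ExposureConfig, SimulationContext, TableSet, core_model
from .pbk import Absorption, Clearance, Compartment, PBKModelSpec
from .types import (
    CellLineProperties,
    ChemicalProperties,
    PlateSpec,
    ToxicityParams,
    ViabilityObservation,
)

__all__ = [
    "PROFILE_KINDS",
    "make_chemical",
    "make_cell_line",
    "make_plate",
    "make_toxicity",
    "make_tables",
    "make_context",
    "make_viability_observations",
    "make_one_compartment_pbk",
    "make_multi_compartment_pbk",
    "write_fixture_set",
]

PROFILE_KINDS = ("volatile", "lipophilic", "hydrophilic", "inert")

_CHEMICAL_DEFAULTS = {
    # kind: (log_kow, molar_volume, diffusion_volume, mw,
    #        k_deg_water, k_deg_air, henry_kaw)
    "volatile": (2.0, 98.0, 95.0, 120.0, 0.0, 0.01, 0.25),
    "lipophilic": (4.5, 240.0, 260.0, 310.0, 0.002, 0.0, 1e-7),
    "hydrophilic": (-0.5, 85.0, 90.0, 150.0, 0.01, 0.0, 1e-8),
    "inert": (1.0, 130.0, 140.0, 200.0, 0.0, 0.0, 0.0),
}


def make_chemical(kind: str = "inert", seed: int = 0) -> ChemicalProperties:
    """A synthetic chemical of the requested character.

    ``volatile`` has an appreciable air-water partition (Kaw >= 0.1),
    ``lipophilic`` a high log Kow (>= 4), ``hydrophilic`` a low log Kow
    and negligible Kaw, and ``inert`` no degradation at all.  The seed
    perturbs nothing structural, only the label, so records for the same
    (kind, seed) are identical.
    """
    if kind not in PROFILE_KINDS:
        raise ValueError(f"kind must be one of {PROFILE_KINDS}")
    lk, vm, dv, mw, kw, ka, kaw = _CHEMICAL_DEFAULTS[kind]
    return ChemicalProperties(
        name=f"{kind}-{seed}", cas=f"0000-{seed:02d}-{len(kind)}",
        log_kow=lk, molar_volume=vm, atomic_diffusion_volume=dv, mw=mw,
        k_deg_water=kw, k_deg_air=ka, henry_kaw=kaw)


def make_cell_line(doubling_time: float = 24.0,
                   mortality: float = 0.0,
                   name: str = "synthetic-line") -> CellLineProperties:
    """A cell line whose chemical-free population doubles in
    ``doubling_time`` hours.

    Uses four equal stage durations; for equal stages with per-stage exit
    rate k and division doubling the stage-4 outflow, the dominant growth
    eigenvalue is ``lambda = k (2^(1/4) - 1)``, so k is chosen as
    ``(ln 2 / doubling_time) / (2^(1/4) - 1)``.  Verified against the
    numerical eigenvalue at construction.
    """
    if doubling_time <= 0:
        raise ValueError("doubling_time must be > 0")
    lam = math.log(2.0) / doubling_time
    k = lam / (2.0 ** 0.25 - 1.0)
    cell = CellLineProperties(
        name=name,
        stage_duration=(1.0 / k,) * 4,
        stage_mortality=(mortality,) * 4,
        cell_mass=3.5e-9, cell_volume=3.5e-9,
        f_water=0.7, f_lipid=0.1, f_protein=0.2)
    if mortality == 0.0:
        got = cd.growth_rate(cell)
        assert abs(got - lam) <= 0.01 * lam, (got, lam)
    return cell


def make_plate(name: str = "96-well") -> PlateSpec:
    """A 96-well-like plate at 0.2 cm^3 assay volume."""
    return PlateSpec(name=name, well_total_volume=0.36,
                     well_bottom_area=0.32,
                     well_wall_area_per_volume=6.3,
                     headspace_volume=0.16)


def make_toxicity(chemical: str, cell_line: str,
                  nec: float = 5e-5, kt: float = 500.0) -> ToxicityParams:
    return ToxicityParams(chemical=chemical, cell_line=cell_line,
                          nec=nec, kt=kt)


def make_tables(kind: str = "inert", seed: int = 0,
                doubling_time: float = 24.0,
                nec: float = 5e-5, kt: float = 500.0) -> TableSet:
    """A complete, internally consistent table set for one chemical."""
    chem = make_chemical(kind, seed)
    cell = make_cell_line(doubling_time)
    plate = make_plate()
    tox = make_toxicity(chem.name, cell.name, nec=nec, kt=kt)
    return TableSet.from_records([chem], [cell], [plate], [tox])


def make_context(kind: str = "inert", seed: int = 0,
                 doubling_time: float = 24.0, total_time: float = 48.0,
                 assay_volume: float = 0.2, output_grid: float = 1.0,
                 **fate_kwargs) -> SimulationContext:
    """A ready SimulationContext for the fixture chemical/cell/plate."""
    from .fate import FateConfig

    return SimulationContext(
        chem=make_chemical(kind, seed), cell=make_cell_line(doubling_time),
        plate=make_plate(), assay_volume=assay_volume,
        total_time=total_time, output_grid=output_grid,
        fate_config=FateConfig(**fate_kwargs))


#: Nominal medium concentrations (mol/cm^3) spanning the response of the
#: default fixture toxicity parameters over 48 h.
DEFAULT_CONCENTRATIONS = tuple(float(c) for c in
                               np.geomspace(2e-8, 2e-6, 8))


def make_viability_observations(nec: float, kt: float,
                                concentrations=DEFAULT_CONCENTRATIONS,
                                noise_sd: float = 0.0, seed: int = 0,
                                context: SimulationContext | None = None,
                                n_cells: float = 1e5,
                                ) -> list[ViabilityObservation]:
    """Model-generated (concentration, viability) pairs with optional
    seeded Gaussian noise, clamped to [0, 1]."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    context = context or make_context()
    rng = np.random.default_rng(seed)
    obs = []
    for c in concentrations:
        res = core_model(float(c), 0.0, n_cells, nec, kt, context,
                         end_only=True)
        v = min(res.viability_end, 1.0)
        if noise_sd > 0:
            v = float(np.clip(v + rng.normal(0.0, noise_sd), 0.0, 1.0))
        obs.append(ViabilityObservation(concentration=float(c),
                                        viability_exp=v))
    return obs


def make_one_compartment_pbk(v: float = 42.0, cl: float = 2.0,
                             body_weight: float = 70.0,
                             ka: float = 1e3) -> PBKModelSpec:
    """A spec that reduces the engine to one-compartment kinetics
    dC/dt = -(cl/v) C after (near-instantaneous) oral absorption.

    The single tissue is flagged as liver and carries a linear intrinsic
    clearance, so the closed forms AUC = dose/cl and Cmax = dose/v hold.
    """
    if v <= 0 or cl < 0:
        raise ValueError("v must be > 0 and cl >= 0")
    return PBKModelSpec(
        body_weight=body_weight, cardiac_output=400.0,
        compartments=(Compartment(name="body", volume=v, blood_flow=390.0,
                                  partition_coefficient=1.0, is_liver=True),),
        absorption=Absorption(oral_ka=ka, oral_fraction_absorbed=1.0),
        clearance=Clearance(hepatic_clint=cl),
        route="oral")


def make_multi_compartment_pbk(body_weight: float = 70.0,
                               route: str = "oral") -> PBKModelSpec:
    """A small five-compartment body (liver, kidney, fat, skin, rest)
    with linear hepatic clearance; synthetic parameters."""
    comps = (
        Compartment(name="liver", volume=1.8, blood_flow=90.0,
                    partition_coefficient=2.0, is_liver=True),
        Compartment(name="kidney", volume=0.31, blood_flow=70.0,
                    partition_coefficient=1.5),
        Compartment(name="fat", volume=10.0, blood_flow=20.0,
                    partition_coefficient=8.0),
        Compartment(name="skin", volume=2.6, blood_flow=20.0,
                    partition_coefficient=1.2, is_skin=True),
        Compartment(name="rest", volume=35.0, blood_flow=150.0,
                    partition_coefficient=1.1),
    )
    return PBKModelSpec(
        body_weight=body_weight, cardiac_output=360.0, compartments=comps,
        absorption=Absorption(oral_ka=1.0, oral_fraction_absorbed=0.9,
                              dermal_kp=0.01, skin_area=100.0,
                              vehicle_concentration=10.0),
        clearance=Clearance(hepatic_clint=30.0, renal_ke=0.2),
        route=route)


def write_fixture_set(directory: str | Path, kind: str = "inert",
                      seed: int = 0) -> dict[str, Path]:
    """Write a complete ready-to-run input set (four tables, a run
    configuration and a PBK spec) to ``directory``."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    chem = make_chemical(kind, seed)
    cell = make_cell_line()
    plate = make_plate()
    tox = make_toxicity(chem.name, cell.name)

    paths: dict[str, Path] = {}

    def _write(name: str, header: list[str], rows: list[list]) -> None:
        p = directory / f"{name}.csv"
        lines = [",".join(header)]
        lines += [",".join(repr(x) if isinstance(x, float) else str(x)
                           for x in row) for row in rows]
        p.write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths[name] = p

    _write("chemicals",
           ["name", "cas", "log_kow", "molar_volume",
            "atomic_diffusion_volume", "mw", "k_deg_water", "k_deg_air",
            "henry_kaw"],
           [[chem.name, chem.cas, chem.log_kow, chem.molar_volume,
             chem.atomic_diffusion_volume, chem.mw, chem.k_deg_water,
             chem.k_deg_air, chem.henry_kaw]])
    _write("cell_lines",
           ["name"] + [f"stage_duration_{i}" for i in range(1, 5)]
           + [f"stage_mortality_{i}" for i in range(1, 5)]
           + ["cell_mass", "cell_volume", "f_water", "f_lipid", "f_protein"],
           [[cell.name, *cell.stage_duration, *cell.stage_mortality,
             cell.cell_mass, cell.cell_volume, cell.f_water, cell.f_lipid,
             cell.f_protein]])
    _write("plates",
           ["name", "well_total_volume", "well_bottom_area",
            "well_wall_area_per_volume", "headspace_volume"],
           [[plate.name, plate.well_total_volume, plate.well_bottom_area,
             plate.well_wall_area_per_volume, plate.headspace_volume]])
    _write("toxicity", ["chemical", "cell_line", "nec", "kt"],
           [[tox.chemical, tox.cell_line, tox.nec, tox.kt]])

    config = {
        "tables": {k: str(paths[k]) for k in
                   ("chemicals", "cell_lines", "plates", "toxicity")},
        "exposure": {
            "mode": "single",
            "concentrations": list(DEFAULT_CONCENTRATIONS),
            "total_time": 48.0,
            "n_cells_initial": 1e5,
            "assay_volume": 0.2,
            "chemical": chem.name,
            "cell_line": cell.name,
            "plate": plate.name,
            "output_grid": 1.0,
        },
        "fate": {},
    }
    cfg_path = directory / "run_config.json"
    cfg_path.write_text(json.dumps(config, indent=2) + "\n", encoding="utf-8")
    paths["run_config"] = cfg_path

    pbk_path = directory / "pbk_spec.json"
    pbk_path.write_text(
        make_multi_compartment_pbk().model_dump_json(indent=2) + "\n",
        encoding="utf-8")
    paths["pbk_spec"] = pbk_path
    return paths
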