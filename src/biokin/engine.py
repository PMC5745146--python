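"""The virtual cell based assay engine.

Assembles the well fate model and the cell-cycle/toxicity model into one
coupled ODE system and runs it in single- and repeated-exposure modes.

State vector (10 components):

``[a_dissolved, a_headspace, a_plastic, a_cells, a_degraded, a_debris,
n_1, n_2, n_3, n_4]``

with chemical amounts in mol and cell counts per stage.  In
instantaneous-equilibrium uptake mode the first slot instead holds the
combined medium+cell amount, which is algebraically re-partitioned at
every derivative evaluation (and in the output series) so that the
intracellular concentration always sits at the cell-water partition
equilibrium with the medium.

The whole engine is deterministic: the control (zero-concentration)
population used as the viability denominator is the matrix exponential of
the linear stage-transition system, and a treated run at zero
concentration is by construction identical to it (viability exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.integrate import odeint, solve_ivp
from scipy.linalg import expm

from . import cells as cd
from .fate import FateConfig, FateCoefficients, derive_fate_coefficients, fate_derivatives
from .types import CellLineProperties, ChemicalProperties, PlateSpec, ToxicityParams

__all__ = [
    "ExposureConfig",
    "SimulationContext",
    "SimulationResult",
    "TableSet",
    "core_model",
    "simulate_single_exposure",
    "simulate_repeated_exposure",
    "mass_balance",
]

RTOL = 1e-8
ATOL_FLOOR = 1e-30


class IntegrationError(RuntimeError):
    """Raised when the stiff solver fails; carries the last good time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time {last_time:.6g} h)")
        self.last_time = last_time


class ExposureConfig(BaseModel):
    """Run settings for one exposure simulation."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    mode: Literal["single", "repeated"] = "single"
    concentrations: tuple[float, ...] = ()   # single mode, mol/cm^3
    concentration: float | None = None       # repeated mode, mol/cm^3
    dose_interval: float | None = Field(default=None, description="h")
    n_doses: int | None = None
    total_time: float = Field(gt=0, description="h")
    n_cells_initial: float = Field(gt=0)
    assay_volume: float = Field(gt=0, description="cm^3")
    chemical: str
    cell_line: str
    plate: str
    output_grid: float = Field(default=0.5, gt=0, description="h")

    @model_validator(mode="after")
    def _check(self):
        if self.mode == "single":
            if len(self.concentrations) < 1:
                raise ValueError("single mode requires >= 1 concentration")
            if any(c < 0 for c in self.concentrations):
                raise ValueError("concentrations must be >= 0")
        else:
            if self.concentration is None or self.concentration < 0:
                raise ValueError("repeated mode requires a concentration >= 0")
            if not self.dose_interval or self.dose_interval <= 0:
                raise ValueError("repeated mode requires dose_interval > 0")
            if not self.n_doses or self.n_doses < 1:
                raise ValueError("repeated mode requires n_doses >= 1")
            if self.n_doses * self.dose_interval > self.total_time:
                raise ValueError("n_doses * dose_interval must be <= total_time")
        return self


@dataclass
class TableSet:
    """The four validated input tables, keyed for lookup."""

    chemicals: dict[str, ChemicalProperties]
    cell_lines: dict[str, CellLineProperties]
    plates: dict[str, PlateSpec]
    toxicity: dict[tuple[str, str], ToxicityParams]

    @classmethod
    def from_records(cls, chemicals, cell_lines, plates, toxicity) -> "TableSet":
        return cls(
            chemicals={c.name: c for c in chemicals},
            cell_lines={c.name: c for c in cell_lines},
            plates={p.name: p for p in plates},
            toxicity={t.key: t for t in toxicity},
        )

    def lookup(self, config: ExposureConfig):
        for attr, key in (("chemicals", config.chemical),
                          ("cell_lines", config.cell_line),
                          ("plates", config.plate)):
            if key not in getattr(self, attr):
                raise KeyError(f"unknown {attr[:-1]} key {key!r}")
        tox_key = (config.chemical, config.cell_line)
        if tox_key not in self.toxicity:
            raise KeyError(f"unknown toxicity key {tox_key!r}")
        return (self.chemicals[config.chemical],
                self.cell_lines[config.cell_line],
                self.plates[config.plate],
                self.toxicity[tox_key])


@dataclass
class SimulationContext:
    """Everything core_model needs besides its five contract parameters."""

    chem: ChemicalProperties
    cell: CellLineProperties
    plate: PlateSpec
    assay_volume: float
    total_time: float
    output_grid: float = 0.5
    fate_config: FateConfig = field(default_factory=FateConfig)
    coeffs: FateCoefficients | None = None

    def __post_init__(self) -> None:
        self.plate = self.plate.with_assay_volume(self.assay_volume)
        if self.coeffs is None:
            self.coeffs = derive_fate_coefficients(
                self.chem, self.cell, self.plate, self.fate_config)


@dataclass
class SimulationResult:
    """Sampled trajectories of one exposure run."""

    frame: pd.DataFrame
    viability_end: float
    nominal_concentration: float
    final_state: np.ndarray  # raw 10-component state at t_end

    @property
    def n_total_end(self) -> float:
        return float(self.frame["n_total"].iloc[-1])


def _split_equilibrium(a_combined: float, n_total: float,
                       ctx: SimulationContext) -> tuple[float, float]:
    """Partition a combined medium+cell amount so c_cell is at the
    cell-water equilibrium with the medium."""
    v_cells_eff = n_total * ctx.cell.cell_volume * ctx.coeffs.k_cell_water
    frac_d = ctx.assay_volume / (ctx.assay_volume + v_cells_eff)
    a_d = a_combined * frac_d
    return a_d, a_combined - a_d


def _rhs_factory(ctx: SimulationContext, nec: float, kt: float):
    """Fused derivative of the 10-component well state.

    Mathematically identical to composing :func:`biokin.fate.
    fate_derivatives` with the cell-dynamics terms (the composition is
    asserted equal in the test suite); constants are hoisted out of the
    per-step closure for speed.
    """
    chem, cell, plate = ctx.chem, ctx.cell, ctx.plate
    coeffs, cfg = ctx.coeffs, ctx.fate_config
    eq_mode = cfg.equilibrium_uptake
    debris = cfg.debris_sink

    v_m = ctx.assay_volume
    v_head = plate.headspace_volume
    volatile = coeffs.k_vol > 0 and coeffs.kaw > 0 and not cfg.sealed
    kvol_area = coeffs.k_vol * plate.well_bottom_area
    inv_kaw = 1.0 / coeffs.kaw if coeffs.kaw > 0 else 0.0
    k_on_wall = coeffs.k_plastic_on * plate.well_wall_area_per_volume * v_m
    k_off = coeffs.k_plastic_off
    kdw, kda = chem.k_deg_water, (0.0 if cfg.sealed else chem.k_deg_air)
    mw, cell_mass, cell_vol = chem.mw, cell.cell_mass, cell.cell_volume
    density = cell.density
    k_cw = coeffs.k_cell_water
    k_up = cfg.k_up
    v_cell_eff = cell_vol * k_cw  # per cell, for the equilibrium split
    k_stage = 1.0 / np.asarray(cell.stage_duration)
    mortality = np.asarray(cell.stage_mortality)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        n = np.maximum(y[6:10], 0.0)
        n_total = n[0] + n[1] + n[2] + n[3]
        a_h, a_p = y[1], y[2]
        if eq_mode:
            a_mc = max(y[0], 0.0)
            frac_d = v_m / (v_m + n_total * v_cell_eff)
            a_d = a_mc * frac_d
            a_c = a_mc - a_d
        else:
            a_d, a_c = max(y[0], 0.0), max(y[3], 0.0)

        c_cell = (a_c * mw / (n_total * cell_mass)) if n_total > 0 else 0.0

        c_d = a_d / v_m
        dd = dh = 0.0
        if volatile:
            flux = kvol_area * (c_d - (a_h / v_head) * inv_kaw)
            dd -= flux
            dh += flux
        sorb = k_on_wall * c_d - k_off * a_p
        dd -= sorb
        loss_w = kdw * a_d
        loss_a = kda * a_h
        dd -= loss_w
        dh -= loss_a
        if cfg.sealed:
            dh = 0.0
        dg = loss_w + loss_a

        k_tox = kt * (c_cell - nec) if c_cell > nec else 0.0
        outflow = (k_stage + mortality + k_tox) * n
        deaths = float((mortality + k_tox) @ n)
        per_cell = a_c / n_total if n_total > 0 else 0.0
        release = deaths * per_cell

        out = np.empty(10)
        if eq_mode:
            out[0] = dd - (release if debris else 0.0)
            out[3] = 0.0
        else:
            c_eq = c_cell * density / mw / k_cw
            upt = k_up * n_total * cell_vol * (c_d - c_eq)
            out[0] = dd - upt + (0.0 if debris else release)
            out[3] = upt - release
        out[1], out[2], out[4] = dh, sorb, dg
        out[5] = release if debris else 0.0
        out[6] = 2.0 * k_stage[3] * n[3] - outflow[0]
        out[7] = k_stage[0] * n[0] - outflow[1]
        out[8] = k_stage[1] * n[1] - outflow[2]
        out[9] = k_stage[2] * n[2] - outflow[3]
        return out

    return rhs


def _integrate(ctx: SimulationContext, nec: float, kt: float,
               y0: np.ndarray, t0: float, t1: float,
               t_eval: np.ndarray,
               fast: bool = False) -> tuple[np.ndarray, np.ndarray]:
    mass_scale = max(float(np.sum(y0[:6])), 1e-15)
    atol = np.full(10, ATOL_FLOOR)
    atol[:6] = mass_scale * 1e-14 + ATOL_FLOOR
    atol[6:] = max(float(np.sum(y0[6:])), 1.0) * 1e-12
    rhs = _rhs_factory(ctx, nec, kt)
    if fast and t_eval.size == 2:
        # endpoint-only fast path through the lower-overhead LSODA wrapper
        y, info = odeint(rhs, y0, t_eval, rtol=RTOL, atol=atol,
                         tfirst=True, full_output=True, mxstep=100000)
        if info["message"] != "Integration successful.":
            raise IntegrationError(info["message"], float(info["tcur"][-1]))
        return t_eval, y.T
    sol = solve_ivp(rhs, (t0, t1), y0,
                    method="LSODA", rtol=RTOL, atol=atol, t_eval=t_eval,
                    dense_output=False)
    if not sol.success:
        raise IntegrationError(sol.message, sol.t[-1] if sol.t.size else t0)
    return sol.t, sol.y


def _control_total(cell: CellLineProperties, n0_stage: np.ndarray,
                   t: float) -> float:
    """Control population total at time t: matrix exponential of the
    linear growth system (exact, chemical-free)."""
    return float((expm(cd.stage_transition_matrix(cell) * t) @ n0_stage).sum())


def _frame_from(ctx: SimulationContext, t: np.ndarray, y: np.ndarray,
                mass_expected: np.ndarray) -> pd.DataFrame:
    eq_mode = ctx.fate_config.equilibrium_uptake
    n = np.maximum(y[6:10], 0.0)
    n_total = n.sum(axis=0)
    if eq_mode:
        a_d = np.empty_like(t)
        a_c = np.empty_like(t)
        for j in range(t.size):
            a_d[j], a_c[j] = _split_equilibrium(max(y[0, j], 0.0),
                                                n_total[j], ctx)
    else:
        a_d, a_c = y[0], y[3]
    c_cell = np.where(
        n_total > 0,
        a_c * ctx.chem.mw / (np.maximum(n_total, 1e-300) * ctx.cell.cell_mass),
        0.0)
    return pd.DataFrame({
        "time": t,
        "a_dissolved": a_d,
        "a_headspace": y[1],
        "a_plastic": y[2],
        "a_cells": a_c,
        "a_degraded": y[4],
        "a_debris": y[5],
        "n_stage_1": n[0], "n_stage_2": n[1],
        "n_stage_3": n[2], "n_stage_4": n[3],
        "n_total": n_total,
        "c_medium": a_d / ctx.assay_volume,
        "c_headspace": y[1] / ctx.plate.headspace_volume,
        "c_cell": c_cell,
        "mass_expected": mass_expected,
    })


def _initial_state(ctx: SimulationContext, c_medium_0: float, c_cell_0: float,
                   n_cells_0: float) -> np.ndarray:
    y0 = np.zeros(10)
    n_stage = cd.stable_stage_distribution(ctx.cell) * n_cells_0
    a_cells = c_cell_0 * n_cells_0 * ctx.cell.cell_mass / ctx.chem.mw
    y0[3] = a_cells
    y0[0] = c_medium_0 * ctx.assay_volume
    if ctx.fate_config.equilibrium_uptake:
        y0[0] += a_cells
        y0[3] = 0.0
    y0[6:10] = n_stage
    return y0


def _output_times(t0: float, t1: float, grid: float) -> np.ndarray:
    n_steps = max(int(np.ceil((t1 - t0) / grid)), 1)
    return np.linspace(t0, t1, n_steps + 1)


def core_model(c_medium_0: float, c_cell_0: float, n_cells_0: float,
               nec: float, kt: float, context: SimulationContext,
               end_only: bool = False) -> SimulationResult:
    """Integrate one exposure from the given initial conditions.

    The five contract parameters are the nominal medium concentration
    (mol/cm^3), the initial intracellular concentration (g/g ww), the
    initial cell count, and the two toxicity parameters.  The control
    population for the viability denominator is the chemical-free linear
    growth solution from the same initial count.

    With ``end_only`` the trajectory is sampled at the endpoints only
    (fast path for parameter fitting); the dynamics are unchanged.
    """
    if min(c_medium_0, c_cell_0, n_cells_0) < 0 or nec < 0 or kt < 0:
        raise ValueError("core_model parameters must be >= 0")
    ctx = context
    y0 = _initial_state(ctx, c_medium_0, c_cell_0, n_cells_0)
    t_end = ctx.total_time
    t_eval = (np.array([0.0, t_end]) if end_only
              else _output_times(0.0, t_end, ctx.output_grid))
    t, y = _integrate(ctx, nec, kt, y0, 0.0, t_end, t_eval, fast=end_only)
    mass0 = float(np.sum(y0[:6]))
    frame = _frame_from(ctx, t, y, np.full(t.size, mass0))

    # when the killing term provably never switches on, the treated run
    # coincides with the control in exact arithmetic: c_cell is bounded by
    # its initial value and the full-partition equilibrium of the total
    # inventory, neither of which can exceed NEC here
    total_conc = (c_medium_0 + y0[3] / ctx.assay_volume
                  if not ctx.fate_config.equilibrium_uptake
                  else y0[0] / ctx.assay_volume)
    c_cell_bound = max(
        c_cell_0,
        ctx.coeffs.k_cell_water * total_conc * ctx.chem.mw / ctx.cell.density)
    if (c_medium_0 == 0.0 and c_cell_0 == 0.0) or kt == 0.0 \
            or c_cell_bound <= nec:
        viab = 1.0  # treated run is the control run
    else:
        control = _control_total(ctx.cell, y0[6:10], t_end)
        viab = cd.viability(float(np.sum(np.maximum(y[6:10, -1], 0.0))), control)
    return SimulationResult(frame=frame, viability_end=viab,
                            nominal_concentration=c_medium_0,
                            final_state=y[:, -1].copy())


def simulate_single_exposure(config: ExposureConfig,
                             tables: TableSet) -> list[SimulationResult]:
    """One independent run per nominal concentration, each from identical
    fresh initial conditions."""
    chem, cell, plate, tox = tables.lookup(config)
    results = []
    for conc in config.concentrations:
        ctx = SimulationContext(chem=chem, cell=cell, plate=plate,
                                assay_volume=config.assay_volume,
                                total_time=config.total_time,
                                output_grid=config.output_grid)
        results.append(core_model(conc, 0.0, config.n_cells_initial,
                                  tox.nec, tox.kt, ctx))
    return results


def simulate_repeated_exposure(config: ExposureConfig,
                               tables: TableSet,
                               fate_config: FateConfig | None = None,
                               reset_headspace: bool = True,
                               retain_plastic: bool = True) -> SimulationResult:
    """Repeated dosing of a single nominal concentration.

    At every dosing time the medium is refreshed to the nominal
    concentration; by default the headspace is reset to zero (plate
    opened), plastic-bound chemical is retained (same physical plate), and
    the cells with their intracellular burden carry over.  Dosing is
    handled by restarting the integrator at each event time.
    """
    if config.mode != "repeated":
        raise ValueError("config.mode must be 'repeated'")
    chem, cell, plate, tox = tables.lookup(config)
    ctx = SimulationContext(chem=chem, cell=cell, plate=plate,
                            assay_volume=config.assay_volume,
                            total_time=config.total_time,
                            output_grid=config.output_grid,
                            fate_config=fate_config or FateConfig())
    conc = float(config.concentration)
    dose_times = [i * config.dose_interval for i in range(config.n_doses)]
    boundaries = dose_times + [config.total_time]

    y = _initial_state(ctx, conc, 0.0, config.n_cells_initial)
    frames = []
    expected = float(np.sum(y[:6]))
    for seg, (t0, t1) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        if seg > 0:  # re-dose: refresh medium, optionally vent headspace
            if ctx.fate_config.equilibrium_uptake:
                _, a_c = _split_equilibrium(max(y[0], 0.0),
                                            float(np.sum(y[6:10])), ctx)
                y[0] = conc * ctx.assay_volume + a_c
            else:
                y[0] = conc * ctx.assay_volume
            if reset_headspace:
                y[1] = 0.0
            if not retain_plastic:
                y[2] = 0.0
            expected = float(np.sum(y[:6]))
        if t1 <= t0:
            continue
        t_eval = _output_times(t0, t1, ctx.output_grid)
        t, ys = _integrate(ctx, tox.nec, tox.kt, y, t0, t1, t_eval)
        frames.append(_frame_from(ctx, t, ys, np.full(t.size, expected)))
        y = ys[:, -1].copy()

    frame = pd.concat(frames, ignore_index=True)
    frame = frame.drop_duplicates(subset="time", keep="last").reset_index(drop=True)
    n_end = float(frame["n_total"].iloc[-1])
    if conc == 0.0:
        viab = 1.0
    else:
        n0_stage = cd.stable_stage_distribution(cell) * config.n_cells_initial
        viab = cd.viability(n_end, _control_total(cell, n0_stage,
                                                  config.total_time))
    return SimulationResult(frame=frame, viability_end=viab,
                            nominal_concentration=conc, final_state=y)


MASS_POOLS = ("a_dissolved", "a_headspace", "a_plastic", "a_cells",
              "a_degraded", "a_debris")


def mass_balance(result: SimulationResult) -> float:
    """Maximum relative drift of total chemical mass over the run.

    The total includes the degradation and debris sinks and is compared
    against the expected inventory (initial mass plus dosing events).
    Zero initial mass returns 0 by convention.
    """
    frame = result.frame
    total = sum(frame[p].to_numpy() for p in MASS_POOLS)
    expected = frame["mass_expected"].to_numpy()
    denom = float(np.max(expected))
    if denom == 0.0:
        return 0.0
    return float(np.max(np.abs(total - expected)) / denom)
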