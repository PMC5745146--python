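"""Fit the two toxicity parameters (NEC, kt) to paired
concentration/viability observations.

The objective is the sum of squared viability residuals

    error = sum_i (viability_exp_i - viability_sim_i)^2

where each simulated viability comes from a full well simulation at the
observation's nominal concentration.  Minimisation is a bounded
derivative-free simplex search (Nelder-Mead), deterministic for identical
inputs; ties on plateaus are broken toward the smallest kt, then the
smallest nec.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .engine import SimulationContext, core_model
from .types import ViabilityObservation

__all__ = ["FitOptions", "FitResult", "viability_error", "fit",
           "optimization_check"]


@dataclass(frozen=True)
class FitOptions:
    kt_max: float = 1e5          # upper bound on kt, 1/((g/g ww) h)
    nec_max: float | None = None  # default: max equilibrium c_cell over obs
    max_evaluations: int = 500
    f_tol: float = 1e-10         # stop when error improvement falls below


@dataclass
class FitResult:
    nec_hat: float
    kt_hat: float
    error: float
    n_evaluations: int
    converged: bool
    per_point: pd.DataFrame
    warning: str | None = None


def _simulated_viabilities(nec: float, kt: float,
                           observations: list[ViabilityObservation],
                           context: SimulationContext,
                           n_cells: float) -> np.ndarray:
    """One simulated end-point viability per observation.

    Observations whose nominal concentration cannot raise the
    intracellular concentration above NEC even at full partition
    equilibrium are returned as exactly 1 without integrating: the
    killing term never switches on, so treated and control populations
    coincide (the medium concentration in a single-exposure well never
    exceeds its starting value).
    """
    ctx = context
    # sup over time of c_cell (g/g ww) for a well started at c_medium_0
    bound = (ctx.coeffs.k_cell_water * ctx.chem.mw / ctx.cell.density)
    out = np.empty(len(observations))
    for i, obs in enumerate(observations):
        if kt == 0.0 or bound * obs.concentration <= nec:
            out[i] = 1.0
            continue
        try:
            res = core_model(obs.concentration, 0.0, n_cells, nec, kt,
                             context, end_only=True)
        except Exception as exc:
            raise RuntimeError(
                f"simulation failed at concentration {obs.concentration!r}: {exc}"
            ) from exc
        out[i] = res.viability_end
    return out


def viability_error(nec: float, kt: float,
                    observations: list[ViabilityObservation],
                    context: SimulationContext,
                    n_cells: float = 1e5) -> float:
    """Sum of squared (experimental - simulated) viability residuals."""
    if not observations:
        raise ValueError("at least one observation required")
    sim = _simulated_viabilities(nec, kt, observations, context, n_cells)
    exp = np.array([o.viability_exp for o in observations])
    return float(np.sum((exp - sim) ** 2))


def _per_point_table(nec: float, kt: float, observations, context,
                     n_cells: float) -> pd.DataFrame:
    sim = _simulated_viabilities(nec, kt, observations, context, n_cells)
    exp = np.array([o.viability_exp for o in observations])
    return pd.DataFrame({
        "concentration": [o.concentration for o in observations],
        "viability_exp": exp,
        "viability_sim": sim,
        "squared_residual": (exp - sim) ** 2,
    })


def _default_nec_max(observations, context) -> float:
    """Upper NEC bound: the largest equilibrium intracellular
    concentration (g/g ww) reachable from the observed nominal
    concentrations if all chemical partitioned into the cells' wet mass
    at the cell-water coefficient."""
    c_max = max(o.concentration for o in observations)
    ctx = context
    c_eq = (ctx.coeffs.k_cell_water * c_max * ctx.chem.mw / ctx.cell.density)
    return max(c_eq * 2.0, 1e-12)


def fit(initial_nec: float, initial_kt: float,
        observations: list[ViabilityObservation],
        context: SimulationContext,
        options: FitOptions | None = None,
        n_cells: float = 1e5) -> FitResult:
    """Bounded Nelder-Mead minimisation of the viability error over
    (nec, kt).

    Returns ``converged=False`` (never raises) when the evaluation budget
    is exhausted.  If every observed viability is >= 0.99 the data carry
    no toxicity signal and ``kt_hat = 0`` is reported with a warning.
    """
    if initial_nec < 0 or initial_kt < 0:
        raise ValueError("initial values must be >= 0")
    options = options or FitOptions()
    nec_max = options.nec_max or _default_nec_max(observations, context)
    kt_max = options.kt_max

    if all(o.viability_exp >= 0.99 for o in observations):
        err = viability_error(0.0, 0.0, observations, context, n_cells)
        return FitResult(
            nec_hat=0.0, kt_hat=0.0, error=err, n_evaluations=1,
            converged=True,
            per_point=_per_point_table(0.0, 0.0, observations, context, n_cells),
            warning="all observed viabilities >= 0.99: kt not identifiable, "
                    "reported as 0")

    exp = np.array([o.viability_exp for o in observations])
    n_evals = 0

    # optimise in units of the starting guess (the bounds are far from
    # the optimum and would make the simplex steps wildly anisotropic);
    # a ~1e-13-scale regulariser breaks plateau ties toward small kt then
    # small nec without moving any genuine optimum (it is far below the
    # 1e-10 convergence scale)
    scale = np.array([min(max(initial_nec, nec_max * 1e-3), nec_max),
                      min(max(initial_kt, kt_max * 1e-4), kt_max)])
    z_hi = np.array([nec_max, kt_max]) / scale

    def objective(z: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        nec = float(np.clip(z[0], 0.0, z_hi[0])) * scale[0]
        kt = float(np.clip(z[1], 0.0, z_hi[1])) * scale[1]
        sim = _simulated_viabilities(nec, kt, observations, context, n_cells)
        err = float(np.sum((exp - sim) ** 2))
        return err + 1e-13 * (kt / kt_max + 1e-3 * nec / nec_max)

    z0 = np.clip(np.array([initial_nec, initial_kt]) / scale, 0.0, z_hi)
    best = None
    while n_evals < options.max_evaluations:
        res = minimize(
            objective, z0, method="Nelder-Mead",
            bounds=[(0.0, z_hi[0]), (0.0, z_hi[1])],
            options={"maxfev": options.max_evaluations - n_evals,
                     "fatol": options.f_tol, "xatol": 1e-4,
                     "initial_simplex": _initial_simplex(z0, z_hi)})
        if best is None or res.fun < best.fun:
            improved = best is None or best.fun - res.fun > options.f_tol
            best = res
        else:
            improved = False
        if best.fun <= max(options.f_tol, 1e-10) or not improved:
            break
        z0 = best.x  # deterministic restart from the incumbent
    res = best

    nec_hat = float(np.clip(res.x[0], 0.0, z_hi[0])) * scale[0]
    kt_hat = float(np.clip(res.x[1], 0.0, z_hi[1])) * scale[1]
    table = _per_point_table(nec_hat, kt_hat, observations, context, n_cells)
    return FitResult(nec_hat=nec_hat, kt_hat=kt_hat,
                     error=float(table["squared_residual"].sum()),
                     n_evaluations=n_evals,
                     converged=bool(res.success),
                     per_point=table)


def _initial_simplex(z0: np.ndarray, z_hi: np.ndarray) -> np.ndarray:
    """A simplex stepping ~35% of the guess in each direction, kept
    inside the bounds even when the guess sits on one."""
    simplex = np.tile(z0, (3, 1))
    for i in range(2):
        step = 0.35 * max(z0[i], 0.1)
        z_try = z0[i] + step
        simplex[i + 1, i] = z_try if z_try <= z_hi[i] else z0[i] - step
    return simplex


def optimization_check(nec: float, kt: float,
                       observations: list[ViabilityObservation],
                       context: SimulationContext,
                       n_cells: float = 1e5) -> FitResult:
    """Evaluate supplied (nec, kt) against observations without fitting."""
    table = _per_point_table(nec, kt, observations, context, n_cells)
    return FitResult(nec_hat=nec, kt_hat=kt,
                     error=float(table["squared_residual"].sum()),
                     n_evaluations=1, converged=True, per_point=table)
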