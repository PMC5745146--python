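"""In vitro - in vivo extrapolation: couple the PBK engine with the
cell-population toxicity model to map external doses to predicted
viabilities, and invert the mapping.

For each external dose the PBK model yields the target-compartment
concentration time course C(t) (mg/L); the four-stage cell population is
then driven by the time-varying death rate ``kt * max(0, c_cell(t) - nec)``
where the cell-experienced concentration is obtained from C(t) through a
configurable unit bridge (default: tissue density 1 kg/L, so
1 mg/L = 1e-6 g per g wet weight).  Viability is the treated/control
population ratio at the end of the exposure window.  This uses the full
dynamic profile, not a scalar summary; a scalar-Cmax mode is available
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from . import cells as cd
from .pbk import PBKModelSpec, PBKResult, simulate_pbk
from .types import CellLineProperties, ToxicityParams

__all__ = ["ExtrapolationTable", "driven_viability", "build_dose_response",
           "extrapolate"]

MG_PER_L_TO_G_PER_G = 1e-6  # at tissue density 1 kg/L


@dataclass
class ExtrapolationTable:
    """Monotone dose -> internal metric -> predicted viability mapping."""

    frame: pd.DataFrame  # columns: dose (mg/kg), internal_metric (mg/L), viability_pred
    target_compartment: str = "venous"
    metric_kind: str = "cmax"
    exposure_duration: float = 24.0  # h

    def __post_init__(self) -> None:
        d = self.frame["dose"].to_numpy()
        v = self.frame["viability_pred"].to_numpy()
        if not np.all(np.diff(d) > 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("viability_pred must be non-increasing in dose")
        if np.any(v < 0) or np.any(v > 1 + 1e-9):
            raise ValueError("viabilities must lie in [0, 1]")


def driven_viability(time: np.ndarray, concentration: np.ndarray,
                     tox: ToxicityParams, cell: CellLineProperties,
                     t_end: float | None = None,
                     bridge: float = MG_PER_L_TO_G_PER_G) -> float:
    """Viability of a cell population exposed to a time-varying external
    concentration profile (mg/L).

    The profile is linearly interpolated; the control denominator is the
    chemical-free linear growth solution over the same window.
    """
    t_end = float(time[-1]) if t_end is None else t_end
    n0 = cd.stable_stage_distribution(cell)

    def k_tox(t: float) -> float:
        c = float(np.interp(t, time, concentration)) * bridge
        return tox.kt * max(0.0, c - tox.nec)

    if tox.kt == 0 or np.all(concentration * bridge <= tox.nec):
        return 1.0

    def rhs(t, n):
        return cd.cycle_derivatives(np.maximum(n, 0.0), cell, k_tox(t))

    sol = solve_ivp(rhs, (0.0, t_end), n0, method="LSODA",
                    rtol=1e-8, atol=1e-12, t_eval=[t_end])
    if not sol.success:
        raise RuntimeError(f"effect-model integration failed: {sol.message}")
    treated = float(np.maximum(sol.y[:, -1], 0.0).sum())
    control = float((expm(cd.stage_transition_matrix(cell) * t_end) @ n0).sum())
    return cd.viability(treated, control)


def build_dose_response(pbk_spec: PBKModelSpec, tox: ToxicityParams,
                        cell: CellLineProperties, dose_grid,
                        route: str | None = None, t_end: float = 24.0,
                        target_compartment: str = "venous",
                        metric_kind: str = "cmax",
                        bridge: float = MG_PER_L_TO_G_PER_G,
                        use_full_profile: bool = True,
                        grid: float = 0.1) -> ExtrapolationTable:
    """Build the dose -> internal metric -> predicted viability table.

    ``dose_grid`` is in mg/kg body weight, converted to absolute doses via
    the spec's body weight.  With ``use_full_profile`` (default) the
    effect model is driven by the whole concentration time course; with it
    off, a constant exposure at the scalar metric (Cmax or AUC/t average)
    is used instead.
    """
    doses = np.asarray(sorted(dose_grid), dtype=float)
    if doses.size < 2:
        raise ValueError("dose grid needs at least 2 doses")
    if np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be strictly increasing")
    if route is not None and route != pbk_spec.route:
        pbk_spec = pbk_spec.model_copy(update={"route": route})

    rows = []
    for dose_mg_kg in doses:
        dose = dose_mg_kg * pbk_spec.body_weight
        if dose == 0.0:
            rows.append((0.0, 0.0, 1.0))
            continue
        try:
            res = simulate_pbk(pbk_spec, dose, t_end=t_end, grid=grid)
        except Exception as exc:
            raise RuntimeError(f"PBK simulation failed at dose "
                               f"{dose_mg_kg!r} mg/kg: {exc}") from exc
        series = _target_series(res, target_compartment)
        if metric_kind == "cmax":
            metric = float(series.max())
        elif metric_kind == "auc_average":
            metric = float(np.trapezoid(series, res.time) / (res.time[-1] - res.time[0]))
        else:
            raise ValueError(f"unknown metric kind {metric_kind!r}")
        if use_full_profile:
            viab = driven_viability(res.time, series, tox, cell,
                                    t_end=t_end, bridge=bridge)
        else:
            const = np.full_like(res.time, metric)
            viab = driven_viability(res.time, const, tox, cell,
                                    t_end=t_end, bridge=bridge)
        rows.append((float(dose_mg_kg), metric, min(viab, 1.0)))

    frame = pd.DataFrame(rows, columns=["dose", "internal_metric",
                                        "viability_pred"])
    # clip ~1e-9-scale solver noise so the table is exactly monotone
    frame["viability_pred"] = np.minimum.accumulate(frame["viability_pred"])
    return ExtrapolationTable(frame=frame,
                              target_compartment=target_compartment,
                              metric_kind=metric_kind,
                              exposure_duration=t_end)


def _target_series(res: PBKResult, compartment: str) -> np.ndarray:
    if compartment == "venous":
        return res.venous
    if compartment in res.concentrations.columns:
        return res.concentrations[compartment].to_numpy()
    raise KeyError(f"unknown target compartment {compartment!r}")


def extrapolate(table: ExtrapolationTable, dose: float | None = None,
                viability: float | None = None) -> float:
    """Interpolate the table: dose -> predicted viability, or
    viability -> smallest consistent dose (inverse lookup).

    Piecewise-linear in both directions; on flat viability segments the
    inverse returns the smallest consistent dose.  Out-of-range queries
    raise with the covered interval.
    """
    if (dose is None) == (viability is None):
        raise ValueError("provide exactly one of dose= or viability=")
    d = table.frame["dose"].to_numpy()
    v = table.frame["viability_pred"].to_numpy()

    if dose is not None:
        if not d[0] <= dose <= d[-1]:
            raise ValueError(f"dose {dose} outside covered interval "
                             f"[{d[0]}, {d[-1]}]")
        return float(np.interp(dose, d, v))

    lo, hi = float(v.min()), float(v.max())
    if not lo <= viability <= hi:
        raise ValueError(f"viability {viability} outside covered interval "
                         f"[{lo}, {hi}]")
    # v is non-increasing in d; walk segments from low dose up and return
    # the smallest dose consistent with the query
    for i in range(d.size):
        if v[i] == viability:
            return float(d[i])
        if i + 1 < d.size and v[i] > viability > v[i + 1]:
            frac = (v[i] - viability) / (v[i] - v[i + 1])
            return float(d[i] + frac * (d[i + 1] - d[i]))
    raise ValueError("viability query not bracketed by the table")
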