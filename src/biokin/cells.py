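"""Cell-cycle population balance, intracellular partitioning and the
NEC/kt toxicity term.

The population is resolved into the four cell-cycle stages.  Cells leave
stage ``i`` at rate ``k_i = 1/stage_duration_i``; the outflow of stage 4
doubles into stage 1 (division).  Each stage carries a background
mortality and a shared chemical-induced death rate
``kt * max(0, c_cell - nec)``, where ``c_cell`` is the intracellular
concentration in g chemical per g cell wet weight.
"""

from __future__ import annotations

import numpy as np

from .fate import FateCoefficients
from .types import CellLineProperties, ChemicalProperties, ToxicityParams

__all__ = [
    "intracellular_concentration",
    "aqueous_equivalent",
    "uptake_flux",
    "toxic_rate",
    "cycle_derivatives",
    "stage_transition_matrix",
    "stable_stage_distribution",
    "growth_rate",
    "viability",
]


def intracellular_concentration(a_cells: float, n_total: float,
                                cell: CellLineProperties,
                                chem: ChemicalProperties) -> float:
    """Intracellular concentration c_cell in g/g wet weight from the total
    intracellular amount (mol) and the cell count."""
    if n_total <= 0:
        return 0.0
    return a_cells * chem.mw / (n_total * cell.cell_mass)


def aqueous_equivalent(c_cell: float, cell: CellLineProperties,
                       chem: ChemicalProperties,
                       coeffs: FateCoefficients) -> float:
    """Medium concentration (mol/cm^3) in equilibrium with ``c_cell``."""
    return c_cell * cell.density / chem.mw / coeffs.k_cell_water


def uptake_flux(c_medium: float, c_cell: float, chem: ChemicalProperties,
                cell: CellLineProperties, coeffs: FateCoefficients,
                n_total: float, k_up: float = 100.0) -> float:
    """Kinetic uptake flux medium -> cells, mol/h.

    First-order relaxation toward the cell-water partition equilibrium:
    ``flux = k_up * V_cells * (c_medium - c_cell_aqueous_equivalent)``.
    Negative flux means net efflux back to the medium.
    """
    if n_total < 0 or c_medium < 0 or c_cell < 0:
        raise ValueError("negative input to uptake_flux")
    if n_total == 0:
        return 0.0
    v_cells = n_total * cell.cell_volume
    return k_up * v_cells * (c_medium - aqueous_equivalent(c_cell, cell, chem, coeffs))


def toxic_rate(c_cell: float, tox: ToxicityParams) -> float:
    """Chemical-induced death rate, 1/h: ``kt * max(0, c_cell - nec)``."""
    return tox.kt * max(0.0, c_cell - tox.nec)


def cycle_derivatives(n_stage, cell: CellLineProperties,
                      k_tox: float = 0.0) -> np.ndarray:
    """d n_stage / dt for the four-stage cycle with division.

    ``k_tox`` is added uniformly to every stage's death rate.
    """
    n = np.asarray(n_stage, dtype=float)
    k = 1.0 / np.asarray(cell.stage_duration)
    m = np.asarray(cell.stage_mortality)
    out = np.empty(4)
    out[0] = 2.0 * k[3] * n[3] - (k[0] + m[0] + k_tox) * n[0]
    for i in range(1, 4):
        out[i] = k[i - 1] * n[i - 1] - (k[i] + m[i] + k_tox) * n[i]
    return out


def stage_transition_matrix(cell: CellLineProperties,
                            k_tox: float = 0.0) -> np.ndarray:
    """The 4x4 linear operator A with d n/dt = A n."""
    k = 1.0 / np.asarray(cell.stage_duration)
    m = np.asarray(cell.stage_mortality)
    a = np.diag(-(k + m + k_tox))
    for i in range(1, 4):
        a[i, i - 1] = k[i - 1]
    a[0, 3] += 2.0 * k[3]
    return a


def growth_rate(cell: CellLineProperties) -> float:
    """Asymptotic exponential growth rate (1/h): the dominant eigenvalue
    of the stage-transition matrix."""
    eig = np.linalg.eigvals(stage_transition_matrix(cell))
    return float(np.max(eig.real))


def stable_stage_distribution(cell: CellLineProperties) -> np.ndarray:
    """Normalised dominant right eigenvector: the asymptotic fraction of
    cells in each cycle stage."""
    a = stage_transition_matrix(cell)
    w, v = np.linalg.eig(a)
    vec = np.real(v[:, np.argmax(w.real)])
    vec = np.abs(vec)
    return vec / vec.sum()


def viability(n_total_treated: float, n_total_control: float) -> float:
    """Treated/control cell-count ratio at matched time points.

    Clamped at 1 + 1e-9; values may exceed 1 only through numerical noise.
    """
    if n_total_control <= 0:
        raise ValueError("control population extinct (n_total_control <= 0)")
    if n_total_treated < 0:
        raise ValueError("treated population negative")
    return min(n_total_treated / n_total_control, 1.0 + 1e-9)
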