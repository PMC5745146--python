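"""Readers and writers for the four standard input tables and for
tabular simulation output.

Input tables are CSV or TSV (auto-detected), UTF-8, header row required,
column names matched case-insensitively.  Each reader validates every row
against the corresponding domain record and reports schema problems by
column name and data problems by row number.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd
from pydantic import ValidationError

from .types import (
    CellLineProperties,
    ChemicalProperties,
    PlateSpec,
    ToxicityParams,
    ViabilityObservation,
)

__all__ = [
    "TableError",
    "SchemaError",
    "RowError",
    "read_chemical_table",
    "read_cell_line_table",
    "read_plate_table",
    "read_toxicity_table",
    "read_observations",
    "write_timeseries",
    "read_timeseries",
]

GAS_CONSTANT = 8.314462618  # J/(mol K)
ASSAY_TEMPERATURE = 310.15  # K, 37 C


class TableError(ValueError):
    """Base class for table reading problems."""


class SchemaError(TableError):
    """A required column is missing (named in the message)."""


class RowError(TableError):
    """A data row failed validation (1-based row number in the message)."""


def _load_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="", encoding="utf-8") as fh:
        sample = fh.read(4096)
    delimiter = "\t" if sample.count("\t") > sample.count(",") else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df

def _require(df: pd.DataFrame, columns: Sequence[str]) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"missing required column '{col}'")


def _float(raw: str, column: str, row: int) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise RowError(f"row {row}: non-numeric value {raw!r} in column '{column}'")


def _rows(df: pd.DataFrame, build: Callable[[dict, int], object]) -> list:
    out = []
    for i, (_, raw) in enumerate(df.iterrows(), start=1):
        try:
            out.append(build(raw.to_dict(), i))
        except ValidationError as exc:
            first = exc.errors()[0]
            field = ".".join(str(x) for x in first["loc"])
            raise RowError(f"row {i}: invalid '{field}': {first['msg']}") from exc
    return out


CHEMICAL_COLUMNS = (
    "name", "cas", "log_kow", "molar_volume", "atomic_diffusion_volume",
    "mw", "k_deg_water", "k_deg_air", "henry_kaw",
)


def read_chemical_table(path: str | Path) -> list[ChemicalProperties]:
    """Read a chemical-properties table.

    An optional ``henry_unit`` column may tag each row's Henry constant as
    ``dimensionless`` (the stored Kaw form, default) or ``pa_m3_per_mol``,
    which is converted via Kaw = H / (R T) at 310.15 K.
    """
    df = _load_frame(path)
    _require(df, CHEMICAL_COLUMNS)

    def build(raw: dict, i: int) -> ChemicalProperties:
        henry = _float(raw["henry_kaw"], "henry_kaw", i)
        unit = str(raw.get("henry_unit") or "dimensionless").strip().lower()
        if unit in ("pa_m3_per_mol", "pa.m3/mol", "pa*m3/mol"):
            henry = henry / (GAS_CONSTANT * ASSAY_TEMPERATURE)
        elif unit not in ("dimensionless", "kaw", ""):
            raise RowError(f"row {i}: unknown henry_unit {unit!r}")
        return ChemicalProperties(
            name=str(raw["name"]).strip(),
            cas=str(raw.get("cas") or "").strip(),
            log_kow=_float(raw["log_kow"], "log_kow", i),
            molar_volume=_float(raw["molar_volume"], "molar_volume", i),
            atomic_diffusion_volume=_float(
                raw["atomic_diffusion_volume"], "atomic_diffusion_volume", i
            ),
            mw=_float(raw["mw"], "mw", i),
            k_deg_water=_float(raw["k_deg_water"], "k_deg_water", i),
            k_deg_air=_float(raw["k_deg_air"], "k_deg_air", i),
            henry_kaw=henry,
        )

    records = _rows(df, build)
    _check_unique([r.name for r in records], "chemical name")
    return records


CELL_LINE_COLUMNS = (
    "name",
    "stage_duration_1", "stage_duration_2", "stage_duration_3", "stage_duration_4",
    "stage_mortality_1", "stage_mortality_2", "stage_mortality_3", "stage_mortality_4",
    "cell_mass", "cell_volume", "f_water", "f_lipid", "f_protein",
)


def read_cell_line_table(path: str | Path) -> list[CellLineProperties]:
    df = _load_frame(path)
    _require(df, CELL_LINE_COLUMNS)

    def build(raw: dict, i: int) -> CellLineProperties:
        return CellLineProperties(
            name=str(raw["name"]).strip(),
            stage_duration=tuple(
                _float(raw[f"stage_duration_{j}"], f"stage_duration_{j}", i)
                for j in range(1, 5)
            ),
            stage_mortality=tuple(
                _float(raw[f"stage_mortality_{j}"], f"stage_mortality_{j}", i)
                for j in range(1, 5)
            ),
            cell_mass=_float(raw["cell_mass"], "cell_mass", i),
            cell_volume=_float(raw["cell_volume"], "cell_volume", i),
            f_water=_float(raw["f_water"], "f_water", i),
            f_lipid=_float(raw["f_lipid"], "f_lipid", i),
            f_protein=_float(raw["f_protein"], "f_protein", i),
        )

    records = _rows(df, build)
    _check_unique([r.name for r in records], "cell line name")
    return records


PLATE_COLUMNS = (
    "name", "well_total_volume", "well_bottom_area",
    "well_wall_area_per_volume",
)


def read_plate_table(path: str | Path) -> list[PlateSpec]:
    """Read plate specifications.

    The headspace may be given directly (``headspace_volume`` column) or
    derived from an ``assay_volume`` column as total minus assay volume.
    """
    df = _load_frame(path)
    _require(df, PLATE_COLUMNS)
    if "headspace_volume" not in df.columns and "assay_volume" not in df.columns:
        raise SchemaError(
            "missing required column 'headspace_volume' (or 'assay_volume')"
        )

    def build(raw: dict, i: int) -> PlateSpec:
        total = _float(raw["well_total_volume"], "well_total_volume", i)
        if raw.get("headspace_volume") not in (None, "") and not pd.isna(
            raw.get("headspace_volume")
        ):
            headspace = _float(raw["headspace_volume"], "headspace_volume", i)
        else:
            assay = _float(raw["assay_volume"], "assay_volume", i)
            if assay >= total:
                raise RowError(
                    f"row {i}: assay_volume {assay} must be below "
                    f"well_total_volume {total}"
                )
            headspace = total - assay
        return PlateSpec(
            name=str(raw["name"]).strip(),
            well_total_volume=total,
            well_bottom_area=_float(raw["well_bottom_area"], "well_bottom_area", i),
            well_wall_area_per_volume=_float(
                raw["well_wall_area_per_volume"], "well_wall_area_per_volume", i
            ),
            headspace_volume=headspace,
        )

    records = _rows(df, build)
    _check_unique([r.name for r in records], "plate name")
    return records


TOXICITY_COLUMNS = ("chemical", "cell_line", "nec", "kt")


def read_toxicity_table(path: str | Path) -> list[ToxicityParams]:
    df = _load_frame(path)
    _require(df, TOXICITY_COLUMNS)

    def build(raw: dict, i: int) -> ToxicityParams:
        return ToxicityParams(
            chemical=str(raw["chemical"]).strip(),
            cell_line=str(raw["cell_line"]).strip(),
            nec=_float(raw["nec"], "nec", i),
            kt=_float(raw["kt"], "kt", i),
        )

    records = _rows(df, build)
    _check_unique([r.key for r in records], "(chemical, cell_line) key")
    return records


def read_observations(path: str | Path) -> list[ViabilityObservation]:
    """Read a two-column (concentration, viability) observations file."""
    df = _load_frame(path)
    _require(df, ("concentration", "viability"))

    def build(raw: dict, i: int) -> ViabilityObservation:
        return ViabilityObservation(
            concentration=_float(raw["concentration"], "concentration", i),
            viability_exp=_float(raw["viability"], "viability", i),
        )

    return _rows(df, build)


def _check_unique(keys: list, what: str) -> None:
    seen = set()
    for k in keys:
        if k in seen:
            raise RowError(f"duplicate {what}: {k!r}")
        seen.add(k)


def write_timeseries(result, path: str | Path) -> None:
    """Write a time series to CSV at full (round-trippable) precision.

    ``result`` is either a pandas DataFrame with a ``time`` column or an
    object exposing one as ``.frame``.
    """
    frame = getattr(result, "frame", result)
    if not isinstance(frame, pd.DataFrame):
        raise TypeError("result must be a DataFrame or expose .frame")
    if frame.empty:
        raise ValueError("refusing to write an empty time series")
    if "time" not in frame.columns:
        raise ValueError("time series must contain a 'time' column")
    frame.to_csv(path, index=False, float_format="%.17g",
                 quoting=csv.QUOTE_MINIMAL, lineterminator="\n")


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_timeseries`."""
    return pd.read_csv(path)
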