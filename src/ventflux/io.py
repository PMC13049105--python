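"""CSV readers/writers with schema validation and provenance headers.

All pipeline tables are UTF-8, comma-separated, decimal-point CSV with a
header row.  Files written by the package carry ``# key: value`` provenance
comment lines (tool version, config hash, seed) which readers skip.
Validation is schema-driven: required columns are hard errors; row-level
range violations are collected with line numbers and either raised (strict)
or warned about (lax).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["SchemaError", "SCHEMAS", "read_table", "write_table", "validate"]


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    dtype: str = "float"  # float | int | str
    required: bool = True
    bounds: tuple | None = None
    choices: tuple | None = None


SCHEMAS: dict[str, tuple[ColumnSpec, ...]] = {
    "ph_sensor": (
        ColumnSpec("timestamp", "str"),
        ColumnSpec("zone", "str"),
        ColumnSpec("ph_total", "float", bounds=(3.0, 9.5)),
        ColumnSpec("temperature_c", "float", bounds=(-2.0, 40.0)),
        ColumnSpec("salinity", "float", required=False, bounds=(0.0, 45.0)),
        ColumnSpec("depth_m", "float", required=False, bounds=(0.0, 50.0)),
    ),
    "o2_series": (
        ColumnSpec("chamber_id", "str"),
        ColumnSpec("tile_id", "str", required=False),
        ColumnSpec("mode", "str",
                   choices=("light", "dark", "control_light", "control_dark")),
        ColumnSpec("minute", "float", bounds=(0.0, 120.0)),
        ColumnSpec("o2_umol_l", "float", bounds=(0.0, 1000.0)),
    ),
    "cover": (
        ColumnSpec("tile_id", "str"),
        ColumnSpec("side", "str", choices=("front", "back")),
        ColumnSpec("time_point", "str"),
        ColumnSpec("species_id", "str"),
        ColumnSpec("squares_occupied", "int", bounds=(0, 25)),
    ),
    "registry": (
        ColumnSpec("species_id", "str"),
        ColumnSpec("taxon_group", "str"),
        ColumnSpec("roles", "str"),
        ColumnSpec("dry_weight_density", "float", bounds=(0.0, 50.0)),
    ),
    "model_input": (
        ColumnSpec("tile_id", "str"),
        ColumnSpec("community", "str",
                   choices=("calcifying", "mixed", "fleshy")),
        ColumnSpec("ph_zone", "str",
                   choices=("ambient", "low", "extreme_low")),
        ColumnSpec("time_days", "float", bounds=(0.0, 10000.0)),
        ColumnSpec("response", "float"),
        ColumnSpec("response_type", "str", required=False),
    ),
}

SCHEMAS["water_samples"] = (
    ColumnSpec("chamber_id", "str"),
    ColumnSpec("tile_id", "str", required=False),
    ColumnSpec("mode", "str",
               choices=("light", "dark", "control_light", "control_dark")),
    ColumnSpec("duration_h", "float", bounds=(0.0, 24.0)),
    ColumnSpec("at_start", "float", required=False, bounds=(0.0, 5000.0)),
    ColumnSpec("at_end", "float", required=False, bounds=(0.0, 5000.0)),
    ColumnSpec("nh4_start", "float", required=False, bounds=(0.0, 1000.0)),
    ColumnSpec("nh4_end", "float", required=False, bounds=(0.0, 1000.0)),
    ColumnSpec("no3_start", "float", required=False, bounds=(0.0, 1000.0)),
    ColumnSpec("no3_end", "float", required=False, bounds=(0.0, 1000.0)),
    ColumnSpec("po4_start", "float", required=False, bounds=(0.0, 1000.0)),
    ColumnSpec("po4_end", "float", required=False, bounds=(0.0, 1000.0)),
)


def validate(df: pd.DataFrame, schema_name: str) -> list[str]:
    """Return a list of row-level violations ('line N: message')."""
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    violations = []
    for col in SCHEMAS[schema_name]:
        if col.name not in df.columns:
            if col.required:
                raise SchemaError(
                    f"schema {schema_name!r}: missing required column {col.name!r}"
                )
            continue
        series = df[col.name]
        if col.dtype in ("float", "int"):
            series = pd.to_numeric(series, errors="coerce")
            bad = series.isna() & df[col.name].notna()
            for i in df.index[bad]:
                violations.append(f"line {i + 2}: {col.name} not numeric")
            if col.bounds is not None:
                lo, hi = col.bounds
                out = (series < lo) | (series > hi)
                for i in df.index[out.fillna(False)]:
                    violations.append(
                        f"line {i + 2}: {col.name}={series[i]} outside [{lo}, {hi}]"
                    )
        if col.choices is not None:
            bad = ~df[col.name].isin(col.choices)
            for i in df.index[bad]:
                violations.append(
                    f"line {i + 2}: {col.name}={df[col.name][i]!r} "
                    f"not in {col.choices}"
                )
    return violations


def read_table(path, schema_name: str, strict: bool = True) -> pd.DataFrame:
    """Read a CSV, coerce to schema types, and validate.

    Provenance comment lines starting with '#' are skipped.  In strict mode
    any row-level violation raises; in lax mode they are warned about.
    """
    df = pd.read_csv(path, comment="#")
    violations = validate(df, schema_name)
    if violations:
        msg = f"{path}: {len(violations)} schema violation(s): " + "; ".join(
            violations[:10]
        )
        if strict:
            raise SchemaError(msg)
        warnings.warn(msg, stacklevel=2)
    for col in SCHEMAS[schema_name]:
        if col.name in df.columns and col.dtype in ("float", "int"):
            df[col.name] = pd.to_numeric(df[col.name], errors="coerce")
    return df


def write_table(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a CSV with '# key: value' provenance header lines."""
    meta = {"tool": f"ventflux {__version__}"}
    meta.update(provenance or {})
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)
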