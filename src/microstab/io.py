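"""CSV readers/writers with explicit schemas.

Dialect: comma-separated, dot decimal, UTF-8, header row required.
Column names embed their units (``conc_ng_per_ml``, ``time_min``) so a
table cannot silently drift units.  Locale decimal commas are rejected
with a clear message rather than misparsed.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import SchemaError

__all__ = ["SCHEMAS", "read_table", "write_table"]

#: schema name -> {column: dtype}, dtype in {"float", "int", "str"}
SCHEMAS: dict[str, dict[str, str]] = {
    "calibration": {
        "nominal_ng_per_ml": "float",
        "replicate": "int",
        "response_ratio": "float",
    },
    "qc": {
        "level_label": "str",
        "nominal_ng_per_ml": "float",
        "replicate": "int",
        "conc_ng_per_ml": "float",
    },
    "qc_summary": {
        "level_label": "str",
        "nominal_ng_per_ml": "float",
        "mean_ng_per_ml": "float",
        "sd_ng_per_ml": "float",
        "n": "int",
    },
    "matrix_effect": {
        "group": "str",
        "analyte": "str",
        "replicate": "int",
        "peak_area": "float",
    },
    "depletion": {
        "time_min": "float",
        "replicate": "int",
        "conc_ng_per_ml": "float",
    },
    "depletion_mean": {
        "time_min": "float",
        "mean_conc_ng_per_ml": "float",
    },
    "agree": {
        "principle_id": "int",
        "score": "float",
        "weight": "int",
    },
}

_CASTERS = {"float": float, "int": int, "str": str}


def _detect_schema(columns) -> str | None:
    cols = set(columns)
    for name, schema in SCHEMAS.items():
        if cols == set(schema):
            return name
    return None


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a CSV and validate it against a named schema.

    Raises :class:`SchemaError` naming any missing or unexpected columns,
    and rejects non-numeric cells (e.g. locale decimal commas) in numeric
    columns with an explicit message.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    spec = SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = sorted(set(spec) - set(df.columns))
    extra = sorted(set(df.columns) - set(spec))
    if missing or extra:
        raise SchemaError(
            f"{Path(path).name}: schema {schema!r} mismatch; "
            f"missing columns {missing}, unexpected columns {extra}"
        )
    out = {}
    for col, kind in spec.items():
        if kind == "str":
            out[col] = df[col].astype(str)
            continue
        try:
            out[col] = df[col].astype(float)
        except ValueError as exc:
            bad = [v for v in df[col] if _not_numeric(v)][:3]
            hint = (
                " (decimal commas are not supported; use dot decimals)"
                if any("," in v for v in bad)
                else ""
            )
            raise SchemaError(
                f"{Path(path).name}: column {col!r} has non-numeric "
                f"values {bad}{hint}"
            ) from exc
        if kind == "int":
            out[col] = out[col].astype(int)
    return pd.DataFrame(out, columns=list(spec))


def _not_numeric(v: str) -> bool:
    try:
        float(v)
        return False
    except ValueError:
        return True


def write_table(df: pd.DataFrame, path, schema: str | None = None) -> None:
    """Write a CSV in the package dialect, optionally validating the
    schema first."""
    if schema is not None:
        spec = SCHEMAS[schema]
        missing = sorted(set(spec) - set(df.columns))
        if missing:
            raise SchemaError(f"cannot write {schema!r}: missing {missing}")
        df = df[list(spec)]
    df.to_csv(path, index=False)
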