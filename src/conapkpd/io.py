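"""File formats: observation tables (CSV), parameter configs (YAML/JSON).

Observation tables are animal-level records of destructive sampling — one row
per animal per analyte, columns ``group, animal_id, dose_mg_per_kg, time_h,
analyte, value, unit`` (an optional ``cona`` 0/1 column marks whether the
group received the ConA challenge; it defaults to 1).  Times are stored
relative to the drug dose (the model's clock, ConA at ``cona_time``); rows
whose unit is recorded in minutes (``min`` suffix) are converted to hours on
ingest.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import pandas as pd
import yaml

from .model import ModelParameters, OBSERVABLES, SchemaError

__all__ = [
    "ANALYTE_ALIASES",
    "normalize_analyte",
    "read_observation_table",
    "write_observation_table",
    "validate_observation_table",
    "read_parameters",
    "write_parameters",
    "reference_parameters",
]

REQUIRED_COLUMNS = ("group", "animal_id", "dose_mg_per_kg", "time_h", "analyte", "value", "unit")

# canonical analyte names plus the spellings commonly seen in lab exports
ANALYTE_ALIASES = {
    "grms55": "GRMS55", "grms-55": "GRMS55", "drug": "GRMS55",
    "tnfa": "TNFa", "tnf": "TNFa", "tnf-a": "TNFa", "tnf-alpha": "TNFa", "tnf-α": "TNFa",
    "ifng": "IFNg", "ifn": "IFNg", "ifn-g": "IFNg", "ifn-gamma": "IFNg", "ifn-γ": "IFNg",
    "il6": "IL6", "il-6": "IL6",
    "il10": "IL10", "il-10": "IL10",
    "alt": "ALT", "ast": "AST",
}


def normalize_analyte(name: str) -> str:
    """Map an analyte spelling onto the canonical set; SchemaError if unknown."""
    key = str(name).strip().lower()
    if key in ANALYTE_ALIASES:
        return ANALYTE_ALIASES[key]
    raise SchemaError(f"unknown analyte {name!r}; expected one of {OBSERVABLES}")


def validate_observation_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize an observation table in place conventions.

    Normalizes analyte names, converts minute-denominated times to hours,
    coerces the optional ``cona`` column to boolean (default True), and
    enforces positivity and the one-observation-per-animal-per-analyte rule.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"observation table missing column(s): {missing}")
    table = table.copy()
    table["analyte"] = [normalize_analyte(a) for a in table["analyte"]]

    # unit-aware time conversion: units like "ng/L @min" are not expected;
    # a unit string ending in "min" marks the *time* as recorded in minutes
    unit = table["unit"].astype(str)
    in_minutes = unit.str.strip().str.lower().str.endswith("min")
    if in_minutes.any():
        table.loc[in_minutes, "time_h"] = table.loc[in_minutes, "time_h"] / 60.0
        table.loc[in_minutes, "unit"] = (
            unit[in_minutes].str.strip().str.lower().str.removesuffix("min").str.rstrip(" @,;")
        )

    if "cona" not in table.columns:
        table["cona"] = True
    table["cona"] = table["cona"].astype(bool)
    table["time_h"] = table["time_h"].astype(float)
    table["value"] = table["value"].astype(float)
    table["dose_mg_per_kg"] = table["dose_mg_per_kg"].astype(float)

    bad = table.index[table["value"] <= 0]
    if len(bad):
        raise SchemaError(f"nonpositive value in row(s) {list(bad[:5])}")
    bad = table.index[table["time_h"] < 0]
    if len(bad):
        raise SchemaError(f"negative time in row(s) {list(bad[:5])}")
    dup = table.duplicated(subset=["animal_id", "analyte"], keep=False)
    if dup.any():
        raise SchemaError(
            "duplicate (animal_id, analyte) observation in row(s) "
            f"{list(table.index[dup][:5])}: destructive sampling allows one per animal"
        )
    return table


def read_observation_table(path) -> pd.DataFrame:
    """Read a CSV observation table and validate it."""
    table = pd.read_csv(path)
    return validate_observation_table(table)


def write_observation_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Parameter configs
# ---------------------------------------------------------------------------

_BASELINE_KEYS = ("R0_TNFa", "R0_IFNg", "R0_IL6", "R0_IL10", "R0_ALT", "R0_AST")


def _params_from_mapping(raw: dict) -> ModelParameters:
    if not isinstance(raw, dict):
        raise SchemaError("parameter config must be a mapping of name -> value")
    missing_baselines = [k for k in _BASELINE_KEYS if k not in raw]
    if missing_baselines:
        raise SchemaError(
            f"baselines required: supply {missing_baselines} (measured healthy-animal "
            "levels; they are not estimable from the diseased-group data)"
        )
    negative = [k for k, v in raw.items() if isinstance(v, (int, float)) and v < 0]
    if negative:
        raise SchemaError(f"negative parameter value(s) for {negative}")
    return ModelParameters.from_dict(raw)


def read_parameters(path) -> ModelParameters:
    """Load a full parameter vector from a YAML (or JSON) config file."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return _params_from_mapping(raw)


def write_parameters(params: ModelParameters, path) -> None:
    path = Path(path)
    flat = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(flat, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(flat, sort_keys=False))


def reference_parameters() -> ModelParameters:
    """The packaged reported parameter set (with the documented assumed baselines)."""
    resource = importlib.resources.files("conapkpd.data").joinpath("grms55_cona_mouse.yaml")
    raw = yaml.safe_load(resource.read_text())
    return _params_from_mapping(raw)
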