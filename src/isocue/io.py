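"""CSV schemas, validation and run configuration for the pipeline.

All tables are plain CSV with a header row, UTF-8, "." decimal separator and
empty fields for missing values. Validation reports every offending row with
its number rather than stopping at the first problem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from isocue.isotope import NATURAL_ABUNDANCE_AT

__all__ = [
    "RunConfig",
    "load_config",
    "SchemaError",
    "validate_kinetics",
    "validate_endpoints",
    "validate_soils",
    "validate_standards",
    "read_csv",
    "write_csv",
    "soil_water_lookup_from_report",
]

log = logging.getLogger("isocue")

KINETICS_COLUMNS = ["vial_id", "pool", "time_h", "atom_pct", "replicate", "batch_id"]
ENDPOINTS_COLUMNS = [
    "vial_id",
    "treatment",
    "moisture",
    "soil_id",
    "co2_ppm_t0",
    "co2_ppm_t24",
    "o_dna_ug",
    "at_dna_label",
    "at_dna_na",
    "incubation_h",
]
SOILS_COLUMNS = ["soil_id", "mbc_ug_per_g", "dna_ug_per_g", "gwc", "whc"]
STANDARDS_COLUMNS = ["batch_id", "known_atom_pct", "measured_atom_pct"]

VALID_TREATMENTS = {"vapor", "liquid_high", "liquid_low", "control"}
VALID_POOLS = {"soil", "external"}


class SchemaError(ValueError):
    """A CSV table violated its schema; ``errors`` lists row-level problems."""

    def __init__(self, table: str, errors: list[str]):
        self.table = table
        self.errors = errors
        msg = f"{table}: {len(errors)} schema problem(s)\n" + "\n".join(errors[:20])
        if len(errors) > 20:
            msg += f"\n... and {len(errors) - 20} more"
        super().__init__(msg)


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> list[str]:
    missing = [c for c in required if c not in df.columns]
    return [f"missing column {c!r}" for c in missing] if missing else []


def validate_kinetics(df: pd.DataFrame) -> list[str]:
    """Row-level schema problems of a kinetics table (empty list if valid)."""
    errors = _require_columns(df, KINETICS_COLUMNS, "kinetics")
    if errors:
        return errors
    if df.empty:
        return ["table has no data rows"]
    for i, r in df.iterrows():
        row = i + 2  # 1-based with header
        if r["pool"] not in VALID_POOLS:
            errors.append(f"row {row}: pool {r['pool']!r} not in {sorted(VALID_POOLS)}")
        if not np.isfinite(r["time_h"]) or r["time_h"] < 0:
            errors.append(f"row {row}: time_h must be a non-negative number")
        if not np.isfinite(r["atom_pct"]) or not 0 <= r["atom_pct"] <= 100:
            errors.append(f"row {row}: atom_pct must lie in [0, 100]")
    return errors


def validate_endpoints(df: pd.DataFrame) -> list[str]:
    errors = _require_columns(df, ENDPOINTS_COLUMNS, "endpoints")
    if errors:
        return errors
    if df.empty:
        return ["table has no data rows"]
    for i, r in df.iterrows():
        row = i + 2
        if r["treatment"] not in VALID_TREATMENTS:
            errors.append(
                f"row {row}: treatment {r['treatment']!r} not in {sorted(VALID_TREATMENTS)}"
            )
        for col in ("co2_ppm_t0", "co2_ppm_t24"):
            if not np.isfinite(r[col]) or r[col] < 0:
                errors.append(f"row {row}: {col} must be a non-negative number")
        if not np.isfinite(r["incubation_h"]) or r["incubation_h"] <= 0:
            errors.append(f"row {row}: incubation_h must be positive")
        if r["treatment"] != "control":
            if not np.isfinite(r["o_dna_ug"]) or r["o_dna_ug"] < 0:
                errors.append(f"row {row}: o_dna_ug must be non-negative for labeled vials")
    return errors


def validate_soils(df: pd.DataFrame) -> list[str]:
    errors = _require_columns(df, SOILS_COLUMNS, "soils")
    if errors:
        return errors
    if df.empty:
        return ["table has no data rows"]
    for i, r in df.iterrows():
        row = i + 2
        if not np.isfinite(r["mbc_ug_per_g"]) or r["mbc_ug_per_g"] <= 0:
            errors.append(f"row {row}: mbc_ug_per_g must be positive")
        if not np.isfinite(r["dna_ug_per_g"]) or r["dna_ug_per_g"] <= 0:
            errors.append(f"row {row}: dna_ug_per_g must be positive")
        if not np.isfinite(r["gwc"]) or r["gwc"] < 0:
            errors.append(f"row {row}: gwc cannot be negative")
    if df["soil_id"].duplicated().any():
        errors.append("duplicate soil_id values")
    return errors


def validate_standards(df: pd.DataFrame) -> list[str]:
    errors = _require_columns(df, STANDARDS_COLUMNS, "standards")
    if errors:
        return errors
    if df.empty:
        return ["table has no data rows"]
    for batch, sub in df.groupby("batch_id"):
        if len(sub) < 2:
            errors.append(f"batch {batch!r}: fewer than 2 standards")
        elif sub["known_atom_pct"].nunique() < 2:
            errors.append(f"batch {batch!r}: known standards all identical")
    return errors


def read_csv(path, table: str) -> pd.DataFrame:
    """Read and validate one of the standard tables; raises SchemaError."""
    validators = {
        "kinetics": validate_kinetics,
        "endpoints": validate_endpoints,
        "soils": validate_soils,
        "standards": validate_standards,
    }
    df = pd.read_csv(path)
    errors = validators[table](df)
    if errors:
        raise SchemaError(table, errors)
    return df


def write_csv(df: pd.DataFrame, path) -> None:
    """Write a table with ≥ 6 significant digits on floats."""
    df.to_csv(path, index=False, float_format="%.10g")


def soil_water_lookup_from_report(report: pd.DataFrame) -> dict:
    """(soil_id, moisture) → time-averaged soil-water atom% from a fit report.

    Only vapor-arm rows feed the lookup; liquid arms carry their measured
    enrichment in the endpoints table directly.
    """
    sub = report
    if "treatment" in report.columns:
        sub = report[report["treatment"] == "vapor"]
    return {
        (r["soil_id"], r["moisture"]): float(r["time_average"])
        for _, r in sub.iterrows()
        if np.isfinite(r.get("time_average", np.nan))
    }


@dataclass
class RunConfig:
    """Pipeline configuration; every default is overridable from a YAML file."""

    kinetics_csv: str | None = None
    endpoints_csv: str | None = None
    soils_csv: str | None = None
    standards_csv: str | None = None
    natural_abundance_at: float = NATURAL_ABUNDANCE_AT
    horizon_h: float = 24.0
    headspace_ml: float = 25.8
    soil_fresh_g: float = 0.4
    temperature_c: float = 25.0
    pressure_kpa: float = 101.325
    liquid_addition_at: float = 20.0
    fit_mode: str = "direct"  # direct (soil pool) or indirect (external pool)
    plateau_source: str = "external_fit"  # or "measured_24h" for indirect mode
    fix_at_in: bool = False
    excess_mode: bool = False
    seed: int = 0

    def vial(self):
        from isocue.cue import VialConfig

        return VialConfig(
            headspace_ml=self.headspace_ml,
            soil_fresh_g=self.soil_fresh_g,
            temperature_c=self.temperature_c,
            pressure_kpa=self.pressure_kpa,
        )


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def dump_config(config: RunConfig, path) -> None:
    """Echo the effective configuration into the output directory."""
    with open(path, "w") as fh:
        yaml.safe_dump(vars(config), fh, sort_keys=True)
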