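"""CSV schemas, readers and validation for the tracing pipeline.

All tables are long-format UTF-8 CSV with '.' decimals; times in hours,
concentrations in μM, intensities in arbitrary units, fluxes in
mmol/hr/L cell volume. Validation fails loudly with row-level diagnostics
rather than silently coercing bad input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exchange import GrowthCurve
from .mid import MassIsotopomerDistribution
from .quant import SimMeasurement

SIM_COLUMNS = ["sample_id", "time_hr", "mz61", "mz63", "mz64"]
MID_COLUMNS = ["sample_id", "analyte", "mass_shift", "intensity"]
GROWTH_COLUMNS = ["time_hr", "pcv_ul"]


@dataclass(frozen=True)
class ValidationIssue:
    table: str
    row: int | None
    message: str

    def __str__(self) -> str:
        loc = f"row {self.row}" if self.row is not None else "table"
        return f"{self.table} [{loc}]: {self.message}"


class BundleValidationError(ValueError):
    """Raised when a bundle fails validation; carries all issues found."""

    def __init__(self, issues: Sequence[ValidationIssue]):
        self.issues = list(issues)
        super().__init__(
            "validation failed:\n" + "\n".join(str(i) for i in self.issues)
        )


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping '#' comment lines (units headers)."""
    return pd.read_csv(path, comment="#")


def validate_sim_table(df: pd.DataFrame, name: str = "sim") -> list[ValidationIssue]:
    issues = _require_columns(df, SIM_COLUMNS, name)
    if issues:
        return issues
    for col in ("mz61", "mz63", "mz64"):
        bad = np.flatnonzero(df[col].to_numpy() < 0)
        issues += [
            ValidationIssue(name, int(i), f"negative intensity in {col}") for i in bad
        ]
    bad64 = np.flatnonzero(df["mz64"].to_numpy() <= 0)
    issues += [
        ValidationIssue(name, int(i), "internal-standard channel mz64 is zero")
        for i in bad64
    ]
    return issues


def validate_mid_table(df: pd.DataFrame, name: str = "mids") -> list[ValidationIssue]:
    issues = _require_columns(df, MID_COLUMNS, name)
    if issues:
        return issues
    bad = np.flatnonzero(df["intensity"].to_numpy() < 0)
    issues += [ValidationIssue(name, int(i), "negative intensity") for i in bad]
    for sid, grp in df.groupby("sample_id"):
        shifts = np.sort(grp["mass_shift"].to_numpy())
        if not np.array_equal(shifts, np.arange(shifts.size)):
            issues.append(
                ValidationIssue(name, None, f"{sid}: mass shifts not contiguous from 0")
            )
    return issues


def validate_growth_table(df: pd.DataFrame, name: str = "growth") -> list[ValidationIssue]:
    issues = _require_columns(df, GROWTH_COLUMNS, name)
    if issues:
        return issues
    t = df["time_hr"].to_numpy()
    if np.any(np.diff(t) <= 0):
        issues.append(ValidationIssue(name, None, "times not strictly increasing"))
    bad = np.flatnonzero(df["pcv_ul"].to_numpy() <= 0)
    issues += [ValidationIssue(name, int(i), "non-positive packed cell volume") for i in bad]
    return issues


def validate_bundle(bundle_dir: str | Path) -> list[ValidationIssue]:
    """Validate a simulated/assembled experiment bundle directory."""
    bundle = Path(bundle_dir)
    issues: list[ValidationIssue] = []
    manifest_path = bundle / "manifest.json"
    if not manifest_path.exists():
        return [ValidationIssue("manifest", None, "manifest.json missing")]
    manifest = json.loads(manifest_path.read_text())
    files = manifest.get("files", {})
    validators = {
        "growth": validate_growth_table,
        "medium_sim": validate_sim_table,
        "palmitate_mids": validate_mid_table,
        "histone_sim": validate_sim_table,
    }
    for key, validator in validators.items():
        rel = files.get(key)
        if rel is None:
            issues.append(ValidationIssue(key, None, "missing from manifest"))
            continue
        path = bundle / rel
        if not path.exists():
            issues.append(ValidationIssue(key, None, f"file {rel} not found"))
            continue
        issues += validator(read_table(path), name=key)
    return issues


def _require_columns(
    df: pd.DataFrame, cols: Sequence[str], name: str
) -> list[ValidationIssue]:
    missing = [c for c in cols if c not in df.columns]
    return [ValidationIssue(name, None, f"missing column {c!r}") for c in missing]


def sim_measurements_from_table(
    df: pd.DataFrame,
    *,
    is_volume_ml: float = 0.040,
    is_conc_um: float = 1000.0,
    sample_volume_ml: float = 0.200,
) -> list[SimMeasurement]:
    """Rows of a SIM table as :class:`SimMeasurement` objects."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SimMeasurement(
                sample_id=str(row.sample_id),
                time_hr=float(row.time_hr),
                i61=float(row.mz61),
                i63=float(row.mz63),
                i64=float(row.mz64),
                is_volume_ml=is_volume_ml,
                is_conc_um=is_conc_um,
                sample_volume_ml=sample_volume_ml,
                sample_type=str(getattr(row, "sample_type", "medium")),
            )
        )
    return out


def mids_from_table(df: pd.DataFrame) -> dict[str, MassIsotopomerDistribution]:
    """Raw MIDs keyed by sample_id (intensities normalized to fractions)."""
    out: dict[str, MassIsotopomerDistribution] = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("mass_shift")
        out[str(sid)] = MassIsotopomerDistribution(
            analyte=str(grp["analyte"].iloc[0]),
            fractions=grp["intensity"].to_numpy(float),
        )
    return out


def growth_from_table(df: pd.DataFrame, medium_volume_ml: float) -> GrowthCurve:
    return GrowthCurve(
        times=df["time_hr"].to_numpy(float),
        pcv=df["pcv_ul"].to_numpy(float),
        medium_volume_ml=medium_volume_ml,
    )
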