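"""Tidy schemas, readers/writers and validation for lesion and patient tables.

Two CSV tables drive the pipeline:

``measurements.csv`` — one radiographic observation per row
    patient_id, lesion_id, organ, lesion_class {target,nontarget,new},
    time (days since treatment start), long_diameter (mm, optional),
    volume (mm^3, optional), below_loq (bool), status_code
    ({CR,PR,SD,PD,NE}, non-target rows only).

``patients.csv`` — one patient per row
    patient_id, arm, treatment_group {TAR+Chemo, Chemo Alone}, age, gender,
    race, bmi, prior_surgery, line_of_therapy {first,second},
    os_time, os_event, pfs_time, pfs_event.

Missing values are empty fields; the dialect is comma-separated UTF-8 with
"." decimals, long format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import diameter_to_volume

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ORGAN_CATALOG",
    "SchemaError",
    "ValidationError",
    "ValidationReport",
    "load_measurements",
    "load_patients",
    "write_measurements",
    "write_patients",
    "fill_volumes",
    "validate_measurements",
    "validate_cohort",
]

#: The 15 metastatic sites modelled by default (config-overridable).
DEFAULT_ORGAN_CATALOG = [
    "abdomen",
    "bone",
    "brain_cns",
    "gi",
    "gr",
    "kidney",
    "liver",
    "LN",
    "lung",
    "muscle",
    "other",
    "pancreas",
    "peritoneum",
    "skin",
    "spleen",
]

LESION_CLASSES = ("target", "nontarget", "new")
STATUS_CODES = ("CR", "PR", "SD", "PD", "NE")

#: Earliest admissible baseline scan: 12 weeks before treatment start.
MIN_BASELINE_DAY = -84.0

MEASUREMENT_COLUMNS = [
    "patient_id",
    "lesion_id",
    "organ",
    "lesion_class",
    "time",
    "long_diameter",
    "volume",
    "below_loq",
    "status_code",
]
_MANDATORY_MEASUREMENT_COLUMNS = ["patient_id", "lesion_id", "organ", "lesion_class", "time"]

PATIENT_COLUMNS = [
    "patient_id",
    "arm",
    "treatment_group",
    "age",
    "gender",
    "race",
    "bmi",
    "prior_surgery",
    "line_of_therapy",
    "os_time",
    "os_event",
    "pfs_time",
    "pfs_event",
]


class SchemaError(ValueError):
    """A file does not match the declared column schema."""


class ValidationError(ValueError):
    """Rows violate table invariants; message carries row-level diagnostics."""


@dataclass
class ValidationReport:
    """Cross-table integrity report produced by :func:`validate_cohort`."""

    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    organ_lesion_counts: pd.Series | None = None
    visits_per_target_lesion: pd.Series | None = None

    @property
    def ok(self) -> bool:
        return not self.errors


def _coerce_bool(s: pd.Series) -> pd.Series:
    if s.dtype == bool:
        return s
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "": False,
    }
    return (
        s.astype("string")
        .fillna("")
        .str.strip()
        .str.lower()
        .map(mapping)
        .fillna(False)
        .astype(bool)
    )


def fill_volumes(df: pd.DataFrame, axis_ratio: float | None = None) -> pd.DataFrame:
    """Fill missing volumes from long diameters (idempotent).

    Rows with both fields already present are left untouched.
    """
    kwargs = {} if axis_ratio is None else {"axis_ratio": axis_ratio}
    df = df.copy()
    need = df["volume"].isna() & df["long_diameter"].notna()
    if need.any():
        df.loc[need, "volume"] = diameter_to_volume(df.loc[need, "long_diameter"].to_numpy(), **kwargs)
    return df


def validate_measurements(df: pd.DataFrame, organ_catalog=None) -> pd.DataFrame:
    """Check measurement-table invariants; raise with row diagnostics on failure."""
    catalog = list(organ_catalog) if organ_catalog is not None else DEFAULT_ORGAN_CATALOG
    problems = []

    bad_organ = ~df["organ"].isin(catalog)
    if bad_organ.any():
        problems.append(f"organs outside catalog: {sorted(df.loc[bad_organ, 'organ'].unique())}")
    bad_class = ~df["lesion_class"].isin(LESION_CLASSES)
    if bad_class.any():
        problems.append(f"invalid lesion_class values: {sorted(df.loc[bad_class, 'lesion_class'].unique())}")
    early = df["time"] < MIN_BASELINE_DAY
    if early.any():
        problems.append(
            f"{int(early.sum())} rows earlier than {MIN_BASELINE_DAY} days "
            f"(lesions {sorted(df.loc[early, 'lesion_id'].unique()[:5])})"
        )
    has_status = df["status_code"].notna()
    bad_status = has_status & ~df["status_code"].isin(STATUS_CODES)
    if bad_status.any():
        problems.append(f"invalid status codes: {sorted(df.loc[bad_status, 'status_code'].unique())}")

    key = ["patient_id", "lesion_id"]
    dup = df.duplicated(subset=key + ["time"], keep=False)
    if dup.any():
        problems.append(
            "duplicated (lesion_id, time) for lesions "
            f"{sorted(df.loc[dup, 'lesion_id'].unique()[:5].tolist())}"
        )
    else:
        # strictly increasing times within a lesion
        order = df.sort_values(key + ["time"]).groupby(key, sort=False)["time"].diff()
        nonmono = order.notna() & (order <= 0)
        if nonmono.any():
            bad = df.loc[nonmono[nonmono].index, "lesion_id"].unique()
            problems.append(f"non-monotone times within lesions {sorted(bad[:5].tolist())}")

    measured = df["lesion_class"].isin(["target"])
    missing_size = measured & df["volume"].isna() & df["long_diameter"].isna() & ~_coerce_bool(df["below_loq"])
    if missing_size.any():
        problems.append(
            f"{int(missing_size.sum())} target rows with neither diameter nor volume"
        )
    tgt_counts = df[df["lesion_class"] == "target"].groupby(key).size()
    single = tgt_counts[tgt_counts < 2]
    if len(single):
        problems.append(
            f"target lesions with < 2 time points: {sorted(single.index.get_level_values(1)[:5].tolist())}"
        )

    if problems:
        raise ValidationError("measurement table invalid: " + "; ".join(problems))
    return df


def load_measurements(path, organ_catalog=None, axis_ratio: float | None = None) -> pd.DataFrame:
    """Read and validate a measurements CSV, filling volumes from diameters.

    Raises :class:`SchemaError` for missing mandatory columns and
    :class:`ValidationError` (naming offending lesions) for invariant
    violations.
    """
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY_MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"measurements file missing mandatory columns {missing}")
    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[MEASUREMENT_COLUMNS].copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["lesion_id"] = df["lesion_id"].astype(str)
    df["time"] = df["time"].astype(float)
    df["below_loq"] = _coerce_bool(df["below_loq"])
    df = fill_volumes(df, axis_ratio=axis_ratio)
    validate_measurements(df, organ_catalog=organ_catalog)
    return df


def load_patients(path) -> pd.DataFrame:
    """Read and validate a patients CSV."""
    df = pd.read_csv(path)
    missing = [c for c in ["patient_id", "os_time", "os_event", "pfs_time", "pfs_event"] if c not in df.columns]
    if missing:
        raise SchemaError(f"patients file missing mandatory columns {missing}")
    for col in PATIENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[PATIENT_COLUMNS].copy()
    df["patient_id"] = df["patient_id"].astype(str)
    for col in ("os_event", "pfs_event", "prior_surgery"):
        df[col] = _coerce_bool(df[col])
    bad = (df["pfs_time"] < 0) | (df["os_time"] < df["pfs_time"])
    if bad.any():
        raise ValidationError(
            f"patients with os_time < pfs_time or negative pfs_time: "
            f"{sorted(df.loc[bad, 'patient_id'][:5].tolist())}"
        )
    if df["patient_id"].duplicated().any():
        raise ValidationError("duplicated patient_id in patients table")
    return df


def write_measurements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_patients(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def validate_cohort(measurements: pd.DataFrame, patients: pd.DataFrame) -> ValidationReport:
    """Cross-table referential integrity plus per-organ / per-lesion summaries."""
    report = ValidationReport()
    known = set(patients["patient_id"])
    orphan = ~measurements["patient_id"].isin(known)
    if orphan.any():
        for pid in sorted(measurements.loc[orphan, "patient_id"].unique()):
            report.errors.append(f"referential: patient {pid!r} in measurements missing from patients")
    silent = known - set(measurements["patient_id"])
    if silent:
        report.warnings.append(f"{len(silent)} patients have no lesion rows")

    report.organ_lesion_counts = (
        measurements.drop_duplicates(["patient_id", "lesion_id"]).groupby("organ").size().sort_index()
    )
    tgt = measurements[measurements["lesion_class"] == "target"]
    report.visits_per_target_lesion = tgt.groupby(["patient_id", "lesion_id"]).size()
    if not report.ok:
        logger.warning("cohort validation found %d errors", len(report.errors))
    return report
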