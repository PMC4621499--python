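"""Delimited-text I/O for vessel tables, subject tables, ground truth and
simulation manifests.

On-disk conventions: tab-separated with a header row; saturations are
percent on disk and fractions in memory; vessel types are "A"/"V"; diameter
sources are "RVA" (fundus photograph static analysis) or "OCT".
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .hemodynamics import DiameterSource, VesselMeasurement, VesselType
from .oxygen_extraction import Condition, SubjectRecord
from .synthetic_cohort import CohortSpec, GroundTruth
from .units import PERCENT

VESSEL_COLUMNS = [
    "subject_id", "condition", "vessel_id", "vessel_type", "mean_velocity_mm_s",
    "diameter_um", "diameter_source", "beta_deg", "distance_to_onh_um", "sao2_percent",
]
SUBJECT_COLUMNS = ["subject_id", "condition", "hb_g_ml", "pao2_mmhg"]

_TYPE_CODE = {VesselType.ARTERY: "A", VesselType.VEIN: "V"}
_TYPE_FROM_CODE = {"A": VesselType.ARTERY, "V": VesselType.VEIN}
_SOURCE_CODE = {DiameterSource.PHOTOGRAPH: "RVA", DiameterSource.OCT: "OCT"}
_SOURCE_FROM_CODE = {"RVA": DiameterSource.PHOTOGRAPH, "OCT": DiameterSource.OCT}


def vessel_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Flatten subject records into the on-disk vessel-table layout."""
    rows = []
    for rec in records:
        for v in rec.vessels:
            rows.append({
                "subject_id": rec.subject_id,
                "condition": rec.condition.value,
                "vessel_id": v.vessel_id,
                "vessel_type": _TYPE_CODE[v.vessel_type],
                "mean_velocity_mm_s": v.mean_velocity_mm_s,
                "diameter_um": v.diameter_um,
                "diameter_source": _SOURCE_CODE[v.diameter_source],
                "beta_deg": v.beta_deg,
                "distance_to_onh_um": v.distance_to_onh_um,
                "sao2_percent": PERCENT * v.measured_saturation,
            })
    return pd.DataFrame(rows, columns=VESSEL_COLUMNS)


def subject_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": rec.subject_id,
            "condition": rec.condition.value,
            "hb_g_ml": rec.hb_g_ml,
            "pao2_mmhg": rec.pao2_mmhg,
        }
        for rec in records
    ]
    return pd.DataFrame(rows, columns=SUBJECT_COLUMNS)


def write_tables(records: list[SubjectRecord], vessel_path, subject_path) -> None:
    vessel_frame(records).to_csv(vessel_path, sep="\t", index=False)
    subject_frame(records).to_csv(subject_path, sep="\t", index=False)


def read_vessel_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(VESSEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"vessel table {path} missing columns: {sorted(missing)}")
    return df


def read_subject_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"subject table {path} missing columns: {sorted(missing)}")
    return df


def vessels_from_frame(df: pd.DataFrame) -> list[VesselMeasurement]:
    """Build vessel measurements from (one subject-condition's) table rows."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            VesselMeasurement(
                vessel_id=str(row.vessel_id),
                vessel_type=_TYPE_FROM_CODE[str(row.vessel_type).upper()],
                mean_velocity_mm_s=float(row.mean_velocity_mm_s),
                diameter_um=float(row.diameter_um),
                beta_deg=float(row.beta_deg),
                distance_to_onh_um=float(row.distance_to_onh_um),
                measured_saturation=float(row.sao2_percent) / PERCENT,
                diameter_source=_SOURCE_FROM_CODE[str(row.diameter_source).upper()],
            )
        )
    return out


def subjects_from_tables(
    vessel_df: pd.DataFrame, subject_df: pd.DataFrame
) -> list[SubjectRecord]:
    """Join the vessel and subject tables into subject records."""
    records = []
    for row in subject_df.itertuples(index=False):
        mask = (vessel_df["subject_id"] == row.subject_id) & (
            vessel_df["condition"] == row.condition
        )
        sub = vessel_df[mask]
        if sub.empty:
            raise ValueError(
                f"no vessels for subject {row.subject_id} / {row.condition}"
            )
        records.append(
            SubjectRecord(
                subject_id=str(row.subject_id),
                condition=Condition(str(row.condition)),
                vessels=vessels_from_frame(sub),
                hb_g_ml=float(row.hb_g_ml),
                pao2_mmhg=float(row.pao2_mmhg),
            )
        )
    return records


def load_subjects(vessel_path, subject_path) -> list[SubjectRecord]:
    return subjects_from_tables(
        read_vessel_table(vessel_path), read_subject_table(subject_path)
    )


def ground_truth_frame(truths: list[GroundTruth]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": t.subject_id,
            "condition": t.condition.value,
            "total_flow_ul_min": t.total_flow_ul_min,
            "sat_cra_pct": PERCENT * t.sat_cra,
            "sat_crv_pct": PERCENT * t.sat_crv,
            "hb_g_ml": t.hb_g_ml,
            "pao2_mmhg": t.pao2_mmhg,
            "venous_po2_mmhg": t.venous_po2_mmhg,
            "content_cra_ml_ml": t.content_cra_ml_ml,
            "content_crv_ml_ml": t.content_crv_ml_ml,
            "ext_o2_ul_min": t.ext_o2_ul_min,
            "ext_o2_per_100g_ml_min": t.ext_o2_per_100g_ml_min,
        }
        for t in truths
    ]
    return pd.DataFrame(rows)


def read_phase_series(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a per-vessel phase-difference series (columns timestamp_s,
    delta_phi_rad); returns (timestamps, phases)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("timestamp_s", "delta_phi_rad"):
        if col not in df.columns:
            raise ValueError(f"phase series {path} missing column {col}")
    return df["timestamp_s"].to_numpy(float), df["delta_phi_rad"].to_numpy(float)


def write_manifest(path, spec: CohortSpec, files: dict[str, str]) -> None:
    """Record the generating spec and output files of a simulation run."""
    payload = {
        "spec": _jsonable(asdict(spec)),
        "files": files,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if hasattr(obj, "value"):
        return obj.value
    return obj
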