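"""Reading and writing machine recordings, nodule tables and result tables.

All files are plain CSV (comma separator, "." decimal, mandatory header,
UTF-8).  Machine exports with different column names are handled through an
explicit ``column_map``; a supplementary-style XLSX table of per-nodule
clinical parameters and CS/CE values can be ingested for re-analysis.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import KeyMismatchError, RecordingFormatError
from .mechanics import StiffnessProfile
from .types import MachineSpec, NoduleRecord, TestRecording

RECORDING_COLUMNS = ("time_ms", "load_N", "displacement_mm")

NODULE_COLUMNS = (
    "nodule_id",
    "patient_id",
    "A0_mm2",
    "H0_mm",
    "ct_hu",
    "dialysis",
    "cusp",
    "pattern_truth",
)


def read_load_test(
    path: str | Path,
    machine: MachineSpec | None = None,
    nodule_id: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> TestRecording:
    """Read and validate one load-test CSV.

    ``column_map`` maps the canonical names (time_ms, load_N,
    displacement_mm) to the names actually present in the file, covering
    machine exports with vendor headers.

    Raises :class:`RecordingFormatError` naming the offending row for any
    missing column, non-numeric cell, empty file, negative load, or
    non-monotone time/displacement.
    """
    path = Path(path)
    machine = machine or MachineSpec()
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise RecordingFormatError(f"{path}: empty file") from None
    if frame.empty:
        raise RecordingFormatError(f"{path}: no data rows")
    colmap = dict(column_map or {})
    series = {}
    for canon in RECORDING_COLUMNS:
        name = colmap.get(canon, canon)
        if name not in frame.columns:
            raise RecordingFormatError(f"{path}: missing column '{name}'")
        values = pd.to_numeric(frame[name], errors="coerce")
        if values.isna().any():
            row = int(values.isna().idxmax())
            raise RecordingFormatError(
                f"{path}: non-numeric value in column '{name}' at data row {row + 1}"
            )
        series[canon] = values.to_numpy(dtype=float)
    try:
        return TestRecording(
            time_ms=series["time_ms"],
            load_n=series["load_N"],
            displacement_mm=series["displacement_mm"],
            machine=machine,
            nodule_id=nodule_id if nodule_id is not None else path.stem,
        )
    except RecordingFormatError as exc:
        raise RecordingFormatError(f"{path}: {exc}") from None


def write_recording(rec: TestRecording, path: str | Path) -> None:
    """Write one recording to CSV with the canonical three columns."""
    frame = pd.DataFrame(
        {
            "time_ms": rec.time_ms,
            "load_N": rec.load_n,
            "displacement_mm": rec.displacement_mm,
        }
    )
    # 17 significant digits round-trip float64 exactly through read_load_test.
    frame.to_csv(path, index=False, float_format="%.17g")


def write_nodule_table(records: Sequence[NoduleRecord], path: str | Path) -> None:
    """Write the per-nodule geometry/covariate table to CSV."""
    rows = [
        {
            "nodule_id": r.nodule_id,
            "patient_id": r.patient_id,
            "A0_mm2": r.a0_mm2,
            "H0_mm": r.h0_mm,
            "ct_hu": r.ct_hu,
            "dialysis": r.dialysis,
            "cusp": r.cusp,
            "pattern_truth": r.pattern_truth,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(NODULE_COLUMNS)).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_nodule_table(path: str | Path) -> list[NoduleRecord]:
    """Read a per-nodule table written by :func:`write_nodule_table`."""
    frame = pd.read_csv(path)
    for col in ("nodule_id", "A0_mm2", "H0_mm"):
        if col not in frame.columns:
            raise RecordingFormatError(f"{path}: missing column '{col}'")
    records = []
    for _, row in frame.iterrows():
        records.append(
            NoduleRecord(
                nodule_id=str(row["nodule_id"]),
                patient_id=str(row.get("patient_id", "")),
                a0_mm2=float(row["A0_mm2"]),
                h0_mm=float(row["H0_mm"]),
                ct_hu=float(row.get("ct_hu", math.nan)),
                dialysis=_parse_bool(row.get("dialysis")),
                cusp=_parse_optional_str(row.get("cusp")),
                pattern_truth=_parse_optional_str(row.get("pattern_truth")),
            )
        )
    return records


def _parse_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in ("true", "1", "yes")


def _parse_optional_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return str(value)


def results_frame(
    profiles: Sequence[StiffnessProfile], records: Sequence[NoduleRecord]
) -> pd.DataFrame:
    """Join stiffness profiles with nodule records into one row per nodule.

    Columns: identifiers, geometry, covariates, ct_hu, CS10..CS50,
    CE10..CE50, max_strain and the crush-pattern label, in a fixed order.

    Raises :class:`KeyMismatchError` listing orphan ids when the two inputs
    do not match one-to-one.
    """
    by_id = {r.nodule_id: r for r in records}
    profile_ids = [p.nodule_id for p in profiles]
    orphan_profiles = sorted(set(profile_ids) - set(by_id))
    orphan_records = sorted(set(by_id) - set(profile_ids))
    if orphan_profiles or orphan_records:
        raise KeyMismatchError(
            "profiles and records do not match: "
            f"profiles without record {orphan_profiles}, "
            f"records without profile {orphan_records}"
        )
    rows = []
    for p in profiles:
        r = by_id[p.nodule_id]
        row: dict[str, object] = {
            "nodule_id": p.nodule_id,
            "patient_id": r.patient_id,
            "A0_mm2": r.a0_mm2,
            "H0_mm": r.h0_mm,
            "ct_hu": r.ct_hu,
            "dialysis": r.dialysis,
            "cusp": r.cusp,
        }
        for level in p.levels:
            row[f"CS{round(level * 100):d}"] = p.cs(level)
        for level in p.levels:
            row[f"CE{round(level * 100):d}"] = p.ce(level)
        row["max_strain"] = p.max_strain
        row["pattern"] = p.pattern
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(
    profiles: Sequence[StiffnessProfile],
    records: Sequence[NoduleRecord],
    path: str | Path,
) -> pd.DataFrame:
    """Write the joined per-nodule results table to CSV and return it."""
    frame = results_frame(profiles, records)
    frame.to_csv(path, index=False, float_format="%.12g")
    return frame


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a results CSV back into a DataFrame."""
    return pd.read_csv(path)


def read_supplementary_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a supplementary-style XLSX (or CSV) table of per-nodule clinical
    parameters and stiffness values, renaming columns to canonical names via
    ``column_map`` (canonical -> file column)."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path)
    if column_map:
        frame = frame.rename(columns={v: k for k, v in column_map.items()})
    return frame
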