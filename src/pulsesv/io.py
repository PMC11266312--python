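"""CSV/JSON input–output for observations, participants and reports.

Canonical observation CSV dialect: comma-separated, UTF-8, "." decimal,
header ``subject_id,day,posture,condition,sap_mmhg,dap_mmhg,hr_bpm,sv_ml``.
Posture/condition labels are normalised case-insensitively to ``supine`` /
``hut60`` and ``thermoneutral`` / ``hot``. Malformed rows are reported with
their row numbers and reading aborts — never a silent drop.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    SubjectProfile,
    ValidationError,
    parse_condition,
    parse_posture,
)

__all__ = [
    "OBSERVATION_COLUMNS",
    "read_observations",
    "write_observations",
    "read_participants",
    "write_participants",
    "attach_subjects",
    "write_ranking",
    "write_report",
]

OBSERVATION_COLUMNS = (
    "subject_id",
    "day",
    "posture",
    "condition",
    "sap_mmhg",
    "dap_mmhg",
    "hr_bpm",
    "sv_ml",
)

_CSV_TO_FRAME = {
    "sap_mmhg": "sap",
    "dap_mmhg": "dap",
    "hr_bpm": "hr",
    "sv_ml": "sv_measured",
}


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read an observation CSV into the canonical frame (with derived PP)."""
    raw = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in raw.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    frame = raw.rename(columns=_CSV_TO_FRAME)[
        ["subject_id", "day", "posture", "condition", "sap", "dap", "hr", "sv_measured"]
    ].copy()
    bad_rows: list[str] = []
    postures, conditions = [], []
    for i, (p, c) in enumerate(zip(frame["posture"], frame["condition"])):
        try:
            postures.append(parse_posture(p).value)
            conditions.append(parse_condition(c).value)
        except ValidationError as exc:
            bad_rows.append(f"row {i}: {exc}")
            postures.append(None)
            conditions.append(None)
    frame["posture"] = postures
    frame["condition"] = conditions
    for col in ("sap", "dap", "hr", "sv_measured"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        for i in np.flatnonzero(vals.isna() & frame[col].notna()):
            bad_rows.append(f"row {i}: non-numeric {col} ({frame[col].iloc[i]!r})")
        frame[col] = vals
    ok = frame["sap"].notna() & frame["dap"].notna() & frame["sv_measured"].notna()
    for i in np.flatnonzero(~ok):
        bad_rows.append(f"row {i}: missing pressure or SV value")
    inverted = ok & ~((frame["sap"] > frame["dap"]) & (frame["dap"] > 0))
    for i in np.flatnonzero(inverted):
        bad_rows.append(
            f"row {i}: requires sap > dap > 0 "
            f"(sap={frame['sap'].iloc[i]}, dap={frame['dap'].iloc[i]})"
        )
    nonpos_sv = ok & ~(frame["sv_measured"] > 0)
    for i in np.flatnonzero(nonpos_sv):
        bad_rows.append(f"row {i}: non-positive measured SV")
    if bad_rows:
        shown = "; ".join(bad_rows[:20])
        more = f" (+{len(bad_rows) - 20} more)" if len(bad_rows) > 20 else ""
        raise ValidationError(f"{path}: {len(bad_rows)} malformed rows: {shown}{more}")
    frame["day"] = frame["day"].astype(int)
    frame["pp"] = frame["sap"] - frame["dap"]
    return frame


def write_observations(frame: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical frame back to the documented CSV schema."""
    out = pd.DataFrame(
        {
            "subject_id": frame["subject_id"],
            "day": frame["day"],
            "posture": frame["posture"],
            "condition": frame["condition"],
            "sap_mmhg": frame["sap"],
            "dap_mmhg": frame["dap"],
            "hr_bpm": frame["hr"],
            "sv_ml": frame["sv_measured"],
        }
    )
    out.to_csv(path, index=False)


def read_participants(path: str | Path, bsa_method: str = "dubois") -> list[SubjectProfile]:
    raw = pd.read_csv(path)
    needed = ["subject_id", "age_y", "height_m", "weight_kg"]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return [
        SubjectProfile(
            subject_id=str(row.subject_id),
            age=float(row.age_y),
            height=float(row.height_m),
            weight=float(row.weight_kg),
            bsa_method=bsa_method,
        )
        for row in raw.itertuples()
    ]


def write_participants(participants: list[SubjectProfile], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in participants],
            "age_y": [p.age for p in participants],
            "height_m": [p.height for p in participants],
            "weight_kg": [p.weight for p in participants],
            "bsa_m2": [p.bsa for p in participants],
            "bmi_kg_m2": [p.bmi for p in participants],
        }
    ).to_csv(path, index=False)


def attach_subjects(
    frame: pd.DataFrame, participants: list[SubjectProfile]
) -> pd.DataFrame:
    """Join subject anthropometry columns onto an observation frame."""
    anthro = pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in participants],
            "age": [p.age for p in participants],
            "height": [p.height for p in participants],
            "weight": [p.weight for p in participants],
            "bsa": [p.bsa for p in participants],
            "bmi": [p.bmi for p in participants],
        }
    )
    unknown = set(frame["subject_id"]) - set(anthro["subject_id"])
    if unknown:
        raise ValidationError(f"observations reference unknown subjects: {sorted(unknown)}")
    merged = frame.merge(anthro, on="subject_id", how="left", validate="many_to_one")
    merged.index = frame.index
    return merged


def write_ranking(table, path: str | Path) -> None:
    """RankingTable → CSV (and a sibling .json with the same rows)."""
    path = Path(path)
    df = table.to_frame()
    df.insert(0, "stratum", table.stratum)
    df.to_csv(path, index=False)
    with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(
            {"stratum": table.stratum, "rows": [dict(r) for r in table.rows]},
            fh,
            indent=2,
            default=float,
        )


def write_report(report: dict, path: str | Path) -> None:
    """Stratified report (stratum label → RankingTable) → one JSON document."""
    doc = {
        label: {"rows": [dict(r) for r in table.rows], "best": dict(table.best)}
        for label, table in report.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, default=float)
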