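"""CSV (and XLSX) interchange with schema validation.

All pipeline stages exchange plain CSV tables.  Readers validate the schema
eagerly and raise :class:`SchemaError` naming the missing column or the
offending line, so malformed inputs fail at the boundary rather than deep in
an analysis.  An XLSX ingest shim with a caller-supplied column mapping is
provided for spreadsheet-shaped study exports.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .laterality import LEFT, RIGHT, PreferenceRecord
from .simulate import ANSWER_SETS, MISSING_ANSWER, PARAMS

__all__ = [
    "SchemaError",
    "STRIDE_COLUMNS",
    "QUESTIONNAIRE_COLUMNS",
    "PREFERENCE_COLUMNS",
    "read_stride_table",
    "write_stride_table",
    "read_trial_summaries",
    "write_trial_summaries",
    "read_questionnaire",
    "write_questionnaire",
    "read_preference",
    "write_preference",
    "read_visit_xlsx",
    "write_report",
]

STRIDE_COLUMNS = [
    "horse_id", "visit", "stride_index", *PARAMS, "stride_duration", "surface",
]
QUESTIONNAIRE_COLUMNS = ["horse_id", "visit", *ANSWER_SETS.keys()]
PREFERENCE_COLUMNS = ["horse_id", "obs_index", "label", "valid"]

_NUMERIC_STRIDE = ["visit", "stride_index", *PARAMS, "stride_duration"]


class SchemaError(ValueError):
    """A file does not conform to its documented schema; names the location."""


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")


def _numeric(df: pd.DataFrame, col: str, path, integer: bool = False) -> pd.Series:
    converted = pd.to_numeric(df[col], errors="coerce")
    bad = converted.isna() & df[col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise SchemaError(
            f"{path}: line {line}: non-numeric value {df[col][bad.idxmax()]!r}"
            f" in column {col!r}"
        )
    if converted.isna().any():
        line = int(converted.isna().idxmax()) + 2
        raise SchemaError(f"{path}: line {line}: missing value in column {col!r}")
    return converted.astype(int) if integer else converted.astype(float)


def read_stride_table(path) -> pd.DataFrame:
    """Read and validate a per-stride parameter table."""
    df = _read_csv(path)
    _require_columns(df, STRIDE_COLUMNS, path)
    out = pd.DataFrame({"horse_id": df["horse_id"].astype(str)})
    for col in _NUMERIC_STRIDE:
        out[col] = _numeric(df, col, path, integer=col in ("visit", "stride_index"))
    surf = df["surface"].astype(str).str.strip().str.lower()
    bad = ~surf.isin(["soft", "hard"])
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise SchemaError(
            f"{path}: line {line}: surface must be soft or hard,"
            f" got {df['surface'][bad.idxmax()]!r}"
        )
    out["surface"] = surf
    return out[STRIDE_COLUMNS]


def write_stride_table(path, table: pd.DataFrame) -> None:
    table[STRIDE_COLUMNS].to_csv(path, index=False)


def read_trial_summaries(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require_columns(df, ["horse_id", "visit", *PARAMS, "tas"], path)
    out = pd.DataFrame({"horse_id": df["horse_id"].astype(str)})
    for col in df.columns:
        if col in ("horse_id", "surface", "any_asymmetric") or col.endswith("_class"):
            out[col] = df[col]
        else:
            out[col] = _numeric(df, col, path, integer=col in ("visit",) or col.endswith(("_n_used", "_n_removed")))
    if "any_asymmetric" in out:
        out["any_asymmetric"] = out["any_asymmetric"].astype(str).str.lower().eq("true")
    return out


def write_trial_summaries(path, summaries: pd.DataFrame) -> None:
    summaries.to_csv(path, index=False)


def read_questionnaire(path) -> pd.DataFrame:
    """Read a questionnaire table, validating answer tokens per question."""
    df = _read_csv(path)
    _require_columns(df, QUESTIONNAIRE_COLUMNS, path)
    out = pd.DataFrame(
        {
            "horse_id": df["horse_id"].astype(str),
            "visit": _numeric(df, "visit", path, integer=True),
        }
    )
    for q, levels in ANSWER_SETS.items():
        ans = df[q].astype(str).str.strip().str.lower()
        allowed = set(levels) | {MISSING_ANSWER, "no perception", "did not answer"}
        bad = ~ans.isin(allowed)
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise SchemaError(
                f"{path}: line {line}: unknown answer token {df[q][bad.idxmax()]!r}"
                f" for question {q}"
            )
        out[q] = ans
    return out


def write_questionnaire(path, answers: pd.DataFrame) -> None:
    answers[QUESTIONNAIRE_COLUMNS].to_csv(path, index=False)


def read_preference(path) -> List[PreferenceRecord]:
    """Read a long preference-observation table into per-horse records."""
    df = _read_csv(path)
    _require_columns(df, PREFERENCE_COLUMNS, path)
    labels = df["label"].astype(str).str.strip().str.upper()
    bad = ~labels.isin([LEFT, RIGHT])
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise SchemaError(
            f"{path}: line {line}: label must be LEFT or RIGHT,"
            f" got {df['label'][bad.idxmax()]!r}"
        )
    valid = _numeric(df, "valid", path, integer=True)
    if not valid.isin([0, 1]).all():
        line = int((~valid.isin([0, 1])).idxmax()) + 2
        raise SchemaError(f"{path}: line {line}: valid must be 0 or 1")
    obs_index = _numeric(df, "obs_index", path, integer=True)
    work = pd.DataFrame(
        {
            "horse_id": df["horse_id"].astype(str),
            "obs_index": obs_index, "label": labels, "valid": valid,
        }
    )
    records = []
    for horse_id, grp in work.groupby("horse_id", sort=True):
        grp = grp.sort_values("obs_index")
        records.append(
            PreferenceRecord(
                horse_id=str(horse_id),
                observations=list(grp.loc[grp["valid"] == 1, "label"]),
                n_invalid=int((grp["valid"] == 0).sum()),
            )
        )
    return records


def write_preference(path, records: Sequence[PreferenceRecord]) -> None:
    rows = []
    for r in records:
        for i, label in enumerate(r.observations):
            rows.append(
                {"horse_id": r.horse_id, "obs_index": i, "label": label, "valid": 1}
            )
        for j in range(r.n_invalid):
            rows.append(
                {
                    "horse_id": r.horse_id, "obs_index": len(r.observations) + j,
                    "label": LEFT, "valid": 0,
                }
            )
    pd.DataFrame(rows, columns=PREFERENCE_COLUMNS).to_csv(path, index=False)


def read_waveform(path) -> pd.DataFrame:
    """Read a sampled displacement waveform (time, head_z, pelvis_z in mm)."""
    df = _read_csv(path)
    _require_columns(df, ["time", "head_z", "pelvis_z"], path)
    out = pd.DataFrame({c: _numeric(df, c, path) for c in ("time", "head_z", "pelvis_z")})
    if (out["time"].diff().dropna() <= 0).any():
        raise SchemaError(f"{path}: time column must be strictly increasing")
    return out


def write_waveform(path, signal) -> None:
    pd.DataFrame(
        {"time": signal.time, "head_z": signal.head_z, "pelvis_z": signal.pelvis_z}
    ).to_csv(path, index=False)


def read_stance_events(path) -> List[tuple]:
    """Read stance annotations: (time, limb) with limb right_fore/left_fore."""
    df = _read_csv(path)
    _require_columns(df, ["time", "limb"], path)
    times = _numeric(df, "time", path)
    limbs = df["limb"].astype(str).str.strip().str.lower()
    bad = ~limbs.isin(["right_fore", "left_fore"])
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise SchemaError(
            f"{path}: line {line}: limb must be right_fore or left_fore,"
            f" got {df['limb'][bad.idxmax()]!r}"
        )
    return list(zip(times.tolist(), limbs.tolist()))


def write_stance_events(path, events: Sequence[tuple]) -> None:
    pd.DataFrame(events, columns=["time", "limb"]).to_csv(path, index=False)


def read_visit_xlsx(path, column_map: Dict[str, str], sheet: Optional[str] = None
                    ) -> pd.DataFrame:
    """Ingest a spreadsheet-shaped study export.

    ``column_map`` maps the spreadsheet's column headers to the package's
    visit-record column names (horse_id, visit, hdmin, ..., tas, q1...).
    Unmapped columns are dropped; mapped columns missing from the sheet
    raise a :class:`SchemaError`.
    """
    df = pd.read_excel(path, sheet_name=sheet or 0)
    missing = [src for src in column_map if src not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    return df[list(column_map)].rename(columns=column_map)


def write_report(out_dir, tables: Dict[str, pd.DataFrame]) -> List[str]:
    """Write each report table as <name>.csv under ``out_dir``; returns paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for name, table in tables.items():
        p = os.path.join(out_dir, f"{name}.csv")
        table.to_csv(p, index=False)
        paths.append(p)
    return paths
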