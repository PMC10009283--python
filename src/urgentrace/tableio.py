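"""Reading and writing canonical trial-table CSV files.

The canonical schema has one row per trial and the header
``monkey_id,session_id,trial_index,trial_type,target_color,
target_angle_deg,eccentricity_deg,gap_ms,rt_ms,correct,valid``.
Extra columns (e.g. ``pt_ms``, ``choice_side``) round-trip untouched.
An adapter hook (``column_map``) renames a foreign layout's columns onto
the canonical names, so externally deposited tables can be analyzed
without rewriting them.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["REQUIRED_COLUMNS", "read_trial_table", "write_trial_table"]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "monkey_id",
    "session_id",
    "trial_index",
    "trial_type",
    "target_color",
    "target_angle_deg",
    "eccentricity_deg",
    "gap_ms",
    "rt_ms",
    "correct",
    "valid",
)

_NUMERIC = ("trial_index", "target_angle_deg", "eccentricity_deg", "gap_ms", "rt_ms")
_BOOLEAN = ("correct", "valid")
_TRIAL_TYPES = {"congruent", "symmetric", "incongruent"}

#: Plausibility bounds for flagging, not rejecting, rows.
GAP_RANGE = (0.0, 1000.0)
RT_RANGE = (0.0, 2000.0)


def _coerce_bool(series: pd.Series) -> pd.Series:
    mapping = {
        "1": True, "0": False, "true": True, "false": False,
        "True": True, "False": False, 1: True, 0: False,
        True: True, False: False, 1.0: True, 0.0: False,
    }
    out = series.map(mapping)
    if out.isna().any():
        bad = series[out.isna()].index
        raise ValueError(
            f"column {series.name!r}: unparseable boolean value(s) at "
            f"line(s) {[i + 2 for i in bad[:10]]}"
        )
    return out.astype(bool)


def read_trial_table(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a trial table, validating the canonical schema.

    Parameters
    ----------
    path : path to a CSV file with a header row.
    column_map : optional adapter mapping ``{source_column: canonical_column}``
        for files in a foreign layout.

    Raises ``ValueError`` naming any missing required column, and listing
    (1-based, header-inclusive) line numbers of rows whose numeric fields
    do not parse.  Rows with out-of-range gap or RT are kept but flagged
    ``valid = False`` and logged.
    """
    df = pd.read_csv(path, dtype=object, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"trial table {path} is missing required column {col!r}")

    bad_lines: list[int] = []
    for col in _NUMERIC:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & numeric.isna()
        bad_lines.extend(int(i) + 2 for i in df.index[bad])
        if not bad.any():
            # astype(float) parses each value with full round-trip precision
            df[col] = df[col].astype(float)
    if bad_lines:
        raise ValueError(
            f"trial table {path}: malformed numeric value(s) at line(s) "
            f"{sorted(set(bad_lines))[:20]}"
        )
    for col in _BOOLEAN:
        df[col] = _coerce_bool(df[col])
    df["trial_index"] = df["trial_index"].astype(int)

    unknown = set(df["trial_type"].unique()) - _TRIAL_TYPES
    if unknown:
        raise ValueError(f"trial table {path}: unknown trial_type value(s) {sorted(unknown)}")

    gap = df["gap_ms"].to_numpy(dtype=float)
    rt = df["rt_ms"].to_numpy(dtype=float)
    out_of_range = (
        (gap < GAP_RANGE[0]) | (gap > GAP_RANGE[1])
        | (np.isfinite(rt) & ((rt < RT_RANGE[0]) | (rt > RT_RANGE[1])))
    )
    if out_of_range.any():
        lines = [int(i) + 2 for i in df.index[out_of_range]]
        log.warning(
            "trial table %s: %d row(s) with out-of-range gap or RT flagged "
            "invalid (lines %s)", path, int(out_of_range.sum()), lines[:20],
        )
        df.loc[out_of_range, "valid"] = False

    # extra numeric columns (pt_ms etc.) parse opportunistically
    for col in df.columns:
        if col not in REQUIRED_COLUMNS:
            maybe = pd.to_numeric(df[col], errors="coerce")
            parseable = maybe.notna() | df[col].isna()
            if parseable.all() and maybe.notna().any():
                df[col] = df[col].astype(float)
    return df


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as canonical CSV (booleans as 0/1)."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"table is missing required column {col!r}")
    out = table.copy()
    for col in _BOOLEAN:
        out[col] = out[col].astype(int)
    cols = list(REQUIRED_COLUMNS) + [c for c in out.columns if c not in REQUIRED_COLUMNS]
    out[cols].to_csv(path, index=False)
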