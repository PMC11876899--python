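"""Trial-table readers/writers with validation.

The interchange format is a flat CSV/TSV, one row per trial, with columns
``subject_id, group, trial_index, status, ms1, mo1, ms2, mo2, choice, rt``
(``group`` optional).  RTs are seconds; a millisecond-scale column is
rejected with a unit heuristic rather than silently converted.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_trials", "write_trials", "TrialValidationError"]

REQUIRED_COLUMNS = ("subject_id", "trial_index", "status", "ms1", "mo1", "ms2", "mo2")
VALID_STATUS = {"better", "equal", "worse"}


class TrialValidationError(ValueError):
    pass


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial table (CSV, or TSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"missing required columns: {missing}")
    df["status"] = df["status"].astype(str).str.strip().str.lower()
    bad_status = ~df["status"].isin(VALID_STATUS)
    if bad_status.any():
        rows = df.index[bad_status].tolist()[:10]
        raise TrialValidationError(
            f"unknown status labels at rows {rows}: "
            f"{sorted(df.loc[bad_status, 'status'].unique())}"
        )
    for col in ("ms1", "mo1", "ms2", "mo2"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if "rt" in df.columns and df["rt"].notna().any():
        rt = df["rt"].dropna()
        if not (rt > 0).all():
            rows = df.index[df["rt"] <= 0].tolist()[:10]
            raise TrialValidationError(f"non-positive RTs at rows {rows}")
        if rt.median() > 100:
            raise TrialValidationError(
                f"median RT {rt.median():.0f} looks like milliseconds; this reader "
                "expects seconds"
            )
    if "choice" in df.columns and df["choice"].notna().any():
        vals = set(df["choice"].dropna().unique())
        if not vals <= {0, 1}:
            raise TrialValidationError(f"choice must be 0/1, found {sorted(vals)}")
    return df


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    cols = [
        c
        for c in (
            "subject_id",
            "group",
            "trial_index",
            "status",
            "ms1",
            "mo1",
            "ms2",
            "mo2",
            "choice",
            "rt",
            "censored",
        )
        if c in df.columns
    ]
    df[cols].to_csv(path, index=False)
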