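"""CSV schemas: trial logs, estimates, summation tables, cohort manifests.

All files are plain UTF-8 CSV with a header row and '.' decimal separator.
The trial-log schema (one row per trial) is the interchange format for
measured or simulated sessions:

    subject_id, condition {NDE, DE, BIN}, trial_index, frequency_cpd,
    contrast, correct {0, 1}

Unknown columns are preserved on round trip; malformed rows raise errors
naming the offending line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .engine import Stimulus, TrialRecord
from .observers import CONDITIONS, Cohort

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "ESTIMATES_COLUMNS",
    "SUMMATION_COLUMNS",
    "read_trial_log",
    "write_trial_log",
    "trial_records",
    "write_estimates",
    "write_summation",
    "write_cohort_manifest",
]

TRIAL_LOG_COLUMNS = (
    "subject_id",
    "condition",
    "trial_index",
    "frequency_cpd",
    "contrast",
    "correct",
)

ESTIMATES_COLUMNS = (
    "subject_id",
    "condition",
    "peak_gain",
    "peak_frequency_cpd",
    "bandwidth",
    "truncation",
    "aulcsf",
    "csf_acuity_cpd",
    "ci_width_683",
)

SUMMATION_COLUMNS = (
    "subject_id",
    "group",
    "fuses",
    "aulcsf_nde",
    "aulcsf_de",
    "aulcsf_bin",
    "summation_index",
    "p_nde",
    "p_de",
    "p_expected",
    "classification",
)


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV.

    Returns the validated DataFrame (extra columns preserved).  Raises
    ``ValueError`` naming the first offending data row (1-based, counting
    the header as line 1) for malformed values.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log {path}: missing columns {missing}")
    if df.empty:
        return df

    def bad(mask: pd.Series, what: str) -> None:
        if mask.any():
            row = int(mask.idxmax()) + 2  # header is line 1
            raise ValueError(f"trial log {path}, line {row}: {what}")

    bad(~df["condition"].isin(CONDITIONS), f"condition not in {CONDITIONS}")
    for col in ("trial_index", "frequency_cpd", "contrast", "correct"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad(vals.isna(), f"non-numeric {col}")
        df[col] = vals
    bad(df["trial_index"] < 1, "trial_index must be >= 1")
    bad(df["frequency_cpd"] <= 0, "frequency_cpd must be > 0")
    bad((df["contrast"] <= 0) | (df["contrast"] > 1), "contrast outside (0, 1]")
    bad(~df["correct"].isin([0, 1]), "correct must be 0 or 1")
    df["trial_index"] = df["trial_index"].astype(int)
    df["correct"] = df["correct"].astype(int)
    return df


def write_trial_log(
    sessions: Mapping[tuple[str, str], Sequence[TrialRecord]] | pd.DataFrame,
    path,
) -> None:
    """Write sessions (or an already-assembled DataFrame) as a trial log."""
    if isinstance(sessions, pd.DataFrame):
        df = sessions
    else:
        rows = [
            {
                "subject_id": sid,
                "condition": cond,
                "trial_index": t.trial_index,
                "frequency_cpd": t.stimulus.frequency,
                "contrast": t.stimulus.contrast,
                "correct": int(t.correct),
            }
            for (sid, cond), trials in sessions.items()
            for t in trials
        ]
        df = pd.DataFrame(rows, columns=list(TRIAL_LOG_COLUMNS))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def trial_records(
    df: pd.DataFrame, subject_id: str, condition: str
) -> list[TrialRecord]:
    """Extract one session's TrialRecords from a trial-log DataFrame."""
    sub = df[(df["subject_id"] == subject_id) & (df["condition"] == condition)]
    sub = sub.sort_values("trial_index")
    return [
        TrialRecord(
            trial_index=int(r.trial_index),
            stimulus=Stimulus(
                frequency=float(r.frequency_cpd), contrast=float(r.contrast)
            ),
            correct=bool(r.correct),
        )
        for r in sub.itertuples()
    ]


def write_estimates(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, columns=list(ESTIMATES_COLUMNS))


def write_summation(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, columns=list(SUMMATION_COLUMNS))


def write_cohort_manifest(cohort: Cohort, path) -> None:
    """Ground-truth cohort table: group, fusion, per-eye CSF parameters."""
    rows = []
    for o in cohort.observers:
        row = {"subject_id": o.subject_id, "group": o.group,
               "fuses": int(o.fuses), "regime": o.regime.kind,
               "regime_factor": o.regime.factor}
        for cond, csf in (("nde", o.csf_nde), ("de", o.csf_de)):
            for k, v in csf.as_dict().items():
                row[f"{cond}_{k}"] = v
        rows.append(row)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
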