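"""Trial-record CSV interchange: schema validation, reading and writing.

The schema is one row per behavioral trial:

    subject_id, cohort, condition, block, trial_index, tone, tone_hz,
    reward_map_variant, response, correct, rt_ms, outcome,
    scheduled_mid_outcome

RTs are serialized as integer milliseconds (empty for missed trials);
``correct`` is defined only for unambiguous tones (the mid-tone outcome is
random, so mid-tone choice is a bias measure, not an accuracy one).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

__all__ = ["SCHEMA_COLUMNS", "read_trials", "write_trials", "SchemaError"]

SCHEMA_COLUMNS = [
    "subject_id", "cohort", "condition", "block", "trial_index", "tone",
    "tone_hz", "reward_map_variant", "response", "correct", "rt_ms",
    "outcome", "scheduled_mid_outcome",
]

_TONES = {"low", "mid", "high"}
_RESPONSES = {"low", "high", "none"}
_CONDITIONS = {"neutral", "safe", "threat"}


class SchemaError(ValueError):
    """A trial-record file violates the interchange schema."""


def write_trials(records: pd.DataFrame, path) -> None:
    """Serialize trial records (column order fixed; NaNs as empty fields)."""
    out = records.copy()
    missing = [c for c in SCHEMA_COLUMNS if c not in out.columns]
    if missing:
        raise SchemaError(f"records missing columns: {missing}")
    out = out[SCHEMA_COLUMNS]
    for col in ("rt_ms", "correct"):
        out[col] = out[col].map(lambda x: "" if pd.isna(x) else str(int(x)))
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-record CSV.

    Raises :class:`SchemaError` naming the offending column or the 1-based
    data row numbers of malformed records.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "cohort": str,
                                  "condition": str, "tone": str,
                                  "response": str, "outcome": str,
                                  "scheduled_mid_outcome": str},
                     keep_default_na=True)
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")

    bad = {}

    def flag(mask, reason):
        for i in np.flatnonzero(np.asarray(mask)):
            bad.setdefault(int(i) + 1, []).append(reason)

    flag(~df["tone"].isin(_TONES), "unknown tone")
    flag(~df["response"].isin(_RESPONSES), "unknown response")
    flag(~df["condition"].isin(_CONDITIONS), "unknown condition")
    for col in ("block", "trial_index", "tone_hz", "reward_map_variant"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        flag(coerced.isna(), f"non-integer {col}")
        df[col] = coerced
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    df["rt_ms"] = rt
    responded = df["response"] != "none"
    flag(responded & rt.isna(), "responded trial without rt_ms")
    flag(~responded & rt.notna(), "rt_ms set on a missed trial")
    flag(responded & (rt <= 0), "non-positive rt_ms")
    corr = pd.to_numeric(df["correct"], errors="coerce")
    df["correct"] = corr
    unamb = df["tone"].isin({"low", "high"})
    flag(unamb & responded & ~corr.isin([0, 1]), "unambiguous responded trial needs correct in {0,1}")
    flag((df["tone"] == "mid") & corr.notna(), "correct must be empty for mid tones")

    dupes = df.duplicated(subset=["subject_id", "block", "trial_index"], keep=False)
    flag(dupes, "duplicate (subject, block, trial) key")

    if bad:
        lines = "; ".join(f"row {r}: {', '.join(msgs)}" for r, msgs in
                          sorted(bad.items())[:20])
        raise SchemaError(f"{len(bad)} malformed rows: {lines}")
    return df


def write_provenance(path, **fields) -> None:
    """Reproducibility sidecar: config, seeds, software version."""
    from . import __version__

    payload = {"tonebias_version": __version__, **fields}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
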