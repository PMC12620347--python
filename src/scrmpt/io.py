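"""Delimited-text input/output and aggregation helpers.

All tables are plain tab-separated text.  Schemas:

* trials: ``participant_id, group, condition, probe, response``
  (lower-case tokens ``intact|related|unrelated`` for probe/response)
* participant metadata: ``participant_id, group, education_years``
* Stroop trials: ``participant_id, condition, rt_ms, correct``
  (condition ``consistent|inconsistent``; correct 0/1)
* fixations: ``participant_id, trial, x, y, onset_ms, duration_ms``
* observations (path models): one row per participant, free columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .tree import PROBE_ORDER, RESPONSE_ORDER, CountTable

__all__ = [
    "read_table",
    "write_table",
    "validate_trials",
    "aggregate_trials",
    "counts_frame_to_arrays",
    "count_table_from_row",
]

TRIAL_COLUMNS = ["participant_id", "group", "condition", "probe", "response"]
COUNT_COLUMNS = [
    f"n_{p.value}_{r.value}" for p in PROBE_ORDER for r in RESPONSE_ORDER
]


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated table with a header row."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-level schema and token sets; return the frame."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing columns: {missing}")
    valid = {p.value for p in PROBE_ORDER}
    bad_probe = set(trials["probe"].unique()) - valid
    bad_resp = set(trials["response"].unique()) - valid
    if bad_probe:
        raise ValueError(f"unknown probe tokens: {sorted(bad_probe)}")
    if bad_resp:
        raise ValueError(f"unknown response tokens: {sorted(bad_resp)}")
    return trials


def aggregate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Aggregate trials to per participant x condition response counts.

    Returns one row per (participant_id, group, condition) with the nine
    ``n_<probe>_<response>`` count columns in canonical order — the
    serialized CountTable form.
    """
    validate_trials(trials)
    keys = ["participant_id", "group", "condition"]
    rows = []
    for key_vals, sub in trials.groupby(keys, sort=True):
        tab = CountTable.from_responses(sub["probe"], sub["response"])
        row = dict(zip(keys, key_vals))
        row.update(dict(zip(COUNT_COLUMNS, tab.counts.ravel().tolist())))
        rows.append(row)
    return pd.DataFrame(rows, columns=keys + COUNT_COLUMNS)


def count_table_from_row(row: pd.Series) -> CountTable:
    """Rebuild a CountTable from one aggregated row."""
    arr = np.asarray([row[c] for c in COUNT_COLUMNS], dtype=np.int64)
    return CountTable(arr.reshape(3, 3))


def counts_frame_to_arrays(counts: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Stack an aggregated count frame into an (n, 3, 3) array.

    Returns the array and the participant_id list in row order.
    """
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"count frame is missing columns: {missing}")
    arr = counts[COUNT_COLUMNS].to_numpy(dtype=np.int64).reshape(-1, 3, 3)
    ids = counts["participant_id"].tolist() if "participant_id" in counts else list(
        range(len(counts))
    )
    return arr, ids
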