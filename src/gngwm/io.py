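"""Reading and writing trial tables and parameter tables.

Trial tables are delimited text with a fixed header (the columns of
:data:`gngwm.task.TRIAL_COLUMNS`); missing actions/outcomes are empty
fields.  Parameter tables are delimited text keyed by ``subject_id``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .task import TRIAL_COLUMNS

_DTYPES = {
    "subject_id": "string",
    "task": "string",
    "block": "Int64",
    "trial_index": "Int64",
    "cue_id": "Int64",
    "cue_type": "string",
    "required_action": "string",
    "action": "string",
    "outcome": "Int64",
    "feedback_valid": "boolean",
    "nback_truth": "string",
}


def write_trials(trials: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    trials[list(TRIAL_COLUMNS)].to_csv(path, sep=sep, index=False)


def read_trials(path: str | Path, sep: str = ",") -> pd.DataFrame:
    trials = pd.read_csv(path, sep=sep, dtype=_DTYPES)
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return trials[list(TRIAL_COLUMNS)]


def write_params(params: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    if "subject_id" not in params.columns:
        raise ValueError("parameter table must carry subject_id")
    params.to_csv(path, sep=sep, index=False)


def read_params(path: str | Path, sep: str = ",") -> pd.DataFrame:
    params = pd.read_csv(path, sep=sep)
    if "subject_id" not in params.columns:
        raise ValueError("parameter table must carry subject_id")
    return params
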